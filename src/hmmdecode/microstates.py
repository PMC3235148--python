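"""Momentary-state segmentation and dwell-time statistics.

Under a fitted model, each trial decodes into a sequence of hidden states —
quasi-stable multichannel voltage configurations.  A *momentary state* is a
maximal run of consecutive frames in the same state; its duration in
milliseconds is the run length divided by the sampling rate.  Comparing
mean state durations between sessions requires segmenting both datasets
with the *same* model (enforced here through the model fingerprint), so
that a duration difference cannot be an artifact of different state counts.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .hmm import GaussianHMM
from .io import EpochSet

__all__ = [
    "SegmentationResult",
    "segment",
    "run_lengths",
    "compare_durations",
    "plot_state_raster",
]


def run_lengths(path: np.ndarray) -> np.ndarray:
    """Lengths of the maximal constant runs of a state path (sum equals L)."""
    path = np.asarray(path)
    if path.size == 0:
        return np.array([], dtype=int)
    change = np.flatnonzero(np.diff(path) != 0)
    bounds = np.concatenate([[-1], change, [path.size - 1]])
    return np.diff(bounds).astype(int)


@dataclass
class SegmentationResult:
    """Per-trial state paths, run lengths and mean state durations (ms)."""

    trial_ids: list[str]
    paths: list[np.ndarray]
    runs: list[np.ndarray]
    mean_duration_ms: np.ndarray  # per trial
    sampling_rate_hz: float
    model_fingerprint: str

    @property
    def grand_mean_ms(self) -> float:
        return float(np.mean(self.mean_duration_ms))

    def __len__(self) -> int:
        return len(self.paths)


def segment(
    model: GaussianHMM, es: EpochSet, decoder: str = "viterbi"
) -> SegmentationResult:
    """Segment every trial of ``es`` into momentary states under ``model``.

    ``decoder`` is ``viterbi`` (global MAP path, default) or ``posterior``
    (per-frame argmax of the posterior marginals).
    """
    paths = [model.decode(t.data, method=decoder) for t in es]
    runs = [run_lengths(p) for p in paths]
    frame_ms = 1000.0 / es.sampling_rate_hz
    mean_ms = np.array([float(np.mean(r)) * frame_ms for r in runs])
    return SegmentationResult(
        trial_ids=[t.trial_id for t in es],
        paths=paths,
        runs=runs,
        mean_duration_ms=mean_ms,
        sampling_rate_hz=es.sampling_rate_hz,
        model_fingerprint=model.fingerprint,
    )


def compare_durations(
    seg1: SegmentationResult, seg2: SegmentationResult
) -> tuple[tuple[float, float], float]:
    """Welch t-test on per-trial mean state durations of two datasets.

    Both segmentations must come from the same model (fingerprints are
    compared), so the duration contrast reflects the data, not different
    state counts.  Returns ((grand mean 1 ms, grand mean 2 ms), p).
    """
    if seg1.model_fingerprint != seg2.model_fingerprint:
        raise ValueError(
            "segmentations come from different models; duration comparison "
            "requires applying the same model to both datasets"
        )
    a, b = seg1.mean_duration_ms, seg2.mean_duration_ms
    if np.array_equal(a, b):
        return (seg1.grand_mean_ms, seg2.grand_mean_ms), 1.0
    if np.var(a) == 0 and np.var(b) == 0:
        p = 1.0 if a.mean() == b.mean() else 0.0
    else:
        _, p = stats.ttest_ind(a, b, equal_var=False)
    return (seg1.grand_mean_ms, seg2.grand_mean_ms), float(p)


def plot_state_raster(seg: SegmentationResult, ax=None, cmap: str = "gray"):
    """Grayscale raster of state labels, trials (rows) x time (columns).

    Trials shorter than the longest one are padded with NaN (rendered
    transparent).  Requires matplotlib (optional dependency).
    """
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    lmax = max(p.size for p in seg.paths)
    img = np.full((len(seg.paths), lmax), np.nan)
    for i, p in enumerate(seg.paths):
        img[i, : p.size] = p
    frame_ms = 1000.0 / seg.sampling_rate_hz
    ax.imshow(
        img, aspect="auto", interpolation="nearest", cmap=cmap,
        extent=(0.0, lmax * frame_ms, len(seg.paths), 0.0),
    )
    ax.set_xlabel("time (ms)")
    ax.set_ylabel("trial")
    return ax
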