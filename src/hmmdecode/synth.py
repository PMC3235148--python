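"""Synthetic two-session, two-condition iEEG-like epoch sets.

The generator emulates the statistical structure the decoder is built to
detect, with known ground truth.  A montage of electrode arrays carries
mostly noise contacts; the contacts of the designated *informative* arrays
see state-dependent mean topographies (evoked deflections of ~100 µV on a
~25 µV background, iEEG scale).  Each session has its own generative hidden
Markov chain over those voltage configurations:

* both sessions share the state means of the common states;
* session 2 may scale the emission variance of the informative contacts
  (the covariance effect) and dwell longer in each state (higher
  self-transition), and may carry one extra state;
* the control condition is drawn from a session-invariant model for both
  days, so any control-condition discriminability can only come from
  trial-length differences, not from emission structure.

Trial lengths (= reaction times under the default ``equal_to_length``
coupling) are Gaussian in milliseconds per session, echoing the behavioral
range of a serial reaction-time task (day 1 slower than day 2).

Everything is reproducible from the config seed; hidden state paths are
returned alongside the data for recovery tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
import numpy as np
import pandas as pd

from .hmm import GaussianHMM
from .io import ChannelLayout, EpochSet, Trial

__all__ = [
    "SyntheticConfig",
    "SyntheticDataset",
    "build_layout",
    "build_generators",
    "sample_epochset",
    "paper_like",
    "fast_preset",
    "null_preset",
]


@dataclass(frozen=True)
class SyntheticConfig:
    """Study conditions for the synthetic generator (defaults: the
    paper-like preset — 8 arrays x 8 contacts, one informative array,
    Q=3 vs 4 states, 512 Hz, 60 S- and 20 C-trials per day)."""

    n_arrays: int = 8
    contacts_per_array: int = 8
    informative_arrays: tuple[int, ...] = (0,)
    q_day1: int = 3
    q_day2: int = 4
    noise_sd_uv: float = 25.0
    state_amplitude_uv: float = 100.0
    cov_scale: tuple[float, float] = (1.0, 2.0)
    self_transition: tuple[float, float] = (0.980, 0.9824)
    trial_len_mean_ms: tuple[float, float] = (600.0, 575.0)
    trial_len_sd_ms: tuple[float, float] = (70.0, 70.0)
    n_trials_s: tuple[int, int] = (60, 60)
    n_trials_c: tuple[int, int] = (20, 20)
    rt_coupling: str = "equal_to_length"  # or "independent"
    sampling_rate_hz: float = 512.0
    seed: int = 0

    def __post_init__(self) -> None:
        for p in self.self_transition:
            if not 0.0 < p < 1.0:
                raise ValueError("self-transition probabilities must lie in (0,1)")
        if any(m <= 0 for m in self.trial_len_mean_ms):
            raise ValueError("trial lengths must be positive")
        if not set(self.informative_arrays) <= set(range(self.n_arrays)):
            raise ValueError("informative_arrays must be a subset of the arrays")
        if self.rt_coupling not in ("equal_to_length", "independent"):
            raise ValueError(f"unknown rt_coupling {self.rt_coupling!r}")

    @property
    def n_contacts(self) -> int:
        return self.n_arrays * self.contacts_per_array


def paper_like(seed: int = 0) -> SyntheticConfig:
    """The default study-scale preset (512 Hz)."""
    return SyntheticConfig(seed=seed)


def fast_preset(seed: int = 0, sampling_rate_hz: float = 128.0) -> SyntheticConfig:
    """Same conditions on a coarser time grid: the per-frame self-transition
    probabilities are re-derived so state dwell times in milliseconds are
    preserved at the new sampling rate."""
    base = paper_like(seed)
    ratio = base.sampling_rate_hz / sampling_rate_hz
    p = tuple(1.0 - (1.0 - pk) * ratio for pk in base.self_transition)
    return replace(base, sampling_rate_hz=sampling_rate_hz, self_transition=p)


def null_preset(
    seed: int = 0, sampling_rate_hz: float = 64.0, n_trials_per_day: int = 120
) -> SyntheticConfig:
    """Identical generative models on both days: no covariance effect, no
    dwell effect, equal state counts and equal trial-length distributions.
    Used for null-safety checks (areas should center on 0.5)."""
    cfg = fast_preset(seed, sampling_rate_hz)
    return replace(
        cfg,
        q_day2=cfg.q_day1,
        cov_scale=(1.0, 1.0),
        self_transition=(cfg.self_transition[0], cfg.self_transition[0]),
        trial_len_mean_ms=(600.0, 600.0),
        n_trials_s=(n_trials_per_day, n_trials_per_day),
        n_trials_c=(0, 0),
    )


@dataclass
class SyntheticDataset:
    """A sampled dataset with its layout, generators and ground truth."""

    epochs: EpochSet
    layout: ChannelLayout
    true_paths: dict[str, np.ndarray] = field(default_factory=dict)
    generators: tuple[GaussianHMM, GaussianHMM, GaussianHMM] | None = None
    config: SyntheticConfig | None = None


def build_layout(cfg: SyntheticConfig) -> ChannelLayout:
    """Contact ids ``A<array>c<position>`` on ``n_arrays`` linear arrays."""
    rows = [
        {"contact_id": f"A{a}c{p}", "array_id": f"A{a}", "position": p}
        for a in range(cfg.n_arrays)
        for p in range(cfg.contacts_per_array)
    ]
    return ChannelLayout(pd.DataFrame(rows))


def _informative_mask(cfg: SyntheticConfig) -> np.ndarray:
    mask = np.zeros(cfg.n_contacts, dtype=bool)
    for a in cfg.informative_arrays:
        start = a * cfg.contacts_per_array
        mask[start : start + cfg.contacts_per_array] = True
    return mask


def _transition_matrix(q: int, p_self: float) -> np.ndarray:
    if q == 1:
        return np.ones((1, 1))
    A = np.full((q, q), (1.0 - p_self) / (q - 1))
    np.fill_diagonal(A, p_self)
    return A


def build_generators(
    cfg: SyntheticConfig,
) -> tuple[GaussianHMM, GaussianHMM, GaussianHMM]:
    """(day-1 model, day-2 model, session-invariant control model).

    The day models share the means of the common states; day 2 differs only
    through the configured covariance scale on the informative contacts,
    its self-transition probability, and any extra states.  Under the null
    configuration the two day models are identical.
    """
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_contacts
    q_max = max(cfg.q_day1, cfg.q_day2)
    mask = _informative_mask(cfg)
    means_all = np.zeros((q_max, n))
    means_all[:, mask] = rng.normal(
        0.0, cfg.state_amplitude_uv, size=(q_max, int(mask.sum()))
    )

    def _model(q: int, session: int) -> GaussianHMM:
        var = np.full(n, cfg.noise_sd_uv**2)
        var[mask] *= cfg.cov_scale[session]
        covars = np.stack([np.diag(var)] * q)
        return GaussianHMM.from_params(
            startprob=np.full(q, 1.0 / q),
            transmat=_transition_matrix(q, cfg.self_transition[session]),
            means=means_all[:q].copy(),
            covars=covars,
        )

    day1 = _model(cfg.q_day1, 0)
    day2 = _model(cfg.q_day2, 1)
    control = _model(cfg.q_day1, 0)  # session-invariant: the day-1 statistics
    return day1, day2, control


def _sample_path(
    pi: np.ndarray, A: np.ndarray, n_frames: int, rng: np.random.Generator
) -> np.ndarray:
    """Exact chain sampling via geometric dwell times + the embedded jump
    chain (fast for the dwell-dominated transition matrices used here)."""
    q = pi.size
    path = np.empty(n_frames, dtype=int)
    pos = 0
    state = int(rng.choice(q, p=pi))
    while pos < n_frames:
        p_stay = A[state, state]
        if p_stay >= 1.0:
            dwell = n_frames - pos
        else:
            dwell = int(rng.geometric(1.0 - p_stay))
        dwell = min(dwell, n_frames - pos)
        path[pos : pos + dwell] = state
        pos += dwell
        if pos < n_frames:
            off = A[state].copy()
            off[state] = 0.0
            off /= off.sum()
            state = int(rng.choice(q, p=off))
    return path


def _sample_trials(
    model: GaussianHMM,
    n_trials: int,
    day_idx: int,
    condition: str,
    cfg: SyntheticConfig,
    rng: np.random.Generator,
) -> tuple[list[Trial], dict[str, np.ndarray]]:
    rate = cfg.sampling_rate_hz
    sds = np.array([np.sqrt(np.diag(c)) for c in model.covars_])
    trials: list[Trial] = []
    paths: dict[str, np.ndarray] = {}
    for k in range(n_trials):
        length_ms = rng.normal(
            cfg.trial_len_mean_ms[day_idx], cfg.trial_len_sd_ms[day_idx]
        )
        n_frames = max(3, int(round(length_ms * rate / 1000.0)))
        path = _sample_path(model.startprob_, model.transmat_, n_frames, rng)
        data = model.means_[path] + sds[path] * rng.standard_normal(
            (n_frames, model.means_.shape[1])
        )
        if cfg.rt_coupling == "equal_to_length":
            rt = n_frames * 1000.0 / rate
        else:
            rt = max(
                50.0,
                rng.normal(
                    cfg.trial_len_mean_ms[day_idx], cfg.trial_len_sd_ms[day_idx]
                ),
            )
        tid = f"day{day_idx + 1}-{condition}-{k:04d}"
        trials.append(
            Trial(data=data, day=f"day{day_idx + 1}", condition=condition,
                  rt_ms=float(rt), trial_id=tid)
        )
        paths[tid] = path
    return trials, paths


def sample_epochset(cfg: SyntheticConfig) -> SyntheticDataset:
    """Draw the full two-day, two-condition epoch set configured by ``cfg``.

    S-condition trials come from the day-specific models; C-condition trials
    of both days come from the single control model.  Bit-reproducible from
    ``cfg.seed``; ground-truth hidden paths are kept per trial.
    """
    day1, day2, control = build_generators(cfg)
    rng = np.random.default_rng([cfg.seed, 2**20])
    trials: list[Trial] = []
    paths: dict[str, np.ndarray] = {}
    for day_idx, model in ((0, day1), (1, day2)):
        t, p = _sample_trials(model, cfg.n_trials_s[day_idx], day_idx, "S", cfg, rng)
        trials += t
        paths.update(p)
    for day_idx in (0, 1):
        t, p = _sample_trials(
            control, cfg.n_trials_c[day_idx], day_idx, "C", cfg, rng
        )
        trials += t
        paths.update(p)
    layout = build_layout(cfg)
    es = EpochSet(
        trials, sampling_rate_hz=cfg.sampling_rate_hz, contact_ids=layout.contact_ids
    )
    return SyntheticDataset(
        epochs=es,
        layout=layout,
        true_paths=paths,
        generators=(day1, day2, control),
        config=cfg,
    )
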