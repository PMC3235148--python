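"""Epoch containers, channel layouts and epoch extraction.

A *trial* (epoch) is the multichannel voltage segment from fixation-cross
onset to the key press for one stimulus: a ``(n_frames, n_contacts)`` float
matrix in microvolts sampled at a fixed rate (512 Hz by default), tagged with
the recording session (``day1``/``day2``), the task condition (``S`` for the
structured sequence, ``C`` for the pseudo-random control) and the reaction
time in milliseconds.  Trials within one :class:`EpochSet` share the contact
montage and sampling rate but may differ in length.

Data on disk live in one directory per dataset: a tab-separated
``manifest.tsv`` (trial_id, day, condition, rt_ms, n_frames) plus a single
``data.npz`` container holding one matrix per trial keyed by trial_id.
Channel layouts are plain TSV (contact_id, array_id, position, x, y, z).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterator, Sequence

import numpy as np
import pandas as pd

DAYS = ("day1", "day2")
CONDITIONS = ("S", "C")

__all__ = [
    "Trial",
    "EpochSet",
    "ChannelLayout",
    "EventList",
    "select_contacts",
    "extract_epochs",
    "read_epochset",
    "write_epochset",
    "read_layout",
    "write_layout",
]


@dataclass
class Trial:
    """One epoch: voltages ``(n_frames, n_contacts)`` plus metadata."""

    data: np.ndarray
    day: str
    condition: str
    rt_ms: float
    trial_id: str

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2 or self.data.shape[0] < 1:
            raise ValueError(
                f"trial {self.trial_id!r}: data must be a (n_frames>=1, n_contacts) "
                f"matrix, got shape {self.data.shape}"
            )
        if self.rt_ms <= 0:
            raise ValueError(f"trial {self.trial_id!r}: rt_ms must be positive")

    @property
    def n_frames(self) -> int:
        return self.data.shape[0]

    @property
    def n_contacts(self) -> int:
        return self.data.shape[1]


class EpochSet:
    """An ordered collection of variable-length trials on a shared montage."""

    def __init__(
        self,
        trials: Sequence[Trial],
        sampling_rate_hz: float = 512.0,
        contact_ids: Sequence[str] | None = None,
    ) -> None:
        trials = list(trials)
        if sampling_rate_hz <= 0:
            raise ValueError("sampling_rate_hz must be positive")
        widths = {t.n_contacts for t in trials}
        if len(widths) > 1:
            raise ValueError(f"trials disagree on contact count: {sorted(widths)}")
        self.trials = trials
        self.sampling_rate_hz = float(sampling_rate_hz)
        if contact_ids is not None:
            contact_ids = [str(c) for c in contact_ids]
            if trials and len(contact_ids) != trials[0].n_contacts:
                raise ValueError("contact_ids length does not match trial width")
        self.contact_ids = contact_ids

    # -- container protocol -------------------------------------------------
    def __len__(self) -> int:
        return len(self.trials)

    def __iter__(self) -> Iterator[Trial]:
        return iter(self.trials)

    def __getitem__(self, i: int) -> Trial:
        return self.trials[i]

    @property
    def n_contacts(self) -> int:
        if self.trials:
            return self.trials[0].n_contacts
        if self.contact_ids is not None:
            return len(self.contact_ids)
        return 0

    # -- views ---------------------------------------------------------------
    def subset(self, day: str | None = None, condition: str | None = None) -> "EpochSet":
        """Trials matching the given day and/or condition (metadata filter)."""
        kept = [
            t
            for t in self.trials
            if (day is None or t.day == day)
            and (condition is None or t.condition == condition)
        ]
        return EpochSet(kept, self.sampling_rate_hz, self.contact_ids)

    def restrict(self, contacts: Sequence[str] | Sequence[int]) -> "EpochSet":
        """Keep only the given contacts (ids if the set carries ids, else
        column indices); trial data are column-sliced accordingly."""
        if len(contacts) == 0:
            raise ValueError("cannot restrict to an empty contact set")
        if all(isinstance(c, (int, np.integer)) for c in contacts):
            idx = [int(c) for c in contacts]
            ids = (
                [self.contact_ids[i] for i in idx]
                if self.contact_ids is not None
                else None
            )
        else:
            if self.contact_ids is None:
                raise ValueError("EpochSet has no contact_ids; restrict by index")
            pos = {c: i for i, c in enumerate(self.contact_ids)}
            missing = [str(c) for c in contacts if str(c) not in pos]
            if missing:
                raise KeyError(f"unknown contact ids: {missing}")
            idx = [pos[str(c)] for c in contacts]
            ids = [str(c) for c in contacts]
        new_trials = [replace(t, data=t.data[:, idx]) for t in self.trials]
        return EpochSet(new_trials, self.sampling_rate_hz, ids)

    # -- convenience columns -------------------------------------------------
    def data_list(self) -> list[np.ndarray]:
        return [t.data for t in self.trials]

    def days(self) -> np.ndarray:
        return np.array([t.day for t in self.trials])

    def conditions(self) -> np.ndarray:
        return np.array([t.condition for t in self.trials])

    def rts(self) -> np.ndarray:
        return np.array([t.rt_ms for t in self.trials], dtype=float)

    def __repr__(self) -> str:  # pragma: no cover
        return (
            f"EpochSet(n_trials={len(self)}, n_contacts={self.n_contacts}, "
            f"rate={self.sampling_rate_hz} Hz)"
        )


@dataclass
class EventList:
    """Stimulus/response events for epoching a continuous recording.

    Each event is ``(onset_frame, response_frame, day, condition, rt_ms)``
    with ``response_frame > onset_frame``; events must be time-ordered and
    non-overlapping.
    """

    events: list[tuple[int, int, str, str, float]] = field(default_factory=list)

    def __post_init__(self) -> None:
        prev_end = -1
        for ev in self.events:
            onset, response = int(ev[0]), int(ev[1])
            if response <= onset:
                raise ValueError(f"event {ev}: response_frame must exceed onset_frame")
            if onset < prev_end:
                raise ValueError("events must be non-overlapping and time-ordered")
            prev_end = response


class ChannelLayout:
    """Contact -> electrode-array membership with an optional selection mask.

    Backed by a DataFrame with columns ``contact_id, array_id, position``
    (+ optional ``x, y, z`` coordinates and a boolean ``selected`` flag).
    """

    REQUIRED = ("contact_id", "array_id", "position")

    def __init__(self, table: pd.DataFrame) -> None:
        table = table.copy()
        for col in self.REQUIRED:
            if col not in table.columns:
                raise ValueError(f"layout table missing column {col!r}")
        table["contact_id"] = table["contact_id"].astype(str)
        table["array_id"] = table["array_id"].astype(str)
        if table["contact_id"].duplicated().any():
            raise ValueError("duplicate contact_id in layout")
        dup = table.duplicated(subset=["array_id", "position"])
        if dup.any():
            raise ValueError("position indices within an array must be unique")
        if "selected" not in table.columns:
            table["selected"] = False
        self.table = table.reset_index(drop=True)

    @property
    def contact_ids(self) -> list[str]:
        return list(self.table["contact_id"])

    @property
    def array_ids(self) -> list[str]:
        # insertion order of first appearance
        return list(dict.fromkeys(self.table["array_id"]))

    @property
    def n_arrays(self) -> int:
        return len(self.array_ids)

    @property
    def selected_ids(self) -> list[str]:
        return list(self.table.loc[self.table["selected"], "contact_id"])

    def has_coordinates(self) -> bool:
        return all(c in self.table.columns for c in ("x", "y", "z")) and not (
            self.table[["x", "y", "z"]].isna().any().any()
        )

    def contacts_of(self, array_id: str) -> list[str]:
        return list(
            self.table.loc[self.table["array_id"] == str(array_id), "contact_id"]
        )

    def copy(self) -> "ChannelLayout":
        return ChannelLayout(self.table.copy())

    def __repr__(self) -> str:  # pragma: no cover
        return (
            f"ChannelLayout(n_contacts={len(self.table)}, n_arrays={self.n_arrays}, "
            f"n_selected={int(self.table['selected'].sum())})"
        )


def select_contacts(layout: ChannelLayout, strategy: str = "most_distant") -> ChannelLayout:
    """Mark the contacts entering the analysis.

    ``most_distant`` keeps the two extreme contacts of each electrode array —
    the extreme position indices, or the maximally separated Euclidean pair
    when coordinates are present — so each array contributes a couple of
    contacts (16 of 64 on an 8x8 montage).  ``all`` keeps everything;
    ``first`` keeps the lowest-position contact per array.  Idempotent and
    independent of row order.
    """
    if strategy not in ("most_distant", "all", "first"):
        raise ValueError(f"unknown selection strategy {strategy!r}")
    out = layout.copy()
    tab = out.table
    if strategy == "all":
        tab["selected"] = True
        return out
    tab["selected"] = False
    for arr in out.array_ids:
        sub = tab[tab["array_id"] == arr].sort_values("position")
        if strategy == "first":
            tab.loc[sub.index[:1], "selected"] = True
            continue
        if len(sub) == 1:
            warnings.warn(
                f"array {arr!r} has a single contact; selecting it alone",
                stacklevel=2,
            )
            tab.loc[sub.index, "selected"] = True
            continue
        if out.has_coordinates():
            xyz = sub[["x", "y", "z"]].to_numpy(float)
            d = np.linalg.norm(xyz[:, None, :] - xyz[None, :, :], axis=-1)
            i, j = np.unravel_index(np.argmax(d), d.shape)
            pick = sub.index[[min(i, j), max(i, j)]]
        else:
            pick = sub.index[[0, -1]]
        tab.loc[pick, "selected"] = True
    return out


def extract_epochs(
    continuous: np.ndarray,
    events: EventList,
    rate_hz: float,
    id_prefix: str = "trial",
) -> tuple[EpochSet, list[str]]:
    """Slice a continuous ``(time, n_contacts)`` recording into trials.

    Epochs are half-open ``[onset_frame, response_frame)`` with 0-based
    frames.  Events reaching past the recording bounds are rejected and
    reported (second return value), the rest are kept.
    """
    continuous = np.asarray(continuous, dtype=float)
    if continuous.ndim != 2:
        raise ValueError("continuous recording must be 2-D (time x contacts)")
    n_time = continuous.shape[0]
    trials: list[Trial] = []
    rejected: list[str] = []
    for k, (onset, response, day, condition, rt_ms) in enumerate(events.events):
        tid = f"{id_prefix}{k:04d}"
        if onset < 0 or response > n_time:
            rejected.append(f"{tid}: event ({onset}, {response}) outside recording of {n_time} frames")
            continue
        trials.append(
            Trial(
                data=continuous[onset:response].copy(),
                day=day,
                condition=condition,
                rt_ms=float(rt_ms),
                trial_id=tid,
            )
        )
    return EpochSet(trials, sampling_rate_hz=rate_hz), rejected


# ---------------------------------------------------------------------------
# container I/O
# ---------------------------------------------------------------------------

MANIFEST = "manifest.tsv"
DATAFILE = "data.npz"
META = "meta.tsv"


def write_epochset(es: EpochSet, path: str | Path) -> Path:
    """Write an EpochSet as manifest.tsv + data.npz (+ meta.tsv) in ``path``."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    manifest = pd.DataFrame(
        {
            "trial_id": [t.trial_id for t in es],
            "day": [t.day for t in es],
            "condition": [t.condition for t in es],
            "rt_ms": [t.rt_ms for t in es],
            "n_frames": [t.n_frames for t in es],
        }
    )
    manifest.to_csv(path / MANIFEST, sep="\t", index=False)
    np.savez(path / DATAFILE, **{t.trial_id: t.data for t in es})
    meta = {
        "sampling_rate_hz": [es.sampling_rate_hz],
        "contact_ids": [
            ",".join(es.contact_ids) if es.contact_ids is not None else ""
        ],
    }
    pd.DataFrame(meta).to_csv(path / META, sep="\t", index=False)
    return path


def read_epochset(path: str | Path) -> EpochSet:
    """Read an EpochSet written by :func:`write_epochset`.

    Round-trips bit-exactly; a manifest row without a matching matrix (or a
    contact-count mismatch) raises naming the offending trial_id.
    """
    path = Path(path)
    manifest = pd.read_csv(path / MANIFEST, sep="\t", dtype={"trial_id": str})
    meta = pd.read_csv(path / META, sep="\t")
    rate = float(meta["sampling_rate_hz"].iloc[0])
    raw_ids = meta["contact_ids"].iloc[0]
    contact_ids = (
        str(raw_ids).split(",") if isinstance(raw_ids, str) and raw_ids else None
    )
    trials: list[Trial] = []
    with np.load(path / DATAFILE) as data:
        for row in manifest.itertuples(index=False):
            tid = str(row.trial_id)
            if tid not in data:
                raise ValueError(f"manifest trial {tid!r} has no data matrix")
            mat = data[tid]
            if mat.shape[0] != int(row.n_frames):
                raise ValueError(
                    f"trial {tid!r}: manifest says {row.n_frames} frames, "
                    f"data has {mat.shape[0]}"
                )
            trials.append(
                Trial(
                    data=mat,
                    day=str(row.day),
                    condition=str(row.condition),
                    rt_ms=float(row.rt_ms),
                    trial_id=tid,
                )
            )
    return EpochSet(trials, sampling_rate_hz=rate, contact_ids=contact_ids)


def write_layout(layout: ChannelLayout, path: str | Path) -> Path:
    path = Path(path)
    layout.table.to_csv(path, sep="\t", index=False)
    return path


def read_layout(path: str | Path) -> ChannelLayout:
    tab = pd.read_csv(path, sep="\t", dtype={"contact_id": str, "array_id": str})
    if "selected" in tab.columns:
        tab["selected"] = tab["selected"].astype(bool)
    return ChannelLayout(tab)


def read_continuous_edf(path: str | Path) -> tuple[np.ndarray, float, list[str]]:
    """Optional EDF reader: returns (time x channels µV, rate, channel names).

    Requires ``mne``; imported lazily so the core package has no hard
    dependency on it.
    """
    try:
        import mne
    except ImportError as exc:  # pragma: no cover
        raise ImportError("reading EDF requires the optional dependency 'mne'") from exc
    raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
    data = raw.get_data().T * 1e6  # volts -> microvolts
    return data, float(raw.info["sfreq"]), list(raw.ch_names)
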