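"""Assay timeline, cage geometry, pose-table I/O and the likelihood filter.

This module is the shared substrate of the home-cage pipeline.  A recording
session is a 22-hour time-lapse (1 frame/s by default) of a single mouse in a
home cage, structured into four light phases (day / night / night-with-stimuli
/ day) and tiled into 10-minute analysis periods.  Three visual stimuli are
presented during the third phase; at the defaults their onsets fall at the
starts of periods 73, 85 and 97.

Pose tables come in the DeepLabCut wide-CSV dialect (three header rows:
scorer / bodyparts / coords) or a flat per-row layout; both are auto-detected.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
import numpy as np
import pandas as pd

__all__ = [
    "AssayTimeline",
    "CageGeometry",
    "GroupLabel",
    "PoseRecording",
    "FormatError",
    "read_pose_table",
    "write_pose_table",
    "filter_low_likelihood",
    "period_index",
    "phase_of",
    "BODYPARTS",
]

#: The 12 tracked body parts, nose to tail.
BODYPARTS = (
    "nose",
    "left_ear",
    "right_ear",
    "head",
    "neck",
    "center",
    "left_hip",
    "right_hip",
    "hip",
    "tail_base",
    "mid_tail",
    "tail_tip",
)

DEFAULT_DURATION_H = 22.0


class FormatError(ValueError):
    """Raised when an input table violates its declared layout."""


@dataclass(frozen=True)
class AssayTimeline:
    """Phase structure and period tiling of one home-cage session.

    Parameters
    ----------
    frame_rate
        Frames per second (the assay acquires one snapshot per second).
    phases
        Ordered ``(name, start_hour, end_hour)`` triples tiling
        ``[0, duration_hours)`` with half-open intervals.
    stimulus_onsets
        Stimulus onset times in *elapsed* hours.  The default onsets
        ``12, 14, 16`` are the starts of assay hours 13, 15 and 17.
    period_length_min
        Length of one analysis period in minutes.
    """

    frame_rate: float = 1.0
    phases: tuple[tuple[str, float, float], ...] = (
        ("day", 0.0, 6.0),
        ("night", 6.0, 12.0),
        ("night_stimuli", 12.0, 18.0),
        ("day2", 18.0, 22.0),
    )
    stimulus_onsets: tuple[float, ...] = (12.0, 14.0, 16.0)
    period_length_min: float = 10.0

    def __post_init__(self) -> None:
        prev_end = 0.0
        for name, start, end in self.phases:
            if not np.isclose(start, prev_end):
                raise ValueError(f"phase {name!r} starts at {start} h, expected {prev_end} h")
            if end <= start:
                raise ValueError(f"phase {name!r} has non-positive length")
            prev_end = end
        for t in self.stimulus_onsets:
            if not (0 <= t < self.duration_hours):
                raise ValueError(f"stimulus onset {t} h outside the assay")

    @property
    def duration_hours(self) -> float:
        return self.phases[-1][2]

    @property
    def duration_seconds(self) -> float:
        return self.duration_hours * 3600.0

    @property
    def n_frames(self) -> int:
        return int(round(self.duration_seconds * self.frame_rate))

    @property
    def n_periods(self) -> int:
        return int(np.ceil(self.duration_hours * 60.0 / self.period_length_min))

    @property
    def period_seconds(self) -> float:
        return self.period_length_min * 60.0

    @classmethod
    def scaled(cls, duration_hours: float, frame_rate: float = 1.0,
               period_length_min: float = 10.0) -> "AssayTimeline":
        """A timeline with the default phase proportions compressed to
        ``duration_hours``.  Period length is *not* scaled, so short sessions
        keep 10-minute analysis periods (used for desk-scale cohorts)."""
        f = duration_hours / DEFAULT_DURATION_H
        base = cls()
        return cls(
            frame_rate=frame_rate,
            phases=tuple((n, s * f, e * f) for n, s, e in base.phases),
            stimulus_onsets=tuple(t * f for t in base.stimulus_onsets),
            period_length_min=period_length_min,
        )

    def period_index(self, t_seconds: float) -> int:
        """1-based index of the 10-minute period containing ``t_seconds``.

        Periods are half-open ``[start, start + period)``; at the defaults the
        first stimulus onset (12 elapsed hours, the start of assay hour 13)
        falls in period 73.
        """
        if not (0 <= t_seconds < self.duration_seconds):
            raise ValueError(f"t = {t_seconds} s outside the assay [0, {self.duration_seconds}) s")
        return int(t_seconds // self.period_seconds) + 1

    def phase_of(self, t_seconds: float) -> str:
        """Name of the phase containing ``t_seconds`` (half-open intervals)."""
        if not (0 <= t_seconds < self.duration_seconds):
            raise ValueError(f"t = {t_seconds} s outside the assay")
        h = t_seconds / 3600.0
        for name, start, end in self.phases:
            if start <= h < end:
                return name
        raise ValueError(f"t = {t_seconds} s not covered by any phase")  # pragma: no cover

    def phase_interval(self, name: str) -> tuple[float, float]:
        """(start, end) of a phase in seconds."""
        for pname, start, end in self.phases:
            if pname == name:
                return start * 3600.0, end * 3600.0
        raise KeyError(name)

    def period_interval(self, period: int) -> tuple[float, float]:
        """(start, end) seconds of a 1-based period."""
        if not (1 <= period <= self.n_periods):
            raise ValueError(f"period {period} outside 1..{self.n_periods}")
        start = (period - 1) * self.period_seconds
        return start, min(start + self.period_seconds, self.duration_seconds)


def period_index(t_seconds: float, timeline: AssayTimeline) -> int:
    """Module-level alias of :meth:`AssayTimeline.period_index`."""
    return timeline.period_index(t_seconds)


def phase_of(t_seconds: float, timeline: AssayTimeline) -> str:
    """Module-level alias of :meth:`AssayTimeline.phase_of`."""
    return timeline.phase_of(t_seconds)


@dataclass(frozen=True)
class CageGeometry:
    """Pixel geometry of one cage crop.

    Origin at the top-left of the crop, x rightward, y downward.  The cage
    floor is split into a 2x2 quadrant grid; the social window is a
    2.5-inch hole in the lower inside-facing corner; a red hut provides
    shelter.
    """

    width: float = 320.0
    height: float = 240.0
    px_per_cm: float = 8.0
    window_center: tuple[float, float] = (320.0, 228.0)
    window_radius: float = 25.4  # 2.5 in * 2.54 cm/in / 2 * 8 px/cm
    hut_bounds: tuple[float, float, float, float] = (10.0, 10.0, 90.0, 90.0)  # x0,y0,x1,y1

    def __post_init__(self) -> None:
        x0, y0, x1, y1 = self.hut_bounds
        if not (0 <= x0 < x1 <= self.width and 0 <= y0 < y1 <= self.height):
            raise ValueError("hut region must lie inside the cage bounds")

    def quadrant_of(self, x: np.ndarray, y: np.ndarray) -> np.ndarray:
        """Quadrant index 0..3 for points (clipped to bounds): row-major 2x2."""
        x = np.clip(np.asarray(x, dtype=float), 0, np.nextafter(self.width, 0))
        y = np.clip(np.asarray(y, dtype=float), 0, np.nextafter(self.height, 0))
        col = (x >= self.width / 2).astype(int)
        row = (y >= self.height / 2).astype(int)
        return row * 2 + col

    def in_hut(self, x: np.ndarray, y: np.ndarray) -> np.ndarray:
        x0, y0, x1, y1 = self.hut_bounds
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        return (x >= x0) & (x < x1) & (y >= y0) & (y < y1)

    def near_window(self, x: np.ndarray, y: np.ndarray) -> np.ndarray:
        wx, wy = self.window_center
        d = np.hypot(np.asarray(x, float) - wx, np.asarray(y, float) - wy)
        return d <= self.window_radius

    def wall_distance(self, x: np.ndarray, y: np.ndarray) -> np.ndarray:
        """Minimum distance to any of the four cage walls, px."""
        x = np.asarray(x, float)
        y = np.asarray(y, float)
        return np.minimum.reduce([x, self.width - x, y, self.height - y])

    @property
    def hut_center(self) -> tuple[float, float]:
        x0, y0, x1, y1 = self.hut_bounds
        return (x0 + x1) / 2.0, (y0 + y1) / 2.0


GENOTYPES = ("WT", "AD")
AGE_CLASSES = ("young", "old", "aged")
TREATMENTS = ("none", "CsA", "Neb", "Cab")
_TREATMENT_TAG = {"none": "", "CsA": "CSA", "Neb": "NEB", "Cab": "XL"}
_AGE_TAG = {"young": "Y", "old": "O", "aged": "A"}


@dataclass(frozen=True)
class GroupLabel:
    """Experimental group of one animal: genotype x age class x treatment."""

    genotype: str = "WT"
    age: str = "young"
    treatment: str = "none"

    def __post_init__(self) -> None:
        if self.genotype not in GENOTYPES:
            raise ValueError(f"unknown genotype {self.genotype!r}")
        if self.age not in AGE_CLASSES:
            raise ValueError(f"unknown age class {self.age!r}")
        if self.treatment not in TREATMENTS:
            raise ValueError(f"unknown treatment {self.treatment!r}")

    @property
    def label(self) -> str:
        """Compact label, e.g. ``WT_Y``, ``AD_O``, ``AD_CSA_Y``."""
        parts = [self.genotype]
        tag = _TREATMENT_TAG[self.treatment]
        if tag:
            parts.append(tag)
        parts.append(_AGE_TAG[self.age])
        return "_".join(parts)

    @classmethod
    def from_label(cls, label: str) -> "GroupLabel":
        parts = label.split("_")
        genotype = parts[0]
        age = {v: k for k, v in _AGE_TAG.items()}[parts[-1]]
        treatment = "none"
        if len(parts) == 3:
            treatment = {v: k for k, v in _TREATMENT_TAG.items() if v}[parts[1]]
        return cls(genotype, age, treatment)


@dataclass
class PoseRecording:
    """Per-animal keypoint time series on an assay timeline.

    ``xy`` has shape ``(n_frames, n_bodyparts, 2)`` in cage pixels,
    ``likelihood`` shape ``(n_frames, n_bodyparts)`` in [0, 1].  ``mask``
    marks entries invalidated by the likelihood filter (kept for audit even
    after their coordinates have been interpolated over).
    """

    animal_id: str
    bodyparts: tuple[str, ...]
    xy: np.ndarray
    likelihood: np.ndarray
    timeline: AssayTimeline = field(default_factory=AssayTimeline)
    geometry: CageGeometry = field(default_factory=CageGeometry)
    group: GroupLabel = field(default_factory=GroupLabel)
    mask: np.ndarray | None = None
    unknown_bodyparts: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        self.xy = np.asarray(self.xy, dtype=float)
        self.likelihood = np.asarray(self.likelihood, dtype=float)
        n, k, two = self.xy.shape
        if two != 2 or self.likelihood.shape != (n, k) or len(self.bodyparts) != k:
            raise ValueError("inconsistent keypoint array shapes")
        if self.mask is None:
            self.mask = np.zeros((n, k), dtype=bool)

    @property
    def n_frames(self) -> int:
        return self.xy.shape[0]

    @property
    def times(self) -> np.ndarray:
        """Frame timestamps in seconds."""
        return np.arange(self.n_frames) / self.timeline.frame_rate

    def part(self, name: str) -> np.ndarray:
        """(n_frames, 2) coordinates of one body part."""
        try:
            i = self.bodyparts.index(name)
        except ValueError:
            raise KeyError(f"body part {name!r} not in recording") from None
        return self.xy[:, i, :]

    def has_part(self, name: str) -> bool:
        return name in self.bodyparts

    @property
    def centroid(self) -> np.ndarray:
        if self.has_part("center"):
            return self.part("center")
        return self.xy.mean(axis=1)

    def frames_in(self, interval: tuple[float, float]) -> np.ndarray:
        """Boolean frame mask for a half-open time interval in seconds."""
        t = self.times
        return (t >= interval[0]) & (t < interval[1])

    def copy(self) -> "PoseRecording":
        new = dataclasses.replace(
            self, xy=self.xy.copy(), likelihood=self.likelihood.copy(),
            mask=None if self.mask is None else self.mask.copy())
        partner = getattr(self, "partner_near_window", None)
        if partner is not None:
            new.partner_near_window = partner.copy()  # type: ignore[attr-defined]
        return new


# ---------------------------------------------------------------------------
# Pose table I/O (DLC wide dialect and a flat fallback)
# ---------------------------------------------------------------------------

def read_pose_table(path: str | Path, dialect: str = "auto", **kwargs) -> PoseRecording:
    """Read a pose-estimation table into a :class:`PoseRecording`.

    The DLC wide layout (header rows scorer / bodyparts / coords, columns
    x, y, likelihood per body part) is auto-detected; a flat layout with
    columns ``frame, bodypart, x, y, likelihood`` is accepted as fallback.
    Extra keyword arguments (timeline, geometry, group, animal_id) are passed
    to the recording.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    with open(path) as fh:
        first = fh.readline()
    if not first.strip():
        raise FormatError(f"{path}: empty file")
    if dialect == "auto":
        dialect = "dlc" if first.lower().startswith("scorer") else "flat"
    if dialect == "dlc":
        return _read_dlc(path, **kwargs)
    if dialect == "flat":
        return _read_flat(path, **kwargs)
    raise ValueError(f"unknown dialect {dialect!r}")


def _read_dlc(path: Path, **kwargs) -> PoseRecording:
    df = pd.read_csv(path, header=[0, 1, 2], index_col=0)
    if df.empty:
        raise FormatError(f"{path}: no data rows")
    frames = df.index.to_numpy()
    if not np.all(np.diff(frames) > 0):
        raise FormatError(f"{path}: non-monotone frame index")
    parts = list(dict.fromkeys(df.columns.get_level_values(1)))
    xy = np.empty((len(df), len(parts), 2))
    lik = np.empty((len(df), len(parts)))
    scorer = df.columns.get_level_values(0)[0]
    for j, part in enumerate(parts):
        sub = df[scorer][part]
        for col in ("x", "y", "likelihood"):
            if col not in sub.columns:
                raise FormatError(f"{path}: body part {part!r} missing column {col!r}")
        xy[:, j, 0] = sub["x"].to_numpy(float)
        xy[:, j, 1] = sub["y"].to_numpy(float)
        lik[:, j] = sub["likelihood"].to_numpy(float)
    unknown = tuple(p for p in parts if p not in BODYPARTS)
    kwargs.setdefault("animal_id", path.stem)
    return PoseRecording(bodyparts=tuple(parts), xy=xy, likelihood=lik,
                         unknown_bodyparts=unknown, **kwargs)


def _read_flat(path: Path, **kwargs) -> PoseRecording:
    df = pd.read_csv(path)
    required = {"frame", "bodypart", "x", "y", "likelihood"}
    missing = required - set(df.columns)
    if missing:
        raise FormatError(f"{path}: flat layout missing column(s) {sorted(missing)}")
    if df.empty:
        raise FormatError(f"{path}: no data rows")
    parts = list(dict.fromkeys(df["bodypart"]))
    wide = df.pivot(index="frame", columns="bodypart", values=["x", "y", "likelihood"])
    frames = wide.index.to_numpy()
    if not np.all(np.diff(frames) > 0):
        raise FormatError(f"{path}: non-monotone frame index")
    xy = np.stack([wide["x"][parts].to_numpy(float), wide["y"][parts].to_numpy(float)], axis=-1)
    lik = wide["likelihood"][parts].to_numpy(float)
    unknown = tuple(p for p in parts if p not in BODYPARTS)
    kwargs.setdefault("animal_id", path.stem)
    return PoseRecording(bodyparts=tuple(parts), xy=xy, likelihood=lik,
                         unknown_bodyparts=unknown, **kwargs)


def write_pose_table(rec: PoseRecording, path: str | Path, dialect: str = "dlc",
                     scorer: str = "phenocage") -> None:
    """Write a recording back to CSV in the DLC wide dialect (or flat)."""
    path = Path(path)
    if dialect == "dlc":
        cols = pd.MultiIndex.from_tuples(
            [(scorer, p, c) for p in rec.bodyparts for c in ("x", "y", "likelihood")],
            names=["scorer", "bodyparts", "coords"])
        data = np.empty((rec.n_frames, 3 * len(rec.bodyparts)))
        for j in range(len(rec.bodyparts)):
            data[:, 3 * j] = rec.xy[:, j, 0]
            data[:, 3 * j + 1] = rec.xy[:, j, 1]
            data[:, 3 * j + 2] = rec.likelihood[:, j]
        df = pd.DataFrame(data, columns=cols)
        df.to_csv(path, index=True, index_label=None)
    elif dialect == "flat":
        rows = []
        for f in range(rec.n_frames):
            for j, p in enumerate(rec.bodyparts):
                rows.append((f, p, rec.xy[f, j, 0], rec.xy[f, j, 1], rec.likelihood[f, j]))
        pd.DataFrame(rows, columns=["frame", "bodypart", "x", "y", "likelihood"]).to_csv(
            path, index=False)
    else:
        raise ValueError(f"unknown dialect {dialect!r}")


# ---------------------------------------------------------------------------
# Likelihood filter
# ---------------------------------------------------------------------------

def filter_low_likelihood(rec: PoseRecording, threshold: float = 0.90) -> PoseRecording:
    """Mask keypoint entries with likelihood below ``threshold`` and repair
    their coordinates.

    Masked coordinates are linearly interpolated from the nearest valid
    neighbours; runs touching the recording edge are filled from the nearest
    valid value.  The audit mask and the number of masked entries are kept on
    the returned recording (``mask``, ``n_masked``); the operation is
    idempotent because likelihoods are left untouched.
    """
    if not (0 < threshold <= 1):
        raise ValueError("threshold must lie in (0, 1]")
    out = rec.copy()
    bad = out.likelihood < threshold
    frames = np.arange(out.n_frames)
    for j, part in enumerate(out.bodyparts):
        col_bad = bad[:, j]
        if not col_bad.any():
            continue
        valid = ~col_bad
        if not valid.any():
            raise ValueError(f"keypoint {part!r} has no frames above the likelihood threshold")
        for d in range(2):
            out.xy[col_bad, j, d] = np.interp(
                frames[col_bad], frames[valid], out.xy[valid, j, d])
    out.mask = bad
    out.n_masked = int(bad.sum())  # type: ignore[attr-defined]
    return out
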