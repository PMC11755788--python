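"""CatWalk-style gait metrics from timestamped footfall records.

A walkway session yields a set of paw prints (footfalls) per run.  Runs are
kept only when compliant — a one-directional crossing completed in strictly
less than 10 seconds — and animals need at least three compliant runs.  From
the compliant runs we compute the standard gait battery: per-paw print
geometry and intensity, stand / step cycle / swing timing, the seven-way
support decomposition, base of support, cadence, number of steps, and the
percentage of normal step sequence patterns (NSSP).

NSSP uses the six canonical quadruped patterns — alternate (Aa, Ab),
cruciate (Ca, Cb) and rotary (Ra, Rb) — matched up to rotation of the
starting paw over sliding 4-step windows.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "PAWS",
    "FootfallRecord",
    "GaitRun",
    "NSSP_PATTERNS",
    "normal_windows",
    "compliance_filter",
    "paw_parameters",
    "support_fractions",
    "base_of_support",
    "nssp_percent",
    "run_summary",
    "animal_summary",
]

PAWS = ("RF", "LF", "RH", "LH")
FRONT = ("RF", "LF")
HIND = ("RH", "LH")

#: The six canonical normal step sequence patterns (starting-paw rotation
#: is factored out when matching).
NSSP_PATTERNS: dict[str, tuple[str, str, str, str]] = {
    "Aa": ("RF", "RH", "LF", "LH"),
    "Ab": ("LF", "RH", "RF", "LH"),
    "Ca": ("RF", "LF", "RH", "LH"),
    "Cb": ("LF", "RF", "LH", "RH"),
    "Ra": ("RF", "LF", "LH", "RH"),
    "Rb": ("LF", "RF", "RH", "LH"),
}


def _rotations(seq: tuple[str, ...]) -> list[tuple[str, ...]]:
    return [seq[i:] + seq[:i] for i in range(len(seq))]


#: All 4-step windows counted as normal: each pattern in any starting-paw
#: rotation.  (With four distinct paws these 6 x 4 rotations cover the 24
#: permutations, so a window is abnormal exactly when a paw is skipped or
#: repeated — the CatWalk regularity convention.)
NORMAL_WINDOWS: frozenset[tuple[str, str, str, str]] = frozenset(
    rot for pat in NSSP_PATTERNS.values() for rot in _rotations(pat)
)


def normal_windows() -> frozenset[tuple[str, str, str, str]]:
    """The set of 4-step paw orders classified as normal."""
    return NORMAL_WINDOWS


@dataclass
class FootfallRecord:
    """One paw print: contact interval, print geometry and intensity.

    Positions are in walkway pixels; ``position_cm`` is the print's location
    along the walkway axis.  ``intensities`` are per-frame 0-255 a.u. samples.
    """

    paw: str
    contact: float
    release: float
    heel: tuple[float, float]
    third_toe: tuple[float, float]
    toe1: tuple[float, float] | None = None
    toe5: tuple[float, float] | None = None
    toe2: tuple[float, float] | None = None
    toe4: tuple[float, float] | None = None
    print_area: float = np.nan
    max_contact_area: float = np.nan
    intensities: np.ndarray | None = None
    position_cm: float = np.nan

    def __post_init__(self) -> None:
        if self.paw not in PAWS:
            raise ValueError(f"unknown paw {self.paw!r}")
        if not self.release > self.contact:
            raise ValueError("release must be after contact")
        if self.intensities is not None:
            self.intensities = np.asarray(self.intensities, dtype=float)
            if ((self.intensities < 0) | (self.intensities > 255)).any():
                raise ValueError("intensities must lie in [0, 255]")

    @property
    def mean_intensity(self) -> float:
        return float(np.mean(self.intensities)) if self.intensities is not None else np.nan

    @property
    def min_intensity(self) -> float:
        return float(np.min(self.intensities)) if self.intensities is not None else np.nan

    @property
    def stand(self) -> float:
        """Duration of contact with the walkway, s."""
        return self.release - self.contact


@dataclass
class GaitRun:
    """One walkway crossing: time-ordered footfalls plus compliance state."""

    animal_id: str
    footfalls: list[FootfallRecord]
    group: object = None

    def __post_init__(self) -> None:
        self.footfalls = sorted(self.footfalls, key=lambda f: f.contact)

    @property
    def start(self) -> float:
        return self.footfalls[0].contact

    @property
    def end(self) -> float:
        return max(f.release for f in self.footfalls)

    @property
    def duration(self) -> float:
        """Run duration based on the identified steps, s."""
        return self.end - self.start

    @property
    def n_steps(self) -> int:
        return len(self.footfalls)

    @property
    def direction(self) -> int:
        pos = [f.position_cm for f in self.footfalls]
        return int(np.sign(pos[-1] - pos[0])) or 1

    def compliance(self, max_duration: float = 10.0) -> tuple[bool, str]:
        """Strictly-less-than duration bound and one-directionality."""
        pos = np.array([f.position_cm for f in self.footfalls])
        deltas = np.diff(pos)
        if (deltas > 1e-9).any() and (deltas < -1e-9).any():
            return False, "bidirectional"
        if not self.duration < max_duration:
            return False, f"duration {self.duration:.2f} s >= {max_duration} s"
        return True, "compliant"


def compliance_filter(runs: Iterable[GaitRun], max_duration: float = 10.0,
                      min_runs: int = 3) -> tuple[list[GaitRun], pd.DataFrame]:
    """Keep compliant runs; report exclusions and under-sampled animals."""
    kept: list[GaitRun] = []
    rows = []
    for i, run in enumerate(runs):
        ok, reason = run.compliance(max_duration)
        rows.append({"run": i, "animal": run.animal_id, "compliant": ok, "reason": reason})
        if ok:
            kept.append(run)
    report = pd.DataFrame(rows, columns=["run", "animal", "compliant", "reason"])
    if len(report):
        counts = report[report["compliant"]].groupby("animal").size()
        short = [a for a in report["animal"].unique() if counts.get(a, 0) < min_runs]
        report.attrs["animals_below_min_runs"] = short
    return kept, report


# ---------------------------------------------------------------------------
# Per-paw parameters
# ---------------------------------------------------------------------------

def _dist(a: tuple[float, float] | None, b: tuple[float, float] | None) -> float:
    if a is None or b is None:
        return np.nan
    return float(np.hypot(a[0] - b[0], a[1] - b[1]))


def paw_parameters(run: GaitRun, px_per_mm: float = 10.0) -> pd.DataFrame:
    """Per-print geometry and timing, one row per footfall.

    print length = third toe to heel; toe spread = toe 1 to toe 5;
    intermediate toe spread = toe 2 to toe 4; paw angle = signed angle of the
    heel->third-toe axis against the body axis (run direction along the
    walkway), folded to [-90, 90] degrees; step cycle = time to the next
    initial contact of the same paw (the last contact of a paw has none).
    """
    direction = run.direction
    body_axis = np.array([direction, 0.0])
    next_contact: dict[str, list[float]] = {p: [] for p in PAWS}
    for f in run.footfalls:
        next_contact[f.paw].append(f.contact)
    rows = []
    for f in run.footfalls:
        later = [t for t in next_contact[f.paw] if t > f.contact]
        cycle = min(later) - f.contact if later else np.nan
        paw_vec = np.array([f.third_toe[0] - f.heel[0], f.third_toe[1] - f.heel[1]])
        if np.hypot(*paw_vec) > 0:
            ang = np.degrees(np.arctan2(
                body_axis[0] * paw_vec[1] - body_axis[1] * paw_vec[0],
                body_axis @ paw_vec))
            # fold to [-90, 90]: the paw axis is orientation-symmetric
            if ang > 90:
                ang -= 180
            elif ang < -90:
                ang += 180
        else:
            ang = np.nan
        rows.append({
            "paw": f.paw,
            "contact": f.contact,
            "print_length_mm": _dist(f.third_toe, f.heel) / px_per_mm,
            "toe_spread_mm": _dist(f.toe1, f.toe5) / px_per_mm,
            "intermediate_toe_spread_mm": _dist(f.toe2, f.toe4) / px_per_mm,
            "print_area": f.print_area,
            "max_contact_area": f.max_contact_area,
            "mean_intensity": f.mean_intensity,
            "min_intensity": f.min_intensity,
            "stand_s": f.stand,
            "step_cycle_s": cycle,
            "swing_s": cycle - f.stand if np.isfinite(cycle) else np.nan,
            "paw_angle_deg": ang,
        })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Support decomposition
# ---------------------------------------------------------------------------

SUPPORT_CATEGORIES = ("zero", "single", "girdle", "lateral", "diagonal", "three", "four")
_PAIR_CATEGORY = {
    frozenset(("RF", "LF")): "girdle", frozenset(("RH", "LH")): "girdle",
    frozenset(("RF", "RH")): "lateral", frozenset(("LF", "LH")): "lateral",
    frozenset(("RF", "LH")): "diagonal", frozenset(("LF", "RH")): "diagonal",
}


def _classify(contact_set: frozenset) -> str:
    n = len(contact_set)
    if n == 0:
        return "zero"
    if n == 1:
        return "single"
    if n == 2:
        return _PAIR_CATEGORY[contact_set]
    return "three" if n == 3 else "four"


def support_fractions(run: GaitRun, dt: float = 0.001,
                      method: str = "discrete") -> dict[str, float]:
    """Percent of run time per instantaneous support category.

    The run span (first contact to last release) is classified by the set of
    paws in contact: zero, single, girdle pair (RF-LF / RH-LH), lateral pair
    (RF-RH / LF-LH), diagonal pair (RF-LH / LF-RH), three, or four paws.
    ``method='discrete'`` samples at midpoints of a dt grid (fractions sum to
    exactly 100); ``method='event'`` integrates the piecewise-constant
    classification exactly between contact/release events.
    """
    t0, t1 = run.start, run.end
    span = t1 - t0
    intervals = [(f.paw, f.contact, f.release) for f in run.footfalls]

    def active(t: float) -> frozenset:
        return frozenset(p for p, a, b in intervals if a <= t < b)

    if method == "discrete":
        n = max(1, int(np.ceil(span / dt)))
        paw_idx = {p: i for i, p in enumerate(PAWS)}
        samples = t0 + (np.arange(n) + 0.5) * (span / n)
        occupied = np.zeros((4, n), dtype=bool)
        for p, a, b in intervals:
            occupied[paw_idx[p]] |= (samples >= a) & (samples < b)
        # contact bitmask -> category lookup over the 16 configurations
        code = (occupied << np.arange(4)[:, None]).sum(axis=0)
        cat_of_code = np.array([SUPPORT_CATEGORIES.index(
            _classify(frozenset(p for p in PAWS if (c >> paw_idx[p]) & 1)))
            for c in range(16)])
        counts = np.bincount(cat_of_code[code], minlength=len(SUPPORT_CATEGORIES))
        return {c: 100.0 * counts[i] / n for i, c in enumerate(SUPPORT_CATEGORIES)}
    if method == "event":
        events = sorted({t0, t1, *(a for _, a, _ in intervals), *(b for _, _, b in intervals)})
        events = [t for t in events if t0 <= t <= t1]
        dur = dict.fromkeys(SUPPORT_CATEGORIES, 0.0)
        for a, b in zip(events[:-1], events[1:]):
            if b > a:
                dur[_classify(active((a + b) / 2.0))] += b - a
        return {c: 100.0 * dur[c] / span for c in SUPPORT_CATEGORIES}
    raise ValueError(f"unknown method {method!r}")


def base_of_support(run: GaitRun) -> tuple[float, float]:
    """(front, hind) mean lateral width between left and right placements.

    For each girdle (front or hind), successive placements alternating sides
    are paired in time order and the perpendicular (lateral) distance between
    the paired prints is averaged.  NaN when a girdle never alternates.
    """
    widths = []
    for pair in (FRONT, HIND):
        prints = sorted((f for f in run.footfalls if f.paw in pair), key=lambda f: f.contact)
        ws = []
        for a, b in zip(prints[:-1], prints[1:]):
            if a.paw != b.paw:
                ws.append(abs(a.heel[1] - b.heel[1]))
        widths.append(float(np.mean(ws)) if ws else np.nan)
    return widths[0], widths[1]


def nssp_percent(run: GaitRun, weight: str = "steps") -> float:
    """Percentage of 4-step sliding windows matching a normal step sequence
    pattern.  ``weight='steps'`` counts windows; ``weight='time'`` weights
    each window by the time to the next initial contact.  NaN (undefined)
    for runs with fewer than 4 steps.
    """
    order = [f.paw for f in run.footfalls]
    times = [f.contact for f in run.footfalls]
    if len(order) < 4:
        return np.nan
    n_win = len(order) - 3
    if weight == "steps":
        weights = np.ones(n_win)
    elif weight == "time":
        weights = np.array([times[i + 1] - times[i] for i in range(n_win)])
        if weights.sum() <= 0:
            weights = np.ones(n_win)
    else:
        raise ValueError(f"unknown weight {weight!r}")
    normal = np.array([tuple(order[i:i + 4]) in NORMAL_WINDOWS for i in range(n_win)])
    return float(100.0 * (weights * normal).sum() / weights.sum())


# ---------------------------------------------------------------------------
# Run and animal summaries
# ---------------------------------------------------------------------------

def run_summary(run: GaitRun, px_per_mm: float = 10.0,
                support_dt: float = 0.001) -> dict[str, float]:
    """Flat Table-1-style metric dict for one run."""
    out: dict[str, float] = {}
    out["duration_s"] = run.duration
    out["n_steps"] = run.n_steps
    out["cadence"] = run.n_steps / run.duration
    out["nssp_pct"] = nssp_percent(run)
    out["nssp_pct_time"] = nssp_percent(run, weight="time")
    front, hind = base_of_support(run)
    out["bos_front"] = front
    out["bos_hind"] = hind
    for cat, val in support_fractions(run, dt=support_dt).items():
        out[f"support_{cat}"] = val
    paw_df = paw_parameters(run, px_per_mm=px_per_mm)
    per_paw_cols = ("print_length_mm", "toe_spread_mm", "intermediate_toe_spread_mm",
                    "print_area", "max_contact_area", "mean_intensity", "min_intensity",
                    "stand_s", "step_cycle_s", "paw_angle_deg")
    means = paw_df.groupby("paw")[list(per_paw_cols)].mean()
    for paw in PAWS:
        for col in per_paw_cols:
            val = means.loc[paw, col] if paw in means.index else np.nan
            out[f"{col}_{paw}"] = float(val)
    return out


def animal_summary(runs: Sequence[GaitRun], px_per_mm: float = 10.0,
                   support_dt: float = 0.001) -> pd.DataFrame:
    """Per-animal gait metrics: mean over each animal's compliant runs."""
    kept, _ = compliance_filter(runs)
    rows = []
    for run in kept:
        row = run_summary(run, px_per_mm=px_per_mm, support_dt=support_dt)
        row["animal"] = run.animal_id
        row["group"] = getattr(run.group, "label", None) or str(run.group)
        rows.append(row)
    df = pd.DataFrame(rows)
    if df.empty:
        return df
    return df.groupby(["animal", "group"], as_index=False).mean(numeric_only=True)
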