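"""Synthetic cohorts with known, configurable group effects.

The generator emulates the statistical structure of a 22-hour home-cage
assay (1 frame/s, day/night phases, three stimulus presentations), of
syllable label sequences over a 29-state codebook, and of CatWalk-style
walkway runs — so every downstream pipeline stage has a parameter-recovery
test surface.  It does not attempt realistic mouse kinematics beyond the
structure the features measure.

All group effects are expressed as ratios against the young wild-type
baseline.  A single integer seed fully determines the cohort.

Knob -> recovered-parameter map
-------------------------------
``activity`` / ``night_activity``  -> % moved (per phase, night/day ratio)
``sap``                            -> % stretch-attend posture
``stim_gain`` / ``stim_retention`` -> stimulus response and habituation index
``acclimation``                    -> acclimation indices (hour-1 decline)
``hindpaw_intensity``              -> mean/min print intensity of LH/RH
``print_length``                   -> manual print length per paw
``nssp_corruption``                -> % normal step sequence patterns (down)
``n_steps``                        -> number of steps / cadence
``syllable_tilt``                  -> per-syllable bout frequency
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .assay import (AssayTimeline, CageGeometry, GroupLabel, PoseRecording,
                    BODYPARTS, DEFAULT_DURATION_H)
from .gait import FootfallRecord, GaitRun, PAWS

__all__ = [
    "GroupEffects",
    "CohortConfig",
    "SyllableCodebook",
    "default_codebook",
    "simulate_homecage",
    "simulate_syllables",
    "simulate_gait_runs",
    "simulate_cohort",
    "write_cohort",
]


@dataclass(frozen=True)
class GroupEffects:
    """Multiplicative effects of one experimental group vs the WT-young
    baseline (1.0 = no effect), plus the step-corruption probability."""

    activity: float = 1.0
    night_activity: float = 1.0
    sap: float = 1.0
    stim_gain: float = 1.0
    stim_retention: float = 1.0
    acclimation: float = 1.0
    hindpaw_intensity: float = 1.0
    forepaw_intensity: float = 1.0
    print_length: float = 1.0
    nssp_corruption: float = 0.0
    n_steps: float = 1.0
    stand: float = 1.0
    syllable_tilt: tuple[tuple[int, float], ...] = ()

    def __post_init__(self) -> None:
        if not (0.0 <= self.nssp_corruption <= 1.0):
            raise ValueError("nssp_corruption must lie in [0, 1]")

    def tilt(self) -> dict[int, float]:
        return dict(self.syllable_tilt)


# Default planted effects for the ten study groups (genotype x age x drug).
# Directions mirror the study's findings: activity and step counts decline
# with age; the AD genotype shows early NSSP/print-length deficits, elevated
# SAP, blunted stimulus response/habituation, and an age-dependent shift of
# weight onto the hind paws; drug-treated old groups sit between old WT and
# old AD (CsA closest to WT, cabozantinib-young closest to old AD).
DEFAULT_EFFECTS: dict[str, GroupEffects] = {
    "WT_Y": GroupEffects(),
    "WT_O": GroupEffects(activity=0.70, night_activity=0.9, sap=0.9, stim_gain=0.85,
                         n_steps=0.75, nssp_corruption=0.18, stand=1.1),
    "AD_Y": GroupEffects(activity=0.85, sap=1.35, stim_gain=0.8, stim_retention=1.2,
                         acclimation=0.7, print_length=0.88, nssp_corruption=0.20,
                         n_steps=0.78, syllable_tilt=((5, 1.5),)),
    "AD_O": GroupEffects(activity=0.45, night_activity=0.7, sap=1.8, stim_gain=0.45,
                         stim_retention=1.5, acclimation=0.5, hindpaw_intensity=1.3,
                         nssp_corruption=0.22, n_steps=0.75, stand=1.25,
                         syllable_tilt=((5, 2.0), (11, 0.5))),
    "AD_CSA_Y": GroupEffects(activity=0.95, sap=1.1, nssp_corruption=0.12, n_steps=0.95),
    "AD_CSA_O": GroupEffects(activity=0.68, night_activity=0.88, sap=1.0, stim_gain=0.8,
                             n_steps=0.8, nssp_corruption=0.18, stand=1.1),
    "AD_NEB_Y": GroupEffects(activity=0.9, sap=1.3, print_length=0.9,
                             nssp_corruption=0.2, n_steps=0.8),
    "AD_NEB_O": GroupEffects(activity=0.8, sap=1.3, stim_gain=0.75, acclimation=0.7,
                             nssp_corruption=0.2, n_steps=0.8),
    "AD_XL_Y": GroupEffects(activity=0.55, sap=1.6, stim_gain=0.55, stim_retention=1.4,
                            acclimation=0.6, hindpaw_intensity=1.15, stand=1.2,
                            nssp_corruption=0.2, n_steps=0.8, syllable_tilt=((5, 1.8),)),
    "AD_XL_O": GroupEffects(activity=0.82, sap=1.35, stim_gain=0.75, acclimation=0.7,
                            nssp_corruption=0.18, n_steps=0.82),
}


@dataclass(frozen=True)
class CohortConfig:
    """Cohort design plus the generator's baseline rates and noise scales.

    Baselines are per-frame/seconds quantities of the young WT group; group
    effects multiply them.  ``duration_hours`` below 22 compresses the phase
    structure proportionally (10-minute analysis periods are kept).
    """

    n_per_group: int = 3
    groups: tuple[str, ...] = tuple(DEFAULT_EFFECTS)
    seed: int = 0
    frame_rate: float = 1.0
    duration_hours: float = DEFAULT_DURATION_H
    effects: dict[str, GroupEffects] = field(default_factory=lambda: dict(DEFAULT_EFFECTS))
    # home-cage baselines
    base_activity: float = 0.25        # day-phase active fraction
    night_mult: float = 2.0            # night/day activity ratio
    mean_active_bout_s: float = 20.0
    mean_speed_px: float = 6.0         # px/frame while active
    sap_propensity: float = 0.15       # P(stretch-attend | resting frame)
    acclim_amp: float = 1.0            # hour-1 excess activity multiplier
    acclim_tau_s: float = 900.0
    stim_amp: float = 1.5              # activity boost at first presentation
    stim_retention: float = 0.5        # response retained per presentation
    stim_window_s: float = 600.0
    dropout: float = 0.03              # likelihood < 0.90 rate
    noise_px: float = 0.5
    partner_window_rate: float = 0.15
    # gait baselines
    runs_per_animal: int = 4
    base_n_steps: int = 20
    step_interval_s: float = 0.18
    base_stand_s: float = 0.30
    base_print_length_mm: dict[str, float] = field(
        default_factory=lambda: {"RF": 7.0, "LF": 7.0, "RH": 9.0, "LH": 9.0})
    base_intensity: dict[str, float] = field(
        default_factory=lambda: {"RF": 120.0, "LF": 120.0, "RH": 105.0, "LH": 105.0})
    px_per_mm: float = 10.0
    inject_noncompliant: bool = False

    def __post_init__(self) -> None:
        if self.n_per_group <= 0 or self.duration_hours <= 0:
            raise ValueError("n_per_group and duration_hours must be positive")
        if not (0.0 <= self.dropout < 1.0):
            raise ValueError("dropout rate must lie in [0, 1)")
        for g in self.groups:
            if g not in self.effects:
                raise ValueError(f"group {g!r} has no effect-table entry")

    def timeline(self) -> AssayTimeline:
        if np.isclose(self.duration_hours, DEFAULT_DURATION_H) and self.frame_rate == 1.0:
            return AssayTimeline()
        return AssayTimeline.scaled(self.duration_hours, frame_rate=self.frame_rate)

    def animals(self) -> list[tuple[str, GroupLabel]]:
        """Deterministic (animal id, group) roster."""
        roster = []
        for g in self.groups:
            for i in range(self.n_per_group):
                roster.append((f"{g}_m{i}", GroupLabel.from_label(g)))
        return roster


def _fold(x: np.ndarray, lo: float, hi: float) -> np.ndarray:
    """Reflect values into [lo, hi] (triangular fold: billiard in a box)."""
    period = 2.0 * (hi - lo)
    y = np.mod(x - lo, period)
    return lo + np.minimum(y, period - y)


# longitudinal/lateral template offsets (px) of the 12 keypoints from the
# body center; longitudinal offsets scale with the elongation factor.
_TEMPLATE = {
    "nose": (14.0, 0.0), "left_ear": (11.0, 3.0), "right_ear": (11.0, -3.0),
    "head": (10.0, 0.0), "neck": (7.0, 0.0), "center": (0.0, 0.0),
    "left_hip": (-5.0, 3.0), "right_hip": (-5.0, -3.0), "hip": (-5.0, 0.0),
    "tail_base": (-9.0, 0.0), "mid_tail": (-13.0, 0.0), "tail_tip": (-17.0, 0.0),
}
SAP_ELONGATION = 1.35


def _activity_target(t: float, cfg: CohortConfig, eff: GroupEffects,
                     timeline: AssayTimeline) -> float:
    """Target active fraction at time t (seconds)."""
    a = cfg.base_activity * eff.activity
    if timeline.phase_of(min(t, timeline.duration_seconds - 1e-6)).startswith("night"):
        a *= cfg.night_mult * eff.night_activity
    a *= 1.0 + cfg.acclim_amp * eff.acclimation * np.exp(-t / cfg.acclim_tau_s)
    retention = min(1.0, cfg.stim_retention * eff.stim_retention)
    for k, onset_h in enumerate(timeline.stimulus_onsets):
        onset = onset_h * 3600.0
        if onset <= t < onset + cfg.stim_window_s:
            a *= 1.0 + cfg.stim_amp * eff.stim_gain * retention ** k
    return float(np.clip(a, 0.0, 0.95))


def _simulate_animal(animal_id: str, group: GroupLabel, cfg: CohortConfig,
                     rng: np.random.Generator) -> PoseRecording:
    timeline = cfg.timeline()
    geom = CageGeometry()
    eff = cfg.effects[group.label]
    n = timeline.n_frames
    fr = timeline.frame_rate

    # --- two-state semi-Markov activity process ------------------------------
    active = np.zeros(n, dtype=bool)
    t = 0.0
    state_active = False
    T = timeline.duration_seconds
    while t < T:
        if state_active:
            dur = rng.exponential(cfg.mean_active_bout_s)
        else:
            a = _activity_target(t, cfg, eff, timeline)
            if a <= 0:
                dur = T - t  # frozen animal: rest forever
            else:
                mean_rest = cfg.mean_active_bout_s * (1.0 - a) / a
                dur = rng.exponential(mean_rest)
        dur = max(dur, 1.0 / fr)
        f0, f1 = int(t * fr), min(int((t + dur) * fr), n)
        if state_active:
            active[f0:f1] = True
        t += dur
        state_active = not state_active

    # --- correlated random walk of the body center ---------------------------
    margin = 20.0
    pos = np.empty((n, 2))
    heading = np.empty(n)
    p = np.array([geom.width * 0.5, geom.height * 0.5]) + rng.normal(0, 10, 2)
    h = rng.uniform(0, 2 * np.pi)
    hut = np.array(geom.hut_center)
    stim_windows = [(o * 3600.0, o * 3600.0 + cfg.stim_window_s)
                    for o in timeline.stimulus_onsets]
    times = np.arange(n) / fr
    in_stim = np.zeros(n, dtype=bool)
    for a0, b0 in stim_windows:
        in_stim |= (times >= a0) & (times < b0)

    # walk over runs of active frames (vectorized within each run)
    idx = 0
    prev_active = False
    while idx < n:
        j = idx
        cur = active[idx]
        while j < n and active[j] == cur:
            j += 1
        length = j - idx
        if cur:
            if in_stim[idx]:  # stimulus response: head toward the hut shelter
                to_hut = hut - p
                h = np.arctan2(to_hut[1], to_hut[0]) + rng.normal(0, 0.3)
            dh = rng.normal(0, 0.4, length)
            hs = h + np.cumsum(dh)
            speed = rng.gamma(4.0, cfg.mean_speed_px / 4.0, length)
            speed[in_stim[idx:j]] *= 1.8
            steps = np.stack([speed * np.cos(hs), speed * np.sin(hs)], axis=1)
            raw = p + np.cumsum(steps, axis=0)
            raw[:, 0] = _fold(raw[:, 0], margin, geom.width - margin)
            raw[:, 1] = _fold(raw[:, 1], margin, geom.height - margin)
            pos[idx:j] = raw
            heading[idx:j] = hs
            p = raw[-1].copy()
            h = hs[-1]
        else:
            # long rest bouts after activity sometimes happen inside the hut
            if length * fr >= 60 and prev_active and rng.random() < 0.3:
                p = hut + rng.normal(0, 5, 2)
            pos[idx:j] = p
            heading[idx:j] = h
        prev_active = cur
        idx = j

    # --- stretch-attend posture on resting frames ----------------------------
    p_sap = np.clip(cfg.sap_propensity * eff.sap
                    * (1.0 + np.exp(-times / cfg.acclim_tau_s)), 0.0, 0.95)
    sap = (~active) & (rng.random(n) < p_sap)
    elong = np.where(sap, SAP_ELONGATION, 1.0)

    # --- keypoints from the rigid body template ------------------------------
    u = np.stack([np.cos(heading), np.sin(heading)], axis=1)
    v = np.stack([-np.sin(heading), np.cos(heading)], axis=1)
    parts = list(BODYPARTS)
    xy = np.empty((n, len(parts), 2))
    for jx, part in enumerate(parts):
        lon, lat = _TEMPLATE[part]
        xy[:, jx, :] = pos + (lon * elong)[:, None] * u + lat * v
        if cfg.noise_px > 0:
            xy[:, jx, :] += rng.normal(0, cfg.noise_px, (n, 2))

    lik = 0.95 + 0.05 * rng.random((n, len(parts)))
    drop = rng.random((n, len(parts))) < cfg.dropout
    lik[drop] = 0.30 + 0.59 * rng.random(int(drop.sum()))

    rec = PoseRecording(animal_id=animal_id, bodyparts=tuple(parts), xy=xy,
                        likelihood=lik, timeline=timeline, geometry=geom, group=group)
    rec.partner_near_window = rng.random(n) < cfg.partner_window_rate  # type: ignore
    return rec


def simulate_homecage(config: CohortConfig) -> list[PoseRecording]:
    """Simulate one home-cage pose recording per animal in the cohort."""
    ss = np.random.SeedSequence(config.seed)
    children = ss.spawn(len(config.animals()))
    recs = []
    for (animal_id, group), child in zip(config.animals(), children):
        rng = np.random.default_rng(child)
        recs.append(_simulate_animal(animal_id, group, config, rng))
    return recs


# ---------------------------------------------------------------------------
# Syllable sequences
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SyllableCodebook:
    """Fixed syllable inventory: labels, mean bout durations, transitions."""

    labels: tuple[int, ...]
    mean_durations: tuple[float, ...]       # seconds
    transition: np.ndarray                  # row-stochastic, zero diagonal

    def __post_init__(self) -> None:
        k = len(self.labels)
        P = np.asarray(self.transition, dtype=float)
        if P.shape != (k, k) or len(self.mean_durations) != k:
            raise ValueError("codebook shapes inconsistent")
        if not np.allclose(P.sum(axis=1), 1.0):
            raise ValueError("transition rows must sum to 1")
        if k > 1 and not np.allclose(np.diag(P), 0.0):
            raise ValueError("transition diagonal must be zero (bouts are maximal runs)")
        if any(d <= 0 for d in self.mean_durations):
            raise ValueError("mean durations must be positive")
        object.__setattr__(self, "transition", P)

    @property
    def n_syllables(self) -> int:
        return len(self.labels)


def default_codebook(n_syllables: int = 29) -> SyllableCodebook:
    """Uniform off-diagonal transitions; mean bout durations spanning 2-4 s."""
    if n_syllables == 1:
        P = np.ones((1, 1))  # degenerate: self-loop allowed for the constant seq
        return SyllableCodebook(labels=(0,), mean_durations=(3.0,), transition=P)
    P = np.full((n_syllables, n_syllables), 1.0 / (n_syllables - 1))
    np.fill_diagonal(P, 0.0)
    durs = tuple(np.linspace(2.0, 4.0, n_syllables))
    return SyllableCodebook(labels=tuple(range(n_syllables)), mean_durations=durs,
                            transition=P)


def _tilted(P: np.ndarray, labels: tuple[int, ...], tilt: dict[int, float]) -> np.ndarray:
    if not tilt:
        return P
    w = np.array([tilt.get(lab, 1.0) for lab in labels])
    Q = P * w[None, :]
    if P.shape[0] > 1:
        np.fill_diagonal(Q, 0.0)
    rows = Q.sum(axis=1, keepdims=True)
    rows[rows == 0] = 1.0
    return Q / rows


def simulate_syllables(config: CohortConfig,
                       codebook: SyllableCodebook | None = None) -> list:
    """Semi-Markov syllable label sequences, one per cohort animal.

    Bout labels follow the (group-tilted) transition matrix; bout lengths
    are geometric around each syllable's mean duration.
    """
    from .syllables import SyllableSequence

    codebook = codebook or default_codebook()
    timeline = config.timeline()
    n = timeline.n_frames
    fr = timeline.frame_rate
    ss = np.random.SeedSequence((config.seed, 1))
    children = ss.spawn(len(config.animals()))
    label_arr = np.array(codebook.labels)
    seqs = []
    for (animal_id, group), child in zip(config.animals(), children):
        rng = np.random.default_rng(child)
        P = _tilted(codebook.transition, codebook.labels,
                    config.effects[group.label].tilt())
        start_w = P.mean(axis=0)
        state = rng.choice(codebook.n_syllables, p=start_w / start_w.sum())
        out = np.empty(n, dtype=int)
        f = 0
        while f < n:
            mean_frames = max(codebook.mean_durations[state] * fr, 1.0)
            length = rng.geometric(1.0 / mean_frames)
            out[f:f + length] = label_arr[state]
            f += length
            if codebook.n_syllables > 1:
                state = rng.choice(codebook.n_syllables, p=P[state])
        seqs.append(SyllableSequence(animal_id=animal_id, labels=out,
                                     frame_rate=fr, codebook_labels=codebook.labels,
                                     group=group))
    return seqs


# ---------------------------------------------------------------------------
# Gait runs
# ---------------------------------------------------------------------------

_CANONICAL = ("RF", "RH", "LF", "LH")  # alternate pattern Aa
_LATERAL_Y = {"RF": -9.0, "LF": 9.0, "RH": -11.0, "LH": 11.0}


def _make_run(animal_id: str, group: GroupLabel, cfg: CohortConfig,
              rng: np.random.Generator, slow: bool = False,
              reverse: bool = False) -> GaitRun:
    eff = cfg.effects[group.label]
    n_steps = max(8, int(round(cfg.base_n_steps * eff.n_steps + rng.normal(0, 1.5))))
    interval = cfg.step_interval_s * (4.0 if slow else 1.0)
    direction = 1
    falls = []
    t = 0.0
    x_cm = 0.0
    for i in range(n_steps):
        paw = _CANONICAL[i % 4]
        if rng.random() < eff.nssp_corruption:
            paw = PAWS[rng.integers(4)]
        cycle = 4 * interval
        stand = min(cfg.base_stand_s * eff.stand * rng.uniform(0.9, 1.1), 0.8 * cycle)
        if reverse and i == n_steps // 2:
            direction = -1
        x_cm += direction * 1.5
        hx = x_cm * 10.0 * cfg.px_per_mm  # cm -> mm -> px
        hy = _LATERAL_Y[paw] + rng.normal(0, 0.8)
        pl_px = cfg.base_print_length_mm[paw] * eff.print_length * cfg.px_per_mm \
            * rng.uniform(0.95, 1.05)
        heel = (hx, hy)
        toe3 = (hx + direction * pl_px, hy + rng.normal(0, 1.0))
        spread_px = (5.0 if paw in ("RH", "LH") else 4.0) * cfg.px_per_mm
        inter_px = 0.6 * spread_px
        toe1 = (toe3[0], toe3[1] - spread_px / 2)
        toe5 = (toe3[0], toe3[1] + spread_px / 2)
        toe2 = (toe3[0], toe3[1] - inter_px / 2)
        toe4 = (toe3[0], toe3[1] + inter_px / 2)
        gain = eff.hindpaw_intensity if paw in ("RH", "LH") else eff.forepaw_intensity
        mean_i = cfg.base_intensity[paw] * gain
        samples = np.clip(rng.normal(mean_i, 6.0, 8), 0, 255)
        falls.append(FootfallRecord(
            paw=paw, contact=t, release=t + stand, heel=heel, third_toe=toe3,
            toe1=toe1, toe5=toe5, toe2=toe2, toe4=toe4,
            print_area=60.0 * cfg.px_per_mm * rng.uniform(0.9, 1.1),
            max_contact_area=80.0 * cfg.px_per_mm * rng.uniform(0.9, 1.1),
            intensities=samples, position_cm=x_cm))
        t += interval * rng.uniform(0.9, 1.1)
    return GaitRun(animal_id=animal_id, footfalls=falls, group=group)


def simulate_gait_runs(config: CohortConfig) -> list[GaitRun]:
    """Walkway runs per animal (>= 3 compliant; optional non-compliant)."""
    ss = np.random.SeedSequence((config.seed, 2))
    children = ss.spawn(len(config.animals()))
    runs = []
    for (animal_id, group), child in zip(config.animals(), children):
        rng = np.random.default_rng(child)
        for _ in range(config.runs_per_animal):
            runs.append(_make_run(animal_id, group, config, rng))
        if config.inject_noncompliant:
            kind = rng.random() < 0.5
            runs.append(_make_run(animal_id, group, config, rng,
                                  slow=kind, reverse=not kind))
    return runs


def simulate_cohort(config: CohortConfig, codebook: SyllableCodebook | None = None):
    """(recordings, syllable sequences, gait runs) for one cohort."""
    return (simulate_homecage(config),
            simulate_syllables(config, codebook),
            simulate_gait_runs(config))


# ---------------------------------------------------------------------------
# On-disk emission (same dialects the pipeline consumes)
# ---------------------------------------------------------------------------

def write_cohort(outdir: str | Path, recordings, syllable_seqs, gait_runs) -> None:
    """Write pose CSVs (DLC dialect), syllable CSVs, a footfall CSV and the
    cohort manifest TSV into ``outdir``."""
    from .assay import write_pose_table

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = []
    for rec in recordings:
        write_pose_table(rec, outdir / f"pose_{rec.animal_id}.csv")
        manifest.append({"animal": rec.animal_id, "group": rec.group.label})
    pd.DataFrame(manifest).to_csv(outdir / "manifest.tsv", sep="\t", index=False)
    for seq in syllable_seqs:
        pd.DataFrame({"frame": np.arange(len(seq.labels)), "syllable": seq.labels}
                     ).to_csv(outdir / f"syllables_{seq.animal_id}.csv", index=False)
    rows = []
    for i, run in enumerate(gait_runs):
        for f in run.footfalls:
            rows.append({
                "animal": run.animal_id,
                "group": getattr(run.group, "label", ""),
                "run": i, "paw": f.paw, "contact": f.contact, "release": f.release,
                "heel_x": f.heel[0], "heel_y": f.heel[1],
                "toe3_x": f.third_toe[0], "toe3_y": f.third_toe[1],
                "toe1_x": f.toe1[0] if f.toe1 else np.nan,
                "toe1_y": f.toe1[1] if f.toe1 else np.nan,
                "toe5_x": f.toe5[0] if f.toe5 else np.nan,
                "toe5_y": f.toe5[1] if f.toe5 else np.nan,
                "toe2_x": f.toe2[0] if f.toe2 else np.nan,
                "toe2_y": f.toe2[1] if f.toe2 else np.nan,
                "toe4_x": f.toe4[0] if f.toe4 else np.nan,
                "toe4_y": f.toe4[1] if f.toe4 else np.nan,
                "print_area": f.print_area, "max_contact_area": f.max_contact_area,
                "intensities": ";".join(f"{v:.3f}" for v in f.intensities),
                "position_cm": f.position_cm,
            })
    pd.DataFrame(rows).to_csv(outdir / "footfalls.csv", index=False)


def read_footfalls(path: str | Path) -> list[GaitRun]:
    """Read a footfall CSV (the schema emitted by :func:`write_cohort`)."""
    df = pd.read_csv(path)
    runs = []
    for (animal, run_id), sub in df.groupby(["animal", "run"], sort=True):
        falls = []
        for _, r in sub.iterrows():
            falls.append(FootfallRecord(
                paw=r["paw"], contact=r["contact"], release=r["release"],
                heel=(r["heel_x"], r["heel_y"]),
                third_toe=(r["toe3_x"], r["toe3_y"]),
                toe1=(r["toe1_x"], r["toe1_y"]),
                toe5=(r["toe5_x"], r["toe5_y"]),
                toe2=(r["toe2_x"], r["toe2_y"]),
                toe4=(r["toe4_x"], r["toe4_y"]),
                print_area=r["print_area"], max_contact_area=r["max_contact_area"],
                intensities=np.array([float(v) for v in str(r["intensities"]).split(";")]),
                position_cm=r["position_cm"]))
        group = GroupLabel.from_label(sub["group"].iloc[0]) if sub["group"].iloc[0] else None
        runs.append(GaitRun(animal_id=str(animal), footfalls=falls, group=group))
    return runs
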