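"""Supervised behavioral parameter batteries from pose recordings.

Two fixed registries are computed per animal: a 15-parameter *track* battery
(centroid-level measures: movement, acclimation, habituation, cage-location
occupancy) and a 52-parameter *pose* battery (keypoint-level measures:
speed-class fractions, stretch-attend posture, sociability and
stimulus-response/habituation measures).

Speed classes split moving frames into low-speed "scoot" and high-speed
"burst" movement; "escape" frames are burst frames heading toward the hut
shelter shortly after a stimulus onset.  Stretch-attend posture (SAP) is an
elongated, low-speed investigative posture: nose-to-tail-base distance above
1.2x the animal's median body length at sub-movement speed.

Acclimation indices are first-minus-later differences across the first assay
hour (10-minute period 1 minus period 6); habituation indices are
first-minus-third-presentation differences of the stimulus response, where a
response is the metric in the 10-minute period after an onset minus the
period immediately before it.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .assay import AssayTimeline, PoseRecording

__all__ = [
    "SpeedClassConfig",
    "FeatureVector",
    "centroid_speed",
    "percent_moved",
    "speed_class_fractions",
    "sap_fraction",
    "acclimation",
    "habituation",
    "quadrant_occupancy",
    "distance_from_wall",
    "time_near_window",
    "battery_track15",
    "battery_pose52",
    "TRACK15_REGISTRY",
    "POSE52_REGISTRY",
    "features_table",
]


@dataclass(frozen=True)
class SpeedClassConfig:
    """Speed thresholds (px/s) and posture/escape definitions.

    ``move`` is the displacement rate above which a frame counts as moved;
    scoot is the band [move, scoot_hi), burst is >= burst_lo.  Escape frames
    are burst frames within ``escape_window_s`` of a stimulus onset with net
    motion toward the hut.  SAP requires elongation above
    ``sap_elongation`` x median body length at sub-move speed.
    """

    move: float = 2.0
    scoot_hi: float = 8.0
    burst_lo: float = 8.0
    escape_window_s: float = 600.0
    sap_elongation: float = 1.2
    grooming_elongation: float = 0.9

    def __post_init__(self) -> None:
        if not (self.move < self.scoot_hi <= self.burst_lo):
            raise ValueError("need move < scoot_hi <= burst_lo")
        if self.escape_window_s <= 0:
            raise ValueError("escape window must be positive")


@dataclass
class FeatureVector:
    """Ordered named scalar parameters for one animal and one battery."""

    animal_id: str
    battery: str
    values: dict[str, float]
    units: dict[str, str] = field(default_factory=dict)
    missing: set[str] = field(default_factory=set)
    group: object = None

    def __post_init__(self) -> None:
        expected = {"track15": 15, "pose52": 52}.get(self.battery)
        if expected is not None and len(self.values) != expected:
            raise ValueError(
                f"battery {self.battery} must have {expected} entries, got {len(self.values)}")

    def series(self) -> pd.Series:
        return pd.Series(self.values, name=self.animal_id)


# ---------------------------------------------------------------------------
# Elementary measures
# ---------------------------------------------------------------------------

def centroid_speed(rec: PoseRecording) -> np.ndarray:
    """Per-frame centroid displacement rate, px/s (frame 0 gets 0)."""
    c = rec.centroid
    d = np.hypot(*np.diff(c, axis=0).T)
    return np.concatenate([[0.0], d]) * rec.timeline.frame_rate


def _interval_mask(rec: PoseRecording, interval: tuple[float, float]) -> np.ndarray:
    m = rec.frames_in(interval)
    if not m.any():
        raise ValueError(f"interval {interval} contains no frames")
    return m


def percent_moved(rec: PoseRecording, interval: tuple[float, float],
                  cfg: SpeedClassConfig | None = None) -> float:
    """Percent of interval frames whose centroid moved above threshold."""
    cfg = cfg or SpeedClassConfig()
    m = _interval_mask(rec, interval)
    return float(100.0 * np.mean(centroid_speed(rec)[m] > cfg.move))


def _escape_frames(rec: PoseRecording, cfg: SpeedClassConfig) -> np.ndarray:
    """Burst frames within the post-onset window with motion toward the hut."""
    speed = centroid_speed(rec)
    t = rec.times
    in_window = np.zeros(rec.n_frames, dtype=bool)
    for onset_h in rec.timeline.stimulus_onsets:
        onset = onset_h * 3600.0
        in_window |= (t >= onset) & (t < onset + cfg.escape_window_s)
    c = rec.centroid
    vel = np.vstack([[0.0, 0.0], np.diff(c, axis=0)])
    to_hut = np.array(rec.geometry.hut_center) - c
    toward = (vel * to_hut).sum(axis=1) > 0
    return (speed >= cfg.burst_lo) & in_window & toward


def speed_class_fractions(rec: PoseRecording, interval: tuple[float, float],
                          cfg: SpeedClassConfig | None = None) -> dict[str, float]:
    """Moved/scoot/burst/escape percentages and mean speed over moving frames.

    Escape <= burst <= moved by construction.  When no frame moves, mean
    speed is reported as 0 with ``no_moving_frames=True``.
    """
    cfg = cfg or SpeedClassConfig()
    m = _interval_mask(rec, interval)
    speed = centroid_speed(rec)[m]
    moved = speed > cfg.move
    scoot = moved & (speed < cfg.scoot_hi)
    burst = speed >= cfg.burst_lo
    escape = _escape_frames(rec, cfg)[m]
    out = {
        "moved": 100.0 * float(np.mean(moved)),
        "scoot": 100.0 * float(np.mean(scoot)),
        "burst": 100.0 * float(np.mean(burst)),
        "escape": 100.0 * float(np.mean(escape)),
        "mean_speed": float(speed[moved].mean()) if moved.any() else 0.0,
        "no_moving_frames": not bool(moved.any()),
    }
    return out


def _elongation(rec: PoseRecording) -> np.ndarray:
    """Nose-to-tail-base distance over the animal's median body length."""
    for p in ("nose", "tail_base"):
        if not rec.has_part(p):
            raise KeyError(f"body part {p!r} required for posture measures")
    d = np.hypot(*(rec.part("nose") - rec.part("tail_base")).T)
    med = np.median(d)
    if med <= 0:
        raise ValueError("degenerate body length (median 0)")
    return d / med


def sap_fraction(rec: PoseRecording, interval: tuple[float, float],
                 cfg: SpeedClassConfig | None = None) -> float:
    """Percent of interval frames in stretch-attend posture."""
    cfg = cfg or SpeedClassConfig()
    m = _interval_mask(rec, interval)
    elong = _elongation(rec)[m]
    slow = centroid_speed(rec)[m] < cfg.move
    return float(100.0 * np.mean((elong > cfg.sap_elongation) & slow))


def _metric(rec: PoseRecording, interval: tuple[float, float], metric: str,
            cfg: SpeedClassConfig) -> float:
    if metric == "moved":
        return percent_moved(rec, interval, cfg)
    if metric == "scoot":
        return speed_class_fractions(rec, interval, cfg)["scoot"]
    if metric == "sap":
        return sap_fraction(rec, interval, cfg)
    raise ValueError(f"unknown metric {metric!r}")


def acclimation(rec: PoseRecording, metric: str = "moved",
                cfg: SpeedClassConfig | None = None) -> float:
    """Acclimation index: metric in period 1 minus period 6 of hour 1.

    Positive values mean the behavior declines as the animal settles in.
    """
    cfg = cfg or SpeedClassConfig()
    tl = rec.timeline
    if tl.duration_seconds < 6 * tl.period_seconds:
        raise ValueError("first assay hour (6 periods) not fully recorded")
    return (_metric(rec, tl.period_interval(1), metric, cfg)
            - _metric(rec, tl.period_interval(6), metric, cfg))


def habituation(rec: PoseRecording, metric: str = "moved",
                cfg: SpeedClassConfig | None = None) -> dict[str, float]:
    """Stimulus responses per presentation and the habituation index.

    response(k) = metric in the first 10-minute period after onset k minus
    the 10-minute period immediately before it; the habituation index is
    response(1) - response(3) (positive = response wanes with repetition).
    """
    cfg = cfg or SpeedClassConfig()
    tl = rec.timeline
    P = tl.period_seconds
    responses = []
    for onset_h in tl.stimulus_onsets:
        onset = onset_h * 3600.0
        if onset - P < 0 or onset + P > rec.n_frames / tl.frame_rate:
            raise ValueError(f"onset at {onset_h} h too close to the recording edge")
        post = _metric(rec, (onset, onset + P), metric, cfg)
        pre = _metric(rec, (onset - P, onset), metric, cfg)
        responses.append(post - pre)
    out = {f"response_{k + 1}": r for k, r in enumerate(responses)}
    if len(responses) >= 3:
        out["habituation_index"] = responses[0] - responses[2]
    return out


def quadrant_occupancy(rec: PoseRecording,
                       interval: tuple[float, float]) -> np.ndarray:
    """Percent of interval frames spent in each 2x2 cage quadrant (sums to 100)."""
    m = _interval_mask(rec, interval)
    c = rec.centroid[m]
    q = rec.geometry.quadrant_of(c[:, 0], c[:, 1])
    return np.array([100.0 * np.mean(q == i) for i in range(4)])


def distance_from_wall(rec: PoseRecording, interval: tuple[float, float]) -> float:
    """Mean over frames of the minimum centroid distance to any cage wall, px."""
    m = _interval_mask(rec, interval)
    c = rec.centroid[m]
    return float(np.mean(rec.geometry.wall_distance(c[:, 0], c[:, 1])))


def time_near_window(rec: PoseRecording, interval: tuple[float, float],
                     partner_near: np.ndarray | None = None,
                     with_partner: bool = False) -> float:
    """Percent of frames with the nose (fallback centroid) inside the social
    window radius; the with-partner variant additionally requires the paired
    cage's animal to be at its window in the same frame."""
    m = _interval_mask(rec, interval)
    pts = rec.part("nose") if rec.has_part("nose") else rec.centroid
    near = rec.geometry.near_window(pts[m, 0], pts[m, 1])
    if with_partner:
        if partner_near is None:
            partner_near = getattr(rec, "partner_near_window", None)
        if partner_near is None:
            return np.nan
        near = near & np.asarray(partner_near)[m]
    return float(100.0 * np.mean(near))


# ---------------------------------------------------------------------------
# Batteries
# ---------------------------------------------------------------------------

def _phase_names(tl: AssayTimeline) -> list[str]:
    return [name for name, _, _ in tl.phases]


def _first_hour(tl: AssayTimeline) -> tuple[float, float]:
    return 0.0, min(3600.0, tl.duration_seconds)


def _first_night_hour(tl: AssayTimeline) -> tuple[float, float]:
    for name, s, e in tl.phases:
        if name.startswith("night"):
            s, e = s * 3600.0, e * 3600.0
            return s, min(s + 3600.0, e)
    raise ValueError("timeline has no night phase")


#: Registry of the 15 track-battery parameters (name, unit).  Parameters not
#: named in the study text are registry extensions (per-phase movement, hut
#: occupancy) and are labeled as such in the docs.
TRACK15_REGISTRY: tuple[tuple[str, str], ...] = (
    ("movement_first_hour", "% frames"),
    ("movement_first_night_hour", "% frames"),
    ("acclimation_sap", "% points"),
    ("acclimation_movement", "% points"),
    ("habituation_moth_moved", "% points"),
    ("quadrant1_occupancy", "% frames"),
    ("quadrant2_occupancy", "% frames"),
    ("quadrant3_occupancy", "% frames"),
    ("quadrant4_occupancy", "% frames"),
    ("movement_day", "% frames"),
    ("movement_night", "% frames"),
    ("movement_night_stimuli", "% frames"),
    ("movement_day2", "% frames"),
    ("sap_first_hour", "% frames"),
    ("hut_occupancy", "% frames"),
)

_P52: list[tuple[str, str]] = []
for _iv in ("first_hour", "first_night_hour"):
    for _cls in ("moved", "scoot", "burst", "escape", "speed"):
        _P52.append((f"{_cls}_{_iv}", "px/s" if _cls == "speed" else "% frames"))
_P52 += [
    ("acclimation_movement_dlc", "% points"),
    ("acclimation_sap_dlc", "% points"),
    ("stim1_response_moved", "% points"),
    ("stim2_response_moved", "% points"),
    ("stim3_response_moved", "% points"),
    ("habituation_moth_moved_dlc", "% points"),
    ("habituation_moth_scoot", "% points"),
    ("lines1_response_moved", "% points"),
    ("lines1_response_scoot", "% points"),
    ("lines2_response_moved", "% points"),
    ("lines2_response_scoot", "% points"),
    ("distance_from_wall", "px"),
    ("time_near_window", "% frames"),
    ("time_near_window_partner", "% frames"),
]
for _q in range(1, 5):
    _P52.append((f"quadrant{_q}_night_stimuli", "% frames"))
for _ph in ("day", "night", "night_stimuli", "day2"):
    _P52.append((f"hut_{_ph}", "% frames"))
for _ph in ("day", "night", "night_stimuli", "day2"):
    _P52.append((f"moved_{_ph}", "% frames"))
for _ph in ("day", "night", "night_stimuli", "day2"):
    _P52.append((f"speed_{_ph}", "px/s"))
for _ph in ("day", "night", "night_stimuli", "day2"):
    _P52.append((f"sap_{_ph}", "% frames"))
_P52 += [
    ("peeking_from_hut", "% frames"),
    ("eating_zone", "% frames"),
    ("grooming_proxy", "% frames"),
    ("stim_response_sap_mean", "% points"),
    ("total_distance", "px"),
    ("mean_elongation", "ratio"),
    ("moved_total", "% frames"),
    ("mean_distance_window", "px"),
]

#: Registry of the 52 pose-battery parameters (name, unit).
POSE52_REGISTRY: tuple[tuple[str, str], ...] = tuple(_P52)
del _P52

REGISTRY_VERSION = "1"


def _hut_occupancy(rec: PoseRecording, interval: tuple[float, float]) -> float:
    m = _interval_mask(rec, interval)
    c = rec.centroid[m]
    return float(100.0 * np.mean(rec.geometry.in_hut(c[:, 0], c[:, 1])))


def battery_track15(rec: PoseRecording,
                    cfg: SpeedClassConfig | None = None) -> FeatureVector:
    """The 15-parameter centroid/track battery."""
    cfg = cfg or SpeedClassConfig()
    tl = rec.timeline
    full = (0.0, rec.n_frames / tl.frame_rate)
    values: dict[str, float] = {}
    missing: set[str] = set()

    def put(name: str, fn) -> None:
        try:
            values[name] = float(fn())
        except (ValueError, KeyError):
            values[name] = np.nan
            missing.add(name)

    put("movement_first_hour", lambda: percent_moved(rec, _first_hour(tl), cfg))
    put("movement_first_night_hour", lambda: percent_moved(rec, _first_night_hour(tl), cfg))
    put("acclimation_sap", lambda: acclimation(rec, "sap", cfg))
    put("acclimation_movement", lambda: acclimation(rec, "moved", cfg))
    put("habituation_moth_moved",
        lambda: habituation(rec, "moved", cfg)["habituation_index"])
    quads = quadrant_occupancy(rec, full)
    for i in range(4):
        values[f"quadrant{i + 1}_occupancy"] = float(quads[i])
    for ph in ("day", "night", "night_stimuli", "day2"):
        put(f"movement_{ph}",
            lambda ph=ph: percent_moved(rec, tl.phase_interval(ph), cfg))
    put("sap_first_hour", lambda: sap_fraction(rec, _first_hour(tl), cfg))
    put("hut_occupancy", lambda: _hut_occupancy(rec, full))

    units = dict(TRACK15_REGISTRY)
    ordered = {name: values[name] for name, _ in TRACK15_REGISTRY}
    return FeatureVector(rec.animal_id, "track15", ordered, units, missing, rec.group)


def battery_pose52(rec: PoseRecording, cfg: SpeedClassConfig | None = None,
                   partner_near: np.ndarray | None = None) -> FeatureVector:
    """The 52-parameter pose battery (activity, sociability, habituation)."""
    cfg = cfg or SpeedClassConfig()
    tl = rec.timeline
    full = (0.0, rec.n_frames / tl.frame_rate)
    values: dict[str, float] = {}
    missing: set[str] = set()

    def put(name: str, fn) -> None:
        try:
            v = float(fn())
        except (ValueError, KeyError):
            v = np.nan
        if not np.isfinite(v):
            missing.add(name)
            v = np.nan
        values[name] = v

    for tag, iv_fn in (("first_hour", _first_hour), ("first_night_hour", _first_night_hour)):
        try:
            frac = speed_class_fractions(rec, iv_fn(tl), cfg)
        except (ValueError, KeyError):
            frac = {k: np.nan for k in ("moved", "scoot", "burst", "escape", "mean_speed")}
        for cls in ("moved", "scoot", "burst", "escape"):
            put(f"{cls}_{tag}", lambda v=frac[cls]: v)
        put(f"speed_{tag}", lambda v=frac["mean_speed"]: v)

    put("acclimation_movement_dlc", lambda: acclimation(rec, "moved", cfg))
    put("acclimation_sap_dlc", lambda: acclimation(rec, "sap", cfg))
    try:
        hab_m = habituation(rec, "moved", cfg)
        hab_s = habituation(rec, "scoot", cfg)
        hab_sap = habituation(rec, "sap", cfg)
    except ValueError:
        hab_m = hab_s = hab_sap = {}
    for k in (1, 2, 3):
        put(f"stim{k}_response_moved", lambda k=k: hab_m[f"response_{k}"])
    put("habituation_moth_moved_dlc", lambda: hab_m["habituation_index"])
    put("habituation_moth_scoot", lambda: hab_s["habituation_index"])
    # the second and third presentations carry the moving-lines responses
    put("lines1_response_moved", lambda: hab_m["response_2"])
    put("lines1_response_scoot", lambda: hab_s["response_2"])
    put("lines2_response_moved", lambda: hab_m["response_3"])
    put("lines2_response_scoot", lambda: hab_s["response_3"])
    put("distance_from_wall", lambda: distance_from_wall(rec, full))
    put("time_near_window", lambda: time_near_window(rec, full))
    put("time_near_window_partner",
        lambda: time_near_window(rec, full, partner_near, with_partner=True))
    try:
        stim_iv = tl.phase_interval("night_stimuli")
        quads = quadrant_occupancy(rec, stim_iv)
        for i in range(4):
            values[f"quadrant{i + 1}_night_stimuli"] = float(quads[i])
    except (ValueError, KeyError):
        for i in range(4):
            values[f"quadrant{i + 1}_night_stimuli"] = np.nan
            missing.add(f"quadrant{i + 1}_night_stimuli")
    for ph in ("day", "night", "night_stimuli", "day2"):
        put(f"hut_{ph}", lambda ph=ph: _hut_occupancy(rec, tl.phase_interval(ph)))
    for ph in ("day", "night", "night_stimuli", "day2"):
        put(f"moved_{ph}", lambda ph=ph: percent_moved(rec, tl.phase_interval(ph), cfg))
    for ph in ("day", "night", "night_stimuli", "day2"):
        put(f"speed_{ph}", lambda ph=ph: speed_class_fractions(
            rec, tl.phase_interval(ph), cfg)["mean_speed"])
    for ph in ("day", "night", "night_stimuli", "day2"):
        put(f"sap_{ph}", lambda ph=ph: sap_fraction(rec, tl.phase_interval(ph), cfg))

    def peeking() -> float:
        c = rec.centroid
        nose = rec.part("nose")
        in_hut = rec.geometry.in_hut(c[:, 0], c[:, 1])
        nose_out = ~rec.geometry.in_hut(nose[:, 0], nose[:, 1])
        return 100.0 * float(np.mean(in_hut & nose_out))

    def eating() -> float:
        nose = rec.part("nose")
        g = rec.geometry
        # food hopper corner: opposite the window (top-left of the crop)
        d = np.hypot(nose[:, 0], nose[:, 1])
        return 100.0 * float(np.mean(d <= 4.0 * g.px_per_cm))

    def grooming() -> float:
        elong = _elongation(rec)
        slow = centroid_speed(rec) < cfg.move
        return 100.0 * float(np.mean((elong < cfg.grooming_elongation) & slow))

    put("peeking_from_hut", peeking)
    put("eating_zone", eating)
    put("grooming_proxy", grooming)
    put("stim_response_sap_mean",
        lambda: np.mean([hab_sap[f"response_{k}"] for k in (1, 2, 3)]))
    put("total_distance", lambda: float(np.sum(
        np.hypot(*np.diff(rec.centroid, axis=0).T))))
    put("mean_elongation", lambda: float(np.mean(_elongation(rec))))
    put("moved_total", lambda: percent_moved(rec, full, cfg))
    put("mean_distance_window", lambda: float(np.mean(np.hypot(
        rec.part("nose")[:, 0] - rec.geometry.window_center[0],
        rec.part("nose")[:, 1] - rec.geometry.window_center[1]))))

    units = dict(POSE52_REGISTRY)
    ordered = {name: values[name] for name, _ in POSE52_REGISTRY}
    return FeatureVector(rec.animal_id, "pose52", ordered, units, missing, rec.group)


def features_table(vectors: list[FeatureVector]) -> pd.DataFrame:
    """Tidy table: one row per (animal, battery, parameter)."""
    rows = []
    for fv in vectors:
        for name, value in fv.values.items():
            rows.append({
                "animal": fv.animal_id,
                "group": getattr(fv.group, "label", None),
                "battery": fv.battery,
                "parameter": name,
                "value": value,
                "units": fv.units.get(name, ""),
                "missing": name in fv.missing,
            })
    return pd.DataFrame(rows)
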