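"""Shared fixtures: hand-built pose recordings and a desk-scale cohort."""

from __future__ import annotations

import numpy as np
import pytest

from phenocage.assay import AssayTimeline, CageGeometry, GroupLabel, PoseRecording
from phenocage.synth import _TEMPLATE


def build_recording(centroid, timeline=None, geometry=None, elongation=None,
                    likelihood=None, animal_id="m0", group=None) -> PoseRecording:
    """A recording with all 12 keypoints laid on the body template at a fixed
    eastward heading, driven by an explicit centroid track (n, 2)."""
    centroid = np.asarray(centroid, dtype=float)
    n = len(centroid)
    timeline = timeline or AssayTimeline.scaled(n / 3600.0)
    geometry = geometry or CageGeometry()
    parts = tuple(_TEMPLATE)
    elong = np.ones(n) if elongation is None else np.asarray(elongation, float)
    xy = np.empty((n, len(parts), 2))
    for j, p in enumerate(parts):
        lon, lat = _TEMPLATE[p]
        xy[:, j, 0] = centroid[:, 0] + lon * elong
        xy[:, j, 1] = centroid[:, 1] + lat
    lik = np.ones((n, len(parts))) if likelihood is None else likelihood
    return PoseRecording(animal_id=animal_id, bodyparts=parts, xy=xy,
                         likelihood=lik, timeline=timeline, geometry=geometry,
                         group=group or GroupLabel())


def track_with_moved_fraction(windows, n, step=5.0, x0=150.0, y0=120.0):
    """Centroid track that moves (displacement `step` px) on the first
    ``round(frac * len(window))`` frames of each (f0, f1, frac) window and
    stays put elsewhere; motion alternates direction to stay in the cage."""
    moving = np.zeros(n, dtype=bool)
    for f0, f1, frac in windows:
        k = int(round(frac * (f1 - f0)))
        moving[f0:f0 + k] = True
    x = np.full(n, x0)
    dx = np.where(moving, step, 0.0) * np.where(np.arange(n) % 2 == 0, 1, -1)
    x = x0 + np.cumsum(dx)
    return np.stack([x, np.full(n, y0)], axis=1)


@pytest.fixture(scope="session")
def tl3() -> AssayTimeline:
    """3-hour test timeline: full first hour, a night phase, and three
    stimulus onsets with 10-minute margins on both sides."""
    return AssayTimeline(
        frame_rate=1.0,
        phases=(("day", 0.0, 1.0), ("night", 1.0, 1.5),
                ("night_stimuli", 1.5, 2.75), ("day2", 2.75, 3.0)),
        stimulus_onsets=(1.5, 1.9, 2.3),
    )


@pytest.fixture(scope="session")
def small_cohort():
    """One seeded 2-hour cohort with all ten groups, shared across tests."""
    from phenocage.synth import CohortConfig, simulate_cohort

    cfg = CohortConfig(n_per_group=2, duration_hours=2.0, seed=7)
    recs, seqs, runs = simulate_cohort(cfg)
    return cfg, recs, seqs, runs
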