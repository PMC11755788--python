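"""Summaries of behavioral syllable label sequences.

A syllable sequence is a per-frame integer labeling produced by an
unsupervised segmentation (e.g. Keypoint-MoSeq) over a fixed codebook —
here consumed, never fitted.  Bouts are maximal runs of a constant label.
Frequency is bout-based (the fraction of all bouts carried by a syllable),
following the MoSeq convention; frame-based occupancy is emitted alongside
since the two conventions differ whenever bout durations differ.

Label ids may be non-contiguous (unsupervised pipelines renumber freely);
the codebook is an explicit tuple of ids.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .assay import AssayTimeline

__all__ = [
    "SyllableSequence",
    "bouts",
    "frequency_duration",
    "distinct_syllables",
    "transition_matrix",
    "stimulus_onset_summaries",
    "read_syllable_csv",
]


@dataclass
class SyllableSequence:
    """Per-frame integer syllable labels for one animal."""

    animal_id: str
    labels: np.ndarray
    frame_rate: float = 1.0
    codebook_labels: tuple[int, ...] | None = None
    group: object = None

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        if self.labels.ndim != 1 or len(self.labels) == 0:
            raise ValueError("labels must be a non-empty 1-D integer array")
        if self.codebook_labels is None:
            self.codebook_labels = tuple(sorted(np.unique(self.labels)))
        else:
            unknown = set(np.unique(self.labels)) - set(self.codebook_labels)
            if unknown:
                raise ValueError(f"labels {sorted(unknown)} not in the codebook")

    @property
    def n_frames(self) -> int:
        return len(self.labels)

    def window_frames(self, window: tuple[float, float] | None) -> tuple[int, int]:
        """Half-open frame range [f0, f1) for a (t0, t1) second window."""
        if window is None:
            return 0, self.n_frames
        t0, t1 = window
        f0 = int(np.ceil(t0 * self.frame_rate - 1e-9))
        f1 = int(np.ceil(t1 * self.frame_rate - 1e-9))
        return max(f0, 0), min(f1, self.n_frames)


def bouts(seq: SyllableSequence) -> list[tuple[int, int, int]]:
    """Run-length encode the sequence: (label, start frame, length) per bout.

    Concatenating the runs reconstructs the sequence exactly.
    """
    lab = seq.labels
    change = np.flatnonzero(np.diff(lab)) + 1
    starts = np.concatenate([[0], change])
    ends = np.concatenate([change, [len(lab)]])
    return [(int(lab[s]), int(s), int(e - s)) for s, e in zip(starts, ends)]


def _window_bouts(seq: SyllableSequence,
                  window: tuple[float, float] | None) -> list[tuple[int, int, int]]:
    f0, f1 = seq.window_frames(window)
    # a bout belongs to the window containing its start frame (additivity)
    return [b for b in bouts(seq) if f0 <= b[1] < f1]


def frequency_duration(seq: SyllableSequence,
                       window: tuple[float, float] | None = None) -> pd.DataFrame:
    """Per-syllable bout frequency, frame occupancy and mean bout duration.

    Returns one row per codebook syllable with columns ``n_bouts``,
    ``frequency`` (bouts of s / total bouts in window), ``occupancy``
    (fraction of window frames), ``mean_duration_s`` (NaN and
    ``defined=False`` for syllables with zero bouts).
    """
    wb = _window_bouts(seq, window)
    f0, f1 = seq.window_frames(window)
    total_bouts = len(wb)
    rows = []
    for lab in seq.codebook_labels:
        mine = [b for b in wb if b[0] == lab]
        n = len(mine)
        frames = int(np.sum(seq.labels[f0:f1] == lab)) if f1 > f0 else 0
        rows.append({
            "syllable": lab,
            "n_bouts": n,
            "frequency": n / total_bouts if total_bouts else 0.0,
            "occupancy": frames / (f1 - f0) if f1 > f0 else 0.0,
            "mean_duration_s": (np.mean([b[2] for b in mine]) / seq.frame_rate
                                if n else np.nan),
            "defined": n > 0,
        })
    df = pd.DataFrame(rows).set_index("syllable")
    df.attrs["empty_window"] = total_bouts == 0
    return df


def distinct_syllables(seq: SyllableSequence,
                       window: tuple[float, float] | None = None) -> int:
    """Number of syllables with at least one bout starting in the window."""
    return len({b[0] for b in _window_bouts(seq, window)})


def transition_matrix(seq: SyllableSequence,
                      normalize: bool = True) -> pd.DataFrame:
    """Bout-to-bout transition matrix over the codebook.

    Self-transitions are impossible by bout construction.  With
    ``normalize=True`` rows are made stochastic; rows without outgoing
    transitions are left at zero and listed in ``df.attrs['empty_rows']``.
    """
    labs = list(seq.codebook_labels)
    index = {lab: i for i, lab in enumerate(labs)}
    M = np.zeros((len(labs), len(labs)))
    bs = bouts(seq)
    for (a, _, _), (b, _, _) in zip(bs[:-1], bs[1:]):
        M[index[a], index[b]] += 1
    empty = [labs[i] for i in range(len(labs)) if M[i].sum() == 0]
    if normalize:
        sums = M.sum(axis=1, keepdims=True)
        with np.errstate(invalid="ignore", divide="ignore"):
            M = np.where(sums > 0, M / np.where(sums == 0, 1, sums), 0.0)
    df = pd.DataFrame(M, index=labs, columns=labs)
    df.attrs["empty_rows"] = empty
    return df


def stimulus_onset_summaries(seq: SyllableSequence,
                             timeline: AssayTimeline) -> dict[int, pd.DataFrame]:
    """Frequency/duration summaries over the first 10-minute period after
    each stimulus onset, keyed by 1-based period index (73, 85, 97 at the
    default timeline)."""
    out = {}
    for onset_h in timeline.stimulus_onsets:
        t0 = onset_h * 3600.0
        period = timeline.period_index(t0)
        out[period] = frequency_duration(seq, (t0, t0 + timeline.period_seconds))
    return out


def read_syllable_csv(path, animal_id: str | None = None, frame_rate: float = 1.0,
                      codebook_labels: tuple[int, ...] | None = None,
                      group=None) -> SyllableSequence:
    """Read a per-frame label CSV with columns ``frame, syllable``."""
    df = pd.read_csv(path)
    if not {"frame", "syllable"} <= set(df.columns):
        raise ValueError(f"{path}: expected columns frame, syllable")
    df = df.sort_values("frame")
    from pathlib import Path
    return SyllableSequence(
        animal_id=animal_id or Path(path).stem.replace("syllables_", ""),
        labels=df["syllable"].to_numpy(int), frame_rate=frame_rate,
        codebook_labels=codebook_labels, group=group)
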