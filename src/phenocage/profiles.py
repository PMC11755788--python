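"""Behavioral profiles and PCA-weighted hierarchical clustering.

A behavioral profile is one row per experimental group holding 125 named,
ordered parameters: the 15-parameter track battery, the 52-parameter pose
battery, and the per-syllable bout frequency and mean duration over a
29-syllable codebook (15 + 52 + 29 + 29 = 125).

Profiles are clustered with Ward's method on Euclidean distances after two
preprocessing steps: columns are z-scored, then multiplied by the square
root of a per-column weight so that squared Euclidean distance is linear in
the weights.  Weights are the absolute PC1 loadings of a PCA on the
z-scored profile matrix, renormalized to mean 1 (zero-variance columns get
weight 0 and are flagged).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from sklearn.decomposition import PCA

from .homecage import FeatureVector, TRACK15_REGISTRY, POSE52_REGISTRY
from .syllables import SyllableSequence, frequency_duration

__all__ = [
    "N_PROFILE_COLUMNS",
    "profile_columns",
    "assemble_profiles",
    "pca_weights",
    "weighted_ward",
    "ClusterResult",
    "export_dendrogram",
    "linkage_to_newick",
]

N_TRACK, N_POSE, N_SYL = 15, 52, 29
N_PROFILE_COLUMNS = N_TRACK + N_POSE + 2 * N_SYL  # 125


def profile_columns(syllable_labels: tuple[int, ...]) -> list[str]:
    """The fixed, ordered 125 profile column names for a codebook."""
    cols = [f"track15:{n}" for n, _ in TRACK15_REGISTRY]
    cols += [f"pose52:{n}" for n, _ in POSE52_REGISTRY]
    cols += [f"syl_freq:{lab}" for lab in syllable_labels]
    cols += [f"syl_dur:{lab}" for lab in syllable_labels]
    return cols


def assemble_profiles(track: list[FeatureVector], pose: list[FeatureVector],
                      syllables: list[SyllableSequence],
                      per_animal: bool = False) -> pd.DataFrame:
    """Assemble the 125-column profile matrix.

    Every animal must carry all three inputs under the same id; rows are
    per-group means (or per-animal with ``per_animal=True``).  Missing
    values are imputed by the column median; imputed cells are recorded in
    ``df.attrs['imputed']``.
    """
    track_by = {fv.animal_id: fv for fv in track}
    pose_by = {fv.animal_id: fv for fv in pose}
    if len(track_by) != len(track) or len(pose_by) != len(pose):
        raise ValueError("duplicate animal ids in feature vectors")
    syl_by = {s.animal_id: s for s in syllables}
    animals = sorted(track_by)
    if set(animals) != set(pose_by) or set(animals) != set(syl_by):
        raise ValueError("animal ids differ across the three batteries")
    labels = syllables[0].codebook_labels
    if len(labels) != N_SYL:
        raise ValueError(f"codebook must have {N_SYL} syllables, got {len(labels)}")
    cols = profile_columns(labels)
    rows, groups = [], []
    for a in animals:
        fv_t, fv_p, seq = track_by[a], pose_by[a], syl_by[a]
        g = getattr(fv_t.group, "label", None)
        if g is None:
            raise ValueError(f"animal {a!r} has no group label")
        fd = frequency_duration(seq)
        row = list(fv_t.values.values()) + list(fv_p.values.values())
        row += [fd.loc[lab, "frequency"] for lab in labels]
        row += [fd.loc[lab, "mean_duration_s"] for lab in labels]
        rows.append(row)
        groups.append(g)
    df = pd.DataFrame(rows, columns=cols, index=animals)
    df["__group"] = groups
    counts = df.groupby("__group").size()
    if (counts == 0).any():  # pragma: no cover - groupby cannot emit empties
        raise ValueError("group with zero animals")
    if not per_animal:
        df = df.groupby("__group").mean(numeric_only=True)
        df.index.name = "group"
    else:
        df = df.drop(columns="__group")
    df = df.sort_index()
    # impute residual missing values by column median, keeping an audit trail
    imputed = [(str(i), c) for i, c in zip(*np.where(df.isna()))]
    med = df.median()
    df = df.fillna(med).fillna(0.0)
    df.attrs["imputed"] = [(df.index[int(i)], df.columns[c]) for i, c in imputed]
    return df


def pca_weights(profiles: pd.DataFrame) -> tuple[pd.DataFrame, np.ndarray, pd.Series]:
    """PC1-loading weights for the profile columns.

    Columns are z-scored (population sd); zero-variance columns are dropped
    from the PCA and get weight 0.  Returns (loadings, explained-variance
    ratios, weights with mean 1 over retained columns).
    """
    if len(profiles) < 3:
        raise ValueError("need at least 3 profile rows for PCA")
    X = profiles.to_numpy(float)
    sd = X.std(axis=0)
    retained = sd > 0
    if not retained.any():
        raise ValueError("all profile columns are constant")
    Z = (X[:, retained] - X[:, retained].mean(axis=0)) / sd[retained]
    n_comp = min(Z.shape)
    pca = PCA(n_components=n_comp, svd_solver="full")
    pca.fit(Z)
    loadings = pd.DataFrame(
        pca.components_.T, index=profiles.columns[retained],
        columns=[f"PC{i + 1}" for i in range(n_comp)])
    w = np.zeros(profiles.shape[1])
    w_ret = np.abs(pca.components_[0])
    w[retained] = w_ret / w_ret.mean()
    weights = pd.Series(w, index=profiles.columns, name="weight")
    weights.attrs["zero_variance"] = list(profiles.columns[~retained])
    return loadings, pca.explained_variance_ratio_, weights


@dataclass
class ClusterResult:
    """Weighted Ward clustering of a profile matrix."""

    labels: list[str]
    linkage: np.ndarray
    assignments: pd.Series
    weights: pd.Series
    loadings: pd.DataFrame | None = None
    explained_variance_ratio: np.ndarray | None = None

    def newick(self) -> str:
        return linkage_to_newick(self.linkage, self.labels)


def weighted_ward(profiles: pd.DataFrame, weights: pd.Series | np.ndarray,
                  k: int = 3) -> ClusterResult:
    """Ward clustering on z-scored, sqrt-weight-scaled profiles.

    Multiplying the j-th z-scored column by sqrt(w_j) makes the squared
    Euclidean distance linear in the weights.  Rows are processed in
    lexicographic label order so ties break deterministically.
    """
    w = np.asarray(weights, dtype=float)
    if w.shape[0] != profiles.shape[1]:
        raise ValueError("weights length must equal the number of columns")
    if (w < 0).any():
        raise ValueError("weights must be non-negative")
    df = profiles.sort_index()
    X = df.to_numpy(float)
    sd = X.std(axis=0)
    sd[sd == 0] = 1.0
    Z = (X - X.mean(axis=0)) / sd
    if isinstance(weights, pd.Series):
        w = weights.reindex(df.columns).to_numpy(float)
    Xw = Z * np.sqrt(w)
    link = hierarchy.linkage(Xw, method="ward")
    flat = hierarchy.fcluster(link, t=k, criterion="maxclust")
    assignments = pd.Series(flat, index=df.index, name="cluster")
    return ClusterResult(labels=list(df.index), linkage=link, assignments=assignments,
                         weights=pd.Series(w, index=df.columns))


def linkage_to_newick(linkage: np.ndarray, labels: list[str]) -> str:
    """Render a scipy linkage as a Newick string with merge heights as
    cumulative node heights (leaf branch length = parent height)."""
    if len(labels) < 2:
        raise ValueError("need at least 2 leaves for a dendrogram")
    tree = hierarchy.to_tree(linkage)

    def walk(node, parent_height: float) -> str:
        length = parent_height - node.dist
        if node.is_leaf():
            return f"{labels[node.id]}:{length:.6g}"
        left = walk(node.left, node.dist)
        right = walk(node.right, node.dist)
        return f"({left},{right}):{length:.6g}"

    left = walk(tree.left, tree.dist)
    right = walk(tree.right, tree.dist)
    return f"({left},{right});"


def export_dendrogram(result: ClusterResult, path: str | Path) -> Path:
    """Write the dendrogram as a Newick file."""
    path = Path(path)
    path.write_text(result.newick() + "\n")
    return path
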