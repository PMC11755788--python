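"""Group-comparison statistics and significance-matrix reporting.

The battery mirrors standard practice in behavioral phenotyping: a
Shapiro-Wilk normality gate; two-way ANOVA (age x genotype, with
interaction) followed by Tukey HSD when the interaction is significant, for
gait parameters; the unpaired two-sample Wilcoxon rank-sum test for
home-cage parameters; and Kruskal-Wallis with Dunn's two-sided post-hoc
z-tests for syllable frequencies.  Significance is read at p < 0.05
per parameter (no family-wise correction by default; Benjamini-Hochberg is
available behind a flag), with star annotations at 0.05 / 0.01 / 0.001 and
direction arrows versus the reference group.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import comb

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.formula.api import ols
from statsmodels.stats.anova import anova_lm
from statsmodels.stats.multicomp import pairwise_tukeyhsd
from statsmodels.stats.multitest import multipletests

__all__ = [
    "StatResult",
    "stars",
    "shapiro_gate",
    "gait_anova",
    "homecage_wilcoxon",
    "syllable_kw_dunn",
    "significance_matrix",
    "parse_cell",
]

ALPHA = 0.05


def stars(p: float) -> str:
    """Star annotation: * p<0.05, ** p<0.01, *** p<0.001, else NS."""
    if not np.isfinite(p):
        return "NS"
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < ALPHA:
        return "*"
    return "NS"


@dataclass
class StatResult:
    """Outcome of one test: identity, statistic, p, post-hoc, annotation."""

    test: str
    statistic: float
    p: float
    posthoc: pd.DataFrame | None = None
    direction: str | None = None       # "up"/"down" vs reference, p < 0.05 only
    normality_p: float | None = None
    extra: dict | None = None

    def __post_init__(self) -> None:
        if np.isfinite(self.p) and not (0.0 <= self.p <= 1.0):
            raise ValueError("p-value outside [0, 1]")
        if self.p >= ALPHA:
            self.direction = None

    @property
    def stars(self) -> str:
        return stars(self.p)

    @property
    def significant(self) -> bool:
        return bool(self.p < ALPHA)

    @property
    def annotation(self) -> str:
        if not self.significant:
            return "NS"
        arrow = {"up": "↑", "down": "↓", None: ""}[self.direction]
        return f"{self.stars}{arrow}"


def shapiro_gate(sample) -> tuple[float, float, bool]:
    """Shapiro-Wilk normality gate: (W, p, normal at alpha=0.05)."""
    x = np.asarray(sample, dtype=float)
    if len(x) < 3:
        raise ValueError("Shapiro-Wilk needs at least 3 observations")
    if np.ptp(x) == 0:
        raise ValueError("constant sample has no defined normality test")
    W, p = sps.shapiro(x)
    return float(W), float(p), bool(p >= ALPHA)


def gait_anova(values, age, genotype) -> StatResult:
    """Two-way ANOVA (age x genotype with interaction) on one gait parameter.

    Tukey HSD pairwise comparisons across the age-genotype cells are run
    only when the interaction is significant; otherwise the main effects
    stand on their own.  The headline statistic/p is the interaction term;
    main effects are in ``extra``.
    """
    df = pd.DataFrame({
        "value": np.asarray(values, float),
        "age": pd.Categorical(age),
        "genotype": pd.Categorical(genotype),
    })
    if df["value"].isna().any():
        df = df.dropna(subset=["value"])
    model = ols("value ~ C(age) * C(genotype)", data=df).fit()
    table = anova_lm(model, typ=2)
    p_age = float(table.loc["C(age)", "PR(>F)"])
    p_gen = float(table.loc["C(genotype)", "PR(>F)"])
    p_int = float(table.loc["C(age):C(genotype)", "PR(>F)"])
    f_int = float(table.loc["C(age):C(genotype)", "F"])
    posthoc = None
    if p_int < ALPHA:
        cells = df["age"].astype(str) + ":" + df["genotype"].astype(str)
        tk = pairwise_tukeyhsd(df["value"].to_numpy(), cells.to_numpy())
        posthoc = pd.DataFrame(tk.summary().data[1:], columns=tk.summary().data[0])
    return StatResult(
        test="two-way ANOVA", statistic=f_int, p=p_int, posthoc=posthoc,
        extra={"anova_table": table, "p_age": p_age, "p_genotype": p_gen,
               "F_age": float(table.loc["C(age)", "F"]),
               "F_genotype": float(table.loc["C(genotype)", "F"])})


def homecage_wilcoxon(group_a, group_b) -> StatResult:
    """Unpaired two-sample Wilcoxon rank-sum test, two-sided.

    Uses the exact null for groups of up to 10 (full permutation
    enumeration when ties are present, the closed-form exact distribution
    otherwise) and the tie-corrected normal approximation for larger groups.
    Direction reports group A versus group B.
    """
    a = np.asarray(group_a, float)
    b = np.asarray(group_b, float)
    if len(a) < 1 or len(b) < 1:
        raise ValueError("both groups must be non-empty")
    has_ties = len(np.unique(np.concatenate([a, b]))) < len(a) + len(b)
    if max(len(a), len(b)) <= 10:
        if has_ties:
            method = sps.PermutationMethod(n_resamples=comb(len(a) + len(b), len(a)) + 1)
        else:
            method = "exact"
        kind = "exact"
    else:
        method = "asymptotic"
        kind = "asymptotic"
    res = sps.mannwhitneyu(a, b, alternative="two-sided", method=method)
    direction = "up" if np.median(a) > np.median(b) else "down"
    return StatResult(test=f"Wilcoxon rank-sum ({kind})",
                      statistic=float(res.statistic), p=float(res.pvalue),
                      direction=direction)


def _dunn(groups: dict[str, np.ndarray]) -> pd.DataFrame:
    """Dunn's two-sided pairwise z-tests on pooled mid-ranks with tie
    correction; Holm-adjusted p-values by default."""
    names = list(groups)
    pooled = np.concatenate([groups[g] for g in names])
    n_tot = len(pooled)
    ranks = sps.rankdata(pooled)
    mean_rank, sizes, i0 = {}, {}, 0
    for g in names:
        n = len(groups[g])
        mean_rank[g] = ranks[i0:i0 + n].mean()
        sizes[g] = n
        i0 += n
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = (tie_counts ** 3 - tie_counts).sum() / (12.0 * (n_tot - 1))
    rows = []
    for i, gi in enumerate(names):
        for gj in names[i + 1:]:
            se = np.sqrt((n_tot * (n_tot + 1) / 12.0 - tie_term)
                         * (1.0 / sizes[gi] + 1.0 / sizes[gj]))
            z = (mean_rank[gi] - mean_rank[gj]) / se
            p = 2.0 * sps.norm.sf(abs(z))
            rows.append({"group_a": gi, "group_b": gj, "z": z, "p": p})
    df = pd.DataFrame(rows)
    df["p_adj"] = multipletests(df["p"], method="holm")[1]
    return df


def syllable_kw_dunn(groups: dict[str, np.ndarray]) -> StatResult:
    """Kruskal-Wallis across groups with Dunn's post-hoc z-tests.

    ``groups`` maps group label to the per-animal values of one syllable
    measure.  Dunn p-values are Holm-adjusted.
    """
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    arrays = [np.asarray(v, float) for v in groups.values()]
    H, p = sps.kruskal(*arrays)
    posthoc = _dunn({g: np.asarray(v, float) for g, v in groups.items()})
    return StatResult(test="Kruskal-Wallis + Dunn", statistic=float(H),
                      p=float(p), posthoc=posthoc)


def significance_matrix(results: pd.DataFrame,
                        adjust: str | None = None) -> pd.DataFrame:
    """Render a tidy result table as a parameter x contrast annotation grid.

    ``results`` needs columns ``parameter``, ``contrast``, ``p`` and
    ``direction`` ("up"/"down"/None).  Cells read NS, or stars plus an
    arrow (e.g. ``**↑``).  ``adjust='fdr_bh'`` applies
    Benjamini-Hochberg across all cells before annotation.
    """
    df = results.copy()
    required = {"parameter", "contrast", "p", "direction"}
    if not required <= set(df.columns):
        raise ValueError(f"results must have columns {sorted(required)}")
    if adjust:
        df["p"] = multipletests(df["p"], method=adjust)[1]

    def cell(row) -> str:
        if not (row["p"] < ALPHA):
            return "NS"
        arrow = {"up": "↑", "down": "↓"}.get(row["direction"], "")
        return f"{stars(row['p'])}{arrow}"

    df["cell"] = df.apply(cell, axis=1)
    grid = df.pivot(index="parameter", columns="contrast", values="cell")
    return grid


def parse_cell(cell: str) -> tuple[str, str | None]:
    """Invert a significance-matrix cell into (stars, direction)."""
    if cell == "NS":
        return "NS", None
    direction = None
    if cell.endswith("↑"):
        direction, cell = "up", cell[:-1]
    elif cell.endswith("↓"):
        direction, cell = "down", cell[:-1]
    if cell not in {"*", "**", "***"}:
        raise ValueError(f"unparseable cell {cell!r}")
    return cell, direction
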