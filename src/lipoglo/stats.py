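"""Heteroscedasticity-aware statistics for the lipoprotein assays.

The analysis workflow applies one decision tree to every dataset:

* Levene's test (mean-centered) gates on homogeneity of variance.
* Uniform variance: classical one-way ANOVA with Tukey's HSD post hoc.
* Unequal variance: Welch's ANOVA with a Games–Howell post hoc, both using
  Welch–Satterthwaite degrees of freedom.
* Two-factor designs (genotype x developmental stage): a robust two-way
  ANOVA on 20%-trimmed cell means with a percentile-bootstrap null,
  followed by Games–Howell on untrimmed data.
* Bonferroni correction across the per-subclass (k=4, threshold 0.0125) or
  per-region (k=3, reported 0.017) test families.
* Enrichment/depletion calls per class and timepoint against a control
  series (Games–Howell, p < 0.05), rendered as up/down arrowheads in plots.

Levene, the classical one-way F and Tukey's HSD delegate to scipy; Welch's
ANOVA, Games–Howell and the trimmed-mean bootstrap two-way test are
implemented here (with the studentized-range distribution from scipy).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "TestResult",
    "RobustTwoWayResult",
    "levene",
    "anova_tukey",
    "welch_anova",
    "games_howell",
    "robust_two_way",
    "bonferroni_alpha",
    "BonferroniThreshold",
    "call_changes",
    "decision_tree",
    "groups_from_frame",
]


@dataclass
class TestResult:
    """Outcome of one hypothesis test.

    ``df`` may be fractional (Welch–Satterthwaite).  ``pairwise`` holds the
    post hoc table for omnibus tests, with one row per unordered group pair.
    """

    method: str
    statistic: float
    df: tuple[float, ...]
    p_value: float
    pairwise: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_value <= 1.0 or math.isnan(self.p_value)):
            raise ValueError(f"p-value outside [0, 1]: {self.p_value}")

    def summary(self) -> str:
        df_txt = ", ".join(f"{d:g}" for d in self.df)
        lines = [
            f"{self.method}: statistic = {self.statistic:.4f}, "
            f"df = ({df_txt}), p = {self.p_value:.4g}"
        ]
        if self.pairwise is not None:
            lines.append(self.pairwise.to_string(index=False))
        return "\n".join(lines)


def groups_from_frame(
    df: pd.DataFrame, value: str = "value", factor: str = "group"
) -> tuple[list[np.ndarray], list]:
    """Split a long-format table into per-level value arrays."""
    labels, groups = [], []
    for lab, sub in df.groupby(factor, sort=True):
        labels.append(lab)
        groups.append(sub[value].to_numpy(dtype=float))
    return groups, labels


def _check_groups(groups, min_n: int = 2, require_variance: bool = False):
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    for i, g in enumerate(groups):
        if g.size < min_n:
            raise ValueError(f"group {i} has n = {g.size} < {min_n}")
        if require_variance and np.var(g, ddof=1) == 0:
            raise ValueError(f"group {i} has zero variance; test undefined")
    return groups


def levene(groups) -> TestResult:
    """Levene's test for homogeneity of variance (center = mean).

    The classical mean-centered form (not the Brown–Forsythe median
    variant).  Identical groups give statistic 0 and p = 1.
    """
    groups = _check_groups(groups, min_n=2)
    if all(np.all(g == g[0]) for g in groups):  # all-constant: no dispersion anywhere
        k, n = len(groups), sum(g.size for g in groups)
        return TestResult("Levene (center=mean)", 0.0, (k - 1, n - k), 1.0)
    stat, p = sps.levene(*groups, center="mean")
    k, n = len(groups), sum(g.size for g in groups)
    return TestResult("Levene (center=mean)", float(stat), (k - 1, n - k), float(p))


def anova_tukey(groups, labels=None) -> TestResult:
    """Classical one-way ANOVA with Tukey HSD pairwise post hoc.

    Intended for the homogeneous-variance branch of the decision tree
    (callers gate via :func:`levene`).  Pairwise p-values come from the
    studentized-range distribution.
    """
    groups = _check_groups(groups, min_n=2)
    labels = list(labels) if labels is not None else list(range(len(groups)))
    means = [g.mean() for g in groups]
    if all(np.allclose(g.var(ddof=1), 0) for g in groups) and len(set(means)) == 1:
        f_stat, p = 0.0, 1.0
    else:
        f_stat, p = sps.f_oneway(*groups)
        if np.isnan(f_stat):  # zero within-group variance, equal means
            f_stat, p = 0.0, 1.0
    hsd = sps.tukey_hsd(*groups)
    rows = []
    for i, j in combinations(range(len(groups)), 2):
        rows.append(
            {
                "group1": labels[i],
                "group2": labels[j],
                "mean_diff": means[i] - means[j],
                "p_value": float(np.clip(hsd.pvalue[i, j], 0.0, 1.0)),
            }
        )
    k, n = len(groups), sum(g.size for g in groups)
    return TestResult(
        "One-way ANOVA + Tukey HSD",
        float(f_stat),
        (k - 1, n - k),
        float(p),
        pairwise=pd.DataFrame(rows),
    )


def welch_anova(groups, labels=None) -> TestResult:
    """Welch's heteroscedastic one-way ANOVA.

    F* uses inverse-variance weights with a Welch–Satterthwaite denominator
    df; robust to unequal group variances.  Every group needs n >= 2 and
    positive variance.
    """
    groups = _check_groups(groups, min_n=2, require_variance=True)
    k = len(groups)
    n = np.array([g.size for g in groups], dtype=float)
    m = np.array([g.mean() for g in groups])
    v = np.array([g.var(ddof=1) for g in groups])
    w = n / v
    u = w.sum()
    grand = (w * m).sum() / u
    a = (w * (m - grand) ** 2).sum() / (k - 1)
    tmp = ((1 - w / u) ** 2 / (n - 1)).sum()
    b = 1 + 2 * (k - 2) / (k**2 - 1) * tmp
    f_star = a / b
    df2 = (k**2 - 1) / (3 * tmp)
    p = float(sps.f.sf(f_star, k - 1, df2))
    return TestResult("Welch ANOVA", float(f_star), (k - 1, float(df2)), p)


def games_howell(groups, labels=None) -> TestResult:
    """Games–Howell pairwise comparisons.

    Pairwise q statistics with Welch–Satterthwaite df, p-values from the
    studentized range with the full number of groups k.  The omnibus fields
    of the returned result carry the smallest pairwise p.
    """
    groups = _check_groups(groups, min_n=2, require_variance=True)
    labels = list(labels) if labels is not None else list(range(len(groups)))
    k = len(groups)
    n = np.array([g.size for g in groups], dtype=float)
    m = np.array([g.mean() for g in groups])
    v = np.array([g.var(ddof=1) for g in groups])
    rows = []
    for i, j in combinations(range(k), 2):
        se2 = v[i] / n[i] + v[j] / n[j]
        diff = m[i] - m[j]
        df = se2**2 / ((v[i] / n[i]) ** 2 / (n[i] - 1) + (v[j] / n[j]) ** 2 / (n[j] - 1))
        q = abs(diff) / math.sqrt(se2 / 2.0)
        p = float(np.clip(sps.studentized_range.sf(q, k, df), 0.0, 1.0))
        rows.append(
            {"group1": labels[i], "group2": labels[j], "mean_diff": diff,
             "q": q, "df": df, "p_value": p}
        )
    table = pd.DataFrame(rows)
    best = table.loc[table["p_value"].idxmin()]
    return TestResult(
        "Games-Howell", float(best["q"]), (float(k), float(best["df"])),
        float(best["p_value"]), pairwise=table,
    )


# ---------------------------------------------------------------------------
# Robust two-way ANOVA: trimmed means + percentile bootstrap
# ---------------------------------------------------------------------------


@dataclass
class RobustTwoWayResult:
    """Robust two-way ANOVA on trimmed means with a bootstrap null."""

    p_factor1: float
    p_factor2: float
    p_interaction: float
    trim: float
    n_boot: int
    cell_means: pd.DataFrame = field(repr=False, default=None)

    def summary(self) -> str:
        return (
            f"Robust two-way ANOVA ({self.trim:.0%} trimmed means, "
            f"percentile bootstrap B={self.n_boot})\n"
            f"  factor1:     p = {self.p_factor1:.4g}\n"
            f"  factor2:     p = {self.p_factor2:.4g}\n"
            f"  interaction: p = {self.p_interaction:.4g}"
        )


def _two_way_contrasts(j: int, k: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """All-pairwise contrast matrices for main effects and interaction.

    Cells are ordered row-major over (factor1 level, factor2 level).
    """
    con_a = []
    for j1, j2 in combinations(range(j), 2):
        c = np.zeros(j * k)
        c[j1 * k: (j1 + 1) * k] = 1.0
        c[j2 * k: (j2 + 1) * k] = -1.0
        con_a.append(c)
    con_b = []
    for k1, k2 in combinations(range(k), 2):
        c = np.zeros(j * k)
        c[k1::k] = 1.0
        c[k2::k] = -1.0
        con_b.append(c)
    con_ab = []
    for j1, j2 in combinations(range(j), 2):
        for k1, k2 in combinations(range(k), 2):
            c = np.zeros(j * k)
            c[j1 * k + k1] = 1.0
            c[j1 * k + k2] = -1.0
            c[j2 * k + k1] = -1.0
            c[j2 * k + k2] = 1.0
            con_ab.append(c)
    return np.array(con_a), np.array(con_b), np.array(con_ab)


def _depth_p_value(boot_psi: np.ndarray, observed_null: np.ndarray) -> float:
    """How deeply the null point sits in the bootstrap contrast cloud.

    ``boot_psi`` is (B, L).  Distances use the bootstrap covariance
    (Mahalanobis); p = proportion of bootstrap points at least as far from
    the cloud center as the null point.
    """
    center = boot_psi.mean(axis=0)
    dev = boot_psi - center
    cov = dev.T @ dev / (boot_psi.shape[0] - 1)
    cov = np.atleast_2d(cov)
    # Ridge against degenerate clouds (e.g. heavy ties under trimming).
    cov += np.eye(cov.shape[0]) * 1e-12 * max(1.0, np.trace(cov))
    cov_inv = np.linalg.pinv(cov)
    d_boot = np.einsum("bi,ij,bj->b", dev, cov_inv, dev)
    null_dev = observed_null - center
    d_null = float(null_dev @ cov_inv @ null_dev)
    return float(np.mean(d_boot >= d_null))


def robust_two_way(
    values,
    factor1,
    factor2,
    trim: float = 0.2,
    n_boot: int = 599,
    seed: int | None = None,
) -> RobustTwoWayResult:
    """Robust two-way ANOVA: trimmed cell means, percentile-bootstrap null.

    Requires a complete factor1 x factor2 layout with n >= 4 per cell.  For
    each effect, all-pairwise linear contrasts of the 20%-trimmed cell
    means are bootstrapped (resampling within cells); the p-value measures
    how deeply the zero-contrast point is nested within the bootstrap
    cloud.  Deterministic under a fixed seed.
    """
    values = np.asarray(values, dtype=float)
    f1 = np.asarray(factor1)
    f2 = np.asarray(factor2)
    if not (values.size == f1.size == f2.size):
        raise ValueError("values and factors must align")
    if not 0 <= trim < 0.5:
        raise ValueError("trim must be in [0, 0.5)")
    lev1 = sorted(pd.unique(f1).tolist())
    lev2 = sorted(pd.unique(f2).tolist())
    if len(lev1) < 2 or len(lev2) < 2:
        raise ValueError("each factor needs >= 2 levels")
    cells = []
    cell_rows = []
    for a in lev1:
        for b in lev2:
            cell = values[(f1 == a) & (f2 == b)]
            if cell.size == 0:
                raise ValueError(f"empty cell ({a}, {b}): layout must be complete")
            if cell.size < 4:
                raise ValueError(f"cell ({a}, {b}) has n = {cell.size} < 4")
            cells.append(cell)
            cell_rows.append(
                {"factor1": a, "factor2": b, "n": cell.size,
                 "trimmed_mean": float(sps.trim_mean(cell, trim))}
            )
    con_a, con_b, con_ab = _two_way_contrasts(len(lev1), len(lev2))
    rng = np.random.default_rng(seed)
    boot_est = np.empty((n_boot, len(cells)))
    for ci, cell in enumerate(cells):
        idx = rng.integers(0, cell.size, size=(n_boot, cell.size))
        boot_est[:, ci] = sps.trim_mean(cell[idx], trim, axis=1)
    p_vals = {}
    for name, con in (("factor1", con_a), ("factor2", con_b), ("interaction", con_ab)):
        boot_psi = boot_est @ con.T
        p_vals[name] = _depth_p_value(boot_psi, np.zeros(con.shape[0]))
    return RobustTwoWayResult(
        p_factor1=p_vals["factor1"],
        p_factor2=p_vals["factor2"],
        p_interaction=p_vals["interaction"],
        trim=trim,
        n_boot=n_boot,
        cell_means=pd.DataFrame(cell_rows),
    )


# ---------------------------------------------------------------------------
# Multiple-comparison thresholds and enrichment/depletion calls
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class BonferroniThreshold:
    """Per-comparison significance threshold for a family of k tests."""

    alpha: float
    reported: float  # 3-decimal value for figure legends / reports
    k: int
    family_alpha: float


def bonferroni_alpha(k: int, family_alpha: float = 0.05) -> BonferroniThreshold:
    """Bonferroni per-comparison threshold family_alpha / k.

    ``reported`` is the half-up 3-decimal rounding used in reports
    (e.g. 0.05/3 = 0.01667 -> 0.017).
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    alpha = family_alpha / k
    reported = math.floor(alpha * 1000 + 0.5) / 1000
    return BonferroniThreshold(alpha=alpha, reported=reported, k=k, family_alpha=family_alpha)


def call_changes(
    treatment: pd.DataFrame,
    control: pd.DataFrame,
    alpha: float = 0.05,
    label_col: str = "label",
    time_col: str = "timepoint",
    value_col: str = "value",
) -> pd.DataFrame:
    """Per-class (or per-region), per-timepoint enrichment/depletion calls.

    For each (label, timepoint), treatment replicates are compared with
    control replicates by the Games–Howell test; a call of ``up`` (treated
    mean higher) or ``down`` is made only when p < ``alpha``, otherwise
    ``none``.  These are the arrowhead annotations of the stacked-area and
    localization plots.  The two tables must carry the same label set.
    """
    for name, df in (("treatment", treatment), ("control", control)):
        missing = {label_col, time_col, value_col} - set(df.columns)
        if missing:
            raise ValueError(f"{name} table missing columns {sorted(missing)}")
    lab_t = set(treatment[label_col].unique())
    lab_c = set(control[label_col].unique())
    if lab_t != lab_c:
        raise ValueError(f"unmatched labels: treatment {sorted(lab_t)} vs control {sorted(lab_c)}")
    rows = []
    for label in sorted(lab_t):
        t_sub = treatment[treatment[label_col] == label]
        c_sub = control[control[label_col] == label]
        times = sorted(set(t_sub[time_col]) & set(c_sub[time_col]))
        for tp in times:
            tv = t_sub.loc[t_sub[time_col] == tp, value_col].to_numpy(dtype=float)
            cv = c_sub.loc[c_sub[time_col] == tp, value_col].to_numpy(dtype=float)
            res = games_howell([cv, tv], labels=["control", "treatment"])
            p = float(res.pairwise["p_value"].iloc[0])
            diff = tv.mean() - cv.mean()
            call = "none"
            if p < alpha:
                call = "up" if diff > 0 else "down"
            rows.append(
                {"label": label, "timepoint": tp, "mean_diff": diff,
                 "p_value": p, "call": call}
            )
    return pd.DataFrame(rows)


@dataclass
class DecisionTreeResult:
    """Outcome of the variance-gated one-factor analysis."""

    levene: TestResult
    branch: str  # "anova_tukey" or "welch_games_howell"
    omnibus: TestResult
    posthoc: pd.DataFrame

    def summary(self) -> str:
        return (
            f"{self.levene.summary()}\n"
            f"branch: {self.branch}\n"
            f"{self.omnibus.summary()}"
        )


def decision_tree(groups, labels=None, levene_alpha: float = 0.05) -> DecisionTreeResult:
    """The one-factor analysis rule used throughout the assay suite.

    Levene's test gates: uniform variance -> one-way ANOVA + Tukey HSD;
    otherwise -> Welch's ANOVA + Games–Howell.
    """
    lev = levene(groups)
    if lev.p_value < levene_alpha:
        omnibus = welch_anova(groups, labels)
        gh = games_howell(groups, labels)
        return DecisionTreeResult(lev, "welch_games_howell", omnibus, gh.pairwise)
    res = anova_tukey(groups, labels)
    return DecisionTreeResult(lev, "anova_tukey", res, res.pairwise)
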