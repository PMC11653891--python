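"""Group-comparison reporting: normality-gated parametric / nonparametric tests.

This is thin plumbing over scipy/statsmodels routines, mirroring a standard
workflow: check each group for normality (Shapiro-Wilk below 50 samples,
Kolmogorov-Smirnov otherwise) and variance homogeneity (Bartlett); if both
hold use Student's t-test (two groups) or one-way ANOVA with a Tukey or
Dunnett post-hoc; otherwise Mann-Whitney (two groups) or Kruskal-Wallis with
Dunn's post-hoc.  The branch taken is recorded in the report.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as ss
from statsmodels.stats.multitest import multipletests

SHAPIRO_MAX_N = 50


@dataclass
class ComparisonSpec:
    metric: str = "metric"
    policy: str = "auto"  # auto | parametric | nonparametric
    correction: str = "auto"  # auto | tukey | dunnett | dunn | none
    alpha: float = 0.05
    control: str | None = None  # reference group for Dunnett

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if self.policy not in ("auto", "parametric", "nonparametric"):
            raise ValueError(f"unknown policy {self.policy!r}")
        if self.correction not in ("auto", "tukey", "dunnett", "dunn", "none"):
            raise ValueError(f"unknown correction {self.correction!r}")


@dataclass
class ComparisonReport:
    metric: str
    branch: str  # "parametric" or "nonparametric"
    omnibus_test: str
    statistic: float
    p_value: float
    pairwise: pd.DataFrame  # columns: group1, group2, test, statistic, p_adj, significant
    normality_p: dict[str, float] = field(default_factory=dict)
    homogeneity_p: float = float("nan")


def _is_normalish(values: np.ndarray, alpha: float) -> tuple[bool, float]:
    if values.size < 3 or np.ptp(values) == 0:
        return False, 0.0
    if values.size < SHAPIRO_MAX_N:
        p = float(ss.shapiro(values).pvalue)
    else:
        p = float(ss.kstest((values - values.mean()) / values.std(ddof=1), "norm").pvalue)
    return p > alpha, p


def _dunn_pairwise(groups: dict[str, np.ndarray], alpha: float) -> pd.DataFrame:
    """Dunn's rank-based post-hoc with tie correction and Holm adjustment."""
    labels = list(groups)
    pooled = np.concatenate([groups[g] for g in labels])
    ranks = ss.rankdata(pooled)
    n_total = pooled.size
    offsets = np.cumsum([0] + [groups[g].size for g in labels])
    mean_ranks = {g: ranks[offsets[i]:offsets[i + 1]].mean() for i, g in enumerate(labels)}
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = np.sum(tie_counts**3 - tie_counts) / (12.0 * (n_total - 1))
    rows, raw_p = [], []
    for g1, g2 in itertools.combinations(labels, 2):
        n1, n2 = groups[g1].size, groups[g2].size
        se = np.sqrt((n_total * (n_total + 1) / 12.0 - tie_term) * (1.0 / n1 + 1.0 / n2))
        z = (mean_ranks[g1] - mean_ranks[g2]) / se
        rows.append({"group1": g1, "group2": g2, "test": "dunn", "statistic": float(z)})
        raw_p.append(2 * ss.norm.sf(abs(z)))
    adj = multipletests(raw_p, alpha=alpha, method="holm")[1] if raw_p else []
    for row, p in zip(rows, adj):
        row["p_adj"] = float(p)
        row["significant"] = bool(p < alpha)
    return pd.DataFrame(rows)


def compare_groups(values_by_group: Mapping[str, Sequence[float]],
                   spec: ComparisonSpec | None = None) -> ComparisonReport:
    """Compare 2+ groups of a metric; branch and post-hoc chosen per ``spec``."""
    spec = spec or ComparisonSpec()
    groups = {str(g): np.asarray(list(v), dtype=float) for g, v in values_by_group.items()}
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    for g, v in groups.items():
        if v.size < 2:
            raise ValueError(f"group {g!r} has fewer than 2 values")
    labels = list(groups)
    arrays = [groups[g] for g in labels]

    normality_p: dict[str, float] = {}
    all_normal = True
    for g, v in groups.items():
        ok, p = _is_normalish(v, spec.alpha)
        normality_p[g] = p
        all_normal &= ok
    try:
        homo_p = float(ss.bartlett(*arrays).pvalue)
    except ValueError:
        homo_p = 0.0
    if spec.policy == "auto":
        parametric = all_normal and homo_p > spec.alpha
    else:
        parametric = spec.policy == "parametric"

    if len(groups) == 2:
        g1, g2 = labels
        if parametric:
            res = ss.ttest_ind(groups[g1], groups[g2])
            test = "student_t"
        else:
            res = ss.mannwhitneyu(groups[g1], groups[g2], alternative="two-sided")
            test = "mann_whitney"
        pairwise = pd.DataFrame([{
            "group1": g1, "group2": g2, "test": test,
            "statistic": float(res.statistic), "p_adj": float(res.pvalue),
            "significant": bool(res.pvalue < spec.alpha),
        }])
        return ComparisonReport(spec.metric, "parametric" if parametric else "nonparametric",
                                test, float(res.statistic), float(res.pvalue), pairwise,
                                normality_p, homo_p)

    if parametric:
        omni = ss.f_oneway(*arrays)
        correction = spec.correction if spec.correction != "auto" else "tukey"
        if correction == "dunnett":
            control = spec.control or labels[0]
            others = [g for g in labels if g != control]
            res = ss.dunnett(*[groups[g] for g in others], control=groups[control])
            pairwise = pd.DataFrame([
                {"group1": control, "group2": g, "test": "dunnett",
                 "statistic": float(res.statistic[i]), "p_adj": float(res.pvalue[i]),
                 "significant": bool(res.pvalue[i] < spec.alpha)}
                for i, g in enumerate(others)])
        elif correction == "none":
            rows = []
            for g1, g2 in itertools.combinations(labels, 2):
                r = ss.ttest_ind(groups[g1], groups[g2])
                rows.append({"group1": g1, "group2": g2, "test": "student_t",
                             "statistic": float(r.statistic), "p_adj": float(r.pvalue),
                             "significant": bool(r.pvalue < spec.alpha)})
            pairwise = pd.DataFrame(rows)
        else:
            res = ss.tukey_hsd(*arrays)
            rows = []
            for i, j in itertools.combinations(range(len(labels)), 2):
                p = float(res.pvalue[i, j])
                rows.append({"group1": labels[i], "group2": labels[j], "test": "tukey_hsd",
                             "statistic": float(res.statistic[i, j]), "p_adj": p,
                             "significant": bool(p < spec.alpha)})
            pairwise = pd.DataFrame(rows)
        return ComparisonReport(spec.metric, "parametric", "anova",
                                float(omni.statistic), float(omni.pvalue), pairwise,
                                normality_p, homo_p)

    omni = ss.kruskal(*arrays)
    pairwise = _dunn_pairwise(groups, spec.alpha)
    return ComparisonReport(spec.metric, "nonparametric", "kruskal_wallis",
                            float(omni.statistic), float(omni.pvalue), pairwise,
                            normality_p, homo_p)
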