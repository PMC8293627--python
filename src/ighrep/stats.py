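"""Repertoire statistics.

The statistical layer over the per-gene molecule counts:

* **Actively-recombining calls.**  Under the null that every annotated gene
  of a kind captures reads uniformly (p0 = 1/G), each gene's count is
  tested with a one-sided exact binomial test for excess; genes with
  Benjamini-Hochberg q < alpha are called actively recombining.
* **Frequency normalisation.**  Counts are expressed as percent of the
  total quantified reads of that kind.
* **Genotype comparison.**  Per-gene log2 ratios of replicate-mean
  frequencies against a reference genotype; genes at zero in the test
  sample are flagged rather than given a pseudocount, genes at zero in both
  are excluded.
* **Grouped aggregation** by family / clan / chromatin state / family
  domain, and group comparisons using a two-tailed type-III ANOVA with
  pairwise t tests (BH-adjusted) when every group passes a Shapiro-Wilk
  normality check at 0.05, else a Kruskal-Wallis test with pairwise
  Wilcoxon rank-sum tests (BH-adjusted).
"""

from __future__ import annotations

import dataclasses
import itertools
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.stats as sps
import statsmodels.api as sm
import statsmodels.formula.api as smf
from statsmodels.stats.multitest import multipletests

from .assign import CountTable
from .locus import LocusModel

__all__ = [
    "BinomialTestConfig",
    "GroupComparison",
    "binomial_active_test",
    "normalize_frequencies",
    "log2_compare",
    "aggregate_by_group",
    "compare_groups",
]


@dataclasses.dataclass
class BinomialTestConfig:
    alpha: float = 0.05
    null_model: str = "uniform"    # p0 = 1/G for every gene
    correction: str = "bh"

    def __post_init__(self):
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must lie in (0, 1)")
        if self.null_model != "uniform":
            raise ValueError(f"unsupported null model {self.null_model!r}")


def binomial_active_test(counts: pd.Series | CountTable,
                         cfg: BinomialTestConfig | None = None,
                         kind: str = "VH") -> pd.DataFrame:
    """Per-gene one-sided exact binomial test against the uniform null.

    ``counts`` is a full per-gene count vector (zero-count genes included —
    they define G).  Returns a frame indexed by gene with columns ``count``,
    ``freq_pct``, ``binomial_p``, ``q_value`` and ``active``.
    """
    if cfg is None:
        cfg = BinomialTestConfig()
    if isinstance(counts, CountTable):
        counts = counts.v_counts if kind == "VH" else counts.d_counts
    counts = counts.astype(int)
    g = len(counts)
    total = int(counts.sum())
    if g == 0:
        raise ValueError("no genes to test")
    if total == 0:
        raise ValueError("zero total count")
    p0 = 1.0 / g
    # P(X >= count) under Binomial(total, p0), exact
    pvals = sps.binom.sf(counts.values - 1, total, p0)
    reject, qvals, _, _ = multipletests(pvals, alpha=cfg.alpha, method="fdr_bh")
    active = reject & (counts.values > 0)
    return pd.DataFrame({
        "count": counts.values,
        "freq_pct": 100.0 * counts.values / total,
        "binomial_p": pvals,
        "q_value": qvals,
        "active": active,
    }, index=counts.index)


def normalize_frequencies(counts: pd.Series) -> pd.Series:
    """Counts as percent of the total quantified reads (sums to 100)."""
    total = counts.sum()
    if total <= 0:
        raise ValueError("zero total count")
    return 100.0 * counts / total


def log2_compare(test_means: pd.Series, ref_means: pd.Series) -> pd.DataFrame:
    """Per-gene log2(test / reference) of replicate-mean frequencies.

    Genes at zero in both samples are dropped; genes at zero in exactly one
    sample are flagged (``zero_in_test`` / ``zero_in_ref``) with the ratio
    left as NaN — no pseudocount is applied.
    """
    if not test_means.index.equals(ref_means.index):
        raise ValueError("gene universes differ between samples")
    either = (test_means > 0) | (ref_means > 0)
    t = test_means[either]
    r = ref_means[either]
    out = pd.DataFrame(index=t.index)
    out["log2_ratio"] = np.where((t > 0) & (r > 0),
                                 np.log2(t.where(t > 0) / r.where(r > 0)), np.nan)
    out["zero_in_test"] = (t == 0).values
    out["zero_in_ref"] = (r == 0).values
    return out


def aggregate_by_group(values: pd.Series, model: LocusModel, axis: str
                       ) -> pd.DataFrame:
    """Sum per-gene values (e.g. freq_pct) within each group of an axis.

    Returns one row per group with the summed value, the gene count and the
    per-gene value list (for downstream group testing).  Summed freq_pct
    values partition the total.
    """
    groups: dict[str, list] = {}
    for gid, val in values.items():
        g = model.group_of(gid, axis)
        groups.setdefault(g, []).append((gid, val))
    rows = []
    for g, pairs in groups.items():
        vals = [v for _, v in pairs]
        rows.append({"group": g, "n_genes": len(vals), "sum": float(np.sum(vals)),
                     "values": vals})
    return pd.DataFrame(rows).set_index("group")


@dataclasses.dataclass
class GroupComparison:
    axis: str
    group_sizes: dict[str, int]
    test_used: str                 # "ANOVA_typeIII" | "Kruskal-Wallis"
    statistic: float
    df: int
    p_value: float
    pairwise: pd.DataFrame         # columns: group_a, group_b, statistic, p, q


def _shapiro_ok(values: np.ndarray, alpha: float = 0.05) -> bool:
    if len(values) < 3 or np.ptp(values) == 0:
        return True   # too few observations to reject normality
    return sps.shapiro(values).pvalue >= alpha


def compare_groups(values_by_group: Mapping[str, Sequence[float]],
                   axis: str = "", alpha: float = 0.05) -> GroupComparison:
    """Omnibus + pairwise comparison of per-gene values between groups.

    A Shapiro-Wilk check per group at 0.05 selects between a two-tailed
    type-III ANOVA with pairwise t tests and a Kruskal-Wallis test with
    pairwise Wilcoxon rank-sum tests; pairwise p values are BH-adjusted.
    """
    groups = {g: np.asarray(v, dtype=float) for g, v in values_by_group.items()}
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    for g, v in groups.items():
        if len(v) < 2:
            raise ValueError(f"group {g!r} has fewer than 2 observations")
    names = list(groups)
    normal = all(_shapiro_ok(v, alpha) for v in groups.values())

    if normal:
        frame = pd.DataFrame({
            "value": np.concatenate([groups[g] for g in names]),
            "group": np.concatenate([[g] * len(groups[g]) for g in names]),
        })
        fit = smf.ols("value ~ C(group)", data=frame).fit()
        table = sm.stats.anova_lm(fit, typ=3)
        stat = float(table.loc["C(group)", "F"])
        p = float(table.loc["C(group)", "PR(>F)"])
        df = int(table.loc["C(group)", "df"])
        test_used = "ANOVA_typeIII"
        pair_fn = lambda a, b: sps.ttest_ind(a, b, equal_var=True)
    else:
        stat_res = sps.kruskal(*[groups[g] for g in names])
        stat, p = float(stat_res.statistic), float(stat_res.pvalue)
        df = len(names) - 1
        test_used = "Kruskal-Wallis"
        pair_fn = lambda a, b: sps.ranksums(a, b)

    rows = []
    for a, b in itertools.combinations(names, 2):
        res = pair_fn(groups[a], groups[b])
        rows.append({"group_a": a, "group_b": b,
                     "statistic": float(res.statistic), "p": float(res.pvalue)})
    pairwise = pd.DataFrame(rows)
    if not pairwise.empty:
        pairwise["q"] = multipletests(pairwise["p"], method="fdr_bh")[1]
    return GroupComparison(
        axis=axis, group_sizes={g: len(v) for g, v in groups.items()},
        test_used=test_used, statistic=stat, df=df, p_value=p,
        pairwise=pairwise,
    )
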