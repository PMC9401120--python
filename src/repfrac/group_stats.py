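"""Fraction-wise comparison of immunized vs control cohorts.

For every copy-number fraction the chosen index is computed per animal; the
two groups are compared with the Mann-Whitney U test and the resulting row of
p-values (one per fraction) is corrected for multiple testing with Holm's
step-down method, each row independently. Fractions in which an index is
undefined (fewer than two clonotypes) are excluded from the test of that
animal; a fraction whose groups are emptied this way is marked skipped rather
than imputed.

The Jaccard index is reported descriptively only (pairwise values carry a
within/between-group flag, no p-values): the all-pairs design violates the
independence assumptions of rank tests.
"""
from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy.stats import mannwhitneyu
from statsmodels.stats.multitest import multipletests

from .fractioning import FractionScheme, LOG2_SCHEME, split_by_scheme
from .indices import cdi, jaccard, relation_ld, relation_vj, rhi, summary_stats
from .types import IndexValue, Repertoire


def mann_whitney(
    a: Sequence[float], b: Sequence[float], alternative: str = "two-sided"
) -> float:
    """Mann-Whitney U p-value comparing group a (e.g. treated) to group b.

    ``alternative='less'`` tests a stochastic decrease of a relative to b.
    The exact null distribution is used for combined n <= 20 without ties;
    otherwise the normal approximation with tie and continuity correction.
    """
    a = np.asarray(list(a), dtype=float)
    b = np.asarray(list(b), dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both groups must be non-empty")
    alternative = {"two_sided": "two-sided"}.get(alternative, alternative)
    pooled = np.concatenate([a, b])
    exact = len(pooled) <= 20 and len(np.unique(pooled)) == len(pooled)
    method = "exact" if exact else "asymptotic"
    return float(mannwhitneyu(a, b, alternative=alternative, method=method).pvalue)


def holm_correct(p: Sequence[float]) -> np.ndarray:
    """Holm step-down adjustment with monotonicity enforcement, capped at 1."""
    p = np.asarray(list(p), dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="holm")[1]


#: per-animal index functions selectable by name
INDEX_FUNCTIONS: dict[str, Callable] = {
    "rhi_vj": lambda items: rhi(items, relation_vj()),
    "rhi_ld": lambda items: rhi(items, relation_ld(1)),
    "cdi": cdi,
    "n_clonotypes": lambda items: IndexValue(
        float(summary_stats(items)[0]), summary_stats(items)[0], "n_clonotypes"
    ),
    "mean_length": lambda items: (
        IndexValue(summary_stats(items)[1], len(items), "mean_length")
        if len(items) > 0
        else IndexValue.undefined("mean_length")
    ),
}


@dataclass
class CohortComparison:
    """One Holm-corrected row of fraction-wise group comparisons."""

    index_name: str
    timepoint: str
    alternative: str
    fractions: list[int]                 # 1-based fraction indices
    p_raw: np.ndarray                    # NaN where skipped
    p_adjusted: np.ndarray
    tested: np.ndarray                   # bool mask of fractions actually tested
    n_control: np.ndarray
    n_treated: np.ndarray
    median_control: np.ndarray
    median_treated: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "index": self.index_name,
                "timepoint": self.timepoint,
                "fraction": self.fractions,
                "n_control": self.n_control,
                "n_treated": self.n_treated,
                "p_raw": self.p_raw,
                "p_holm": self.p_adjusted,
                "median_control": self.median_control,
                "median_treated": self.median_treated,
                "tested": self.tested,
            }
        )


def index_per_fraction(
    rep: Repertoire, index: str, scheme: FractionScheme = LOG2_SCHEME
) -> list[IndexValue]:
    """Compute one index in every fraction of one animal."""
    fn = INDEX_FUNCTIONS[index]
    return [fn(sub) for sub in split_by_scheme(rep, scheme)]


def compare_cohorts(
    control: Sequence[Repertoire],
    treated: Sequence[Repertoire],
    index: str,
    scheme: FractionScheme = LOG2_SCHEME,
    alternative: str = "two-sided",
    timepoint: str = "",
    min_group_size: int = 2,
) -> CohortComparison:
    """Fraction-wise Mann-Whitney comparison with Holm correction within the row."""
    if len(control) < 2 or len(treated) < 2:
        raise ValueError("need >= 2 samples per group")
    vals_c = np.array(
        [[iv.value if iv.defined else np.nan for iv in index_per_fraction(r, index, scheme)]
         for r in control]
    )
    vals_t = np.array(
        [[iv.value if iv.defined else np.nan for iv in index_per_fraction(r, index, scheme)]
         for r in treated]
    )
    k = len(scheme)
    p_raw = np.full(k, np.nan)
    tested = np.zeros(k, dtype=bool)
    n_c = np.zeros(k, dtype=int)
    n_t = np.zeros(k, dtype=int)
    med_c = np.full(k, np.nan)
    med_t = np.full(k, np.nan)
    for f in range(k):
        a = vals_t[:, f][~np.isnan(vals_t[:, f])]
        b = vals_c[:, f][~np.isnan(vals_c[:, f])]
        n_t[f], n_c[f] = len(a), len(b)
        if len(a):
            med_t[f] = np.median(a)
        if len(b):
            med_c[f] = np.median(b)
        if len(a) >= min_group_size and len(b) >= min_group_size:
            p_raw[f] = mann_whitney(a, b, alternative)
            tested[f] = True
    p_adj = np.full(k, np.nan)
    if tested.any():
        p_adj[tested] = holm_correct(p_raw[tested])
    return CohortComparison(
        index_name=index,
        timepoint=timepoint,
        alternative=alternative,
        fractions=list(range(1, k + 1)),
        p_raw=p_raw,
        p_adjusted=p_adj,
        tested=tested,
        n_control=n_c,
        n_treated=n_t,
        median_control=med_c,
        median_treated=med_t,
    )


def pairwise_jaccard(
    reps: Sequence[Repertoire | object],
    labels: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Descriptive pairwise Jaccard overlap with a within-group flag."""
    rows = []
    labels = list(labels) if labels is not None else [
        getattr(r, "group_label", "") for r in reps
    ]
    ids = [getattr(r, "sample_id", getattr(r, "parent_id", str(i))) for i, r in enumerate(reps)]
    for i, j in itertools.combinations(range(len(reps)), 2):
        jv = jaccard(reps[i], reps[j])
        rows.append(
            {
                "sample_a": ids[i],
                "sample_b": ids[j],
                "jaccard": jv.value if jv.defined else np.nan,
                "within_group": labels[i] == labels[j],
                "group_a": labels[i],
                "group_b": labels[j],
            }
        )
    return pd.DataFrame(rows)
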