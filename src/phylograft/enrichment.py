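"""Gene-list over/under-representation and quantitative value enrichment.

The over-representation test compares a term's frequency in an uploaded gene
list against a reference list with a two-sided Fisher exact test (the
default) or a binomial test, followed by Benjamini-Hochberg FDR correction,
Bonferroni correction, or no correction.  Two-sidedness uses the
minimum-likelihood rule: the p-value sums the probability of every outcome
no more likely than the observed one, covering over- and under-representation
in a single number; the direction is reported separately from the sign of
k - expected.

The value-enrichment test asks whether the quantitative values attached to
genes carrying a term are distributed non-randomly (tend to be higher or
lower than the rest); it uses a two-sided Mann-Whitney U test with tie and
continuity corrections.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy import stats

__all__ = [
    "EnrichmentRow",
    "ValueEnrichmentRow",
    "fisher_exact_2x2",
    "binomial_term_test",
    "adjust_pvalues",
    "run_overrepresentation",
    "run_value_enrichment",
]

#: relative tolerance when comparing pmf values for the two-sided sum;
#: guards against ULP noise deciding whether an equally likely outcome counts
_PMF_RTOL = 1e-7


@dataclass
class EnrichmentRow:
    term_id: str
    list_count: int  # k: term genes in the uploaded list
    list_size: int  # n
    ref_count: int  # K: term genes in the reference
    ref_size: int  # N
    expected: float  # n*K/N
    fold_enrichment: Optional[float]  # k/expected; None when expected == 0
    direction: str  # "over" | "under"
    p_raw: float
    p_adjusted: float


@dataclass
class ValueEnrichmentRow:
    term_id: str
    n_in: int
    n_out: int
    u_statistic: float
    direction: str  # "over" (in-term values higher) | "under"
    p_raw: float
    p_adjusted: float


def fisher_exact_2x2(k: int, n: int, K: int, N: int) -> float:
    """Two-sided Fisher exact p for k term genes in a list of n, given K term
    genes in a reference of N.

    Sums the hypergeometric pmf over every outcome whose probability does not
    exceed pmf(k) (up to a tiny relative tolerance).  Log-space pmf keeps the
    evaluation stable for large tables.
    """
    if not (0 <= k <= n <= N and 0 <= k <= K <= N and n - k <= N - K):
        raise ValueError(f"inconsistent 2x2 margins: k={k}, n={n}, K={K}, N={N}")
    lo = max(0, n - (N - K))
    hi = min(n, K)
    if lo == hi:
        return 1.0
    x = np.arange(lo, hi + 1)
    logpmf = stats.hypergeom.logpmf(x, N, K, n)
    cutoff = logpmf[k - lo] + np.log1p(_PMF_RTOL)
    return float(min(1.0, np.exp(logpmf[logpmf <= cutoff]).sum()))


def binomial_term_test(k: int, n: int, p0: float) -> float:
    """Two-sided binomial p for k successes in n trials at success rate p0,
    by the same minimum-likelihood rule as the Fisher test."""
    if not (0 <= k <= n) or not (0.0 <= p0 <= 1.0):
        raise ValueError(f"invalid binomial test input: k={k}, n={n}, p0={p0}")
    x = np.arange(0, n + 1)
    logpmf = stats.binom.logpmf(x, n, p0)
    cutoff = logpmf[k] + np.log1p(_PMF_RTOL)
    return float(min(1.0, np.exp(logpmf[logpmf <= cutoff]).sum()))


def adjust_pvalues(p: list[float], method: str = "fdr_bh") -> list[float]:
    """Multiple-testing adjustment preserving input order.

    ``bonferroni``: min(1, m*p).  ``fdr_bh``: Benjamini-Hochberg step-up with
    monotonicity enforced from the largest rank down.  ``none``: identity.
    """
    arr = np.asarray(p, dtype=float)
    if arr.size and (arr.min() < 0 or arr.max() > 1):
        raise ValueError("p-values must lie in [0, 1]")
    m = arr.size
    if method == "none" or m == 0:
        return list(arr)
    if method == "bonferroni":
        return list(np.minimum(1.0, m * arr))
    if method == "fdr_bh":
        order = np.argsort(arr, kind="stable")
        q = np.empty(m)
        running = 1.0
        for rank in range(m, 0, -1):
            i = order[rank - 1]
            running = min(running, arr[i] * m / rank)
            q[i] = running
        return list(q)
    raise ValueError(f"unknown correction method {method!r}")


def _direction(k: float, expected: float) -> str:
    return "under" if k < expected else "over"


def run_overrepresentation(
    gene_list,
    reference_list,
    term_map: dict[str, set[str]],
    test: str = "fisher",
    correction: str = "fdr_bh",
    union: bool = False,
) -> list[EnrichmentRow]:
    """Test every term with at least one reference gene for over/under-
    representation in ``gene_list`` relative to ``reference_list``.

    The uploaded list must be a subset of the reference unless ``union`` is
    set, in which case out-of-reference genes are added to the reference.
    Correction is applied across the terms actually tested.  Rows come back
    sorted by raw p, then term id.
    """
    genes = set(gene_list)
    reference = set(reference_list)
    if not reference:
        raise ValueError("empty reference list")
    outside = genes - reference
    if outside:
        if not union:
            raise ValueError(
                f"{len(outside)} list genes missing from the reference "
                f"(e.g. {sorted(outside)[:3]}); pass union=True to merge them"
            )
        reference |= outside
    N = len(reference)
    n = len(genes)
    rows: list[EnrichmentRow] = []
    for term_id in sorted(term_map):
        carriers = term_map[term_id] & reference
        K = len(carriers)
        if K == 0:
            continue
        k = len(genes & carriers)
        expected = n * K / N
        if test == "fisher":
            p = fisher_exact_2x2(k, n, K, N)
        elif test == "binomial":
            p = binomial_term_test(k, n, K / N)
        else:
            raise ValueError(f"unknown test {test!r}")
        rows.append(
            EnrichmentRow(
                term_id=term_id,
                list_count=k,
                list_size=n,
                ref_count=K,
                ref_size=N,
                expected=expected,
                fold_enrichment=(k / expected) if expected > 0 else None,
                direction=_direction(k, expected),
                p_raw=p,
                p_adjusted=p,
            )
        )
    rows.sort(key=lambda r: (r.p_raw, r.term_id))
    adjusted = adjust_pvalues([r.p_raw for r in rows], correction)
    for row, q in zip(rows, adjusted):
        row.p_adjusted = float(q)
    return rows


def run_value_enrichment(
    gene_values: dict[str, float],
    term_map: dict[str, set[str]],
    correction: str = "fdr_bh",
) -> tuple[list[ValueEnrichmentRow], list[str]]:
    """Rank-based (Mann-Whitney U) test of whether in-term gene values differ
    from out-of-term values, per term.

    Terms covering all genes or none are untestable and are returned in the
    second element (skip notes) instead of as rows.
    """
    if len(gene_values) < 2:
        raise ValueError("need values for at least 2 genes")
    all_genes = set(gene_values)
    rows: list[ValueEnrichmentRow] = []
    skipped: list[str] = []
    for term_id in sorted(term_map):
        in_genes = term_map[term_id] & all_genes
        out_genes = all_genes - in_genes
        if not in_genes or not out_genes:
            skipped.append(
                f"{term_id}: covers {'all' if in_genes else 'no'} genes with values"
            )
            continue
        x = np.array([gene_values[g] for g in sorted(in_genes)])
        y = np.array([gene_values[g] for g in sorted(out_genes)])
        res = stats.mannwhitneyu(
            x, y, alternative="two-sided", use_continuity=True, method="asymptotic"
        )
        rows.append(
            ValueEnrichmentRow(
                term_id=term_id,
                n_in=len(x),
                n_out=len(y),
                u_statistic=float(res.statistic),
                direction=_direction(float(res.statistic), len(x) * len(y) / 2.0),
                p_raw=float(res.pvalue),
                p_adjusted=float(res.pvalue),
            )
        )
    rows.sort(key=lambda r: (r.p_raw, r.term_id))
    adjusted = adjust_pvalues([r.p_raw for r in rows], correction)
    for row, q in zip(rows, adjusted):
        row.p_adjusted = float(q)
    return rows, skipped
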