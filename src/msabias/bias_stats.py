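"""Comparison statistics for dataset-bias analysis.

Two homolog-count (or NEFF, or entropy) populations are compared with the
two-tailed Wilcoxon rank-sum (Mann–Whitney) test; per-protein metrics are
related with Pearson correlation; populations carrying group labels
(e.g. taxonomic domain) can be compared stratum by stratum.

The rank-sum test uses midranks for ties. For tiny samples
(n1 + n2 ≤ 12) the null distribution of the rank sum is enumerated
exactly over all C(n, n1) group assignments; larger samples use the
normal approximation with tie correction and a 0.5 continuity
correction.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np
from scipy.stats import norm, pearsonr, rankdata

EXACT_LIMIT = 12  # n1 + n2 at or below this uses exact enumeration


@dataclass(frozen=True)
class TestResult:
    """Two-sided rank-sum test outcome."""

    statistic: float  # tie-corrected z of the first sample's rank sum
    p_value: float
    n1: int
    n2: int
    method: str  # "exact" or "normal"
    sided: str = "two-sided"


def _rank_sum_z(w: float, n1: int, n2: int, ranks: np.ndarray) -> float:
    """Tie-corrected, continuity-corrected z for rank sum ``w`` of sample 1."""
    n = n1 + n2
    mu = n1 * (n + 1) / 2.0
    _, counts = np.unique(ranks, return_counts=True)
    tie_term = float(((counts**3 - counts).sum())) / (n * (n - 1)) if n > 1 else 0.0
    var = n1 * n2 / 12.0 * ((n + 1) - tie_term)
    if var <= 0:
        return 0.0
    d = w - mu
    d -= 0.5 * np.sign(d)  # continuity correction
    return float(d / math.sqrt(var))


def ranksums_test(a: Sequence[float], b: Sequence[float]) -> TestResult:
    """Two-tailed Wilcoxon rank-sum test between samples ``a`` and ``b``.

    Exact enumeration of the midrank-sum null when n1 + n2 ≤ 12;
    otherwise normal approximation with tie and continuity corrections.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    n1, n2 = len(a), len(b)
    if n1 == 0 or n2 == 0:
        raise ValueError("both samples must be non-empty")
    ranks = rankdata(np.concatenate([a, b]))
    w = float(ranks[:n1].sum())
    z = _rank_sum_z(w, n1, n2, ranks)
    n = n1 + n2
    mu = n1 * (n + 1) / 2.0
    if n <= EXACT_LIMIT:
        # exact two-sided p over all assignments of n1 ranks to sample 1
        obs = abs(w - mu)
        total = math.comb(n, n1)
        extreme = sum(
            1
            for comb in combinations(range(n), n1)
            if abs(ranks[list(comb)].sum() - mu) >= obs - 1e-9
        )
        return TestResult(
            statistic=z, p_value=extreme / total, n1=n1, n2=n2, method="exact"
        )
    p = min(1.0, 2.0 * float(norm.sf(abs(z))))
    return TestResult(statistic=z, p_value=p, n1=n1, n2=n2, method="normal")


def pearson_r(x: Sequence[float], y: Sequence[float]) -> float:
    """Sample Pearson correlation coefficient of two equal-length vectors."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y):
        raise ValueError("x and y must have equal length")
    if len(x) < 3:
        raise ValueError("need at least 3 observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("correlation undefined for constant input")
    return float(pearsonr(x, y).statistic)


def stratified_compare(
    records_a: Sequence,
    records_b: Sequence,
    field: str,
    group: str = "group",
) -> Mapping[str, TestResult]:
    """Rank-sum comparison of ``field`` between two record sets, run
    independently within each shared ``group`` label.

    Records may be any objects exposing the named attributes (e.g.
    DatasetRecord). Groups present in only one set are skipped with a
    warning; an error is raised if no group is shared.
    """

    def by_group(records: Sequence) -> dict[str, list[float]]:
        out: dict[str, list[float]] = {}
        for r in records:
            g = getattr(r, group)
            if g is None:
                raise ValueError(f"record {getattr(r, 'id', r)!r} missing group")
            v = getattr(r, field)
            if v is None:
                raise ValueError(f"record {getattr(r, 'id', r)!r} missing {field!r}")
            out.setdefault(str(g), []).append(float(v))
        return out

    ga, gb = by_group(records_a), by_group(records_b)
    shared = sorted(set(ga) & set(gb))
    skipped = sorted(set(ga) ^ set(gb))
    if skipped:
        warnings.warn(
            f"groups present in only one dataset skipped: {skipped}", stacklevel=2
        )
    if not shared:
        raise ValueError("no group labels shared between the two datasets")
    return {g: ranksums_test(ga[g], gb[g]) for g in shared}


def bonferroni(results: Mapping[str, TestResult]) -> Mapping[str, float]:
    """Bonferroni-adjusted p-values for a family of stratified tests."""
    m = len(results)
    return {g: min(1.0, r.p_value * m) for g, r in results.items()}
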