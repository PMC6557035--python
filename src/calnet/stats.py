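"""Two-group comparisons and relative-frequency distributions.

Per-coverslip summaries (ensemble counts, densities) are compared with the
classical pooled-variance unpaired two-tailed t test; per-cell
distributions (baseline fluorescence, ΔF range) with the two-tailed
Mann–Whitney U test.  U is exact (full enumeration) for small groups and
uses the tie-corrected normal approximation with continuity correction
otherwise.
"""

from __future__ import annotations

import dataclasses
from itertools import combinations
from math import comb, sqrt
from typing import Optional, Sequence

import numpy as np
from scipy.stats import norm, rankdata
from scipy.stats import t as t_dist

EXACT_MWU_MAX_N = 8  # exact enumeration when both groups are at most this size


@dataclasses.dataclass
class ComparisonResult:
    test_name: str
    statistic: float
    p_value: float
    n_a: int
    n_b: int
    df: Optional[int] = None  # t test only
    group_a_summary: dict = dataclasses.field(default_factory=dict)
    group_b_summary: dict = dataclasses.field(default_factory=dict)
    method: str = ""  # "exact" | "normal-approximation" for U

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def _as_array(values: Sequence[float], name: str, min_n: int) -> np.ndarray:
    arr = np.asarray(values, dtype=float)
    if arr.ndim != 1 or arr.size < min_n:
        raise ValueError(f"{name} needs at least {min_n} finite values")
    if not np.all(np.isfinite(arr)):
        raise ValueError(f"{name} contains non-finite values")
    return arr


def unpaired_t_test(group_a: Sequence[float], group_b: Sequence[float]) -> ComparisonResult:
    """Classical pooled-variance Student t test, two-tailed.

    df = n_a + n_b - 2.  Degenerate zero-variance inputs: equal means give
    t = 0, p = 1; different means give p = 0 with an infinite statistic.
    """
    a = _as_array(group_a, "group_a", 2)
    b = _as_array(group_b, "group_b", 2)
    na, nb = a.size, b.size
    df = na + nb - 2
    pooled_var = ((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1)) / df
    diff = a.mean() - b.mean()
    summaries = (
        {"mean": float(a.mean()), "sem": float(a.std(ddof=1) / sqrt(na)), "n": na},
        {"mean": float(b.mean()), "sem": float(b.std(ddof=1) / sqrt(nb)), "n": nb},
    )
    if pooled_var == 0:
        t_stat = 0.0 if diff == 0 else float(np.inf) * np.sign(diff)
        p = 1.0 if diff == 0 else 0.0
    else:
        t_stat = diff / sqrt(pooled_var * (1.0 / na + 1.0 / nb))
        p = 2.0 * float(t_dist.sf(abs(t_stat), df))
    return ComparisonResult(
        test_name="unpaired-t",
        statistic=float(t_stat),
        p_value=p,
        n_a=na,
        n_b=nb,
        df=df,
        group_a_summary=summaries[0],
        group_b_summary=summaries[1],
    )


def _u_statistics(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    """(U_a, U_b) from midrank sums; U_a + U_b = n_a * n_b."""
    combined = np.concatenate([a, b])
    ranks = rankdata(combined)
    r_a = ranks[: a.size].sum()
    u_a = r_a - a.size * (a.size + 1) / 2.0
    return float(u_a), float(a.size * b.size - u_a)


def _exact_mwu_p(a: np.ndarray, b: np.ndarray, u_obs: float) -> float:
    """Two-tailed exact p by enumerating all group assignments of the data.

    p = 2 * min(P(U <= u), P(U >= u)), capped at 1; ties are handled
    naturally because U is recomputed with midranks for every partition of
    the observed pooled values.
    """
    combined = np.concatenate([a, b])
    n, na = combined.size, a.size
    ranks = rankdata(combined)
    offset = na * (na + 1) / 2.0
    total = comb(n, na)
    n_le = n_ge = 0
    eps = 1e-9
    for idx in combinations(range(n), na):
        u = ranks[list(idx)].sum() - offset
        if u <= u_obs + eps:
            n_le += 1
        if u >= u_obs - eps:
            n_ge += 1
    return min(1.0, 2.0 * min(n_le, n_ge) / total)


def mann_whitney_u(
    group_a: Sequence[float],
    group_b: Sequence[float],
    exact: Optional[bool] = None,
) -> ComparisonResult:
    """Two-tailed Mann–Whitney U test with midranks for ties.

    Exact enumeration over all C(n_a + n_b, n_a) group assignments when
    both groups have at most 8 values (or ``exact=True``); otherwise the
    normal approximation with tie-corrected variance and a 0.5 continuity
    correction.  The reported statistic is min(U_a, U_b).
    """
    a = _as_array(group_a, "group_a", 1)
    b = _as_array(group_b, "group_b", 1)
    na, nb = a.size, b.size
    u_a, u_b = _u_statistics(a, b)
    u_min = min(u_a, u_b)
    if exact is None:
        exact = na <= EXACT_MWU_MAX_N and nb <= EXACT_MWU_MAX_N
    combined = np.concatenate([a, b])
    if np.all(combined == combined[0]):
        p, method = 1.0, "degenerate"
    elif exact:
        p, method = _exact_mwu_p(a, b, u_a), "exact"
    else:
        mu = na * nb / 2.0
        n = na + nb
        _, tie_counts = np.unique(combined, return_counts=True)
        tie_term = float(np.sum(tie_counts**3 - tie_counts)) / (n * (n - 1))
        var = na * nb / 12.0 * ((n + 1) - tie_term)
        if var <= 0:
            p, method = 1.0, "degenerate"
        else:
            z = (abs(u_a - mu) - 0.5) / sqrt(var)
            p = min(1.0, 2.0 * float(norm.sf(max(z, 0.0))))
            method = "normal-approximation"
    return ComparisonResult(
        test_name="mann-whitney-u",
        statistic=u_min,
        p_value=p,
        n_a=na,
        n_b=nb,
        group_a_summary={"median": float(np.median(a)), "n": na},
        group_b_summary={"median": float(np.median(b)), "n": nb},
        method=method,
    )


def relative_frequency(
    values: Sequence[float], bins: int | Sequence[float] = 10
) -> tuple[np.ndarray, np.ndarray]:
    """Histogram of proportions (sums to 1) over half-open bins [lo, hi).

    ``bins`` is a bin count or an explicit edge sequence (numpy semantics:
    the final bin also includes its right edge so no value is dropped).
    Returns ``(proportions, edges)``.
    """
    arr = _as_array(values, "values", 1)
    counts, edges = np.histogram(arr, bins=bins)
    dropped = arr.size - counts.sum()
    if dropped:
        raise ValueError(f"{dropped} values fall outside the supplied bin edges")
    return counts / arr.size, edges
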