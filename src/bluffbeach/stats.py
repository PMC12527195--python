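"""Permutation and multivariate statistics for community and metric data.

Implements the assemblage workflow (abundance transforms, rare-taxa filter,
Bray-Curtis dissimilarity, one-way PERMANOVA with global and pairwise tests)
and a stratified permutation test on univariate site metrics.  Geographic
region enters as permutation strata: labels are shuffled only within each
region, the nonparametric counterpart of a region random effect.

All permutation machinery is written out explicitly here; library routines
(scipy, scikit-bio) appear only as independent cross-checks in the test
suite.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import chi2 as _chi2_dist


class StatsError(ValueError):
    pass


# ---------------------------------------------------------------------------
# abundance handling
# ---------------------------------------------------------------------------

def transform_abundance(m: pd.DataFrame, method: str = "log1") -> pd.DataFrame:
    """Elementwise abundance transform: ``log1`` -> ln(x+1), ``sqrt`` -> sqrt(x),
    ``none`` -> identity."""
    x = m.to_numpy(dtype=float)
    if np.any(x < 0):
        raise StatsError("abundances must be non-negative")
    if method == "log1":
        out = np.log1p(x)
    elif method == "sqrt":
        out = np.sqrt(x)
    elif method == "none":
        out = x
    else:
        raise StatsError(f"unknown transform {method!r}")
    return pd.DataFrame(out, index=m.index, columns=m.columns)


def rare_taxa_filter(m: pd.DataFrame, threshold: float = 0.03) -> pd.DataFrame:
    """Drop taxa that never reach ``threshold`` relative abundance in any
    sample.  Applied to raw abundances, before transformation.  Idempotent."""
    x = m.to_numpy(dtype=float)
    if np.any(x < 0):
        raise StatsError("abundances must be non-negative")
    totals = x.sum(axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        rel = np.where(totals > 0, x / totals, 0.0)
    keep = (rel >= threshold).any(axis=0)
    if not keep.any():
        raise StatsError(f"no taxon reaches {threshold:.0%} in any sample")
    return m.loc[:, keep]


def bray_curtis(m: pd.DataFrame | np.ndarray) -> np.ndarray:
    """Bray-Curtis dissimilarity matrix.

    d(i,k) = sum_j |x_ij - x_kj| / sum_j (x_ij + x_kj), in [0, 1]; a pair of
    all-zero samples gets distance 0 by convention.
    """
    x = np.asarray(m, dtype=float)
    if x.ndim != 2 or x.shape[0] < 2:
        raise StatsError("need a samples x taxa matrix with >= 2 samples")
    if np.any(x < 0):
        raise StatsError("abundances must be non-negative")
    num = np.abs(x[:, None, :] - x[None, :, :]).sum(axis=2)
    den = (x[:, None, :] + x[None, :, :]).sum(axis=2)
    with np.errstate(invalid="ignore", divide="ignore"):
        d = np.where(den > 0, num / den, 0.0)
    np.fill_diagonal(d, 0.0)
    return d


# ---------------------------------------------------------------------------
# PERMANOVA
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PermanovaResult:
    pseudo_f: float
    p_value: float
    n_permutations: int
    df_between: int
    df_within: int
    ss_total: float
    ss_between: float
    ss_within: float


def _validate_distance(d: np.ndarray) -> np.ndarray:
    d = np.asarray(d, dtype=float)
    if d.ndim != 2 or d.shape[0] != d.shape[1]:
        raise StatsError("distance matrix must be square")
    if not np.allclose(d, d.T) or not np.allclose(np.diag(d), 0.0):
        raise StatsError("distance matrix must be symmetric with zero diagonal")
    return d


def _ss_stats(d2: np.ndarray, codes: np.ndarray, counts: np.ndarray):
    n = d2.shape[0]
    ss_t = d2.sum() / (2.0 * n)
    ss_w = 0.0
    for g, ng in enumerate(counts):
        mask = codes == g
        ss_w += d2[np.ix_(mask, mask)].sum() / (2.0 * ng)
    return ss_t, ss_w


def _pseudo_f(ss_t: float, ss_w: float, a: int, n: int) -> float:
    ss_a = ss_t - ss_w
    return (ss_a / (a - 1)) / (ss_w / (n - a))


def _strata_blocks(strata, n: int) -> list[np.ndarray]:
    if strata is None:
        return [np.arange(n)]
    s = np.asarray(strata)
    if s.size != n:
        raise StatsError("strata length does not match the number of samples")
    return [np.flatnonzero(s == v) for v in pd.unique(s)]


def _permuted_codes(codes: np.ndarray, blocks, n_perm: int, rng) -> np.ndarray:
    """n_perm x n matrix of group codes shuffled within strata blocks."""
    n = codes.size
    out = np.broadcast_to(codes, (n_perm, n)).copy()
    keys = rng.random((n_perm, n))
    for idx in blocks:
        order = np.argsort(keys[:, idx], axis=1)
        out[:, idx] = codes[idx][order]
    return out


def _batched_ss_within(d2: np.ndarray, perm_codes: np.ndarray, counts: np.ndarray) -> np.ndarray:
    ss_w = np.zeros(perm_codes.shape[0])
    for g, ng in enumerate(counts):
        b = (perm_codes == g).astype(float)
        ss_w += np.einsum("pi,ij,pj->p", b, d2, b) / (2.0 * ng)
    return ss_w


def permanova(
    d: np.ndarray,
    groups: Sequence,
    permutations: int | str = 9999,
    strata: Sequence | None = None,
    seed: int | None = None,
) -> PermanovaResult:
    """One-way PERMANOVA on a distance matrix.

    The pseudo-F statistic compares among-group to within-group sums of
    squared distances; its null distribution comes from permuting group
    labels, within ``strata`` blocks when given.  ``permutations="exact"``
    enumerates every relabeling (small n only) and reports
    p = #(F_perm >= F_obs) / n!, identity included; random permutations use
    p = (1 + #exceedances) / (1 + n_perm).
    """
    d = _validate_distance(d)
    n = d.shape[0]
    labels = pd.Series(list(groups))
    if labels.size != n:
        raise StatsError("groups length does not match distance matrix")
    codes, uniques = pd.factorize(labels)
    a = len(uniques)
    if a < 2:
        raise StatsError("need at least two groups")
    counts = np.bincount(codes)
    if counts.min() < 2:
        small = [str(uniques[i]) for i in np.flatnonzero(counts < 2)]
        raise StatsError(f"group(s) of size < 2: {small}")
    d2 = d**2
    ss_t, ss_w = _ss_stats(d2, codes, counts)
    f_obs = _pseudo_f(ss_t, ss_w, a, n)
    blocks = _strata_blocks(strata, n)
    if sum(len(b) for b in blocks) != n:
        raise StatsError("strata do not partition the samples")

    if permutations == "exact":
        if n > 9:
            raise StatsError("exact enumeration supported for n <= 9 samples")
        if strata is not None:
            raise StatsError("exact enumeration is unstratified")
        count_ge = 0
        total = 0
        for perm in itertools.permutations(range(n)):
            pc = codes[list(perm)]
            _, ssw_p = _ss_stats(d2, pc, counts)
            if _pseudo_f(ss_t, ssw_p, a, n) >= f_obs - 1e-12:
                count_ge += 1
            total += 1
        p = count_ge / total
        n_perm = total
    else:
        n_perm = int(permutations)
        if n_perm < 99:
            raise StatsError("use at least 99 permutations")
        rng = np.random.default_rng(seed)
        perm_codes = _permuted_codes(codes, blocks, n_perm, rng)
        ss_w_perm = _batched_ss_within(d2, perm_codes, counts)
        f_perm = ((ss_t - ss_w_perm) / (a - 1)) / (ss_w_perm / (n - a))
        p = (1.0 + np.sum(f_perm >= f_obs - 1e-12)) / (1.0 + n_perm)

    return PermanovaResult(
        pseudo_f=float(f_obs),
        p_value=float(p),
        n_permutations=n_perm,
        df_between=a - 1,
        df_within=n - a,
        ss_total=float(ss_t),
        ss_between=float(ss_t - ss_w),
        ss_within=float(ss_w),
    )


def holm_adjust(pvals: Sequence[float]) -> np.ndarray:
    """Holm step-down adjustment, monotone and capped at 1."""
    p = np.asarray(pvals, dtype=float)
    m = p.size
    order = np.argsort(p)
    adj = np.empty(m)
    running = 0.0
    for rank, idx in enumerate(order):
        running = max(running, (m - rank) * p[idx])
        adj[idx] = min(1.0, running)
    return adj


def pairwise_permanova(
    d: np.ndarray,
    groups: Sequence,
    pairs: Sequence[tuple] | None = None,
    permutations: int = 9999,
    strata: Sequence | None = None,
    seed: int | None = None,
) -> pd.DataFrame:
    """Two-group PERMANOVA for each pair of group levels, with Holm-adjusted
    p-values alongside the raw ones."""
    d = _validate_distance(d)
    labels = np.asarray(list(groups))
    levels = list(pd.unique(labels))
    if pairs is None:
        pairs = list(itertools.combinations(levels, 2))
    rows = []
    rng = np.random.default_rng(seed)
    for ga, gb in pairs:
        mask = np.isin(labels, [ga, gb])
        idx = np.flatnonzero(mask)
        sub_strata = np.asarray(strata)[idx] if strata is not None else None
        res = permanova(
            d[np.ix_(idx, idx)],
            labels[idx],
            permutations=permutations,
            strata=sub_strata,
            seed=int(rng.integers(2**31)),
        )
        rows.append(
            {"group_a": ga, "group_b": gb, "pseudo_f": res.pseudo_f, "p_value": res.p_value}
        )
    out = pd.DataFrame(rows)
    out["p_holm"] = holm_adjust(out["p_value"].to_numpy())
    return out


# ---------------------------------------------------------------------------
# chi-squared independence
# ---------------------------------------------------------------------------

def chi_square_independence(table) -> tuple[float, int, float]:
    """Pearson chi-squared test of independence on an r x c count table.

    Returns (chi2, df, p).  No continuity correction.
    """
    obs = np.asarray(table, dtype=float)
    if obs.ndim != 2 or obs.shape[0] < 2 or obs.shape[1] < 2:
        raise StatsError("need an r x c table with r, c >= 2")
    if np.any(obs < 0) or not np.allclose(obs, np.round(obs)):
        raise StatsError("table cells must be non-negative integers")
    row = obs.sum(axis=1)
    col = obs.sum(axis=0)
    if np.any(row <= 0) or np.any(col <= 0):
        raise StatsError("every row and column margin must be positive")
    expected = np.outer(row, col) / obs.sum()
    chi2 = float(((obs - expected) ** 2 / expected).sum())
    df = (obs.shape[0] - 1) * (obs.shape[1] - 1)
    p = float(_chi2_dist.sf(chi2, df))
    return chi2, df, p


# ---------------------------------------------------------------------------
# stratified permutation test on univariate metrics
# ---------------------------------------------------------------------------

def permutation_metric_test(
    values: Sequence[float],
    treatments: Sequence,
    strata: Sequence | None = None,
    permutations: int = 9999,
    seed: int | None = None,
) -> pd.DataFrame:
    """Pairwise difference-of-means permutation tests across treatments.

    For each treatment pair the statistic is |mean_a - mean_b| over the
    pair's sites; labels are reshuffled within strata (regions).  Raw
    p-values use (1 + #exceedances)/(1 + n_perm); Holm adjustment is applied
    across the pairs.
    """
    v = np.asarray(values, dtype=float)
    labels = np.asarray(list(treatments))
    if v.size != labels.size:
        raise StatsError("values and treatments differ in length")
    if strata is not None and len(strata) != v.size:
        raise StatsError("strata length does not match values")
    levels = list(pd.unique(labels))
    if len(levels) < 2:
        raise StatsError("need at least two treatments")
    for lev in levels:
        if np.sum(labels == lev) < 2:
            raise StatsError(f"treatment {lev!r} has fewer than 2 sites")
    rng = np.random.default_rng(seed)
    rows = []
    for ga, gb in itertools.combinations(levels, 2):
        idx = np.flatnonzero(np.isin(labels, [ga, gb]))
        sub_v, sub_l = v[idx], labels[idx]
        is_a = sub_l == ga
        obs = abs(sub_v[is_a].mean() - sub_v[~is_a].mean())
        blocks = _strata_blocks(
            np.asarray(strata)[idx] if strata is not None else None, idx.size
        )
        perm_is_a = _permuted_codes(is_a.astype(int), blocks, permutations, rng).astype(bool)
        n_a = is_a.sum()
        n_b = is_a.size - n_a
        sum_a = np.where(perm_is_a, sub_v, 0.0).sum(axis=1)
        stat = np.abs(sum_a / n_a - (sub_v.sum() - sum_a) / n_b)
        p = (1.0 + np.sum(stat >= obs - 1e-12)) / (1.0 + permutations)
        rows.append(
            {
                "group_a": ga,
                "group_b": gb,
                "mean_diff": float(sub_v[is_a].mean() - sub_v[~is_a].mean()),
                "p_value": float(p),
            }
        )
    out = pd.DataFrame(rows)
    out["p_holm"] = holm_adjust(out["p_value"].to_numpy())
    return out
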