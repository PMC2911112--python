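"""Sign concordance between single-gene and trisomic signatures.

Genes significant both in a trisomic-vs-control comparison and in at
least one single-gene overexpression experiment are paired as
(x = trisomic log-ratio, y = overexpression log-ratio); a gene picked up
by several experiments keeps the y of largest absolute value.  The
headline statistic is the count k of pairs in same-sign quadrants
(x*y > 0, strictly) out of n.  Its significance comes from a resampling
null — random (x, y) sets drawn from the two log-ratio lists — with a
closed-form binomial/hypergeometric oracle for cross-checking, and the
overall trend is summarized by a regression forced through the origin
(slope = sum(xy)/sum(x^2)) with the non-centered correlation
coefficient.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats

from .datatypes import ConfigurationError, IdMap

log = logging.getLogger("ds21")


@dataclass
class ConcordanceSet:
    """Paired log-ratios with their same-sign summary.

    ``pairs`` columns: gene, x (trisomic log ratio), y (overexpression
    log ratio), experiment.
    """

    pairs: pd.DataFrame

    @property
    def n(self) -> int:
        return len(self.pairs)

    @property
    def k(self) -> int:
        if self.pairs.empty:
            return 0
        k, _ = same_sign_count(self.pairs["x"].to_numpy(), self.pairs["y"].to_numpy())
        return k


def map_and_merge(
    de_tables: Mapping[str, pd.DataFrame],
    trisomic_table: pd.DataFrame,
    idmap: IdMap | None = None,
) -> ConcordanceSet:
    """Intersect significant genes per experiment and pool with max-|y| dedup.

    Inputs are already-significant tables with columns (id, log_ratio).
    Trisomic ids are first converted through ``idmap`` (unmapped ids
    drop out; several sources collapsing onto one target keep the x of
    largest absolute value).  Each experiment contributes the
    intersection of its significant ids with the mapped trisomic ids;
    the pooled list removes duplicate genes by keeping the y of maximum
    absolute value and discarding the others.
    """
    tri = trisomic_table.copy()
    if idmap is not None:
        translation = idmap.translate(tri["id"])
        tri = tri[tri["id"].isin(translation)].copy()
        tri["id"] = tri["id"].map(translation)
        tri = tri.loc[tri["log_ratio"].abs().sort_values().index]
        tri = tri.drop_duplicates("id", keep="last")
    x_of = dict(zip(tri["id"], tri["log_ratio"]))

    rows = []
    for experiment, table in de_tables.items():
        for gene, y in zip(table["id"], table["log_ratio"]):
            if gene in x_of:
                rows.append((gene, float(x_of[gene]), float(y), experiment))
    pairs = pd.DataFrame(rows, columns=["gene", "x", "y", "experiment"])
    if pairs.empty:
        log.warning("map_and_merge: no gene significant in both signatures")
        return ConcordanceSet(pairs)
    pooled = (
        pairs.loc[pairs["y"].abs().sort_values(kind="mergesort").index]
        .drop_duplicates("gene", keep="last")
        .sort_index()
        .reset_index(drop=True)
    )
    log.info("map_and_merge: %d pairs pooled from %d experiment hits",
             len(pooled), len(pairs))
    return ConcordanceSet(pooled)


def same_sign_count(x, y) -> tuple[int, int]:
    """(k, n): k = #{x*y > 0, strictly}, so zeros never count as same-sign."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    return int(np.count_nonzero(x * y > 0)), len(x)


@dataclass
class PermutationResult:
    """Resampling p-value; when no set qualifies, p is bounded above."""

    p_value: float
    n_qualifying: int
    n_sets: int

    @property
    def upper_bound(self) -> float:
        """1/n_sets when the count is zero, else the p-value itself."""
        return self.p_value if self.n_qualifying else 1.0 / self.n_sets

    def __str__(self) -> str:
        if self.n_qualifying == 0:
            return f"p < {1.0 / self.n_sets:g}"
        return f"p = {self.p_value:g}"


def permutation_pvalue(
    x_list,
    y_list,
    n: int,
    k: int,
    n_sets: int = 100_000,
    seed: int | None = None,
    replace: bool = True,
) -> PermutationResult:
    """Resampling p-value for observing >= k same-sign pairs out of n.

    Each of ``n_sets`` sets pairs n values of x, drawn at random from
    ``x_list``, with n values of y drawn from ``y_list``; the p-value is
    the fraction of sets with at least k pairs satisfying x*y > 0.  With
    ``replace=False`` draws are without replacement within each list
    (requires lists of length >= n), pairing a random subsample of x
    against a random subsample of y.
    """
    x = np.asarray(x_list, dtype=float)
    y = np.asarray(y_list, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ConfigurationError("log-ratio lists must be non-empty")
    if k > n:
        raise ConfigurationError(f"k={k} cannot exceed n={n}")
    if n_sets < 1000:
        raise ConfigurationError("n_sets must be >= 1000")
    if not replace and (len(x) < n or len(y) < n):
        raise ConfigurationError("without replacement requires lists of length >= n")

    # only the signs of the drawn values decide x*y > 0
    sx = np.sign(x).astype(np.int8)
    sy = np.sign(y).astype(np.int8)
    rng = np.random.default_rng(seed)

    hits = 0
    chunk = max(1, min(n_sets, 20_000_000 // max(n, 1)))
    done = 0
    while done < n_sets:
        c = min(chunk, n_sets - done)
        if replace:
            xi = sx[rng.integers(0, len(sx), size=(c, n))]
            yi = sy[rng.integers(0, len(sy), size=(c, n))]
        else:
            xi = rng.permuted(np.broadcast_to(sx, (c, len(sx))), axis=1)[:, :n]
            yi = rng.permuted(np.broadcast_to(sy, (c, len(sy))), axis=1)[:, :n]
        counts = np.count_nonzero(xi * yi > 0, axis=1)
        hits += int(np.count_nonzero(counts >= k))
        done += c

    p = hits / n_sets
    result = PermutationResult(p_value=p, n_qualifying=hits, n_sets=n_sets)
    log.info("permutation_pvalue: n=%d k=%d sets=%d -> %s", n, k, n_sets, result)
    return result


def concordance_null_oracle(
    frac_pos_x: float,
    frac_pos_y: float,
    n: int,
    k: int,
    variant: str = "replacement",
) -> float:
    """Closed-form null tail probability of >= k same-sign pairs of n.

    replacement : each pair is same-sign with probability
        q = fx*fy + (1-fx)(1-fy); the count is Binomial(n, q).
    pairing : the x and y sign lists (a = round(fx*n) and b = round(fy*n)
        positives) are randomly paired without replacement; with X the
        hypergeometric number of positive-positive matches, the
        same-sign count is n - a - b + 2X.
    """
    for name, f in (("frac_pos_x", frac_pos_x), ("frac_pos_y", frac_pos_y)):
        if not 0.0 <= f <= 1.0:
            raise ConfigurationError(f"{name} must be in [0, 1], got {f}")
    if k > n:
        raise ConfigurationError(f"k={k} cannot exceed n={n}")
    if variant == "replacement":
        q = frac_pos_x * frac_pos_y + (1.0 - frac_pos_x) * (1.0 - frac_pos_y)
        return float(stats.binom.sf(k - 1, n, q))
    if variant == "pairing":
        a = int(round(frac_pos_x * n))
        b = int(round(frac_pos_y * n))
        # same-sign = n - a - b + 2X  =>  X >= ceil((k - n + a + b) / 2)
        t_min = -(-(k - n + a + b) // 2)
        return float(stats.hypergeom.sf(t_min - 1, n, a, b))
    raise ConfigurationError(f"unknown variant {variant!r}")


@dataclass
class OriginRegression:
    """Least-squares line through the origin with non-centered correlation."""

    slope: float
    r_noncentered: float
    p_value: float
    n: int


def origin_regression(x, y) -> OriginRegression:
    """Fit y = A*x with A = sum(xy)/sum(x^2), forced through the origin.

    The non-centered correlation r = sum(xy)/sqrt(sum(x^2) sum(y^2))
    is tested with t = r*sqrt((n-2)/(1-r^2)) on Student t, n-2 df,
    two-sided.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(x)
    if n < 3:
        raise ConfigurationError("origin regression needs >= 3 pairs")
    sxx = float(np.sum(x * x))
    if sxx == 0:
        raise ConfigurationError("all x are zero; slope undefined")
    sxy = float(np.sum(x * y))
    syy = float(np.sum(y * y))
    slope = sxy / sxx
    r = sxy / np.sqrt(sxx * syy) if syy > 0 else 0.0
    if abs(r) >= 1.0:
        p = 0.0
    else:
        t = r * np.sqrt((n - 2) / (1.0 - r * r))
        p = float(2.0 * stats.t.sf(abs(t), n - 2))
    return OriginRegression(slope=slope, r_noncentered=float(r), p_value=p, n=n)


@dataclass
class ConcordanceStats:
    """Pooled summary of a concordance analysis."""

    n: int
    k: int
    p_perm: PermutationResult
    regression: OriginRegression


def analyze_concordance(
    cset: ConcordanceSet,
    x_list,
    y_list,
    n_sets: int = 100_000,
    seed: int | None = None,
    replace: bool = True,
) -> ConcordanceStats:
    """Same-sign permutation p and origin regression for a pooled set.

    ``x_list`` / ``y_list`` are the full significant log-ratio lists the
    resampling null draws from (trisomic and overexpression sides).
    """
    k, n = same_sign_count(cset.pairs["x"].to_numpy(), cset.pairs["y"].to_numpy())
    p_perm = permutation_pvalue(x_list, y_list, n, k, n_sets=n_sets, seed=seed, replace=replace)
    reg = origin_regression(cset.pairs["x"].to_numpy(), cset.pairs["y"].to_numpy())
    return ConcordanceStats(n=n, k=k, p_perm=p_perm, regression=reg)
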