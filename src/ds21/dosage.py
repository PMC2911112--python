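"""Dosage-sensitivity prediction from basal expression and protein disorder.

Two complementary predictors of whether overexpressing a gene perturbs
the transcriptome: (i) genes already highly expressed tend to be
*silent* under further overexpression — tested by ranking all probesets
by mean basal expression and computing a running-sum (GSEA-style)
enrichment score of the silent set toward the top of the ranking with a
set-permutation null; (ii) genes encoding intrinsically disordered
proteins tend to be dosage-sensitive (*effective*) — scored as the total
number of residues in disordered regions and thresholded (default 180).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .datatypes import (
    ConfigurationError,
    ExpressionMatrix,
    FormatError,
    GeneSet,
    check_labels,
)

log = logging.getLogger("ds21")


def basal_ranking(matrix: ExpressionMatrix) -> pd.DataFrame:
    """Rank probesets by mean expression across all arrays (descending).

    The mean over every available array estimates each gene's basal
    expression level; its standard deviation is attached.  Ties in the
    mean break lexicographically by probeset id, so the ranking is
    reproducible.  Columns: id, mean_expression, sd; rank 1 = most
    expressed.
    """
    if matrix.data.empty:
        raise FormatError("cannot rank an empty expression matrix")
    means = matrix.data.mean(axis=1)
    sds = matrix.data.std(axis=1, ddof=1) if matrix.data.shape[1] > 1 else 0.0
    profile = pd.DataFrame(
        {"id": matrix.probeset_ids, "mean_expression": means.to_numpy(), "sd": np.asarray(sds)}
    )
    profile = profile.sort_values(
        ["mean_expression", "id"], ascending=[False, True], kind="mergesort"
    ).reset_index(drop=True)
    profile["rank"] = np.arange(1, len(profile) + 1)
    return profile


def _running_sum(
    metric: np.ndarray, hits: np.ndarray, weight_p: float
) -> np.ndarray:
    n = len(metric)
    n_hit = int(hits.sum())
    if n_hit == 0:
        raise ConfigurationError("gene set does not intersect the ranked profile")
    if n_hit == n:
        raise ConfigurationError("gene set covers the entire profile (miss step undefined)")
    weights = np.abs(metric) ** weight_p
    hit_weights = np.where(hits, weights, 0.0)
    n_r = hit_weights.sum()
    if n_r > 0:
        hit_steps = hit_weights / n_r
    else:  # all hit metrics zero: fall back to uniform hit steps
        hit_steps = hits / n_hit
    miss_steps = np.where(hits, 0.0, 1.0 / (n - n_hit))
    return np.cumsum(hit_steps - miss_steps)


def _extreme(rs: np.ndarray) -> float:
    """Deviation of maximum magnitude; the earliest extreme wins when two
    deviations tie in magnitude to floating-point accuracy."""
    magnitude = np.abs(rs)
    idx = int(np.flatnonzero(magnitude >= magnitude.max() - 1e-12)[0])
    return float(rs[idx])


def gsea_enrichment_score(
    profile: pd.DataFrame, gene_set: GeneSet, weight_p: float = 1.0
) -> float:
    """Running-sum enrichment score of a gene set in a ranked profile.

    Walking the ranking from the top, set members ("hits") advance the
    sum by |metric|^weight_p normalized by the total hit weight; misses
    retreat it by 1/(N - N_hit).  The score is the deviation of maximum
    magnitude, in [-1, 1]; positive means the set concentrates at the
    top.  weight_p=0 gives the classical Kolmogorov-Smirnov statistic.
    """
    metric = profile["mean_expression"].to_numpy(dtype=float)
    hits = profile["id"].isin(gene_set.members).to_numpy()
    rs = _running_sum(metric, hits, weight_p)
    return _extreme(rs)


@dataclass
class EnrichmentResult:
    """Enrichment score with its set-permutation null."""

    es: float
    nes: float
    p_value: float
    q_value: float
    null_es: np.ndarray


def gsea_significance(
    profile: pd.DataFrame,
    gene_set: GeneSet,
    weight_p: float = 1.0,
    n_perm: int = 1000,
    seed: int | None = None,
) -> EnrichmentResult:
    """Set-permutation significance of the enrichment score.

    The null resamples random sets of the same size from the profile
    (the ranking is fixed, so phenotype permutation is unavailable).
    p = (1 + #{|null| >= |es|}) / (n_perm + 1).  The q-value follows the
    sign-stratified normalization of the standard GSEA procedure: scores
    are divided by the mean |null| of their sign and q is the fraction
    of same-sign normalized null scores at least as extreme.
    """
    if n_perm < 100:
        raise ConfigurationError("n_perm must be >= 100")
    metric = profile["mean_expression"].to_numpy(dtype=float)
    hits = profile["id"].isin(gene_set.members).to_numpy()
    n, n_hit = len(metric), int(hits.sum())
    if n_hit > n / 2:
        log.warning("gene set covers more than half the profile; null may be poorly calibrated")
    rs = _running_sum(metric, hits, weight_p)
    es = _extreme(rs)

    rng = np.random.default_rng(seed)
    null = np.empty(n_perm)
    perm_hits = np.zeros(n, dtype=bool)
    for i in range(n_perm):
        perm_hits[:] = False
        perm_hits[rng.choice(n, size=n_hit, replace=False)] = True
        prs = _running_sum(metric, perm_hits, weight_p)
        null[i] = _extreme(prs)

    p = (1.0 + np.count_nonzero(np.abs(null) >= abs(es))) / (n_perm + 1.0)

    pos_mean = np.abs(null[null > 0]).mean() if (null > 0).any() else np.nan
    neg_mean = np.abs(null[null < 0]).mean() if (null < 0).any() else np.nan
    scale = pos_mean if es >= 0 else neg_mean
    nes = es / scale if scale and np.isfinite(scale) else np.nan
    same_sign = null[null >= 0] / pos_mean if es >= 0 else null[null < 0] / neg_mean
    if np.isfinite(nes) and len(same_sign):
        q = float(np.count_nonzero(np.abs(same_sign) >= abs(nes)) / len(same_sign))
    else:
        q = float("nan")
    return EnrichmentResult(es=es, nes=float(nes), p_value=float(p), q_value=q, null_es=null)


def merge_intervals(intervals: Sequence[tuple[int, int]]) -> list[tuple[int, int]]:
    """Union of 1-based inclusive intervals as a sorted, disjoint list."""
    cleaned = []
    for start, end in intervals:
        if start > end:
            raise FormatError(f"inverted interval ({start}, {end})")
        cleaned.append((int(start), int(end)))
    if not cleaned:
        return []
    cleaned.sort()
    merged = [cleaned[0]]
    for start, end in cleaned[1:]:
        last_start, last_end = merged[-1]
        if start <= last_end + 1:
            merged[-1] = (last_start, max(last_end, end))
        else:
            merged.append((start, end))
    return merged


def disorder_score(intervals: Sequence[tuple[int, int]]) -> int:
    """Total residues in disordered regions (union of intervals).

    Overlapping intervals are merged first so each residue counts once.
    """
    return sum(end - start + 1 for start, end in merge_intervals(intervals))


@dataclass(frozen=True)
class DosageClassifier:
    """Threshold classifier on the disorder score (residues).

    Genes whose protein carries at least ``threshold`` disordered
    residues are predicted dosage-sensitive (effective); below it,
    silent.
    """

    threshold: int = 180

    def __post_init__(self) -> None:
        if self.threshold <= 0:
            raise ConfigurationError("threshold must be positive")

    def predict(self, score: int) -> str:
        return "effective" if score >= self.threshold else "silent"


def classify_dosage(
    scores: Mapping[str, int],
    labels: Mapping[str, str],
    classifier: DosageClassifier | None = None,
    exclude: Sequence[str] = (),
) -> tuple[dict[str, str], list[str]]:
    """Predict effective/silent from disorder scores and list exceptions.

    ``exclude`` drops genes from the comparison (e.g. clones carrying
    human coding sequences, whose non-murine proteins would confound the
    disorder comparison).  Exceptions are genes whose prediction
    disagrees with the observed label.
    """
    classifier = classifier or DosageClassifier()
    check_labels(labels)
    excluded = set(exclude)
    predictions = {
        g: classifier.predict(s) for g, s in scores.items()
        if g not in excluded and g in labels
    }
    exceptions = sorted(g for g, pred in predictions.items() if pred != labels[g])
    log.info(
        "disorder classifier (threshold=%d): %d genes, %d exception(s): %s",
        classifier.threshold, len(predictions), len(exceptions), exceptions,
    )
    return predictions, exceptions


def disorder_group_test(
    scores: Mapping[str, int],
    labels: Mapping[str, str],
    welch: bool = False,
) -> tuple[float, float]:
    """Two-sided t-test comparing disorder scores, effective vs silent.

    Student (equal-variance) by default; positive t means effective
    genes carry more disorder.
    """
    check_labels(labels)
    eff = [scores[g] for g, l in labels.items() if l == "effective" and g in scores]
    sil = [scores[g] for g, l in labels.items() if l == "silent" and g in scores]
    if len(eff) < 2 or len(sil) < 2:
        raise ConfigurationError("need >= 2 genes per label for the group test")
    t, p = stats.ttest_ind(eff, sil, equal_var=not welch)
    return float(t), float(p)
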