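"""Differential expression with a Bayesian regularized t-statistic.

With few replicates per condition, per-probeset variance estimates are
unstable; following the Cyber-t approach, each probeset's sample
variance is shrunk toward a background variance estimated from the
probesets nearby in mean-expression rank.  For group ``g`` with ``n``
replicates:

    sigma0_i^2  = mean sample variance over the ``w`` probesets nearest
                  to i in mean-expression rank (window truncated at the
                  ends of the list, ties in rank broken by probeset id)
    s_tilde_i^2 = (K * sigma0_i^2 + (n - 1) * s_i^2) / (K + n - 1)

and the statistic is

    t_i = (mean_a - mean_b) / sqrt(s_tilde_a^2/n_a + s_tilde_b^2/n_b)

referred to a Student t with n_a + n_b + 2K - 2 degrees of freedom: the
prior contributes K pseudo-observations per group, and at K = 0 both the
variance and the degrees of freedom reduce exactly to the classical
two-sample t.  Multiplicity is handled by Benjamini-Hochberg FDR.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .datatypes import ConfigurationError, ExpressionMatrix, FormatError, SampleAnnotation

log = logging.getLogger("ds21")

DE_COLUMNS = [
    "probeset_id",
    "mean_induced",
    "mean_uninduced",
    "log2_fold_change",
    "t_stat",
    "p_value",
    "q_value",
]


@dataclass(frozen=True)
class RegTParams:
    """Regularization parameters of the Bayesian t-test.

    window_size : neighbors in mean-expression rank pooled into the
        background variance (odd, >= 3; default 101).
    prior_confidence : pseudo-observations K given to the background
        variance (default 10).
    """

    window_size: int = 101
    prior_confidence: float = 10.0

    def __post_init__(self) -> None:
        if self.window_size < 3 or self.window_size % 2 == 0:
            raise ConfigurationError(
                f"window_size must be odd and >= 3, got {self.window_size}"
            )
        if self.prior_confidence < 0:
            raise ConfigurationError("prior_confidence must be >= 0")


def _background_variance(
    means: np.ndarray, variances: np.ndarray, ids: np.ndarray, w: int
) -> np.ndarray:
    """Sliding-window mean of sample variances in mean-expression rank.

    Windows are centred and truncated (not wrapped) at the list ends;
    rank ties break lexicographically by probeset id.
    """
    order = np.lexsort((ids, means))
    sorted_vars = variances[order]
    m = len(sorted_vars)
    half = (w - 1) // 2
    csum = np.concatenate(([0.0], np.cumsum(sorted_vars)))
    idx = np.arange(m)
    lo = np.maximum(idx - half, 0)
    hi = np.minimum(idx + half + 1, m)
    bg_sorted = (csum[hi] - csum[lo]) / (hi - lo)
    bg = np.empty(m)
    bg[order] = bg_sorted
    return bg


def regularized_t(
    group_a: pd.DataFrame,
    group_b: pd.DataFrame,
    params: RegTParams | None = None,
) -> pd.DataFrame:
    """Regularized two-sample t per probeset (group_a minus group_b).

    Both groups are probesets x replicates DataFrames sharing an index.
    Returns a DataFrame indexed like the input with columns mean_a,
    mean_b, t_stat, p_value.  Probesets whose statistic is undefined
    (zero variance everywhere with K = 0) carry NaN.
    """
    params = params or RegTParams()
    if not group_a.index.equals(group_b.index):
        raise FormatError("groups must share the same probeset index")
    n_a, n_b = group_a.shape[1], group_b.shape[1]
    if n_a < 2 or n_b < 2:
        raise ConfigurationError("need >= 2 replicates per group")

    ids = group_a.index.to_numpy(dtype=str)
    K = params.prior_confidence

    shrunk = []
    for group, n in ((group_a, n_a), (group_b, n_b)):
        values = group.to_numpy(dtype=float)
        means = values.mean(axis=1)
        s2 = values.var(axis=1, ddof=1)
        if K > 0:
            bg = _background_variance(means, s2, ids, params.window_size)
            s2_tilde = (K * bg + (n - 1) * s2) / (K + n - 1)
        else:
            s2_tilde = s2
        shrunk.append((means, s2_tilde))

    (mean_a, var_a), (mean_b, var_b) = shrunk
    se = np.sqrt(var_a / n_a + var_b / n_b)
    df = n_a + n_b + 2 * K - 2
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, (mean_a - mean_b) / se, np.where(mean_a == mean_b, 0.0, np.nan))
    p = np.where(np.isnan(t), np.nan, 2.0 * stats.t.sf(np.abs(t), df))
    return pd.DataFrame(
        {"mean_a": mean_a, "mean_b": mean_b, "t_stat": t, "p_value": p},
        index=group_a.index,
    )


def bh_fdr(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values.

    q_(i) = min_{j >= i} m * p_(j) / j on the sorted p-values, clipped
    at 1; monotone non-decreasing along sorted p.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.isnan(p).any():
        raise ConfigurationError("missing p-values not allowed in bh_fdr")
    if (p < 0).any() or (p > 1).any():
        raise ConfigurationError("p-values must lie in [0, 1]")
    _, q, _, _ = multipletests(p, method="fdr_bh")
    return q


def run_de(
    matrix: ExpressionMatrix,
    annotation: SampleAnnotation,
    gene: str,
    params: RegTParams | None = None,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Differential expression, induced vs uninduced, for one experiment.

    Clones are pooled within condition (the replicate unit is the array).
    Returns the per-probeset table with fold changes, regularized t,
    p and BH q; the significant set at level ``alpha`` is {q < alpha}.
    """
    induced = annotation.samples_for(gene=gene, condition="induced")
    uninduced = annotation.samples_for(gene=gene, condition="uninduced")
    if len(induced) < 2 or len(uninduced) < 2:
        raise ConfigurationError(
            f"gene {gene!r}: need >= 2 induced and >= 2 uninduced samples "
            f"(got {len(induced)}, {len(uninduced)})"
        )
    res = regularized_t(matrix.data[induced], matrix.data[uninduced], params)

    q = np.full(len(res), np.nan)
    ok = ~res["p_value"].isna().to_numpy()
    if ok.any():
        q[ok] = bh_fdr(res["p_value"].to_numpy()[ok])
    table = pd.DataFrame(
        {
            "probeset_id": res.index,
            "mean_induced": res["mean_a"].to_numpy(),
            "mean_uninduced": res["mean_b"].to_numpy(),
            "log2_fold_change": res["mean_a"].to_numpy() - res["mean_b"].to_numpy(),
            "t_stat": res["t_stat"].to_numpy(),
            "p_value": res["p_value"].to_numpy(),
            "q_value": q,
        }
    )
    n_sig = int((table["q_value"] < alpha).sum())
    log.info(
        "DE %s: %d induced vs %d uninduced arrays, %d probesets, %d significant at FDR<%g",
        gene, len(induced), len(uninduced), len(table), n_sig, alpha,
    )
    return table


def significant_set(de_table: pd.DataFrame, alpha: float = 0.05) -> pd.DataFrame:
    """Rows with q < alpha (the differentially expressed probesets)."""
    return de_table[de_table["q_value"] < alpha].copy()


def classify_effective(
    de_tables: Mapping[str, pd.DataFrame],
    alpha: float = 0.05,
    min_hits: int = 5,
) -> dict[str, str]:
    """Label each overexpression experiment effective or silent.

    A gene is *effective* when its experiment yields at least
    ``min_hits`` probesets with q < alpha.  The default of 5 requires a
    coherent transcriptome perturbation rather than isolated significant
    probesets, keeping the call robust when many experiments are
    screened in parallel.
    """
    labels = {}
    for gene, table in de_tables.items():
        hits = int((table["q_value"] < alpha).sum())
        labels[gene] = "effective" if hits >= min_hits else "silent"
    n_eff = sum(1 for l in labels.values() if l == "effective")
    log.info("classify_effective: %d of %d genes effective (alpha=%g, min_hits=%d)",
             n_eff, len(labels), alpha, min_hits)
    return labels


def leakiness_test(
    matrix: ExpressionMatrix,
    annotation: SampleAnnotation,
    transgene_probes: Mapping[str, str],
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Test each inducible clone set for basal leakage of its transgene.

    Compares the gene's own transgene expression in the parental line
    against the gene's uninduced clone samples with a classical
    two-sample t-test, BH-corrected across genes; leaky iff q < alpha.
    """
    parental = annotation.samples_for(condition="parental")
    if len(parental) < 2:
        raise ConfigurationError("need >= 2 parental samples for the leakiness test")

    rows = []
    for gene, probe in transgene_probes.items():
        uninduced = annotation.samples_for(gene=gene, condition="uninduced")
        if len(uninduced) < 2:
            raise ConfigurationError(f"gene {gene!r}: need >= 2 uninduced samples")
        a = matrix.data.loc[probe, uninduced].to_numpy(dtype=float)
        b = matrix.data.loc[probe, parental].to_numpy(dtype=float)
        t, p = stats.ttest_ind(a, b)
        rows.append((gene, probe, float(t), float(p)))
    out = pd.DataFrame(rows, columns=["gene", "transgene_probe", "t_stat", "p_value"])
    out["q_value"] = bh_fdr(out["p_value"].to_numpy())
    out["leaky"] = out["q_value"] < alpha
    log.info("leakiness: %d of %d genes flagged at FDR<%g",
             int(out["leaky"].sum()), len(out), alpha)
    return out


def relative_expression(ct_target, ct_reference):
    """Comparative-Ct relative expression, 2^-(Ct_target - Ct_reference)."""
    dct = np.asarray(ct_target, dtype=float) - np.asarray(ct_reference, dtype=float)
    out = np.power(2.0, -dct)
    return float(out) if out.ndim == 0 else out
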