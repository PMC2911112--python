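"""2DGE differential-protein analysis.

Spot intensities from large-gel two-dimensional electrophoresis are
normalized to percent volumes (each spot as a percentage of the total
spot volume of its parent gel), induced/uninduced ratios are formed from
condition means across replicate gels, and a change is called only when
it is both statistically significant (two-sided t-test, p < 0.05) and
larger than 20% in magnitude.  Protein changes are then paired with mRNA
log-ratios from the matching overexpression experiment to compare
proteome and transcriptome trends.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats

from .datatypes import FormatError

log = logging.getLogger("ds21")

SPOT_CONDITIONS = ("t0", "t48")


@dataclass
class SpotTable:
    """Spot volumes (spots x gels) with per-gel metadata.

    ``volumes``: DataFrame indexed by spot_id, one column per gel_id,
    non-negative raw or percent volumes.
    ``gels``: DataFrame with columns gel_id, clone, condition (t0/t48),
    replicate.
    """

    volumes: pd.DataFrame
    gels: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"gel_id", "clone", "condition", "replicate"}
        missing = required - set(self.gels.columns)
        if missing:
            raise FormatError(f"gel metadata missing columns: {sorted(missing)}")
        bad = set(self.gels["condition"]) - set(SPOT_CONDITIONS)
        if bad:
            raise FormatError(f"unknown gel conditions: {sorted(bad)}")
        meta_gels = set(self.gels["gel_id"])
        table_gels = set(self.volumes.columns)
        if meta_gels != table_gels:
            raise FormatError(
                f"gel ids disagree between table and metadata: "
                f"{sorted(meta_gels ^ table_gels)}"
            )
        if (self.volumes.to_numpy() < 0).any():
            raise FormatError("negative spot volume")

    def gels_for(self, condition: str) -> list[str]:
        return self.gels.loc[self.gels["condition"] == condition, "gel_id"].tolist()

    @property
    def spot_ids(self) -> list[str]:
        return list(self.volumes.index)


def percent_volume(table: SpotTable) -> SpotTable:
    """Normalize each gel so spot volumes sum to 100 (percent volumes).

    Idempotent and invariant to rescaling any single gel by c > 0.
    """
    totals = table.volumes.sum(axis=0)
    zero = totals[totals == 0]
    if len(zero):
        raise FormatError(f"gel(s) with zero total volume: {list(zero.index)}")
    normalized = table.volumes.div(totals, axis=1) * 100.0
    return SpotTable(normalized, table.gels.copy())


def spot_ratios(table: SpotTable, technical_as_independent: bool = True) -> pd.DataFrame:
    """Per-spot induced/uninduced ratio of mean percent volumes plus t-test p.

    ratio = mean(percent volume, t48 gels) / mean(percent volume, t0 gels);
    the p-value is a two-sided two-sample Student t across gels.  With
    ``technical_as_independent=False`` technical replicates are first
    averaged within each (clone, condition) so the t-test runs across
    clone means instead of individual gels.
    """
    norm = percent_volume(table)
    t0_gels, t48_gels = norm.gels_for("t0"), norm.gels_for("t48")
    if len(t0_gels) < 2 or len(t48_gels) < 2:
        raise FormatError("need >= 2 gels per condition")

    v0 = norm.volumes[t0_gels]
    v48 = norm.volumes[t48_gels]
    mean0, mean48 = v0.mean(axis=1), v48.mean(axis=1)

    if technical_as_independent:
        a, b = v48.to_numpy(), v0.to_numpy()
    else:
        meta = norm.gels.set_index("gel_id")
        group0 = v0.T.groupby(meta.loc[t0_gels, "clone"]).mean().T
        group48 = v48.T.groupby(meta.loc[t48_gels, "clone"]).mean().T
        if group0.shape[1] < 2 or group48.shape[1] < 2:
            raise FormatError("clone-averaged mode needs >= 2 clones per condition")
        a, b = group48.to_numpy(), group0.to_numpy()

    import warnings

    with warnings.catch_warnings():
        # zero-variance spots raise a precision warning; handled below
        warnings.simplefilter("ignore", RuntimeWarning)
        tstat, pval = stats.ttest_ind(a, b, axis=1)
    # degenerate spots: zero variance and zero difference are a non-change
    no_diff = np.isclose(a.mean(axis=1), b.mean(axis=1))
    no_var = (a.std(axis=1) == 0) & (b.std(axis=1) == 0)
    degenerate = no_diff & no_var
    tstat = np.where(degenerate, 0.0, tstat)
    pval = np.where(degenerate, 1.0, pval)

    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(mean0.to_numpy() > 0, mean48.to_numpy() / mean0.to_numpy(), np.nan)
    n_missing = int(np.isnan(ratio).sum())
    if n_missing:
        log.warning("%d spot(s) with zero t0 mean reported as missing", n_missing)

    return pd.DataFrame(
        {
            "spot_id": norm.spot_ids,
            "mean_t0": mean0.to_numpy(),
            "mean_t48": mean48.to_numpy(),
            "ratio": ratio,
            "t_stat": tstat,
            "p_value": pval,
        }
    )


def filter_protein_changes(
    ratios: pd.DataFrame,
    alpha: float = 0.05,
    min_change: float = 0.20,
    symmetric: bool = True,
) -> pd.DataFrame:
    """Call spot changes passing the significance-and-magnitude filter.

    A spot is *up* when ratio >= 1 + min_change, *down* when
    ratio <= 1/(1 + min_change) (or <= 1 - min_change with
    ``symmetric=False``), otherwise *unchanged*; it passes the filter only
    when additionally p < alpha.  Columns: spot_id, ratio, p_value,
    direction, passes_filter.
    """
    up_cut = 1.0 + min_change
    down_cut = 1.0 / (1.0 + min_change) if symmetric else 1.0 - min_change

    r = ratios["ratio"].to_numpy()
    p = ratios["p_value"].to_numpy()
    direction = np.full(len(ratios), "unchanged", dtype=object)
    with np.errstate(invalid="ignore"):
        direction[r >= up_cut] = "up"
        direction[r <= down_cut] = "down"
    direction[np.isnan(r)] = "unchanged"
    passes = (direction != "unchanged") & (p < alpha) & ~np.isnan(p)

    out = ratios[["spot_id", "ratio", "p_value"]].copy()
    out["direction"] = direction
    out["passes_filter"] = passes
    n_up = int(((direction == "up") & passes).sum())
    n_down = int(((direction == "down") & passes).sum())
    log.info(
        "protein filter (alpha=%g, min_change=%g): %d up, %d down of %d spots",
        alpha, min_change, n_up, n_down, len(out),
    )
    return out


def count_changes(change_table: pd.DataFrame) -> dict[str, int]:
    passing = change_table[change_table["passes_filter"]]
    return {
        "up": int((passing["direction"] == "up").sum()),
        "down": int((passing["direction"] == "down").sum()),
        "total": int(len(passing)),
    }


def pair_trends(
    protein_ratios: Mapping[str, float] | pd.DataFrame,
    mrna_ratios: Mapping[str, float] | pd.DataFrame,
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Pair gene-matched protein and mRNA ratios and classify their trend.

    Concordant when both ratios fall on the same side of 1, discordant on
    opposite sides; a ratio exactly 1 is a boundary case, reported but
    excluded from both counts.  Unmatched genes are skipped with a warning.

    Accepts mappings gene -> ratio, or DataFrames with columns
    (gene, ratio).
    """

    def as_mapping(obj) -> dict[str, float]:
        if isinstance(obj, pd.DataFrame):
            return dict(zip(obj["gene"], obj["ratio"]))
        return dict(obj)

    prot = as_mapping(protein_ratios)
    mrna = as_mapping(mrna_ratios)
    skipped = sorted(set(prot) ^ set(mrna))
    if skipped:
        log.warning("pair_trends: %d unmatched gene(s) skipped: %s", len(skipped), skipped)

    rows = []
    for gene in prot:
        if gene not in mrna:
            continue
        pr, mr = float(prot[gene]), float(mrna[gene])
        if pr == 1.0 or mr == 1.0:
            trend = "boundary"
        elif (pr > 1.0) == (mr > 1.0):
            trend = "concordant"
        else:
            trend = "discordant"
        rows.append((gene, pr, mr, trend))

    pairs = pd.DataFrame(rows, columns=["gene", "protein_ratio", "mrna_ratio", "trend"])
    counts = {
        "n_concordant": int((pairs["trend"] == "concordant").sum()),
        "n_discordant": int((pairs["trend"] == "discordant").sum()),
    }
    return pairs, counts
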