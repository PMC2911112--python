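"""Synthetic data with recorded ground truth for every pipeline stage.

The generators emulate the structure of an inducible single-gene
overexpression study in mouse ES cells: a bank of transgenic clones
(default 20 genes x 3 clones, hybridized induced and uninduced = 120
arrays), a trisomic-vs-control comparison whose expression shifts can be
an additive combination of the single-gene effects, per-gene protein
disorder profiles, and a 2DGE spot-volume table (2 clones x 6 gels).
Noise is additive Gaussian on the log2 scale — the standard log-normal
intensity assumption for normalized microarray data.  All randomness
flows from the explicit seed in :class:`SimConfig`; identical
(config, seed) gives bit-identical output.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .datatypes import ConfigurationError, ExpressionMatrix, GeneSet, SampleAnnotation
from .proteome import SpotTable

__all__ = [
    "SimConfig",
    "SimTruth",
    "simulate_overexpression_study",
    "simulate_trisomic_study",
    "simulate_disorder_profiles",
    "simulate_spot_table",
]


@dataclass(frozen=True)
class SimConfig:
    """Parameters of the synthetic study.

    Dimensions default to the emulated design: 20 genes x 3 clones x 2
    conditions, 2000 probesets, 500 2DGE spots of which 54 change.
    Effect sizes and noise are on the log2 scale.
    """

    n_genes: int = 20
    n_clones: int = 3
    n_probesets: int = 2000
    noise_sd: float = 0.25            # within-clone (array-level) log2 sd
    between_clone_sd: float = 0.10    # clone-specific random effect sd
    effect_size_mean: float = 2.0     # planted |log2| effect magnitude
    effect_size_sd: float = 0.5
    fraction_effective: float = 0.35  # 7 of 20 genes perturb the transcriptome
    targets_per_effective: int = 50   # probesets perturbed by an effective gene
    basal_quantile_for_silent: float = 0.80  # silent transgenes sit in the top 20%
    trisomic_group_size: int = 4
    trisomic_scale: float = math.log2(3.0 / 2.0)  # 3:2 dosage imbalance
    n_parental: int = 3
    n_leaky_genes: int = 1
    leak_shift: float = 2.0           # planted log2 leak of the inducible system
    disorder_threshold: int = 180
    exception_score: int = 26         # the planted low-disorder effective gene
    n_spots: int = 500
    fraction_spots_changed: float = 54.0 / 500.0
    spot_noise_cv: float = 0.10       # multiplicative (log-normal) gel noise
    spot_change_low: float = 1.5      # planted spot-ratio magnitude range
    spot_change_high: float = 3.0
    seed: int = 0

    def __post_init__(self) -> None:
        counts = {
            "n_genes": self.n_genes,
            "n_clones": self.n_clones,
            "n_probesets": self.n_probesets,
            "trisomic_group_size": self.trisomic_group_size,
            "n_spots": self.n_spots,
            "n_parental": self.n_parental,
            "targets_per_effective": self.targets_per_effective,
        }
        for name, value in counts.items():
            if value <= 0:
                raise ConfigurationError(f"{name} must be positive, got {value}")
        fractions = {
            "fraction_effective": self.fraction_effective,
            "basal_quantile_for_silent": self.basal_quantile_for_silent,
            "fraction_spots_changed": self.fraction_spots_changed,
        }
        for name, value in fractions.items():
            if not 0.0 <= value <= 1.0:
                raise ConfigurationError(f"{name} must be in [0, 1], got {value}")
        if self.noise_sd < 0 or self.between_clone_sd < 0 or self.spot_noise_cv < 0:
            raise ConfigurationError("noise parameters must be non-negative")
        if self.n_probesets < self.n_genes:
            raise ConfigurationError("need at least one probeset per gene")

    def with_seed(self, seed: int) -> "SimConfig":
        return replace(self, seed=seed)


@dataclass
class SimTruth:
    """Ground truth planted by the generators.

    ``target_sets`` maps each gene to its perturbed probesets with the
    planted log2 effect (empty for silent genes).  Generators that run
    later (disorder, trisomic, spots) fill their fields in place.
    """

    effective_labels: dict[str, str] = field(default_factory=dict)
    target_sets: dict[str, dict[str, float]] = field(default_factory=dict)
    basal_means: dict[str, float] = field(default_factory=dict)
    transgene_probes: dict[str, str] = field(default_factory=dict)
    leaky_genes: dict[str, float] = field(default_factory=dict)
    disorder_truth: dict[str, tuple[int, str]] = field(default_factory=dict)
    trisomic_effects: dict[str, float] = field(default_factory=dict)
    trisomic_additive: bool | None = None
    spot_truth: dict[str, str] = field(default_factory=dict)

    @property
    def effective_genes(self) -> list[str]:
        return [g for g, l in self.effective_labels.items() if l == "effective"]

    @property
    def silent_genes(self) -> list[str]:
        return [g for g, l in self.effective_labels.items() if l == "silent"]

    def silent_gene_set(self) -> GeneSet:
        """The silent genes' transgene probesets, for enrichment analysis."""
        members = frozenset(self.transgene_probes[g] for g in self.silent_genes)
        return GeneSet("silent_transgenes", members, "transgene probesets of silent genes")

    def write(self, directory: str | Path) -> None:
        """Serialize the truth as plain tabular files."""
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        labels = pd.DataFrame(
            {
                "gene": list(self.effective_labels),
                "label": list(self.effective_labels.values()),
                "transgene_probe": [
                    self.transgene_probes.get(g, "") for g in self.effective_labels
                ],
                "leak_shift": [self.leaky_genes.get(g, 0.0) for g in self.effective_labels],
            }
        )
        labels.to_csv(directory / "truth_genes.tsv", sep="\t", index=False)
        rows = [
            (g, p, e)
            for g, targets in self.target_sets.items()
            for p, e in sorted(targets.items())
        ]
        pd.DataFrame(rows, columns=["gene", "probeset", "log2_effect"]).to_csv(
            directory / "truth_effects.tsv", sep="\t", index=False
        )
        if self.spot_truth:
            pd.DataFrame(
                {"spot_id": list(self.spot_truth), "direction": list(self.spot_truth.values())}
            ).to_csv(directory / "truth_spots.tsv", sep="\t", index=False)


def _rng(config: SimConfig, stream: int) -> np.random.Generator:
    return np.random.default_rng([config.seed, stream])


def simulate_overexpression_study(
    config: SimConfig,
) -> tuple[ExpressionMatrix, SampleAnnotation, SimTruth]:
    """Simulate the inducible overexpression study.

    One array per (gene, clone, condition) plus parental baseline arrays.
    Induced samples of effective genes carry the planted log2 shifts on
    their target probesets; silent genes perturb nothing.  The transgene
    probesets of silent genes draw their baseline from the top
    ``basal_quantile_for_silent`` of basal means (silent genes are highly
    endogenously expressed), effective transgenes from the lower half.
    """
    cfg = config
    rng = _rng(cfg, 0)

    genes = [f"G{i + 1:02d}" for i in range(cfg.n_genes)]
    clones = [f"c{j + 1}" for j in range(cfg.n_clones)]
    background = [f"P{i + 1:04d}" for i in range(cfg.n_probesets - cfg.n_genes)]
    transgenes = {g: f"TG_{g}" for g in genes}
    probesets = background + [transgenes[g] for g in genes]

    # basal log2 intensities
    bg_means = rng.normal(8.0, 2.0, size=len(background))
    lo, med, hi = np.min(bg_means), np.median(bg_means), np.max(bg_means)
    top = np.quantile(bg_means, cfg.basal_quantile_for_silent)

    n_eff = int(round(cfg.fraction_effective * cfg.n_genes))
    null_effects = cfg.effect_size_mean == 0 and cfg.effect_size_sd == 0
    eff_genes = set() if null_effects else set(rng.choice(genes, size=n_eff, replace=False))

    truth = SimTruth(transgene_probes=dict(transgenes))
    basal = dict(zip(background, bg_means))
    for g in genes:
        effective = g in eff_genes
        truth.effective_labels[g] = "effective" if effective else "silent"
        if effective:
            basal[transgenes[g]] = float(rng.uniform(lo, med))
        else:
            basal[transgenes[g]] = float(rng.uniform(top, hi))
    truth.basal_means = dict(basal)

    # planted effects: the transgene itself goes up; downstream targets
    # are background probesets with random signs
    for g in genes:
        if g not in eff_genes:
            truth.target_sets[g] = {}
            continue
        magnitudes = np.abs(
            rng.normal(cfg.effect_size_mean, cfg.effect_size_sd, size=cfg.targets_per_effective)
        )
        magnitudes = np.maximum(magnitudes, 0.25)
        signs = rng.choice([-1.0, 1.0], size=cfg.targets_per_effective)
        signs[0] = 1.0
        downstream = rng.choice(
            len(background), size=cfg.targets_per_effective - 1, replace=False
        )
        targets = {transgenes[g]: float(magnitudes[0])}
        for idx, mag, sign in zip(downstream, magnitudes[1:], signs[1:]):
            targets[background[idx]] = float(sign * mag)
        truth.target_sets[g] = targets

    leaky = rng.choice(genes, size=min(cfg.n_leaky_genes, cfg.n_genes), replace=False)
    truth.leaky_genes = {g: cfg.leak_shift for g in leaky}

    base_vec = np.array([basal[p] for p in probesets])
    p_index = {p: i for i, p in enumerate(probesets)}

    columns: dict[str, np.ndarray] = {}
    annot_rows = []
    for g in genes:
        for c in clones:
            clone_offset = rng.normal(0.0, cfg.between_clone_sd, size=len(probesets))
            shift = np.zeros(len(probesets))
            if g in truth.leaky_genes:
                shift[p_index[transgenes[g]]] += truth.leaky_genes[g]
            for cond in ("uninduced", "induced"):
                values = base_vec + clone_offset + shift
                if cond == "induced":
                    values = values.copy()
                    for p, eff in truth.target_sets[g].items():
                        values[p_index[p]] += eff
                sample = f"{g}.{c}.{'ind' if cond == 'induced' else 'uni'}"
                columns[sample] = values + rng.normal(0.0, cfg.noise_sd, size=len(probesets))
                annot_rows.append((sample, g, f"{g}.{c}", cond, 24 if cond == "induced" else 0))

    for r in range(cfg.n_parental):
        sample = f"EB3.r{r + 1}"
        columns[sample] = base_vec + rng.normal(0.0, cfg.noise_sd, size=len(probesets))
        annot_rows.append((sample, "EB3", "", "parental", 0))

    matrix = ExpressionMatrix(pd.DataFrame(columns, index=probesets))
    annotation = SampleAnnotation(
        pd.DataFrame(
            annot_rows,
            columns=["sample_id", "experiment_gene", "clone_id", "condition", "timepoint_h"],
        )
    )
    return matrix, annotation, truth


def simulate_trisomic_study(
    config: SimConfig, truth: SimTruth, additive: bool = True
) -> tuple[ExpressionMatrix, SampleAnnotation]:
    """Simulate the trisomic-vs-control comparison.

    With ``additive`` on, each probeset's trisomic log2 shift is the sum
    of the planted single-gene effects scaled by ``trisomic_scale``
    (default log2(3/2), the 3:2 dosage of a trisomy).  With it off,
    shifts of the same number and magnitude land on freshly drawn
    probesets, independent of the single-gene truth.
    """
    if not truth.basal_means:
        raise ConfigurationError("truth from simulate_overexpression_study required")
    cfg = config
    rng = _rng(cfg, 1)
    probesets = list(truth.basal_means)
    base_vec = np.array([truth.basal_means[p] for p in probesets])
    p_index = {p: i for i, p in enumerate(probesets)}

    shift = np.zeros(len(probesets))
    if additive:
        for targets in truth.target_sets.values():
            for p, eff in targets.items():
                shift[p_index[p]] += cfg.trisomic_scale * eff
    else:
        n_effects = sum(len(t) for t in truth.target_sets.values())
        chosen = rng.choice(len(probesets), size=min(n_effects, len(probesets)), replace=False)
        mags = np.abs(rng.normal(cfg.effect_size_mean, cfg.effect_size_sd, size=len(chosen)))
        signs = rng.choice([-1.0, 1.0], size=len(chosen))
        shift[chosen] = cfg.trisomic_scale * signs * np.maximum(mags, 0.25)
    truth.trisomic_effects = {p: float(shift[i]) for p, i in p_index.items() if shift[i] != 0}
    truth.trisomic_additive = additive

    columns: dict[str, np.ndarray] = {}
    annot_rows = []
    for r in range(cfg.trisomic_group_size):
        sample = f"Tc1.r{r + 1}"
        columns[sample] = base_vec + shift + rng.normal(0.0, cfg.noise_sd, size=len(probesets))
        annot_rows.append((sample, "Tc1", f"Tc1.{r + 1}", "induced", 0))
    for r in range(cfg.trisomic_group_size):
        sample = f"WT.r{r + 1}"
        columns[sample] = base_vec + rng.normal(0.0, cfg.noise_sd, size=len(probesets))
        annot_rows.append((sample, "Tc1", f"WT.{r + 1}", "uninduced", 0))

    matrix = ExpressionMatrix(pd.DataFrame(columns, index=probesets))
    annotation = SampleAnnotation(
        pd.DataFrame(
            annot_rows,
            columns=["sample_id", "experiment_gene", "clone_id", "condition", "timepoint_h"],
        )
    )
    return matrix, annotation


def _intervals_for_score(score: int, rng: np.random.Generator) -> list[tuple[int, int]]:
    """Random non-overlapping 1-based intervals whose residue count is ``score``."""
    if score <= 0:
        return []
    n_chunks = int(rng.integers(1, min(3, score) + 1))
    cuts = sorted(rng.choice(np.arange(1, score), size=n_chunks - 1, replace=False)) if n_chunks > 1 else []
    lengths = np.diff([0, *cuts, score]).astype(int)
    intervals = []
    pos = int(rng.integers(1, 30))
    for length in lengths:
        intervals.append((pos, pos + int(length) - 1))
        pos += int(length) + int(rng.integers(5, 50))
    return intervals


def simulate_disorder_profiles(config: SimConfig, truth: SimTruth):
    """Plant per-gene disorder profiles separable at the threshold.

    Effective genes receive high disorder scores (at or above the
    threshold), silent genes low scores — except one effective gene
    planted at a low score (default 26), emulating the single kinase that
    perturbs the transcriptome despite an ordered protein.
    """
    from .datatypes import DisorderProfile

    if not truth.effective_labels:
        raise ConfigurationError("truth with effective/silent labels required")
    cfg = config
    rng = _rng(cfg, 2)
    theta = cfg.disorder_threshold

    effective = truth.effective_genes
    exception = str(rng.choice(effective)) if effective else None

    intervals: dict[str, list[tuple[int, int]]] = {}
    for gene, label in truth.effective_labels.items():
        if gene == exception:
            score = cfg.exception_score
        elif label == "effective":
            score = int(np.clip(round(rng.normal(300, 80)), theta, 600))
        else:
            score = int(np.clip(round(rng.normal(80, 40)), 0, theta - 1))
        truth.disorder_truth[gene] = (score, label)
        intervals[gene] = _intervals_for_score(score, rng)
    return DisorderProfile(intervals)


def simulate_spot_table(config: SimConfig) -> tuple[SpotTable, SimTruth]:
    """Simulate a 2DGE spot-volume table: 2 clones x (3 t0 + 3 t48) gels.

    A ``fraction_spots_changed`` subset of spots gets planted t48/t0
    ratios outside [0.8, 1.2] (magnitudes drawn between
    ``spot_change_low`` and ``spot_change_high``); the rest stay at
    ratio 1.  Up/down directions are assigned so the perturbations
    approximately conserve the total gel volume, making the planted
    ratios hold on the percent-volume scale as well.  Gel noise is
    multiplicative log-normal with coefficient of variation
    ``spot_noise_cv``.
    """
    cfg = config
    if cfg.n_spots < 10:
        raise ConfigurationError("n_spots must be >= 10")
    rng = _rng(cfg, 3)

    spots = [f"S{i + 1:04d}" for i in range(cfg.n_spots)]
    base = rng.lognormal(mean=2.0, sigma=1.0, size=cfg.n_spots)

    n_changed = int(round(cfg.fraction_spots_changed * cfg.n_spots))
    changed = rng.choice(cfg.n_spots, size=n_changed, replace=False)
    ratios = np.ones(cfg.n_spots)
    directions = np.array(["unchanged"] * cfg.n_spots, dtype=object)
    mags = rng.uniform(cfg.spot_change_low, cfg.spot_change_high, size=n_changed)
    # assign directions so perturbations approximately conserve the total
    # gel volume (greedy, largest spots first); otherwise the shifting
    # total would leak the planted changes into every unchanged spot's
    # percent-volume ratio
    order = np.argsort(-base[changed])
    imbalance = 0.0
    for pos in order:
        spot, mag = changed[pos], mags[pos]
        delta_up = base[spot] * (mag - 1.0)
        delta_down = base[spot] * (1.0 / mag - 1.0)
        if abs(imbalance + delta_up) <= abs(imbalance + delta_down):
            ratios[spot], directions[spot] = mag, "up"
            imbalance += delta_up
        else:
            ratios[spot], directions[spot] = 1.0 / mag, "down"
            imbalance += delta_down

    truth = SimTruth(spot_truth=dict(zip(spots, directions)))

    sigma = math.sqrt(math.log(1.0 + cfg.spot_noise_cv**2)) if cfg.spot_noise_cv > 0 else 0.0
    columns: dict[str, np.ndarray] = {}
    gel_rows = []
    for clone in ("E6", "E7"):
        for cond in ("t0", "t48"):
            for rep in range(1, 4):
                gel = f"{clone}.{cond}.r{rep}"
                expected = base * (ratios if cond == "t48" else 1.0)
                noise = rng.lognormal(mean=-sigma**2 / 2.0, sigma=sigma, size=cfg.n_spots) if sigma else 1.0
                columns[gel] = expected * noise
                gel_rows.append((gel, clone, cond, rep))

    table = SpotTable(
        pd.DataFrame(columns, index=spots),
        pd.DataFrame(gel_rows, columns=["gel_id", "clone", "condition", "replicate"]),
    )
    return table, truth
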