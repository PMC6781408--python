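"""Truncation-selection population simulator with full ground truth.

Emulates the field design of a divergent mass-selection experiment in an
open-pollinated landrace: a heterogeneous random-mating founder population is
planted in several plots, a small fraction of phenotypically extreme plants
(~5% tails, tall in half the plots, short in the other half) is selected as
seed parents, the selected plants are randomly mated to produce the next
generation, and a low-depth genotyping-by-sequencing (GBS) observation layer
is applied to the sampled plants.

Model summary
-------------
* Founders are drawn marker-by-marker in Hardy-Weinberg proportions at
  alt-allele frequencies sampled from a uniform law (linkage equilibrium).
* The trait is strictly additive: ``height = baseline + plot effect +
  sum_j dosage_j * effect_j + e`` with Gaussian environmental noise whose
  variance is solved so that Var(G)/Var(P) equals the target narrow-sense
  heritability.
* Meiosis recombines parental haplotypes with Haldane map probabilities
  derived from a constant cM/Mb density; chromosomes assort independently.
* GBS observation draws a Poisson read depth per call; zero depth yields a
  missing call and heterozygotes are miscalled homozygous when all sampled
  reads carry one allele (probability ``2^(1-d)`` at depth ``d``).

Every stochastic step consumes an independent stream spawned from the single
master seed, so a run is bit-reproducible.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .geno import GenotypeMatrix, concat_individuals

logger = logging.getLogger(__name__)

PHENO_COLUMNS = ["plant_id", "plot", "year", "generation", "regime", "height_cm"]


@dataclass
class SimConfig:
    """Parameters of the simulated selection experiment.

    Defaults mirror the field design being emulated: 4 plots of 5000 plants,
    96 plants sampled per plot for genotyping/phenotyping, ~5% truncation
    selection, mean GBS read depth ~2.01x, and a target narrow-sense
    heritability of 0.75 for plant height in cm.
    """

    n_chromosomes: int = 5
    markers_per_chromosome: int = 400
    chromosome_length: int = 150_000_000  # bp
    cm_per_mb: float = 1.0
    founder_freq_range: tuple = (0.05, 0.95)
    n_plants_per_plot: int = 5000
    n_sampled_per_plot: int = 96
    n_plots: int = 4
    n_qtl: int = 40
    qtl_effect_sd: float = 3.0  # cm per alt allele, Normal(0, sd)
    qtl_effects: Optional[Sequence[float]] = None  # explicit effects override the law
    qtl_freq_range: Optional[tuple] = None  # restrict QTL to this founder-freq band
    target_h2: float = 0.75
    baseline_cm: float = 180.0
    # (gen0, gen1) cm offset per plot; defaults give modest location-year effects
    plot_effects: Optional[tuple] = None
    selection_fraction: float = 0.05
    mean_depth: float = 2.01
    round_to_cm: Optional[float] = None  # e.g. 5.0 to mimic 5-cm measuring sticks
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "n_chromosomes",
            "markers_per_chromosome",
            "chromosome_length",
            "n_plants_per_plot",
            "n_sampled_per_plot",
            "n_plots",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not (0.0 < self.selection_fraction <= 1.0):
            raise ValueError("selection_fraction must be in (0, 1]")
        if not (0.0 <= self.target_h2 <= 1.0):
            raise ValueError("target_h2 must be in [0, 1]")
        if self.markers_per_chromosome < 15:
            raise ValueError("markers_per_chromosome must be >= 15 (smoothing window must fit)")
        lo, hi = self.founder_freq_range
        if not (0.0 <= lo <= hi <= 1.0):
            raise ValueError("founder_freq_range must satisfy 0 <= lo <= hi <= 1")
        if self.mean_depth < 0:
            raise ValueError("mean_depth must be >= 0")
        if self.plot_effects is None:
            base = ((0.0, 6.0), (8.0, 4.0), (-6.0, -2.0), (2.0, -8.0))
            self.plot_effects = tuple(base[i % 4] for i in range(self.n_plots))
        if len(self.plot_effects) != self.n_plots:
            raise ValueError("plot_effects must give one (gen0, gen1) pair per plot")

    @property
    def n_markers(self) -> int:
        return self.n_chromosomes * self.markers_per_chromosome

    def plot_regimes(self) -> list:
        """First half of the plots selects tall, second half short."""
        n_tall = (self.n_plots + 1) // 2
        return ["tall" if i < n_tall else "short" for i in range(self.n_plots)]

    def plot_names(self) -> list:
        names, counts = [], {"tall": 0, "short": 0}
        for r in self.plot_regimes():
            counts[r] += 1
            names.append(f"{r.capitalize()}{counts[r]}")
        return names


@dataclass
class TruthRecord:
    """Ground truth of a simulated experiment."""

    qtl_indices: np.ndarray
    qtl_marker_ids: list
    qtl_effects: np.ndarray
    founder_freqs: np.ndarray
    true_h2: float = np.nan
    sigma_e: float = np.nan
    truncation_threshold: dict = field(default_factory=dict)  # plot name -> cm
    selected_ids: dict = field(default_factory=dict)  # plot name -> ids
    plot_effects: dict = field(default_factory=dict)  # (plot name, generation) -> cm

    def to_json(self, path) -> None:
        payload = {
            "qtl_indices": np.asarray(self.qtl_indices).tolist(),
            "qtl_marker_ids": list(self.qtl_marker_ids),
            "qtl_effects": np.asarray(self.qtl_effects).tolist(),
            "founder_freqs": np.asarray(self.founder_freqs).tolist(),
            "true_h2": float(self.true_h2),
            "sigma_e": float(self.sigma_e),
            "truncation_threshold": {k: float(v) for k, v in self.truncation_threshold.items()},
            "selected_ids": {k: list(map(str, v)) for k, v in self.selected_ids.items()},
            "plot_effects": {f"{k[0]}:{k[1]}": float(v) for k, v in self.plot_effects.items()},
        }
        Path(path).write_text(json.dumps(payload, indent=1))


# ---------------------------------------------------------------------------
# Founders
# ---------------------------------------------------------------------------


def _marker_table(config: SimConfig) -> pd.DataFrame:
    chroms, positions = [], []
    step = config.chromosome_length / config.markers_per_chromosome
    base = np.arange(config.markers_per_chromosome) * step + step / 2
    for c in range(1, config.n_chromosomes + 1):
        chroms.extend([str(c)] * config.markers_per_chromosome)
        positions.extend(np.round(base).astype(int) + 1)
    df = pd.DataFrame(
        {
            "chrom": chroms,
            "pos": positions,
            "ref": "A",
            "alt": "T",
            "diallelic": True,
        }
    )
    df["cm"] = df["pos"] / 1e6 * config.cm_per_mb
    return df


def simulate_founders(
    config: SimConfig,
    rng: Optional[np.random.Generator] = None,
    n_individuals: Optional[int] = None,
    id_prefix: str = "G0",
) -> GenotypeMatrix:
    """Draw a Hardy-Weinberg random-mating founder population.

    Per marker, a base alt-allele frequency is drawn from the founder
    frequency law (uniform on ``founder_freq_range``); each individual then
    receives two independent Bernoulli gametes, so the dosage at marker *j*
    is Binomial(2, freq_j).  Haplotypes are retained for later meiosis.
    The realized base frequency is stored as ``founder_freq`` marker metadata.
    """
    rng = np.random.default_rng(config.seed) if rng is None else rng
    n = config.n_plots * config.n_plants_per_plot if n_individuals is None else n_individuals
    markers = _marker_table(config)
    m = len(markers)
    lo, hi = config.founder_freq_range
    freqs = rng.uniform(lo, hi, size=m)
    haps = (rng.random((n, 2, m)) < freqs).astype(np.uint8)
    markers = markers.assign(founder_freq=freqs)
    ids = np.array([f"{id_prefix}_{i:06d}" for i in range(n)], dtype=object)
    return GenotypeMatrix(
        dosage=haps.sum(axis=1).astype(np.int8),
        individual_ids=ids,
        markers=markers,
        haplotypes=haps,
    )


def assign_qtl(geno: GenotypeMatrix, config: SimConfig, rng: np.random.Generator) -> TruthRecord:
    """Pick QTL markers and additive effects; returns a partial TruthRecord."""
    freqs = geno.markers["founder_freq"].to_numpy(float)
    candidates = np.arange(geno.n_markers)
    if config.qtl_freq_range is not None:
        lo, hi = config.qtl_freq_range
        candidates = candidates[(freqs >= lo) & (freqs <= hi)]
    if config.n_qtl > len(candidates):
        raise ValueError("not enough candidate markers for the requested number of QTL")
    qtl = np.sort(rng.choice(candidates, size=config.n_qtl, replace=False))
    if config.qtl_effects is not None:
        effects = np.asarray(config.qtl_effects, dtype=float)
        if len(effects) != config.n_qtl:
            raise ValueError("qtl_effects length must equal n_qtl")
    else:
        effects = rng.normal(0.0, config.qtl_effect_sd, size=config.n_qtl)
    ids = geno.marker_ids().iloc[qtl].tolist()
    return TruthRecord(
        qtl_indices=qtl,
        qtl_marker_ids=ids,
        qtl_effects=effects,
        founder_freqs=freqs,
    )


# ---------------------------------------------------------------------------
# Phenotypes
# ---------------------------------------------------------------------------


def genetic_values(geno: GenotypeMatrix, truth: TruthRecord) -> np.ndarray:
    return geno.dosage[:, truth.qtl_indices].astype(float) @ truth.qtl_effects


def simulate_phenotypes(
    geno: GenotypeMatrix,
    truth: TruthRecord,
    config: SimConfig,
    rng: np.random.Generator,
    plots: Optional[np.ndarray] = None,
    generation: int = 0,
) -> pd.DataFrame:
    """Simulate plant heights for one generation.

    ``height_i = baseline + plot_effect + g_i + e_i`` with ``e_i``
    Gaussian.  On the first (generation-0) call the environmental standard
    deviation is solved from the realized genetic variance so that
    Var(G)/Var(P) matches ``target_h2``, and both ``sigma_e`` and the
    realized ``true_h2`` are recorded on the truth record; later calls reuse
    the stored ``sigma_e`` (same environment model in both years).
    """
    n = geno.n_individuals
    if plots is None:
        plots = np.zeros(n, dtype=int)
    plots = np.asarray(plots)
    g = genetic_values(geno, truth)
    var_g = float(np.var(g))
    if np.isnan(truth.sigma_e):
        if config.target_h2 == 0.0:
            if np.any(truth.qtl_effects != 0):
                warnings.warn(
                    "target_h2 = 0 with nonzero QTL effects: genetic values are "
                    "ignored in the variance scaling",
                    stacklevel=2,
                )
            truth.sigma_e = 20.0  # cm; arbitrary purely-environmental spread
        elif config.target_h2 == 1.0:
            truth.sigma_e = 0.0
        else:
            truth.sigma_e = float(
                np.sqrt(var_g * (1.0 - config.target_h2) / config.target_h2)
            )
    if config.target_h2 == 0.0:
        g = np.zeros_like(g)
        var_g = 0.0
    e = rng.normal(0.0, truth.sigma_e, size=n) if truth.sigma_e > 0 else np.zeros(n)
    plot_names = config.plot_names()
    plot_eff = np.array([config.plot_effects[p][generation % 2] for p in plots])
    height = config.baseline_cm + plot_eff + g + e
    if config.round_to_cm:
        height = np.round(height / config.round_to_cm) * config.round_to_cm
    if generation == 0 and np.isnan(truth.true_h2):
        var_p = float(np.var(g + e))
        truth.true_h2 = var_g / var_p if var_p > 0 else 0.0
    regimes = config.plot_regimes()
    year = {0: "2016", 1: "2017"}.get(generation, str(generation))
    df = pd.DataFrame(
        {
            "plant_id": geno.individual_ids,
            "plot": [plot_names[p] for p in plots],
            "year": year,
            "generation": generation,
            "regime": [regimes[p] for p in plots],
            "height_cm": height,
        }
    )
    for p, name in enumerate(plot_names):
        truth.plot_effects[(name, generation)] = float(config.plot_effects[p][generation % 2])
    return df


# ---------------------------------------------------------------------------
# Selection and mating
# ---------------------------------------------------------------------------


def truncation_select(phenos: pd.DataFrame, fraction: float, direction: str):
    """Select plants beyond the empirical truncation threshold of one plot.

    ``threshold`` is the empirical (1 - fraction) quantile of the heights for
    ``direction='tall'`` (the ``fraction`` quantile for ``'short'``); plants
    at or beyond the threshold are selected (ties at the threshold are
    included).  Returns ``(selected_ids, threshold_cm)``.
    """
    if len(phenos) == 0:
        raise ValueError("cannot select from an empty plot")
    if not (0.0 < fraction <= 1.0):
        raise ValueError("fraction must be in (0, 1]")
    if direction not in ("tall", "short"):
        raise ValueError("direction must be 'tall' or 'short'")
    h = phenos["height_cm"].to_numpy(float)
    q = 1.0 - fraction if direction == "tall" else fraction
    threshold = float(np.quantile(h, q))
    mask = apply_threshold(h, threshold, direction)
    return phenos["plant_id"].to_numpy(object)[mask], threshold


def apply_threshold(heights: np.ndarray, threshold: float, direction: str) -> np.ndarray:
    """Boolean mask of plants at or beyond the truncation threshold."""
    h = np.asarray(heights, dtype=float)
    return h >= threshold if direction == "tall" else h <= threshold


def _recomb_prob(markers: pd.DataFrame) -> np.ndarray:
    """Per-interval recombination probability (Haldane), 0.5 across chromosomes.

    Entry ``j`` is the probability of a crossover between markers ``j-1`` and
    ``j``; entry 0 is the random choice of starting haplotype (0.5).
    """
    cm = markers["cm"].to_numpy(float)
    chrom = markers["chrom"].to_numpy(object)
    r = np.empty(len(markers))
    r[0] = 0.5
    d = np.diff(cm)
    r[1:] = 0.5 * (1.0 - np.exp(-np.abs(d) / 50.0))  # Haldane, d in cM
    r[1:][chrom[1:] != chrom[:-1]] = 0.5  # independent assortment
    return r


def _gametes(haplotypes: np.ndarray, parent_idx: np.ndarray, recomb: np.ndarray,
             rng: np.random.Generator) -> np.ndarray:
    """Form one gamete per entry of ``parent_idx`` by meiosis."""
    k, m = len(parent_idx), haplotypes.shape[2]
    switch = rng.random((k, m)) < recomb
    state = np.cumsum(switch, axis=1) % 2
    return haplotypes[parent_idx[:, None], state, np.arange(m)[None, :]]


def random_mate(
    selected: GenotypeMatrix,
    n_offspring: int,
    rng: np.random.Generator,
    id_prefix: str = "G1",
) -> GenotypeMatrix:
    """Random union of gametes among the selected parents (open pollination).

    Each offspring draws two parents uniformly with replacement — selfing is
    allowed, as open-pollinated maize includes self pollen — and one
    recombinant gamete from each parent (Haldane crossover probabilities from
    the genetic map; chromosomes assort independently).
    """
    if selected.n_individuals < 2:
        raise ValueError("random mating requires at least 2 selected parents")
    if selected.haplotypes is None:
        raise ValueError("selected parents carry no haplotypes; cannot recombine")
    recomb = _recomb_prob(selected.markers)
    mothers = rng.integers(0, selected.n_individuals, size=n_offspring)
    fathers = rng.integers(0, selected.n_individuals, size=n_offspring)
    hap_a = _gametes(selected.haplotypes, mothers, recomb, rng)
    hap_b = _gametes(selected.haplotypes, fathers, recomb, rng)
    haps = np.stack([hap_a, hap_b], axis=1)
    ids = np.array([f"{id_prefix}_{i:06d}" for i in range(n_offspring)], dtype=object)
    return GenotypeMatrix(
        dosage=haps.sum(axis=1).astype(np.int8),
        individual_ids=ids,
        markers=selected.markers.copy(),
        haplotypes=haps,
    )


# ---------------------------------------------------------------------------
# GBS observation
# ---------------------------------------------------------------------------


def observe_gbs(
    geno: GenotypeMatrix, mean_depth: float, rng: np.random.Generator
):
    """Apply a low-depth GBS observation layer to true genotypes.

    Per individual-site depth is Poisson(``mean_depth``).  Depth 0 yields a
    missing call.  Homozygotes are always called correctly when covered;
    a heterozygote with depth ``d`` samples each read's allele at random and
    is miscalled homozygous when all reads agree (probability ``2^(1-d)``).
    Sequencing error is not modeled.

    Returns ``(observed, depth)`` where ``observed`` is a GenotypeMatrix
    whose marker table gains a ``read_count`` column (total depth over
    individuals) and ``depth`` is the per-call depth matrix.
    """
    if mean_depth < 0:
        raise ValueError("mean_depth must be >= 0")
    n, m = geno.dosage.shape
    depth = rng.poisson(mean_depth, size=(n, m))
    observed = geno.dosage.astype(np.int8).copy()
    het = (observed == 1) & (depth > 0)
    if het.any():
        d_het = depth[het]
        alt_reads = rng.binomial(d_het, 0.5)
        calls = np.ones(len(d_het), dtype=np.int8)
        calls[alt_reads == 0] = 0
        calls[alt_reads == d_het] = 2
        observed[het] = calls
    observed[depth == 0] = -1
    markers = geno.markers.copy()
    markers["read_count"] = depth.sum(axis=0)
    out = GenotypeMatrix(dosage=observed, individual_ids=geno.individual_ids, markers=markers)
    return out, depth


# ---------------------------------------------------------------------------
# End-to-end experiment
# ---------------------------------------------------------------------------


@dataclass
class ExperimentResult:
    """Everything produced by one simulated experiment."""

    config: SimConfig
    truth: TruthRecord
    gen0: GenotypeMatrix  # all generation-0 plants
    gen1: GenotypeMatrix  # all generation-1 plants
    gen0_plots: np.ndarray  # plot index per gen0 individual
    gen1_plots: np.ndarray
    phenos_full: pd.DataFrame  # heights of every plant, both generations
    phenos: pd.DataFrame  # heights of the sampled (genotyped) plants
    observed: GenotypeMatrix  # GBS-observed genotypes of the sampled plants
    depth: np.ndarray
    sampled_ids: dict  # (generation, plot name) -> ids
    bulks: dict  # 'tall'/'short' -> generation-1 sampled ids


def simulate_experiment(config: SimConfig) -> ExperimentResult:
    """Run the full divergent truncation-selection experiment.

    Generation 0 is founded by random mating (HWE draws), planted in
    ``n_plots`` plots, and phenotyped; per plot, a truncation threshold is
    estimated from the ``n_sampled_per_plot`` randomly sampled plants and
    applied to the whole plot; selected plants are randomly mated within
    their plot to produce generation 1, which is phenotyped and sampled the
    same way.  GBS observation is applied to the sampled plants of both
    generations (the association panel).
    """
    ss = np.random.SeedSequence(config.seed)
    (s_found, s_qtl, s_ph0, s_samp0, s_mate, s_ph1, s_samp1, s_gbs) = [
        np.random.default_rng(child) for child in ss.spawn(8)
    ]

    plot_names = config.plot_names()
    regimes = config.plot_regimes()
    n_per = config.n_plants_per_plot

    gen0 = simulate_founders(config, rng=s_found)
    gen0_plots = np.repeat(np.arange(config.n_plots), n_per)
    truth = assign_qtl(gen0, config, s_qtl)

    ph0 = simulate_phenotypes(gen0, truth, config, s_ph0, plots=gen0_plots, generation=0)

    sampled_ids: dict = {}
    gen1_parts, gen1_plot_parts, ph1_parts = [], [], []
    for p, name in enumerate(plot_names):
        plot_mask = gen0_plots == p
        plot_ph = ph0.loc[plot_mask]
        sample_idx = s_samp0.choice(np.flatnonzero(plot_mask), size=config.n_sampled_per_plot,
                                    replace=False)
        sample_idx.sort()
        sampled_ids[(0, name)] = gen0.individual_ids[sample_idx]
        _, threshold = truncation_select(
            ph0.iloc[sample_idx], config.selection_fraction, regimes[p]
        )
        truth.truncation_threshold[name] = threshold
        sel_mask = plot_mask & apply_threshold(
            ph0["height_cm"].to_numpy(float), threshold, regimes[p]
        )
        sel_ids = gen0.individual_ids[sel_mask]
        if len(sel_ids) < 2:
            raise RuntimeError(f"fewer than 2 plants selected in plot {name}")
        truth.selected_ids[name] = sel_ids
        parents = gen0.subset(individuals=sel_mask)
        offspring = random_mate(parents, n_per, s_mate, id_prefix=f"G1{name}")
        gen1_parts.append(offspring)
        gen1_plot_parts.append(np.full(n_per, p))

    gen1 = gen1_parts[0]
    for part in gen1_parts[1:]:
        gen1 = concat_individuals(gen1, part)
    gen1_plots = np.concatenate(gen1_plot_parts)
    ph1 = simulate_phenotypes(gen1, truth, config, s_ph1, plots=gen1_plots, generation=1)

    bulk_ids: dict = {"tall": [], "short": []}
    for p, name in enumerate(plot_names):
        idx = np.flatnonzero(gen1_plots == p)
        sample_idx = s_samp1.choice(idx, size=config.n_sampled_per_plot, replace=False)
        sample_idx.sort()
        ids = gen1.individual_ids[sample_idx]
        sampled_ids[(1, name)] = ids
        bulk_ids[regimes[p]].extend(ids)

    sampled0 = np.concatenate([sampled_ids[(0, n)] for n in plot_names])
    sampled1 = np.concatenate([sampled_ids[(1, n)] for n in plot_names])
    panel = concat_individuals(gen0.subset(individuals=sampled0),
                               gen1.subset(individuals=sampled1))
    observed, depth = observe_gbs(panel, config.mean_depth, s_gbs)

    phenos_full = pd.concat([ph0, ph1], ignore_index=True)
    sampled_all = set(sampled0) | set(sampled1)
    phenos = phenos_full[phenos_full["plant_id"].isin(sampled_all)].reset_index(drop=True)

    logger.info(
        "simulated experiment: %d markers, %d plants/plot x %d plots, %d sampled",
        config.n_markers, n_per, config.n_plots, observed.n_individuals,
    )
    return ExperimentResult(
        config=config,
        truth=truth,
        gen0=gen0,
        gen1=gen1,
        gen0_plots=gen0_plots,
        gen1_plots=gen1_plots,
        phenos_full=phenos_full,
        phenos=phenos,
        observed=observed,
        depth=depth,
        sampled_ids=sampled_ids,
        bulks={k: np.array(v, dtype=object) for k, v in bulk_ids.items()},
    )


def write_phenotypes(phenos: pd.DataFrame, path) -> None:
    phenos.to_csv(path, sep="\t", index=False, columns=PHENO_COLUMNS, float_format="%.6g")


def write_truth(truth: TruthRecord, path) -> None:
    truth.to_json(path)
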