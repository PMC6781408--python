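"""Simulator: founders, phenotypes, truncation selection, mating, GBS layer."""

import numpy as np
import pandas as pd
import pytest

from spgwas import simpop
from spgwas.simpop import SimConfig


def _cfg(**kw):
    defaults = dict(
        n_chromosomes=2,
        markers_per_chromosome=50,
        n_plants_per_plot=200,
        n_qtl=5,
        seed=1,
    )
    defaults.update(kw)
    return SimConfig(**defaults)


# ---------------------------------------------------------------------------
# Founders
# ---------------------------------------------------------------------------


def test_founders_degenerate_frequency_gives_monomorphic():
    cfg = _cfg(founder_freq_range=(0.0, 0.0))
    g = simpop.simulate_founders(cfg, n_individuals=50)
    assert np.all(g.dosage == 0)


def test_founders_sample_frequency_matches_law(rng):
    """At freq 0.5 and n = 10000, the sample frequency sits within 3 binomial SE."""
    cfg = _cfg(founder_freq_range=(0.5, 0.5), markers_per_chromosome=20)
    g = simpop.simulate_founders(cfg, rng=rng, n_individuals=10_000)
    se = np.sqrt(0.5 * 0.5 / (2 * 10_000))
    freqs = g.alt_allele_freq()
    assert np.all(np.abs(freqs - 0.5) < 3 * se + 1e-12) or (
        np.mean(np.abs(freqs - 0.5) < 3 * se) > 0.95  # allow the expected ~0.3% tail
    )


def test_founders_population_size_is_plots_times_plants():
    """Four plots of 5000 plants found a 20000-individual population."""
    cfg = _cfg(n_plants_per_plot=5000, n_plots=4, markers_per_chromosome=15, n_chromosomes=1)
    g = simpop.simulate_founders(cfg)
    assert g.n_individuals == 20_000


def test_founders_markers_sorted_with_map_coordinates():
    g = simpop.simulate_founders(_cfg(), n_individuals=10)
    for _, grp in g.markers.groupby("chrom"):
        assert grp["pos"].is_monotonic_increasing
    assert np.allclose(g.markers["cm"], g.markers["pos"] / 1e6 * 1.0)


# ---------------------------------------------------------------------------
# Phenotypes
# ---------------------------------------------------------------------------


def test_phenotypes_h2_one_is_noiseless(rng):
    cfg = _cfg(target_h2=1.0, n_plots=1, plot_effects=((0.0, 0.0),))
    g = simpop.simulate_founders(cfg, rng=rng, n_individuals=300)
    truth = simpop.assign_qtl(g, cfg, rng)
    ph = simpop.simulate_phenotypes(g, truth, cfg, rng)
    gv = simpop.genetic_values(g, truth)
    assert np.corrcoef(ph["height_cm"], gv)[0, 1] == pytest.approx(1.0)


def test_phenotypes_realized_h2_near_target(rng):
    cfg = _cfg(target_h2=0.75, n_qtl=30, markers_per_chromosome=100)
    g = simpop.simulate_founders(cfg, rng=rng, n_individuals=10_000)
    truth = simpop.assign_qtl(g, cfg, rng)
    simpop.simulate_phenotypes(g, truth, cfg, rng)
    assert 0.70 <= truth.true_h2 <= 0.80


def test_phenotypes_plot_effect_shifts_means(rng):
    cfg = _cfg(n_plots=2, plot_effects=((0.0, 0.0), (10.0, 0.0)), target_h2=0.5)
    g = simpop.simulate_founders(cfg, rng=rng, n_individuals=4000)
    truth = simpop.assign_qtl(g, cfg, rng)
    plots = np.repeat([0, 1], 2000)
    ph = simpop.simulate_phenotypes(g, truth, cfg, rng, plots=plots)
    means = ph.groupby("plot")["height_cm"].mean()
    # plot index 1 carries the +10 cm generation-0 offset
    name0, name1 = cfg.plot_names()
    assert means[name1] - means[name0] == pytest.approx(10.0, abs=1.5)


def test_phenotypes_h2_zero_warns_and_ignores_genetics(rng):
    cfg = _cfg(target_h2=0.0)
    g = simpop.simulate_founders(cfg, rng=rng, n_individuals=500)
    truth = simpop.assign_qtl(g, cfg, rng)
    with pytest.warns(UserWarning, match="genetic values"):
        ph = simpop.simulate_phenotypes(g, truth, cfg, rng)
    gv = simpop.genetic_values(g, truth)
    assert abs(np.corrcoef(ph["height_cm"], gv)[0, 1]) < 0.15


# ---------------------------------------------------------------------------
# Truncation selection
# ---------------------------------------------------------------------------


def test_truncation_select_top_one_of_five():
    ph = pd.DataFrame({"plant_id": list("abcde"), "height_cm": [150, 160, 170, 180, 190]})
    ids, threshold = simpop.truncation_select(ph, 0.2, "tall")
    assert list(ids) == ["e"]
    assert threshold > 180


def test_truncation_select_degenerate_fraction_selects_all():
    ph = pd.DataFrame({"plant_id": list("abc"), "height_cm": [150.0, 160.0, 170.0]})
    ids, _ = simpop.truncation_select(ph, 1.0, "tall")
    assert set(ids) == set("abc")
    ids_short, _ = simpop.truncation_select(ph, 1.0, "short")
    assert set(ids_short) == set("abc")


def test_truncation_select_five_percent_of_5000(rng):
    ph = pd.DataFrame(
        {"plant_id": np.arange(5000).astype(str), "height_cm": rng.normal(180, 20, 5000)}
    )
    ids, _ = simpop.truncation_select(ph, 0.05, "tall")
    assert 240 <= len(ids) <= 260  # ~250 = 5% of 5000


def test_truncation_select_empty_plot_errors():
    with pytest.raises(ValueError, match="empty"):
        simpop.truncation_select(pd.DataFrame({"plant_id": [], "height_cm": []}), 0.05, "tall")


# ---------------------------------------------------------------------------
# Random mating
# ---------------------------------------------------------------------------


def test_random_mate_fixed_marker_stays_fixed(rng):
    cfg = _cfg()
    g = simpop.simulate_founders(cfg, rng=rng, n_individuals=20)
    g.haplotypes[:, :, 0] = 1  # fix marker 0 homozygous alt in every parent
    g.dosage[:, 0] = 2
    off = simpop.random_mate(g, 100, rng)
    assert np.all(off.dosage[:, 0] == 2)


def test_random_mate_conserves_allele_frequency():
    """Mean offspring frequency over 50 seeds within 3 SE of the parental 0.6."""
    cfg = _cfg(founder_freq_range=(0.6, 0.6), markers_per_chromosome=15, n_chromosomes=1)
    means = []
    for seed in range(50):
        rng = np.random.default_rng(seed)
        parents = simpop.simulate_founders(cfg, rng=rng, n_individuals=60)
        off = simpop.random_mate(parents, 200, rng)
        parent_freq = parents.alt_allele_freq()
        means.append(np.mean(off.alt_allele_freq() - parent_freq))
    # offspring draw gametes from the parents: conditional expectation is 0
    se = np.std(means, ddof=1) / np.sqrt(len(means))
    assert abs(np.mean(means)) < 3 * se + 1e-3


def test_random_mate_complete_linkage_has_no_recombinants(rng):
    """Two markers at identical map position never recombine."""
    cfg = _cfg(n_chromosomes=1, markers_per_chromosome=15)
    g = simpop.simulate_founders(cfg, rng=rng, n_individuals=40)
    g.markers.loc[1, "cm"] = g.markers.loc[0, "cm"]  # 0 cM apart
    # make parental haplotypes perfectly coupled at markers 0 and 1
    g.haplotypes[:, :, 1] = g.haplotypes[:, :, 0]
    g.dosage = g.haplotypes.sum(axis=1).astype(np.int8)
    off = simpop.random_mate(g, 300, rng)
    assert np.array_equal(off.haplotypes[:, :, 0], off.haplotypes[:, :, 1])


def test_random_mate_requires_two_parents(rng):
    g = simpop.simulate_founders(_cfg(), rng=rng, n_individuals=1)
    with pytest.raises(ValueError, match="2"):
        simpop.random_mate(g, 10, rng)


# ---------------------------------------------------------------------------
# GBS observation
# ---------------------------------------------------------------------------


def test_observe_gbs_zero_depth_all_missing(rng):
    g = simpop.simulate_founders(_cfg(), rng=rng, n_individuals=30)
    obs, depth = simpop.observe_gbs(g, 0.0, rng)
    assert np.all(obs.missing_mask())
    assert np.all(depth == 0)


def test_observe_gbs_single_read_het_always_homozygous(rng):
    g = simpop.simulate_founders(_cfg(founder_freq_range=(0.5, 0.5)), rng=rng, n_individuals=400)
    obs, depth = simpop.observe_gbs(g, 2.0, rng)
    het_single = (g.dosage == 1) & (depth == 1)
    assert het_single.sum() > 100
    assert np.all(np.isin(obs.dosage[het_single], [0, 2]))
    # homozygotes are always called correctly when covered
    hom = (g.dosage != 1) & (depth > 0)
    assert np.array_equal(obs.dosage[hom], g.dosage[hom])


def test_observe_gbs_het_miscall_rate_matches_closed_form(rng):
    """P(miscall | het, called) = sum_d Pois(d; mu) 2^(1-d) / (1 - Pois(0; mu))."""
    mu = 2.0
    d = np.arange(1, 60)
    from scipy import stats

    pois = stats.poisson.pmf(d, mu)
    expected = float((pois * 2.0 ** (1 - d)).sum() / (1 - stats.poisson.pmf(0, mu)))
    g = simpop.simulate_founders(
        _cfg(founder_freq_range=(0.5, 0.5), markers_per_chromosome=100), rng=rng,
        n_individuals=2000,
    )
    obs, depth = simpop.observe_gbs(g, mu, rng)
    het_called = (g.dosage == 1) & (depth > 0)
    miscall = np.mean(obs.dosage[het_called] != 1)
    se = np.sqrt(expected * (1 - expected) / het_called.sum())
    assert abs(miscall - expected) < 3 * se


def test_observe_gbs_read_counts_are_depth_sums(rng):
    g = simpop.simulate_founders(_cfg(), rng=rng, n_individuals=50)
    obs, depth = simpop.observe_gbs(g, 2.0, rng)
    assert np.array_equal(obs.markers["read_count"].to_numpy(), depth.sum(axis=0))


# ---------------------------------------------------------------------------
# Experiment-level invariants
# ---------------------------------------------------------------------------


def test_same_seed_bit_identical_different_seed_differs():
    cfg = _cfg(seed=42)
    a = simpop.simulate_experiment(cfg)
    b = simpop.simulate_experiment(cfg)
    assert np.array_equal(a.observed.dosage, b.observed.dosage)
    assert a.phenos["height_cm"].equals(b.phenos["height_cm"])
    c = simpop.simulate_experiment(_cfg(seed=43))
    assert not np.array_equal(a.gen0.dosage, c.gen0.dosage)


def test_no_selection_conserves_frequencies():
    """With fraction = 1 the generation-1 frequencies track generation 0."""
    cfg = _cfg(selection_fraction=1.0, n_plants_per_plot=400, seed=7)
    res = simpop.simulate_experiment(cfg)
    f0 = res.gen0.alt_allele_freq()
    f1 = res.gen1.alt_allele_freq()
    n_eff = res.gen0.n_individuals
    se = np.sqrt(np.clip(f0 * (1 - f0), 1e-6, None) / n_eff)  # parents + gamete sampling
    assert np.mean(np.abs(f1 - f0) < 4 * se) > 0.9


def test_selection_shifts_qtl_frequencies_upward():
    """Tall-selected plots raise the mean frequency of +effect QTL alleles."""
    shifts = []
    for seed in range(20):
        cfg = _cfg(
            n_plants_per_plot=400,
            n_qtl=6,
            qtl_effects=(4.0,) * 6,
            target_h2=0.8,
            seed=seed,
        )
        res = simpop.simulate_experiment(cfg)
        tall_plots = [i for i, r in enumerate(cfg.plot_regimes()) if r == "tall"]
        qtl = res.truth.qtl_indices
        for p in tall_plots:
            f0 = res.gen0.dosage[res.gen0_plots == p][:, qtl].mean() / 2
            f1 = res.gen1.dosage[res.gen1_plots == p][:, qtl].mean() / 2
            shifts.append(f1 - f0)
    assert np.mean(shifts) > 0.0
    assert np.mean(np.array(shifts) > 0) > 0.9


def test_truth_record_round_trip(tmp_path, small_experiment):
    truth = small_experiment.truth
    simpop.write_truth(truth, tmp_path / "truth.json")
    import json

    back = json.loads((tmp_path / "truth.json").read_text())
    assert back["qtl_marker_ids"] == list(truth.qtl_marker_ids)
    assert back["true_h2"] == pytest.approx(truth.true_h2)
    assert set(back["selected_ids"]) == set(truth.selected_ids)
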