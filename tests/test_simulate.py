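"""Forward simulator: chain exactness, stationarity, noise models."""

import numpy as np
import pandas as pd
import pytest

import epidrift as ed
from epidrift.simulate import _evolve


def _flat_config(**kw):
    base = dict(
        n_chromosomes=1,
        chrom_length=50_000,
        rates={"centromere": {"CG": (0.0, 0.0)}},
        tau={"centromere": 0.0, "h3k9me3": 0.0, "h3k27me3": 0.0, "euchromatin": 0.0},
        p0={"centromere": 0.3, "h3k9me3": 0.0, "h3k27me3": 0.0, "euchromatin": 0.0},
        eps_fail=0.0,
        eps_over=0.0,
        seed=0,
    )
    base.update(kw)
    return ed.SimulationConfig(**base)


def test_no_process_no_noise_states_equal_root():
    cfg = _flat_config(mean_depth=60.0)
    res = ed.simulate_pedigree(cfg, pedigree_table=ed.wgbs_design(n_lines=3), seed=0)
    root = res.truth.latent[res.pedigree.root]
    for nid, states in res.truth.latent.items():
        assert np.array_equal(states, root)
    # deep coverage + no conversion error: observed level equals latent state
    s = res.samples[0]
    covered = s.total > 0
    assert np.array_equal(s.meth[covered] > 0, root[covered])


def test_full_randomization_divergence_half():
    """alpha = beta = 0.5: each mitosis resamples the state, so two samples
    are independent coin flips and disagree half the time."""
    cfg = _flat_config(rates={"centromere": {"CG": (0.5, 0.5)}}, p0={"centromere": 0.5})
    layout, sites = ed.centromeric_site_table(n_sites=20_000, chrom_length=50_000, seed=0)
    res = ed.simulate_pedigree(cfg, pedigree_table=ed.wgbs_design(n_lines=2, transfers=(5,)), layout=layout, sites=sites, seed=1)
    a = res.truth.latent["L1_t5"]
    b = res.truth.latent["L2_t5"]
    assert abs(np.mean(a != b) - 0.5) < 0.02


def test_centromeric_divergence_matches_closed_form():
    """Two lineages 2000 mitoses apart at the estimated centromeric CG rates,
    starting from equilibrium: mean latent divergence over 50,000 sites
    matches the closed form within Monte-Carlo error."""
    alpha, beta = 1.62e-5, 8.55e-5
    cfg = _flat_config(
        chrom_length=200_000,
        rates={"centromere": {"CG": (alpha, beta)}},
        p0={"centromere": "equilibrium"},
    )
    layout, sites = ed.centromeric_site_table(n_sites=50_000, chrom_length=200_000, seed=2)
    res = ed.simulate_pedigree(
        cfg, pedigree_table=ed.wgbs_design(n_lines=2, transfers=(40,)), layout=layout, sites=sites, seed=2
    )
    a = res.truth.latent["L1_t40"]
    b = res.truth.latent["L2_t40"]
    observed = np.mean(a != b)
    expected = ed.expected_divergence(alpha, beta, alpha / (alpha + beta), 1000, 1000)
    se = np.sqrt(expected * (1 - expected) / 50_000)
    assert abs(observed - expected) < 4 * se


def test_evolve_closed_form_equals_bruteforce_chain():
    rng1 = np.random.default_rng(0)
    states = rng1.random(200_000) < 0.3
    alpha, beta, t = 0.05, 0.1, 5
    out_c = _evolve(states, t, alpha, beta, np.random.default_rng(1))
    out_b = _evolve(states, t, alpha, beta, np.random.default_rng(2), brute_force=True)
    # same marginal distribution: compare conditional transition fractions
    for s0 in (False, True):
        sel = states == s0
        p_c = np.mean(out_c[sel])
        p_b = np.mean(out_b[sel])
        p_true = ed.transition_matrix(alpha, beta, t)[int(s0), 1]
        assert abs(p_c - p_true) < 0.01
        assert abs(p_b - p_true) < 0.01


def test_stationarity_of_marginal_fraction():
    """Starting at p0 = equilibrium, the methylated fraction stays at
    alpha/(alpha+beta) at every node (3-standard-error band)."""
    alpha, beta = 2e-4, 8e-4
    cfg = _flat_config(rates={"centromere": {"CG": (alpha, beta)}}, p0={"centromere": "equilibrium"})
    layout, sites = ed.centromeric_site_table(n_sites=30_000, chrom_length=50_000, seed=3)
    res = ed.simulate_pedigree(cfg, pedigree_table=ed.wgbs_design(n_lines=3), layout=layout, sites=sites, seed=3)
    pi = alpha / (alpha + beta)
    se = np.sqrt(pi * (1 - pi) / 30_000)
    for nid, states in res.truth.latent.items():
        assert abs(states.mean() - pi) < 3 * se + 3 * se  # small extra slack for drift correlation


def test_counts_conserve_depth(small_sim):
    for s in small_sim.samples:
        assert (s.meth <= s.total).all()
        assert (s.meth >= 0).all()


def test_invalid_rates_rejected():
    with pytest.raises(ValueError):
        ed.SimulationConfig(rates={"centromere": {"CG": (0.6, 0.6)}})
    with pytest.raises(ValueError):
        ed.simulate_pedigree(_flat_config(), pedigree_table=pd.DataFrame())


# ------------------------------------------------------------------ mutations


def test_mutation_rate_zero():
    cfg = _flat_config(mutation_rate=0.0)
    res = ed.simulate_pedigree(cfg, pedigree_table=ed.wgbs_design(n_lines=3), seed=0)
    assert res.truth.mutations.empty


def test_mutation_totals_match_expectation():
    """Rate 0.033/mitosis gives ~33 mutations per line over 1000 mitoses."""
    cfg = _flat_config(mutation_rate=0.033)
    ped = ed.Pedigree.from_dataframe(ed.wgbs_design(n_lines=30))
    rng = np.random.default_rng(0)
    muts = ed.simulate_mutations(cfg, ped, rng=rng)
    per_line = muts.groupby("line_id").size()
    assert abs(per_line.mean() - 33) < 3 * np.sqrt(33 / 30)


def test_changes_happen_without_mutations(small_sim):
    """Intervals carrying zero genetic mutations still show methylation
    changes when the epimutation process is active."""
    res = small_sim
    model = ed.call_all(res.samples, "CG")
    states = np.vstack([s.state for s in res.samples])
    ids = [s.sample_id for s in res.samples]
    changes = ed.interval_change_counts(states, ids, res.pedigree)
    whole = changes[changes["domain"] == "all"]
    muts = res.truth.mutations.groupby(["line_id", "interval_end"]).size()
    merged = whole.assign(
        n_mut=[muts.get((r["line_id"], r["interval_end"]), 0) for _, r in whole.iterrows()]
    )
    no_mut = merged[merged["n_mut"] == 0]
    if len(no_mut):  # seed-dependent; the joint property is what matters
        assert no_mut["n_changes"].sum() > 0


# ----------------------------------------------------------------- ChIP model


def test_chip_stable_mode_low_divergence(toy_pedigree):
    cfg = _flat_config()
    counts, peaks = ed.simulate_chip_bins(cfg, toy_pedigree, mean_background=2000.0, seed=0)
    pts = ed.assemble_count_divergence(counts, toy_pedigree)
    # stable enrichment + large counts: normalized divergence is tiny and flat
    out = ed.divergence_trend_test(pts, n_perm=500, seed=0)
    assert out["p_value"] > 0.01
    # identical peak sets across samples
    first = next(iter(peaks.values()))
    for df in peaks.values():
        pd.testing.assert_frame_equal(df, first)


def test_chip_drift_mode_positive_trend(toy_pedigree):
    cfg = _flat_config()
    counts, _ = ed.simulate_chip_bins(cfg, toy_pedigree, drift_sigma=0.02, seed=1)
    pts = ed.assemble_count_divergence(counts, toy_pedigree)
    out = ed.divergence_trend_test(pts, n_perm=500, seed=1)
    assert out["slope"] > 0


def test_chip_library_size_validation(toy_pedigree):
    cfg = _flat_config()
    with pytest.raises(ValueError):
        ed.simulate_chip_bins(cfg, toy_pedigree, library_sizes={n: 0.0 for n in toy_pedigree.samples()}, seed=0)
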