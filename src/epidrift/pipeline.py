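"""End-to-end experiment pipelines: simulate, call, assemble, fit.

These functions wire the package's stages together for the standard
in-silico experiments: rate recovery on a bisulfite-style pedigree,
null-model calibration on a dense-sampling pedigree, and the
centromere-hotspot contrast.  They are what the acceptance checks and the
worked examples run.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from . import model as model_mod
from .divergence import assemble_divergence, divergence_trend_test
from .hmm import call_states, fit_hmm
from .intervals import GenomeLayout
from .model import (
    EpimutationRates,
    ModelComparison,
    NeutralAccumulationModel,
    NullDivergenceModel,
    compare_models,
    compare_models_permutation,
)
from .simulate import SimulationConfig, nanopore_design, simulate_pedigree, wgbs_design


def centromeric_site_table(n_sites=50_000, chrom_length=500_000, context="CG", seed=0):
    """Single-chromosome, all-centromere site table for rate-recovery runs."""
    layout = GenomeLayout(
        {"chr1": chrom_length},
        domains=pd.DataFrame(
            {"Chromosome": ["chr1"], "Start": [0], "End": [chrom_length], "domain": ["centromere"]}
        ),
        annotations=pd.DataFrame(
            {"Chromosome": ["chr1"], "Start": [0], "End": [chrom_length], "annotation": ["TE"]}
        ),
    )
    rng = np.random.default_rng(seed)
    pos = np.sort(rng.choice(chrom_length, size=n_sites, replace=False)) + 1
    sites = pd.DataFrame(
        {
            "chrom": "chr1",
            "pos": pos,
            "strand": np.where(rng.random(n_sites) < 0.5, "+", "-"),
            "context": context,
            "domain": "centromere",
        }
    )
    return layout, sites


def call_all(samples, context, reference_sample=None, **hmm_kwargs):
    """Fit the calling HMM on one reference sample and decode every sample."""
    ref = reference_sample if reference_sample is not None else samples[0]
    model = fit_hmm(ref, context, **hmm_kwargs)
    for s in samples:
        call_states(s, model)
    return model


def ancestral_methylated_fraction(samples) -> float:
    """Methylated fraction among called sites of the ancestor replicates."""
    anc = [s for s in samples if s.line_id == "ancestor"]
    if not anc:
        raise ValueError("no ancestor-line samples")
    fracs = [np.mean(s.state[s.state != -1] == 1) for s in anc]
    return float(np.mean(fracs))


def recovery_experiment(
    seed: int,
    n_sites: int = 50_000,
    context: str = "CG",
    rates: tuple[float, float] = (1.62e-5, 8.55e-5),
    pedigree_table=None,
    n_starts: int = 100,
) -> tuple[EpimutationRates, ModelComparison, pd.DataFrame]:
    """Simulate a bisulfite-design pedigree at the given centromeric rates,
    call states, assemble all within-pedigree pairs and fit the neutral
    model with p0 anchored to the measured ancestral methylated fraction.

    Returns (rates, neutral-vs-null F comparison, divergence points).
    """
    alpha, beta = rates
    cfg = SimulationConfig(
        seed=seed, rates={"centromere": {context: (alpha, beta)}}, p0={"centromere": "equilibrium"}
    )
    layout, sites = centromeric_site_table(n_sites=n_sites, context=context, seed=seed)
    if pedigree_table is None:
        pedigree_table = wgbs_design()
    res = simulate_pedigree(cfg, pedigree_table=pedigree_table, layout=layout, sites=sites, seed=seed)
    call_all(res.samples, context)
    states = np.vstack([s.state for s in res.samples])
    ids = [s.sample_id for s in res.samples]
    points = assemble_divergence(states, ids, res.pedigree, context=context)
    p0_hat = ancestral_methylated_fraction(res.samples)
    X, y = model_mod._points_to_xy(points)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        neutral = NeutralAccumulationModel(p0=p0_hat, n_starts=n_starts, random_state=seed).fit(X, y)
    null = NullDivergenceModel().fit(X, y)
    comp = compare_models(null, neutral, labels=("null", "neutral"))
    fitted = EpimutationRates(
        alpha=neutral.alpha_,
        beta=neutral.beta_,
        p0=neutral.p0_,
        d0=neutral.d0_,
        rss=neutral.rss_,
        n_pairs=neutral.n_points_,
        context=context,
        boundary=neutral.boundary_,
    )
    return fitted, comp, points


def null_calibration_experiment(
    seed: int,
    n_sites: int = 3_000,
    tau: float = 0.005,
    n_perm: int = 79,
    n_starts: int = 4,
) -> float:
    """One no-accumulation replicate: heritable rates 0, transient noise only.

    Uses the dense-sampling design with a single ancestor replicate and
    ancestor-descendant pairs, whose points are exchangeable under the
    null; returns the permutation-calibrated neutral-versus-null p-value.
    """
    cfg = SimulationConfig(seed=seed, rates={}, tau={"centromere": tau}, p0={"centromere": 0.16})
    layout, sites = centromeric_site_table(n_sites=n_sites, chrom_length=60_000, seed=seed)
    res = simulate_pedigree(cfg, pedigree_table=nanopore_design(), layout=layout, sites=sites, seed=seed)
    call_all(res.samples, "CG")
    states = np.vstack([s.state for s in res.samples])
    ids = [s.sample_id for s in res.samples]
    points = assemble_divergence(states, ids, res.pedigree, context="CG", pairs="ancestor")
    X, y = model_mod._points_to_xy(points)
    fast_opts = {"ftol": 1e-10, "gtol": 1e-8, "maxiter": 200}
    comp = compare_models_permutation(
        X,
        y,
        alt_factory=lambda: NeutralAccumulationModel(
            n_starts=n_starts, random_state=seed, optimizer_options=fast_opts
        ),
        n_perm=n_perm,
        seed=seed,
    )
    return comp.p_value


def hotspot_experiment(seed: int, n_sites_per_domain: int = 8_000, n_perm: int = 2_000) -> dict:
    """Centromere-hotspot contrast: heritable epimutations in centromeres,
    transient flicker in euchromatin.

    Simulates the default study conditions on a two-domain site table and
    runs the permutation trend test per domain.  Expected phenotype:
    centromeric divergence increases with mitoses, euchromatic divergence is
    flat.
    """
    L = 400_000
    layout = GenomeLayout(
        {"chr1": L},
        domains=pd.DataFrame(
            {
                "Chromosome": ["chr1", "chr1"],
                "Start": [0, L // 2],
                "End": [L // 2, L],
                "domain": ["centromere", "euchromatin"],
            }
        ),
        annotations=pd.DataFrame(
            {"Chromosome": ["chr1"], "Start": [0], "End": [L], "annotation": ["TE"]}
        ),
    )
    rng = np.random.default_rng(seed)
    frames = []
    for dom, lo, hi in (("centromere", 0, L // 2), ("euchromatin", L // 2, L)):
        pos = np.sort(rng.choice(np.arange(lo, hi), size=n_sites_per_domain, replace=False)) + 1
        frames.append(
            pd.DataFrame({"chrom": "chr1", "pos": pos, "strand": "+", "context": "CG", "domain": dom})
        )
    sites = pd.concat(frames, ignore_index=True)
    cfg = SimulationConfig(seed=seed)  # defaults: centromeric rates, euchromatic transients
    res = simulate_pedigree(cfg, pedigree_table=wgbs_design(), layout=layout, sites=sites, seed=seed)
    call_all(res.samples, "CG")
    states = np.vstack([s.state for s in res.samples])
    ids = [s.sample_id for s in res.samples]
    doms = sites["domain"].to_numpy()
    out = {}
    for dom in ("centromere", "euchromatin"):
        pts = assemble_divergence(
            states, ids, res.pedigree, context="CG", domain=dom, unit_domains=doms
        )
        out[dom] = divergence_trend_test(pts, n_perm=n_perm, seed=seed)
    return out
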