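"""Forward simulation of methylomes along a mutation-accumulation pedigree.

The generator emulates the statistical structure of the MA study it is
built around: two pedigrees propagated by single-spore descent (25 mitoses
per transfer), bisulfite-style sampling of ten lines at transfers 5/20/40
and a denser long-read design of six lines at transfers 1/5/7/8/10/15;
heritable gain/loss epimutations confined to centromeric domains at the
estimated per-mitosis rates; transient (non-heritable) methylation flicker
in euchromatin; negative-binomial sequencing depth; bisulfite conversion
noise; and genetic mutations arriving as an independent Poisson process.

Latent states evolve by the exact two-state chain: the transition over a
t-mitosis edge is computed in closed form (``brute_force=True`` loops the
single-mitosis matrix instead and exists for oracle tests).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .intervals import GenomeLayout
from .io import MethylomeSample
from .model import transition_matrix, _validate_rates
from .pedigree import Pedigree

# Centromeric per-mitosis gain/loss rates per context: the single-site
# point estimates this package's model is designed to recover.
DEFAULT_RATES = {
    "CG": (1.62e-5, 8.55e-5),
    "CHG": (1.54e-5, 8.19e-5),
    "CHH": (2.17e-5, 7.18e-5),
}


@dataclass
class SimulationConfig:
    """Study-condition parameters for the forward simulator.

    Defaults encode the MA design: 25 mitoses per transfer, heritable
    epimutations only in centromeres (per-context rates above, equilibrium
    ancestral fraction), transient observation-level methylation elsewhere,
    mean depth 20 with negative-binomial dispersion 5, conversion error
    0.005 (unmethylated read as methylated) / 0.01 (methylated read as
    unmethylated), and ~33 genetic mutations per line per 1000 mitoses.
    The genome is a desk-scale miniature: chromosome count/length are free,
    the domain fractions follow the organism's layout qualitatively.
    """

    n_chromosomes: int = 2
    chrom_length: int = 300_000
    centromere_fraction: float = 0.10
    h3k9me3_fraction: float = 0.05
    h3k27me3_fraction: float = 0.05
    site_density: float = 0.10  # cytosines per bp per strand pooled across contexts
    context_probs: tuple = (0.25, 0.25, 0.50)  # CG, CHG, CHH

    # heritable two-state rates (alpha, beta) per domain per context;
    # domains absent from the dict have rates (0, 0): no heritable process
    rates: dict = field(default_factory=lambda: {"centromere": dict(DEFAULT_RATES)})
    # ancestral methylated fraction per domain; "equilibrium" = alpha/(alpha+beta)
    p0: dict = field(
        default_factory=lambda: {
            "centromere": "equilibrium",
            "h3k9me3": 0.16,
            "h3k27me3": 0.05,
            "euchromatin": 0.01,
        }
    )
    # transient, non-heritable per-observation flip probability per domain
    tau: dict = field(
        default_factory=lambda: {
            "centromere": 0.0,
            "h3k9me3": 0.005,
            "h3k27me3": 0.005,
            "euchromatin": 0.005,
        }
    )

    mean_depth: float = 20.0
    depth_dispersion: float = 5.0
    eps_fail: float = 0.005  # unconverted unmethylated C read as methylated
    eps_over: float = 0.01  # methylated C read as unmethylated

    mutation_rate: float = 0.033  # genetic mutations per mitosis per line

    mitoses_per_transfer: float = 25.0
    seed: int = 0

    def __post_init__(self):
        for dom, per_ctx in self.rates.items():
            for ctx, (a, b) in per_ctx.items():
                if a + b > 0:
                    _validate_rates(a, b)
        for name, val in [("mean_depth", self.mean_depth), ("depth_dispersion", self.depth_dispersion)]:
            if val <= 0:
                raise ValueError(f"{name} must be positive")
        for p in (self.eps_fail, self.eps_over, *self.tau.values()):
            if not 0 <= p <= 1:
                raise ValueError("probabilities must be in [0, 1]")
        if self.mutation_rate < 0:
            raise ValueError("mutation_rate must be >= 0")

    def domain_rates(self, domain: str, context: str) -> tuple[float, float]:
        return tuple(self.rates.get(domain, {}).get(context, (0.0, 0.0)))

    def domain_p0(self, domain: str, context: str) -> float:
        val = self.p0.get(domain, 0.0)
        if val == "equilibrium":
            a, b = self.domain_rates(domain, context)
            return a / (a + b) if a + b > 0 else 0.0
        return float(val)


def wgbs_design(n_lines=10, transfers=(5, 20, 40), n_ancestor_replicates=3) -> pd.DataFrame:
    """Pedigree table for the bisulfite design: lines sampled at three transfers.

    Within a line, later samples descend from the earlier sampled culture;
    ancestor replicates are transfer-0 children of the root.
    """
    rows = [{"sample_id": "root", "line_id": "ancestor", "transfer": 0, "parent_id": "", "sampled": 0}]
    for r in range(1, n_ancestor_replicates + 1):
        rows.append(
            {"sample_id": f"anc_r{r}", "line_id": "ancestor", "transfer": 0, "parent_id": "root", "sampled": 1}
        )
    for l in range(1, n_lines + 1):
        parent = "root"
        for t in transfers:
            sid = f"L{l}_t{t}"
            rows.append({"sample_id": sid, "line_id": f"L{l}", "transfer": t, "parent_id": parent, "sampled": 1})
            parent = sid
    return pd.DataFrame(rows)


def nanopore_design(n_lines=6, transfers=(1, 5, 7, 8, 10, 15), n_ancestor_replicates=1) -> pd.DataFrame:
    """Pedigree table for the dense long-read design (six time points per line)."""
    return wgbs_design(n_lines=n_lines, transfers=transfers, n_ancestor_replicates=n_ancestor_replicates)


def make_layout(config: SimulationConfig, rng=None) -> GenomeLayout:
    """Desk-scale genome: one centromere block per chromosome plus interspersed
    heterochromatin, with a gene/promoter/TE/intergenic annotation partition."""
    rng = np.random.default_rng(rng if rng is not None else config.seed)
    chrom_lengths = {f"chr{i + 1}": int(config.chrom_length) for i in range(config.n_chromosomes)}
    dom_rows, ann_rows = [], []
    for chrom, L in chrom_lengths.items():
        cen_len = int(L * config.centromere_fraction)
        cen_start = (L - cen_len) // 2
        blocks = [(cen_start, cen_start + cen_len, "centromere")]
        # interspersed heterochromatin: a few equal blocks per flank
        for frac, label in ((config.h3k9me3_fraction, "h3k9me3"), (config.h3k27me3_fraction, "h3k27me3")):
            n_blk = 2
            blk = int(L * frac / n_blk)
            offs = [int(0.1 * L), int(0.75 * L)] if label == "h3k9me3" else [int(0.3 * L), int(0.9 * L) - blk]
            for o in offs:
                blocks.append((o, o + blk, label))
        blocks.sort()
        cursor = 0
        merged = []
        for s, e, lab in blocks:
            s = max(s, cursor)
            if e <= s:
                continue
            if s > cursor:
                merged.append((cursor, s, "euchromatin"))
            merged.append((s, e, lab))
            cursor = e
        if cursor < L:
            merged.append((cursor, L, "euchromatin"))
        for s, e, lab in merged:
            dom_rows.append((chrom, s, e, lab))
            ann_rows.extend(_annotate_block(chrom, s, e, lab, rng))
    domains = pd.DataFrame(dom_rows, columns=["Chromosome", "Start", "End", "domain"])
    annotations = pd.DataFrame(ann_rows, columns=["Chromosome", "Start", "End", "annotation"])
    return GenomeLayout(chrom_lengths, domains=domains, annotations=annotations)


def _annotate_block(chrom, start, end, label, rng):
    """Tile a domain block with annotations: heterochromatin is TE-rich,
    euchromatin alternates gene / 1-kb promoter / intergenic stretches."""
    rows = []
    cursor = start
    if label in ("centromere", "h3k9me3"):
        while cursor < end:
            te = min(int(rng.integers(2000, 5000)), end - cursor)
            rows.append((chrom, cursor, cursor + te, "TE"))
            cursor += te
            if cursor < end:
                gap = min(int(rng.integers(200, 1500)), end - cursor)
                rows.append((chrom, cursor, cursor + gap, "intergenic"))
                cursor += gap
    else:
        while cursor < end:
            inter = min(int(rng.integers(500, 2500)), end - cursor)
            rows.append((chrom, cursor, cursor + inter, "intergenic"))
            cursor += inter
            if cursor >= end:
                break
            prom = min(1000, end - cursor)
            rows.append((chrom, cursor, cursor + prom, "promoter"))
            cursor += prom
            if cursor >= end:
                break
            gene = min(int(rng.integers(1000, 4000)), end - cursor)
            rows.append((chrom, cursor, cursor + gene, "gene"))
            cursor += gene
    return rows


def make_sites(layout: GenomeLayout, config: SimulationConfig, rng=None) -> pd.DataFrame:
    """Cytosine site table: positions thinned at ``site_density``, random
    strand, contexts multinomial, domain looked up from the layout."""
    rng = np.random.default_rng(rng if rng is not None else config.seed)
    frames = []
    for chrom, L in layout.chrom_lengths.items():
        n = rng.binomial(L, min(config.site_density, 1.0))
        pos0 = np.sort(rng.choice(L, size=n, replace=False))
        ctx = rng.choice(len(config.context_probs), size=n, p=config.context_probs)
        frames.append(
            pd.DataFrame(
                {
                    "chrom": chrom,
                    "pos": pos0 + 1,  # 1-based
                    "strand": np.where(rng.random(n) < 0.5, "+", "-"),
                    "context": np.array(["CG", "CHG", "CHH"])[ctx],
                }
            )
        )
    sites = pd.concat(frames, ignore_index=True)
    sites["domain"] = layout.label_positions(sites["chrom"], sites["pos"].to_numpy() - 1, "domain")
    return sites


@dataclass
class TruthTable:
    """Ground truth of one simulation: latent states per node and the
    simulated genetic mutations."""

    latent: dict[str, np.ndarray]  # node_id -> bool array over sites
    mutations: pd.DataFrame | None = None


@dataclass
class SimulationResult:
    samples: list[MethylomeSample]
    truth: TruthTable
    pedigree: Pedigree
    sites: pd.DataFrame
    layout: GenomeLayout
    config: SimulationConfig


def _evolve(states, t, alpha, beta, rng, brute_force=False):
    """One edge of the two-state chain for a site group with common rates."""
    if alpha + beta == 0 or t == 0:
        return states.copy()
    if brute_force:
        out = states.copy()
        for _ in range(int(t)):
            u = rng.random(len(out))
            gain = ~out & (u < alpha)
            loss = out & (u < beta)
            out = out ^ gain ^ loss
        return out
    P = transition_matrix(alpha, beta, t)
    p_m = np.where(states, P[1, 1], P[0, 1])
    return rng.random(len(states)) < p_m


def simulate_pedigree(
    config: SimulationConfig,
    pedigree_table: pd.DataFrame | None = None,
    layout: GenomeLayout | None = None,
    sites: pd.DataFrame | None = None,
    seed: int | None = None,
    brute_force: bool = False,
) -> SimulationResult:
    """Simulate latent methylomes along the pedigree and observe them.

    Latent evolution uses the closed-form multi-mitosis transition per
    (domain, context) group.  Observation per sampled node: depth from a
    negative binomial, a transient flip with probability tau(domain), then
    a binomial read count with success probability eps_fail (observed
    unmethylated) or 1 - eps_over (observed methylated).
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    if layout is None:
        layout = make_layout(config, rng=rng)
    if sites is None:
        sites = make_sites(layout, config, rng=rng)
    if pedigree_table is None:
        pedigree_table = wgbs_design()
    if pedigree_table.empty:
        raise ValueError("empty pedigree")
    ped = Pedigree.from_dataframe(pedigree_table, mitoses_per_transfer=config.mitoses_per_transfer)

    groups = {}  # (domain, context) -> site index array
    dom = sites["domain"].to_numpy()
    ctx = sites["context"].to_numpy()
    for d in np.unique(dom):
        for c in np.unique(ctx):
            idx = np.flatnonzero((dom == d) & (ctx == c))
            if len(idx):
                groups[(d, c)] = idx

    n = len(sites)
    latent: dict[str, np.ndarray] = {}
    root = ped.root
    root_states = np.zeros(n, dtype=bool)
    for (d, c), idx in groups.items():
        root_states[idx] = rng.random(len(idx)) < config.domain_p0(d, c)
    latent[root] = root_states

    for nid in ped.topological_order():
        node = ped.nodes[nid]
        if node.parent_id is None:
            continue
        parent_states = latent[node.parent_id]
        child = parent_states.copy()
        t = node.edge_mitoses
        if t != int(t):
            raise ValueError("pedigree edges must be whole mitoses")
        for (d, c), idx in groups.items():
            a, b = config.domain_rates(d, c)
            child[idx] = _evolve(parent_states[idx], int(t), a, b, rng, brute_force=brute_force)
        latent[nid] = child

    tau_site = np.array([config.tau.get(d, 0.0) for d in dom])
    samples = []
    for nid in ped.samples():
        node = ped.nodes[nid]
        depth = _nbinom_depth(config, n, rng)
        obs = latent[nid].copy()
        flip = rng.random(n) < tau_site
        obs ^= flip
        p_read = np.where(obs, 1.0 - config.eps_over, config.eps_fail)
        meth = rng.binomial(depth, p_read)
        samples.append(
            MethylomeSample(
                nid,
                sites,
                meth,
                depth,
                line_id=node.line_id,
                transfer=node.transfer,
            )
        )

    mutations = simulate_mutations(config, ped, rng=rng, layout=layout)
    return SimulationResult(samples, TruthTable(latent, mutations), ped, sites, layout, config)


def _nbinom_depth(config, n, rng):
    # NB parameterised by mean/dispersion: var = mu + mu^2 / k
    mu, k = config.mean_depth, config.depth_dispersion
    p = k / (k + mu)
    return rng.negative_binomial(k, p, size=n).astype(np.int64)


def simulate_mutations(config: SimulationConfig, pedigree: Pedigree, rng=None, layout=None) -> pd.DataFrame:
    """Genetic mutations per line per transfer interval: Poisson in the edge
    length, positions uniform on the genome, independent of methylation."""
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    chroms = list(layout.chrom_lengths) if layout is not None else ["chr1"]
    lens = np.array([layout.chrom_lengths[c] for c in chroms]) if layout is not None else np.array([1_000_000])
    probs = lens / lens.sum()
    rows = []
    for nid in pedigree.topological_order():
        node = pedigree.nodes[nid]
        if node.parent_id is None:
            continue
        parent = pedigree.nodes[node.parent_id]
        k = rng.poisson(config.mutation_rate * node.edge_mitoses)
        for _ in range(int(k)):
            ci = rng.choice(len(chroms), p=probs)
            rows.append(
                {
                    "line_id": node.line_id,
                    "interval_start": parent.transfer,
                    "interval_end": node.transfer,
                    "chrom": chroms[ci],
                    "pos": int(rng.integers(1, lens[ci] + 1)),
                }
            )
    cols = ["line_id", "interval_start", "interval_end", "chrom", "pos"]
    return pd.DataFrame(rows, columns=cols)


def simulate_chip_bins(
    config: SimulationConfig,
    pedigree: Pedigree,
    layout: GenomeLayout | None = None,
    bin_size: int = 5000,
    centromere_bin_size: int = 500,
    mean_background: float = 20.0,
    enrichment: float = 8.0,
    library_sizes: dict | None = None,
    drift_sigma: float = 0.0,
    peak_dropout: float = 0.0,
    seed: int | None = None,
):
    """Per-bin ChIP read counts and peak calls for each sampled node.

    In stable mode (``drift_sigma=0``) per-bin expected counts are identical
    across samples: heterochromatic bins are ``enrichment``-fold over
    background, counts are Poisson around the mean scaled by library size.
    ``drift_sigma > 0`` adds an independent Gaussian random walk on the
    log-mean along each pedigree edge (per mitosis), giving a
    divergence-accumulating alternative for power analysis.
    ``peak_dropout`` removes each enriched run from a sample's peak set with
    that probability (presence/absence variation).

    Returns ``(counts, peaks)``: a long DataFrame (chrom, start, end,
    sample, count) and a dict sample -> peak interval frame.
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    if layout is None:
        layout = make_layout(config, rng=rng)
    if library_sizes is not None and any(v <= 0 for v in library_sizes.values()):
        raise ValueError("library sizes must be positive")

    bins = []
    for chrom, L in layout.chrom_lengths.items():
        doms = layout.domains[layout.domains["Chromosome"] == chrom]
        cen = doms[doms["domain"] == "centromere"]
        cen_ranges = list(zip(cen["Start"], cen["End"]))
        cursor = 0
        for s, e in sorted(cen_ranges):
            for b0 in range(cursor, s, bin_size):
                bins.append((chrom, b0, min(b0 + bin_size, s)))
            for b0 in range(s, e, centromere_bin_size):
                bins.append((chrom, b0, min(b0 + centromere_bin_size, e)))
            cursor = e
        for b0 in range(cursor, L, bin_size):
            bins.append((chrom, b0, min(b0 + bin_size, L)))
    bdf = pd.DataFrame(bins, columns=["chrom", "start", "end"])
    mid = (bdf["start"] + bdf["end"]) // 2
    dom = layout.label_positions(bdf["chrom"], mid.to_numpy(), "domain")
    enriched = np.isin(dom, ["centromere", "h3k9me3"])
    width_scale = (bdf["end"] - bdf["start"]).to_numpy() / bin_size
    base_mean = mean_background * width_scale * np.where(enriched, enrichment, 1.0)

    log_shift: dict[str, np.ndarray] = {pedigree.root: np.zeros(len(bdf))}
    for nid in pedigree.topological_order():
        node = pedigree.nodes[nid]
        if node.parent_id is None:
            continue
        shift = log_shift[node.parent_id].copy()
        if drift_sigma > 0 and node.edge_mitoses > 0:
            shift = shift + rng.normal(0.0, drift_sigma * np.sqrt(node.edge_mitoses), size=len(bdf))
        log_shift[nid] = shift

    rows = []
    peaks: dict[str, pd.DataFrame] = {}
    for nid in pedigree.samples():
        lib = 1.0 if library_sizes is None else library_sizes[nid]
        mean = base_mean * np.exp(log_shift[nid]) * lib
        counts = rng.poisson(mean)
        rows.append(pd.DataFrame({"chrom": bdf["chrom"], "start": bdf["start"], "end": bdf["end"], "sample": nid, "count": counts}))
        peaks[nid] = _enriched_runs(bdf, enriched, rng, peak_dropout)
    return pd.concat(rows, ignore_index=True), peaks


def _enriched_runs(bdf, enriched, rng, dropout):
    runs = []
    for chrom, grp in bdf.assign(enriched=enriched).groupby("chrom", observed=True):
        grp = grp.sort_values("start")
        run_start = None
        prev_end = None
        for _, r in grp.iterrows():
            if r["enriched"]:
                if run_start is None:
                    run_start = r["start"]
                prev_end = r["end"]
            elif run_start is not None:
                runs.append((chrom, run_start, prev_end))
                run_start = None
        if run_start is not None:
            runs.append((chrom, run_start, prev_end))
    df = pd.DataFrame(runs, columns=["Chromosome", "Start", "End"])
    if dropout > 0 and not df.empty:
        df = df[rng.random(len(df)) >= dropout].reset_index(drop=True)
    return df
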