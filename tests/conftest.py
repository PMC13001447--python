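import numpy as np
import pandas as pd
import pytest

import epidrift as ed


@pytest.fixture(scope="session")
def small_sim():
    """One small forward simulation shared across tests (read-only)."""
    cfg = ed.SimulationConfig(n_chromosomes=1, chrom_length=80_000, seed=11)
    return ed.simulate_pedigree(
        cfg, pedigree_table=ed.wgbs_design(n_lines=4, n_ancestor_replicates=2), seed=11
    )


@pytest.fixture()
def toy_pedigree():
    """Root -> two lines, one sampled at transfers 5 and 20, one at 40."""
    ped = ed.Pedigree()
    ped.add_node("root", line_id="ancestor", transfer=0)
    ped.add_node("anc_r1", line_id="ancestor", transfer=0, parent_id="root", edge_mitoses=0)
    ped.add_node("A5", line_id="A", transfer=5, parent_id="root")
    ped.add_node("A20", line_id="A", transfer=20, parent_id="A5")
    ped.add_node("B40", line_id="B", transfer=40, parent_id="root")
    return ped.validate()


@pytest.fixture()
def two_domain_layout():
    L = 10_000
    domains = pd.DataFrame(
        {
            "Chromosome": ["chr1", "chr1"],
            "Start": [0, 1000],
            "End": [1000, L],
            "domain": ["centromere", "euchromatin"],
        }
    )
    annotations = pd.DataFrame(
        {
            "Chromosome": ["chr1", "chr1"],
            "Start": [0, 1000],
            "End": [1000, L],
            "annotation": ["TE", "intergenic"],
        }
    )
    return ed.GenomeLayout({"chr1": L}, domains=domains, annotations=annotations)


def make_sample(sample_id, pos, meth, total, context="CG", chrom="chr1", state=None, **kw):
    n = len(pos)
    sites = pd.DataFrame(
        {"chrom": chrom, "pos": np.asarray(pos), "strand": "+", "context": context}
    )
    return ed.MethylomeSample(sample_id, sites, np.asarray(meth), np.asarray(total), state=state, **kw)
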