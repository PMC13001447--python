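"""Readers and writers for the external text formats.

Formats handled here: Bismark-style cytosine reports (per-cytosine counts),
pedigree tables, per-sample bin-count tables and YAML run configuration.
Interval formats (BED/GFF) live in :mod:`epidrift.intervals`.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import yaml

from .pedigree import DEFAULT_MITOSES_PER_TRANSFER, Pedigree

CONTEXTS = ("CG", "CHG", "CHH")

# per-site state codes shared across the package
STATE_MISSING = -1
STATE_UNMETHYLATED = 0
STATE_METHYLATED = 1


@dataclass
class MethylomeSample:
    """Per-cytosine counts (and, once called, binary states) for one culture.

    Arrays align row-for-row with a shared site table (``sites``: columns
    chrom, pos, strand, context and optionally domain).  ``state`` uses
    1/0/-1 for methylated/unmethylated/missing; it is all-missing until a
    caller runs, and stays missing wherever ``total == 0``.
    """

    sample_id: str
    sites: pd.DataFrame
    meth: np.ndarray
    total: np.ndarray
    line_id: str = ""
    transfer: int = 0
    replicate: int = 1
    state: np.ndarray = None

    def __post_init__(self):
        self.meth = np.asarray(self.meth, dtype=np.int64)
        self.total = np.asarray(self.total, dtype=np.int64)
        if len(self.meth) != len(self.sites) or len(self.total) != len(self.sites):
            raise ValueError("count arrays must align with the site table")
        if np.any(self.meth < 0) or np.any(self.total < 0):
            raise ValueError("negative counts")
        if np.any(self.meth > self.total):
            raise ValueError("meth_count exceeds total_count")
        if self.state is None:
            self.state = np.full(len(self.sites), STATE_MISSING, dtype=np.int8)
        else:
            self.state = np.asarray(self.state, dtype=np.int8)

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    def level(self) -> np.ndarray:
        """Per-site methylation level meth/total (nan at zero depth)."""
        with np.errstate(divide="ignore", invalid="ignore"):
            return np.where(self.total > 0, self.meth / np.maximum(self.total, 1), np.nan)


def read_cx_report(path, sample_id=None, **sample_kwargs) -> MethylomeSample:
    """Read a Bismark-style cytosine report.

    Tab-separated columns: chrom, 1-based position, strand, methylated read
    count, unmethylated read count, context (CG/CHG/CHH).  Extra columns
    (e.g. the trinucleotide) are ignored.  Malformed rows and unknown
    context tokens raise with the offending line number.
    """
    chroms, poss, strands, meths, totals, ctxs = [], [], [], [], [], []
    with open(path) as fh:
        for ln, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 6:
                raise ValueError(f"{path}: line {ln}: expected >= 6 tab-separated fields")
            try:
                pos = int(parts[1])
                meth = int(parts[3])
                unmeth = int(parts[4])
            except ValueError as e:
                raise ValueError(f"{path}: line {ln}: malformed numeric field") from e
            if pos < 1:
                raise ValueError(f"{path}: line {ln}: position must be >= 1")
            if parts[2] not in ("+", "-"):
                raise ValueError(f"{path}: line {ln}: bad strand {parts[2]!r}")
            if parts[5] not in CONTEXTS:
                raise ValueError(f"{path}: line {ln}: unknown context {parts[5]!r}")
            chroms.append(parts[0])
            poss.append(pos)
            strands.append(parts[2])
            meths.append(meth)
            totals.append(meth + unmeth)
            ctxs.append(parts[5])
    sites = pd.DataFrame(
        {"chrom": chroms, "pos": np.array(poss, dtype=np.int64), "strand": strands, "context": ctxs}
    )
    if sample_id is None:
        sample_id = str(path)
    return MethylomeSample(sample_id, sites, np.array(meths), np.array(totals), **sample_kwargs)


def write_cx_report(sample: MethylomeSample, path) -> None:
    df = pd.DataFrame(
        {
            "chrom": sample.sites["chrom"],
            "pos": sample.sites["pos"],
            "strand": sample.sites["strand"],
            "meth": sample.meth,
            "unmeth": sample.total - sample.meth,
            "context": sample.sites["context"],
        }
    )
    df.to_csv(path, sep="\t", header=False, index=False)


def read_pedigree(path, mitoses_per_transfer=DEFAULT_MITOSES_PER_TRANSFER) -> Pedigree:
    """Read a pedigree TSV: sample_id, line_id, transfer, parent_id[, edge_mitoses].

    A header row is required.  Empty parent_id marks the root.  Missing
    edge_mitoses default to transfer-difference x mitoses_per_transfer.
    """
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "line_id": str, "parent_id": str})
    required = {"sample_id", "line_id", "transfer", "parent_id"}
    if not required.issubset(df.columns):
        raise ValueError(f"pedigree file must have columns {sorted(required)}")
    return Pedigree.from_dataframe(df, mitoses_per_transfer=mitoses_per_transfer)


def write_pedigree(pedigree: Pedigree, path) -> None:
    pedigree.to_dataframe().to_csv(path, sep="\t", index=False)


def read_bin_counts(path) -> pd.DataFrame:
    """Read a bin-count TSV (chrom, start, end, sample, count) with header."""
    df = pd.read_csv(path, sep="\t")
    required = {"chrom", "start", "end", "sample", "count"}
    if not required.issubset(df.columns):
        raise ValueError(f"bin-count file must have columns {sorted(required)}")
    return df


def write_bin_counts(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False)


def load_config(path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    return cfg or {}


def save_config(cfg: dict, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=True)


def merge_symmetric_cg(sample: MethylomeSample) -> MethylomeSample:
    """Collapse complementary CG sites into one strand-merged site (optional).

    A plus-strand CG at position p pairs with the minus-strand CG at p+1;
    their read counts are summed onto a single merged site reported on the
    plus strand.  Off by default throughout the package: the
    methyltransferase modelled here is not symmetric-context-bound, so each
    strand's cytosine is ordinarily treated as its own unit.  Non-CG sites
    and unpaired CG sites pass through unchanged.
    """
    sites = sample.sites.reset_index(drop=True)
    is_cg = (sites["context"] == "CG").to_numpy()
    plus = is_cg & (sites["strand"] == "+").to_numpy()
    minus = is_cg & (sites["strand"] == "-").to_numpy()
    key = pd.MultiIndex.from_arrays([sites["chrom"], sites["pos"]])
    minus_lookup = {k: i for i, k in enumerate(key[minus])}
    minus_idx = np.flatnonzero(minus)
    drop = np.zeros(len(sites), dtype=bool)
    meth = sample.meth.copy()
    total = sample.total.copy()
    for i in np.flatnonzero(plus):
        partner = minus_lookup.get((sites.at[i, "chrom"], sites.at[i, "pos"] + 1))
        if partner is not None:
            j = minus_idx[partner]
            meth[i] += meth[j]
            total[i] += total[j]
            drop[j] = True
    keep = ~drop
    return MethylomeSample(
        sample.sample_id,
        sites[keep].reset_index(drop=True),
        meth[keep],
        total[keep],
        line_id=sample.line_id,
        transfer=sample.transfer,
        replicate=sample.replicate,
    )


def states_to_frame(samples: list[MethylomeSample]) -> pd.DataFrame:
    """Wide per-site state table: site columns plus one int8 column per sample."""
    out = samples[0].sites[["chrom", "pos", "strand", "context"]].copy()
    for s in samples:
        out[s.sample_id] = s.state
    return out
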