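"""Genomic intervals, chromatin domains and annotations.

All internal coordinates are 0-based half-open; BED input is taken as-is
and GFF (1-based closed) is converted at the boundary.  Interval frames use
the pyranges column convention (``Chromosome``, ``Start``, ``End``) plus a
free-form label column, so they can be handed to :mod:`pyranges` for
overlap, merge and nearest-neighbour queries.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import pyranges as pr

DOMAIN_LABELS = ("centromere", "h3k9me3", "h3k27me3", "euchromatin")
ANNOTATION_LABELS = ("gene", "promoter", "TE", "intergenic")


def _check_frame(df: pd.DataFrame, layout=None, kind="intervals") -> pd.DataFrame:
    df = df.copy()
    bad = df["Start"] >= df["End"]
    if bad.any():
        row = df[bad].iloc[0]
        raise ValueError(f"{kind}: start >= end at {row['Chromosome']}:{row['Start']}-{row['End']}")
    if (df["Start"] < 0).any():
        raise ValueError(f"{kind}: negative coordinate")
    if layout is not None:
        for chrom, grp in df.groupby("Chromosome", observed=True):
            if chrom not in layout.chrom_lengths:
                raise ValueError(f"{kind}: unknown chromosome {chrom!r}")
            if (grp["End"] > layout.chrom_lengths[chrom]).any():
                raise ValueError(f"{kind}: interval beyond end of {chrom}")
    return df


def _check_partition(df: pd.DataFrame, chrom_lengths: dict, kind: str) -> None:
    """Intervals must tile each chromosome exactly, without gaps or overlap."""
    for chrom, length in chrom_lengths.items():
        grp = df[df["Chromosome"] == chrom].sort_values("Start")
        if grp.empty:
            raise ValueError(f"{kind}: chromosome {chrom} not covered")
        starts = grp["Start"].to_numpy()
        ends = grp["End"].to_numpy()
        if starts[0] != 0 or ends[-1] != length or np.any(starts[1:] != ends[:-1]):
            raise ValueError(f"{kind}: intervals do not tile chromosome {chrom}")


@dataclass
class GenomeLayout:
    """Chromosome lengths plus the domain and annotation partitions.

    ``domains`` and ``annotations`` are interval frames with a ``domain``
    (resp. ``annotation``) label column; each must tile every chromosome —
    every base belongs to exactly one chromatin domain and one annotation
    class (``intergenic`` is the remainder class).
    """

    chrom_lengths: dict[str, int]
    domains: pd.DataFrame = None
    annotations: pd.DataFrame = None

    def __post_init__(self):
        if self.domains is not None:
            self.domains = _check_frame(self.domains, kind="domains")
            _check_partition(self.domains, self.chrom_lengths, "domains")
        if self.annotations is not None:
            self.annotations = _check_frame(self.annotations, kind="annotations")
            _check_partition(self.annotations, self.chrom_lengths, "annotations")

    @property
    def genome_length(self) -> int:
        return int(sum(self.chrom_lengths.values()))

    def label_positions(self, chroms, pos0, column="domain") -> np.ndarray:
        """Domain/annotation label for each 0-based position."""
        source = self.domains if column == "domain" else self.annotations
        if source is None:
            raise ValueError(f"layout has no {column} intervals")
        out = np.empty(len(pos0), dtype=object)
        pos0 = np.asarray(pos0)
        chroms = np.asarray(chroms, dtype=object)
        for chrom, grp in source.groupby("Chromosome", observed=True):
            mask = chroms == chrom
            if not mask.any():
                continue
            grp = grp.sort_values("Start")
            idx = np.searchsorted(grp["End"].to_numpy(), pos0[mask], side="right")
            idx = np.clip(idx, 0, len(grp) - 1)
            out[mask] = grp[column].to_numpy()[idx]
        if any(v is None for v in out):
            raise ValueError("positions on chromosomes absent from the layout")
        return out


def read_bed(path, layout: GenomeLayout | None = None, kind="intervals") -> pd.DataFrame:
    """Read a BED file (0-based half-open) into an interval frame.

    Column 4, when present, becomes the label column named after ``kind``
    for kinds ``domains``/``annotations``, else ``Name``.  Domain frames are
    additionally checked for overlap (domains must partition the genome).
    """
    rows = []
    with open(path) as fh:
        for ln, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"{path}: line {ln}: BED needs >= 3 columns")
            try:
                rows.append((parts[0], int(parts[1]), int(parts[2]), parts[3] if len(parts) > 3 else "."))
            except ValueError as e:
                raise ValueError(f"{path}: line {ln}: malformed BED row") from e
    label = {"domains": "domain", "annotations": "annotation"}.get(kind, "Name")
    df = pd.DataFrame(rows, columns=["Chromosome", "Start", "End", label])
    df = _check_frame(df, layout=layout, kind=kind)
    if kind == "domains":
        for chrom, grp in df.groupby("Chromosome", observed=True):
            grp = grp.sort_values("Start")
            if np.any(grp["Start"].to_numpy()[1:] < grp["End"].to_numpy()[:-1]):
                raise ValueError(f"domains overlap on {chrom}")
    return df


def write_bed(df: pd.DataFrame, path) -> None:
    cols = [c for c in df.columns if c not in ("Chromosome", "Start", "End")]
    out = df[["Chromosome", "Start", "End"] + cols[:1]]
    out.to_csv(path, sep="\t", header=False, index=False)


def read_gff(path, layout: GenomeLayout | None = None, feature_types=None) -> pd.DataFrame:
    """Read GFF3 features into a 0-based half-open interval frame.

    GFF coordinates are 1-based closed: a feature spanning bases 1..100
    becomes [0, 100).  The feature type (column 3) is kept as ``Name``;
    ``feature_types`` optionally filters.
    """
    rows = []
    with open(path) as fh:
        for ln, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 8:
                raise ValueError(f"{path}: line {ln}: malformed GFF row")
            ftype = parts[2]
            if feature_types is not None and ftype not in feature_types:
                continue
            try:
                start1, end1 = int(parts[3]), int(parts[4])
            except ValueError as e:
                raise ValueError(f"{path}: line {ln}: non-integer GFF coordinates") from e
            rows.append((parts[0], start1 - 1, end1, ftype))
    df = pd.DataFrame(rows, columns=["Chromosome", "Start", "End", "Name"])
    return _check_frame(df, layout=layout, kind="gff")


def to_pyranges(df: pd.DataFrame) -> pr.PyRanges:
    return pr.PyRanges(df[["Chromosome", "Start", "End"]].reset_index(drop=True))


def merge_intervals(df: pd.DataFrame) -> pd.DataFrame:
    """Union-merge overlapping intervals."""
    if df.empty:
        return df[["Chromosome", "Start", "End"]].copy()
    return to_pyranges(df).merge().df[["Chromosome", "Start", "End"]].reset_index(drop=True)


def overlaps_any(query: pd.DataFrame, targets: pd.DataFrame) -> np.ndarray:
    """Boolean: does each query interval overlap (>= 1 bp) any target?"""
    if query.empty:
        return np.zeros(0, dtype=bool)
    if targets.empty:
        return np.zeros(len(query), dtype=bool)
    q = query[["Chromosome", "Start", "End"]].reset_index(drop=True)
    q["_qidx"] = np.arange(len(q))
    hits = pr.PyRanges(q).overlap(to_pyranges(targets)).df
    out = np.zeros(len(query), dtype=bool)
    if not hits.empty:
        out[hits["_qidx"].to_numpy()] = True
    return out


def nearest_distance(query: pd.DataFrame, targets: pd.DataFrame) -> np.ndarray:
    """Edge-to-edge distance from each query interval to its nearest target.

    0 when overlapping; np.inf for query chromosomes with no target.
    """
    q = query[["Chromosome", "Start", "End"]].reset_index(drop=True)
    q["_qidx"] = np.arange(len(q))
    out = np.full(len(q), np.inf)
    if targets.empty or q.empty:
        return out
    near = pr.PyRanges(q).nearest(to_pyranges(targets), overlap=True).df
    if near.empty:
        return out
    out[near["_qidx"].to_numpy()] = near["Distance"].to_numpy().astype(float)
    # pyranges reports distance 1 for bookended/adjacent and >=1 generally as
    # (gap + 1) in some versions; normalise to pure gap length
    starts = near["Start"].to_numpy()
    ends = near["End"].to_numpy()
    t_starts = near["Start_b"].to_numpy()
    t_ends = near["End_b"].to_numpy()
    gap = np.maximum(t_starts - ends, starts - t_ends)
    out[near["_qidx"].to_numpy()] = np.maximum(gap, 0).astype(float)
    return out


def midpoint_labels(query: pd.DataFrame, partition: pd.DataFrame, column: str) -> np.ndarray:
    """Assign each query interval to the partition stratum containing its midpoint."""
    mids = ((query["Start"].to_numpy() + query["End"].to_numpy()) // 2).astype(np.int64)
    out = np.empty(len(query), dtype=object)
    chroms = query["Chromosome"].to_numpy().astype(object)
    for chrom, grp in partition.groupby("Chromosome", observed=True):
        mask = chroms == chrom
        if not mask.any():
            continue
        grp = grp.sort_values("Start")
        idx = np.searchsorted(grp["End"].to_numpy(), mids[mask], side="right")
        idx = np.clip(idx, 0, len(grp) - 1)
        out[mask] = grp[column].to_numpy()[idx]
    if any(v is None for v in out):
        raise ValueError("query intervals on chromosomes absent from the partition")
    return out


def partition_cell_lengths(domains: pd.DataFrame, annotations: pd.DataFrame) -> pd.DataFrame:
    """Base-pair length of every domain x annotation intersection cell."""
    d = domains.rename(columns={"domain": "domain"})[["Chromosome", "Start", "End", "domain"]]
    a = annotations[["Chromosome", "Start", "End", "annotation"]]
    joined = pr.PyRanges(d.reset_index(drop=True)).join(pr.PyRanges(a.reset_index(drop=True))).df
    if joined.empty:
        return pd.DataFrame(columns=["domain", "annotation", "length"])
    lo = np.maximum(joined["Start"], joined["Start_b"])
    hi = np.minimum(joined["End"], joined["End_b"])
    joined = joined.assign(length=(hi - lo).clip(lower=0))
    out = joined.groupby(["domain", "annotation"], observed=True)["length"].sum().reset_index()
    return out[out["length"] > 0].reset_index(drop=True)
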