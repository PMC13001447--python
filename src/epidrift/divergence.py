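"""Pairwise divergence statistics over the MA pedigree.

Two divergence measures are used throughout.  For binary units (single
cytosines, DMR bins, peak presence/absence) the divergence between samples
i and j is the fraction of units scored in both samples whose states
differ — a normalised Hamming distance in [0, 1].  For binned read counts
it is the mean absolute difference of normalised counts — an L1 mean,
symmetric and triangle-inequality-respecting.

Divergence points pair each value with the mitotic separation of the two
samples, delta_t = t_i + t_j through the most recent common ancestor, as
read off the pedigree; ancestor-replicate pairs sit at delta_t = 0 and
measure the technical baseline.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats

from .intervals import merge_intervals, midpoint_labels, overlaps_any
from .io import STATE_MISSING
from .pedigree import Pedigree


def state_divergence(states_i, states_j) -> tuple[float, int]:
    """Normalised Hamming distance over units observed in both samples.

    Returns ``(d, n)``; units missing (-1) in either sample are excluded
    and ``n`` reduced accordingly.  ``d`` is nan (with a warning) when no
    unit is scored in both.
    """
    a = np.asarray(states_i)
    b = np.asarray(states_j)
    if a.shape != b.shape:
        raise ValueError("state vectors must have equal length")
    mask = (a != STATE_MISSING) & (b != STATE_MISSING)
    n = int(mask.sum())
    if n == 0:
        warnings.warn("no units observed in both samples; divergence undefined", RuntimeWarning, stacklevel=2)
        return float("nan"), 0
    return float(np.mean(a[mask] != b[mask])), n


def count_divergence(x_i, x_j) -> float:
    """Mean absolute difference of two normalised count vectors."""
    x = np.asarray(x_i, dtype=float)
    y = np.asarray(x_j, dtype=float)
    if x.shape != y.shape:
        raise ValueError("count vectors must have equal length")
    return float(np.mean(np.abs(x - y)))


def pairwise_state_divergence(states: np.ndarray, sample_ids) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Full matrices of Eq.-style state divergence and unit counts.

    ``states``: (n_samples, n_units) int8.  Returns (d matrix, n matrix) as
    DataFrames indexed by sample id.
    """
    S = np.asarray(states)
    n = len(sample_ids)
    D = np.zeros((n, n))
    N = np.zeros((n, n), dtype=int)
    obs = S != STATE_MISSING
    for i in range(n):
        for j in range(i + 1, n):
            m = obs[i] & obs[j]
            nn = int(m.sum())
            N[i, j] = N[j, i] = nn
            if nn:
                d = float(np.mean(S[i, m] != S[j, m]))
            else:
                d = np.nan
            D[i, j] = D[j, i] = d
    return (
        pd.DataFrame(D, index=sample_ids, columns=sample_ids),
        pd.DataFrame(N, index=sample_ids, columns=sample_ids),
    )


def assemble_divergence(
    states: np.ndarray,
    sample_ids: list[str],
    pedigree: Pedigree,
    context: str = "all",
    site_class: str = "single_site",
    domain: str | None = None,
    unit_domains: np.ndarray | None = None,
    pairs: str = "all",
    include_replicate_pairs: bool = True,
    drop_samples: list[str] | None = None,
) -> pd.DataFrame:
    """Divergence-versus-mitoses points for every within-pedigree pair.

    ``states`` is the (n_samples, n_units) matrix; ``unit_domains`` with
    ``domain`` restricts to units of one chromatin domain.  ``pairs="all"``
    forms every unordered sample pair; ``pairs="ancestor"`` only pairs each
    sample with ancestor-line samples (the replicate-versus-descendant set,
    whose points are statistically independent across descendants).
    ``include_replicate_pairs=False`` drops pairs at delta_t = 0.
    """
    S = np.asarray(states)
    if S.shape[0] != len(sample_ids):
        raise ValueError("states rows must match sample_ids")
    for sid in sample_ids:
        if sid not in pedigree.nodes:
            raise ValueError(f"sample {sid!r} absent from the pedigree")
    if domain is not None:
        if unit_domains is None:
            raise ValueError("domain filter requires unit_domains")
        S = S[:, np.asarray(unit_domains) == domain]
    drop = set(drop_samples or ())
    keep_idx = [k for k, sid in enumerate(sample_ids) if sid not in drop]

    rows = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        for a_pos, ii in enumerate(keep_idx):
            for jj in keep_idx[a_pos + 1 :]:
                si, sj = sample_ids[ii], sample_ids[jj]
                line_i = pedigree.nodes[si].line_id
                line_j = pedigree.nodes[sj].line_id
                if pairs == "ancestor" and "ancestor" not in (line_i, line_j):
                    continue
                t_i, t_j = pedigree.divergence_time(si, sj)
                if not include_replicate_pairs and t_i + t_j == 0:
                    continue
                d, n = state_divergence(S[ii], S[jj])
                rows.append(
                    {
                        "sample_i": si,
                        "sample_j": sj,
                        "line_i": line_i,
                        "line_j": line_j,
                        "t_i": t_i,
                        "t_j": t_j,
                        "delta_t": t_i + t_j,
                        "d": d,
                        "n": n,
                        "context": context,
                        "site_class": site_class,
                        "domain": domain or "all",
                    }
                )
    return pd.DataFrame(rows)


def assemble_count_divergence(
    counts: pd.DataFrame,
    pedigree: Pedigree,
    normalize: str = "cpm",
    site_class: str = "count_bin",
) -> pd.DataFrame:
    """Pairwise mean-|difference| divergence from a long bin-count table.

    ``counts``: columns chrom, start, end, sample, count.  Counts are
    normalised per sample (counts-per-million by default; bins are
    equal-width so a per-million scale is equivalent to RPKM up to a
    constant) before the L1 mean.
    """
    wide = counts.pivot_table(index=["chrom", "start", "end"], columns="sample", values="count")
    if wide.isna().any().any():
        raise ValueError("bin-count table is not complete over bins x samples")
    X = wide.to_numpy(dtype=float)
    if normalize == "cpm":
        X = X / X.sum(axis=0, keepdims=True) * 1e6
    elif normalize is not None and normalize != "none":
        raise ValueError(f"unknown normalization {normalize!r}")
    ids = list(wide.columns)
    rows = []
    for i in range(len(ids)):
        for j in range(i + 1, len(ids)):
            t_i, t_j = pedigree.divergence_time(ids[i], ids[j])
            rows.append(
                {
                    "sample_i": ids[i],
                    "sample_j": ids[j],
                    "line_i": pedigree.nodes[ids[i]].line_id,
                    "line_j": pedigree.nodes[ids[j]].line_id,
                    "t_i": t_i,
                    "t_j": t_j,
                    "delta_t": t_i + t_j,
                    "d": count_divergence(X[:, i], X[:, j]),
                    "n": X.shape[0],
                    "context": "all",
                    "site_class": site_class,
                    "domain": "all",
                }
            )
    return pd.DataFrame(rows)


def interval_change_counts(
    states: np.ndarray,
    sample_ids: list[str],
    pedigree: Pedigree,
    unit_domains: np.ndarray | None = None,
) -> pd.DataFrame:
    """State changes between consecutive sampled transfers of each line.

    A change is a unit observed at both consecutive time points whose state
    differs; reversions in later intervals count again (each interval is
    scored on its own).  Counts are split by unit domain when provided,
    plus a whole-genome row per interval.
    """
    idx_of = {sid: k for k, sid in enumerate(sample_ids)}
    by_line: dict[str, list] = {}
    for sid in sample_ids:
        node = pedigree.nodes[sid]
        if node.line_id == "ancestor":
            continue
        by_line.setdefault(node.line_id, []).append((node.transfer, sid))
    S = np.asarray(states)
    doms = np.asarray(unit_domains) if unit_domains is not None else None
    rows = []
    for line, entries in sorted(by_line.items()):
        entries.sort()
        if len(entries) < 2:
            continue
        for (t0, s0), (t1, s1) in zip(entries[:-1], entries[1:]):
            a, b = S[idx_of[s0]], S[idx_of[s1]]
            obs = (a != STATE_MISSING) & (b != STATE_MISSING)
            changed = obs & (a != b)
            rows.append(
                {"line_id": line, "interval_start": t0, "interval_end": t1, "domain": "all", "n_changes": int(changed.sum()), "n_observed": int(obs.sum())}
            )
            if doms is not None:
                for d in np.unique(doms):
                    sel = doms == d
                    rows.append(
                        {
                            "line_id": line,
                            "interval_start": t0,
                            "interval_end": t1,
                            "domain": d,
                            "n_changes": int(changed[sel].sum()),
                            "n_observed": int(obs[sel].sum()),
                        }
                    )
    return pd.DataFrame(rows)


def mutation_association_test(
    changes: np.ndarray,
    mutation_counts: np.ndarray,
    n_perm: int = 10_000,
    seed: int = 0,
) -> dict:
    """Are state changes elevated in intervals that carry genetic mutations?

    Permutation test (one-sided) of the difference in mean change counts
    between mutation-bearing and mutation-free intervals, with a
    Mann-Whitney rank-sum alternative reported alongside.
    """
    changes = np.asarray(changes, dtype=float)
    muts = np.asarray(mutation_counts)
    if len(changes) != len(muts):
        raise ValueError("changes and mutation_counts must align")
    if len(changes) < 5:
        raise ValueError("need at least 5 intervals")
    has_mut = muts > 0
    if has_mut.all() or (~has_mut).all():
        warnings.warn("all intervals in one mutation group; test undefined", RuntimeWarning, stacklevel=2)
        return {"statistic": np.nan, "p_value": np.nan, "p_ranksum": np.nan, "n_with": int(has_mut.sum()), "n_without": int((~has_mut).sum())}
    obs = changes[has_mut].mean() - changes[~has_mut].mean()
    rng = np.random.default_rng(seed)
    k = int(has_mut.sum())
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(len(changes))
        grp = changes[perm[:k]].mean() - changes[perm[k:]].mean()
        if grp >= obs:
            count += 1
    p = count / n_perm
    if np.ptp(changes) == 0:
        p_rank = 1.0
    else:
        p_rank = float(stats.mannwhitneyu(changes[has_mut], changes[~has_mut], alternative="greater").pvalue)
    return {
        "statistic": float(obs),
        "p_value": float(p),
        "p_ranksum": p_rank,
        "n_with": int(has_mut.sum()),
        "n_without": int((~has_mut).sum()),
    }


def build_peak_matrix(peak_sets: dict[str, pd.DataFrame]) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Nonredundant union peaks x samples presence/absence matrix.

    Overlapping peaks across samples are union-merged into disjoint
    intervals; a sample is *present* at a union peak when any of its peaks
    overlaps it.  Returns ``(union_peaks, presence)`` where ``presence`` is
    a boolean DataFrame indexed like ``union_peaks``.
    """
    if len(peak_sets) < 2:
        raise ValueError("need peak calls for at least 2 samples")
    nonempty = [df for df in peak_sets.values() if not df.empty]
    if not nonempty:
        warnings.warn("no peaks in any sample", RuntimeWarning, stacklevel=2)
        empty = pd.DataFrame(columns=["Chromosome", "Start", "End"])
        return empty, pd.DataFrame(columns=list(peak_sets))
    union = merge_intervals(pd.concat(nonempty, ignore_index=True))
    presence = pd.DataFrame(
        {sid: overlaps_any(union, df) for sid, df in peak_sets.items()}, index=union.index
    )
    return union, presence


def peak_divergence(
    presence: pd.DataFrame,
    pedigree: Pedigree,
    variable_only: bool = True,
) -> pd.DataFrame:
    """State divergence over (variable) peak presence/absence calls."""
    P = presence.to_numpy().astype(np.int8)
    if variable_only:
        var = P.any(axis=1) & (~P.all(axis=1))
        P = P[var]
    return assemble_divergence(P.T, list(presence.columns), pedigree, site_class="peak")


def divergence_trend_test(points: pd.DataFrame, n_perm: int = 10_000, seed: int = 0) -> dict:
    """Does divergence increase with mitotic separation?

    Least-squares slope of d on delta_t; significance by permuting sample
    labels over the pedigree (rows/columns of the pair structure move
    together, so the within-pedigree correlation of pairs is respected).
    One-sided: p is the fraction of permutations with slope >= observed,
    with add-one smoothing.
    """
    pts = points.dropna(subset=["d"])
    if len(pts) < 5:
        raise ValueError("need at least 5 divergence points")
    if pts["delta_t"].nunique() < 2:
        raise ValueError("delta_t is constant; trend undefined")
    ids = sorted(set(pts["sample_i"]) | set(pts["sample_j"]))
    pos = {s: k for k, s in enumerate(ids)}
    ii = pts["sample_i"].map(pos).to_numpy()
    jj = pts["sample_j"].map(pos).to_numpy()
    d = pts["d"].to_numpy(dtype=float)
    dt = pts["delta_t"].to_numpy(dtype=float)
    n = len(ids)
    D = np.full((n, n), np.nan)
    D[ii, jj] = d
    D[jj, ii] = d

    def slope(dvals):
        return float(np.polyfit(dt, dvals, 1)[0])

    obs = slope(d)
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(n)
        dp = D[perm[ii], perm[jj]]
        ok = np.isfinite(dp)
        if ok.sum() < 5 or np.ptp(dt[ok]) == 0:
            continue
        s = float(np.polyfit(dt[ok], dp[ok], 1)[0])
        if s >= obs:
            count += 1
    p = (count + 1) / (n_perm + 1)
    return {"slope": obs, "p_value": float(p), "n_points": int(len(pts))}


def dmr_h3k9_overlap(
    dmrs: pd.DataFrame,
    regions: pd.DataFrame,
    directions: np.ndarray | None = None,
    annotations: pd.DataFrame | None = None,
) -> dict:
    """Fraction of DMRs overlapping (>= 1 bp) stable H3K9me3 regions.

    Optionally classifies the non-overlapping DMRs by methylation direction
    (``directions``: per-DMR "gain"/"loss") and by annotation class of the
    DMR midpoint.
    """
    if dmrs.empty:
        raise ValueError("empty DMR set; overlap fraction undefined")
    hit = overlaps_any(dmrs, regions)
    out = {"fraction_overlapping": float(hit.mean()), "n_dmrs": int(len(dmrs)), "n_overlapping": int(hit.sum())}
    non = dmrs[~hit].reset_index(drop=True)
    breakdown = non.copy()
    if directions is not None:
        breakdown["direction"] = np.asarray(directions, dtype=object)[~hit]
    if annotations is not None and not non.empty:
        breakdown["annotation"] = midpoint_labels(non, annotations, "annotation")
    out["non_overlapping"] = breakdown
    return out
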