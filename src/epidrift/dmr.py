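"""100-bp bin segmentation into differentially methylated regions (DMRs).

The genome is tiled with fixed 100-bp bins.  For one sample a bin is
*eligible* in a context when it holds at least ``min_cytosines`` cytosines
of that context each covered by at least ``min_depth`` reads with a called
state; the bin state is *methylated* when at least half (configurable) of
those qualifying cytosines are called methylated.  A bin is a DMR when two
or more samples are eligible and disagree on the bin state.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import STATE_MISSING, MethylomeSample


@dataclass
class DmrBinSet:
    """Tiled bins with per-sample states.

    ``bins``: frame with Chromosome/Start/End/context/n_sites and per-bin
    ``is_dmr``; ``states``: (n_samples, n_bins) int8 matrix (1/0/-1);
    ``sample_ids`` gives the row order.  ``domain`` column is present when
    the site table carries one (label of the bin midpoint's site majority).
    """

    bins: pd.DataFrame
    states: np.ndarray
    sample_ids: list[str]

    def dmrs(self) -> pd.DataFrame:
        return self.bins[self.bins["is_dmr"]].reset_index(drop=True)


def segment_dmr_bins(
    samples: list[MethylomeSample],
    context: str,
    bin_size: int = 100,
    min_cytosines: int = 5,
    min_depth: int = 5,
    meth_fraction: float = 0.5,
) -> DmrBinSet:
    """Call per-sample bin states and flag DMR bins for one context.

    All samples must share the same site table.  Returns every bin that is
    eligible in at least one sample; ``is_dmr`` marks bins where >= 2
    eligible samples disagree.
    """
    if not samples:
        raise ValueError("no samples")
    sites = samples[0].sites
    for s in samples[1:]:
        if len(s.sites) != len(sites):
            raise ValueError("samples must share one site table")
    mask = (sites["context"] == context).to_numpy()
    sub = sites[mask]
    pos0 = sub["pos"].to_numpy() - 1
    chrom = sub["chrom"].to_numpy()
    bin_start = (pos0 // bin_size) * bin_size
    key = pd.DataFrame({"Chromosome": chrom, "Start": bin_start})
    codes, uniq = pd.factorize(pd.MultiIndex.from_frame(key), sort=True)
    n_bins = len(uniq)

    n_samples = len(samples)
    states = np.full((n_samples, n_bins), STATE_MISSING, dtype=np.int8)
    n_sites_bin = np.bincount(codes, minlength=n_bins)
    for si, s in enumerate(samples):
        st = s.state[mask]
        depth_ok = (s.total[mask] >= min_depth) & (st != STATE_MISSING)
        qual = np.bincount(codes[depth_ok], minlength=n_bins)
        meth = np.bincount(codes[depth_ok & (st == 1)], minlength=n_bins)
        eligible = qual >= min_cytosines
        with np.errstate(invalid="ignore", divide="ignore"):
            frac = np.where(qual > 0, meth / np.maximum(qual, 1), 0.0)
        states[si, eligible] = (frac[eligible] >= meth_fraction).astype(np.int8)

    observed = states != STATE_MISSING
    n_eligible = observed.sum(axis=0)
    any_m = ((states == 1) & observed).any(axis=0)
    any_u = ((states == 0) & observed).any(axis=0)
    is_dmr = (n_eligible >= 2) & any_m & any_u

    keep = n_eligible >= 1
    if not keep.any():
        warnings.warn("no eligible bins in any sample", RuntimeWarning, stacklevel=2)
    bins = pd.DataFrame(
        {
            "Chromosome": [u[0] for u in uniq],
            "Start": [u[1] for u in uniq],
        }
    )
    bins["End"] = bins["Start"] + bin_size
    bins["context"] = context
    bins["n_sites"] = n_sites_bin
    bins["n_eligible"] = n_eligible
    bins["is_dmr"] = is_dmr
    if "domain" in sites.columns:
        dom_codes, dom_uniq = pd.factorize(sub["domain"].to_numpy())
        # majority domain of the bin's sites
        counts = np.zeros((n_bins, len(dom_uniq)), dtype=np.int64)
        np.add.at(counts, (codes, dom_codes), 1)
        bins["domain"] = np.asarray(dom_uniq, dtype=object)[counts.argmax(axis=1)]
    bins = bins[keep].reset_index(drop=True)
    states = states[:, keep]
    return DmrBinSet(bins, states, [s.sample_id for s in samples])


def flag_outlier_samples(divergence: pd.DataFrame | np.ndarray, sample_ids=None, k: float = 3.0) -> list[str]:
    """Flag samples whose typical pairwise divergence is extreme.

    ``divergence`` is a full symmetric matrix.  A sample is flagged when the
    median of its pairwise divergences exceeds the median of all samples'
    medians by more than ``k`` median absolute deviations (unscaled MAD).
    ``k = inf`` flags nothing.
    """
    if isinstance(divergence, pd.DataFrame):
        sample_ids = list(divergence.index)
        D = divergence.to_numpy(dtype=float)
    else:
        D = np.asarray(divergence, dtype=float)
        if sample_ids is None:
            sample_ids = list(range(len(D)))
    if D.ndim != 2 or D.shape[0] != D.shape[1]:
        raise ValueError("divergence must be a square matrix")
    n = len(D)
    if n < 4:
        raise ValueError("outlier statistic undefined for fewer than 4 samples")
    off = ~np.eye(n, dtype=bool)
    med = np.array([np.nanmedian(D[i, off[i]]) for i in range(n)])
    grand = np.nanmedian(med)
    mad = np.nanmedian(np.abs(med - grand))
    if not np.isfinite(k):
        return []
    flagged = med > grand + k * mad
    return [sid for sid, f in zip(sample_ids, flagged) if f]
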