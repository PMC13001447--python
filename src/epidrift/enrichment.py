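"""Enrichment of DMRs in chromatin domains and genome annotations.

Under proportional-to-length placement, the expected DMR count of a
stratum is N_total * length_stratum / length_total.  Each stratum's rate
ratio is observed/expected, with a Wald interval on the log scale and an
exact two-sided Poisson p-value against the expected count.  A Poisson
regression with a log-length offset (the model-based route) is fitted
alongside when it converges.  Euchromatic DMR proximity to transposable
elements is tested by permuting the query set against background features.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats

from .intervals import midpoint_labels, nearest_distance, partition_cell_lengths


def _poisson_two_sided(obs: int, mu: float) -> float:
    """Exact two-sided Poisson tail: doubled smaller tail, capped at 1."""
    lo = stats.poisson.cdf(obs, mu)
    hi = stats.poisson.sf(obs - 1, mu)
    return float(min(1.0, 2.0 * min(lo, hi)))


def _stratum_table(labels, counts, lengths) -> pd.DataFrame:
    total = counts.sum()
    total_len = lengths.sum()
    rows = []
    for lab, obs, L in zip(labels, counts, lengths):
        if L <= 0:
            raise ValueError(f"zero-length stratum {lab!r}")
        exp = total * L / total_len
        ratio = obs / exp if exp > 0 else np.nan
        if obs > 0:
            se = 1.0 / np.sqrt(obs)
            ci = (float(ratio * np.exp(-1.96 * se)), float(ratio * np.exp(1.96 * se)))
        else:
            ci = (0.0, np.nan)
        rows.append(
            {
                "stratum": lab,
                "observed": int(obs),
                "expected": float(exp),
                "length": int(L),
                "rate_ratio": float(ratio),
                "ci_low": ci[0],
                "ci_high": ci[1],
                "p_value": _poisson_two_sided(int(obs), exp),
            }
        )
    return pd.DataFrame(rows)


def _offset_glm_pvalues(table: pd.DataFrame) -> pd.DataFrame:
    """Per-stratum Wald p-values from a Poisson GLM with log-length offset.

    Each stratum's rate is compared to the pooled rate; mirrors the
    model-based route of count regression with region size as exposure.
    """
    import statsmodels.api as sm

    total_obs = table["observed"].sum()
    total_len = table["length"].sum()
    pvals = []
    for _, row in table.iterrows():
        # stratum vs rest-of-genome: Poisson GLM with log-length offset,
        # Wald p for the stratum indicator
        y = np.array([row["observed"], total_obs - row["observed"]], dtype=float)
        X = np.column_stack([np.ones(2), [1.0, 0.0]])
        off = np.log(np.array([row["length"], max(total_len - row["length"], 1)], dtype=float))
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                fit = sm.GLM(y, X, family=sm.families.Poisson(), offset=off).fit()
            pvals.append(float(fit.pvalues[1]))
        except Exception:
            pvals.append(np.nan)
    table = table.copy()
    table["p_glm"] = pvals
    return table


def domain_enrichment(dmrs: pd.DataFrame, domains: pd.DataFrame) -> pd.DataFrame:
    """DMR counts per chromatin domain against proportional-to-length expectation.

    DMRs are assigned to the domain containing their midpoint.  Returns one
    row per domain with observed, expected, rate ratio, Wald 95% CI, exact
    Poisson p-value and the offset-GLM p-value.
    """
    if dmrs.empty:
        raise ValueError("empty DMR set")
    labels = midpoint_labels(dmrs, domains, "domain")
    lengths = domains.assign(length=domains["End"] - domains["Start"]).groupby("domain", observed=True)["length"].sum()
    doms = list(lengths.index)
    counts = np.array([(labels == d).sum() for d in doms])
    table = _stratum_table(doms, counts, lengths.to_numpy())
    return _offset_glm_pvalues(table)


def domain_annotation_enrichment(
    dmrs: pd.DataFrame, domains: pd.DataFrame, annotations: pd.DataFrame
) -> pd.DataFrame:
    """Domain x annotation cells against proportional-to-length expectation.

    Expected counts are proportional to each cell's base-pair length; cells
    with zero length are skipped.  ``interaction`` is the deviation of the
    cell ratio from the product of its marginal domain and annotation
    ratios (1 = no interaction).
    """
    if dmrs.empty:
        raise ValueError("empty DMR set")
    dom_lab = midpoint_labels(dmrs, domains, "domain")
    ann_lab = midpoint_labels(dmrs, annotations, "annotation")
    cells = partition_cell_lengths(domains, annotations)
    counts = []
    for _, row in cells.iterrows():
        counts.append(int(np.sum((dom_lab == row["domain"]) & (ann_lab == row["annotation"]))))
    table = _stratum_table(
        [f"{d}:{a}" for d, a in zip(cells["domain"], cells["annotation"])],
        np.array(counts),
        cells["length"].to_numpy(),
    )
    table[["domain", "annotation"]] = table["stratum"].str.split(":", expand=True)

    # marginal ratios for the interaction summary
    total = table["observed"].sum()
    total_len = table["length"].sum()
    marg = {}
    for col in ("domain", "annotation"):
        g = table.groupby(col)[["observed", "length"]].sum()
        marg[col] = ((g["observed"] / total) / (g["length"] / total_len)).to_dict()
    inter = []
    for _, row in table.iterrows():
        prod = marg["domain"][row["domain"]] * marg["annotation"][row["annotation"]]
        inter.append(row["rate_ratio"] / prod if prod > 0 else np.nan)
    table["interaction"] = inter
    return _offset_glm_pvalues(table)


def te_proximity_test(
    query: pd.DataFrame,
    te: pd.DataFrame,
    background: pd.DataFrame,
    n_perm: int = 1000,
    seed: int = 0,
) -> dict:
    """Are query intervals closer to TEs than random background features?

    Distance is edge-to-edge base pairs to the nearest TE (0 when
    overlapping).  The null draws |query| background features without
    replacement, ``n_perm`` times; p = (1 + #{perm median <= observed
    median}) / (n_perm + 1).  A background smaller than the query is
    sampled with replacement (with a warning).
    """
    if query.empty or te.empty or background.empty:
        raise ValueError("query, TE and background sets must be nonempty")
    obs_dist = nearest_distance(query, te)
    obs_median = float(np.median(obs_dist))
    bg_dist = nearest_distance(background, te)
    replace = len(background) < len(query)
    if replace:
        warnings.warn("background smaller than query; sampling with replacement", RuntimeWarning, stacklevel=2)
    rng = np.random.default_rng(seed)
    count = 0
    null = np.empty(n_perm)
    for k in range(n_perm):
        pick = rng.choice(len(background), size=len(query), replace=replace)
        null[k] = np.median(bg_dist[pick])
        if null[k] <= obs_median:
            count += 1
    return {
        "observed_median": obs_median,
        "null_medians": null,
        "p_value": float((count + 1) / (n_perm + 1)),
        "n_query": int(len(query)),
    }
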