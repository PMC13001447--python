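"""Divergence statistics: Hamming and L1 forms, assembly, interval tests."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp

import epidrift as ed

M, U, X = 1, 0, -1  # methylated, unmethylated, missing


# ------------------------------------------------------------------ Hamming d


def test_state_divergence_examples():
    assert ed.state_divergence([M, U, M], [M, U, M]) == (0.0, 3)
    assert ed.state_divergence([M, U, M, U], [M, M, U, U]) == (0.5, 4)
    # masking: missing in either sample shrinks n
    d, n = ed.state_divergence([M, X, U], [U, M, U])
    assert (d, n) == (0.5, 2)


def test_state_divergence_all_missing_warns():
    with pytest.warns(RuntimeWarning):
        d, n = ed.state_divergence([X, X], [M, U])
    assert np.isnan(d) and n == 0


def test_state_divergence_length_mismatch():
    with pytest.raises(ValueError):
        ed.state_divergence([M], [M, U])


@given(
    a=hnp.arrays(np.int8, 30, elements=st.sampled_from([-1, 0, 1])),
    b=hnp.arrays(np.int8, 30, elements=st.sampled_from([-1, 0, 1])),
)
@settings(max_examples=100, deadline=None, derandomize=True)
def test_state_divergence_properties(a, b):
    """Symmetry, [0, 1] bounds, and zero iff identical on the joint mask."""
    mask = (a != -1) & (b != -1)
    if mask.sum() == 0:
        return
    d_ab, n = ed.state_divergence(a, b)
    d_ba, _ = ed.state_divergence(b, a)
    assert d_ab == d_ba
    assert 0.0 <= d_ab <= 1.0
    assert (d_ab == 0.0) == bool((a[mask] == b[mask]).all())


# ----------------------------------------------------------------------- L1 d


def test_count_divergence_examples():
    assert ed.count_divergence([1.0, 2.0], [1.0, 2.0]) == 0.0
    assert ed.count_divergence([1.0, 2.0], [3.0, 2.0]) == 1.0
    with pytest.raises(ValueError):
        ed.count_divergence([1.0], [1.0, 2.0])


def test_count_divergence_bruteforce_oracle():
    rng = np.random.default_rng(0)
    x, y = rng.random(57), rng.random(57)
    manual = sum(abs(a - b) for a, b in zip(x, y)) / len(x)
    assert abs(ed.count_divergence(x, y) - manual) < 1e-12


@given(
    x=hnp.arrays(np.float64, 20, elements=st.floats(0, 100)),
    y=hnp.arrays(np.float64, 20, elements=st.floats(0, 100)),
    z=hnp.arrays(np.float64, 20, elements=st.floats(0, 100)),
)
@settings(max_examples=100, deadline=None, derandomize=True)
def test_count_divergence_is_a_metric(x, y, z):
    dxy = ed.count_divergence(x, y)
    dyx = ed.count_divergence(y, x)
    assert dxy == dyx
    assert dxy >= 0
    assert ed.count_divergence(x, z) <= dxy + ed.count_divergence(y, z) + 1e-9


# ------------------------------------------------------------------- assembly


def test_assemble_divergence_delta_t(toy_pedigree):
    states = np.array(
        [[M, M, U, U], [M, U, U, U], [U, U, U, U], [M, M, M, M]], dtype=np.int8
    )
    ids = ["anc_r1", "A5", "A20", "B40"]
    pts = ed.assemble_divergence(states, ids, toy_pedigree)
    lookup = {(r["sample_i"], r["sample_j"]): r for _, r in pts.iterrows()}
    assert lookup[("A5", "A20")]["delta_t"] == 375
    assert lookup[("A20", "B40")]["delta_t"] == 1500
    assert lookup[("anc_r1", "A5")]["delta_t"] == 125
    assert lookup[("A5", "A20")]["d"] == 0.25


def test_assemble_divergence_unknown_sample(toy_pedigree):
    with pytest.raises(ValueError):
        ed.assemble_divergence(np.zeros((1, 4), dtype=np.int8), ["ghost"], toy_pedigree)


def test_assemble_ancestor_pairs_only(toy_pedigree):
    states = np.zeros((4, 4), dtype=np.int8)
    ids = ["anc_r1", "A5", "A20", "B40"]
    pts = ed.assemble_divergence(states, ids, toy_pedigree, pairs="ancestor")
    assert len(pts) == 3
    assert (pts["line_i"] == "ancestor").all()


def test_pairwise_matrix_symmetry():
    states = np.array([[M, U, M], [U, U, M], [M, M, X]], dtype=np.int8)
    D, N = ed.pairwise_state_divergence(states, ["a", "b", "c"])
    assert (D.to_numpy() == D.to_numpy().T).all()
    assert D.loc["a", "b"] == pytest.approx(1 / 3)
    assert N.loc["a", "c"] == 2


# ----------------------------------------------------------- interval changes


def test_interval_change_counts_and_reversions(toy_pedigree):
    ped = ed.Pedigree()
    ped.add_node("root", line_id="ancestor", transfer=0)
    for t, prev in [(5, "root"), (7, "L1_t5"), (8, "L1_t7")]:
        ped.add_node(f"L1_t{t}", line_id="L1", transfer=t, parent_id=prev)
    states = np.array(
        [
            [M, M],  # t5
            [U, M],  # t7: one change
            [M, M],  # t8: reversion -> counts again
        ],
        dtype=np.int8,
    )
    out = ed.interval_change_counts(states, ["L1_t5", "L1_t7", "L1_t8"], ped)
    whole = out[out["domain"] == "all"].set_index("interval_end")["n_changes"]
    assert whole.loc[7] == 1 and whole.loc[8] == 1


def test_interval_changes_identical_methylomes(toy_pedigree):
    states = np.zeros((2, 5), dtype=np.int8)
    out = ed.interval_change_counts(states, ["A5", "A20"], toy_pedigree)
    assert (out["n_changes"] == 0).all()


def test_interval_changes_single_time_point(toy_pedigree):
    out = ed.interval_change_counts(np.zeros((1, 5), dtype=np.int8), ["B40"], toy_pedigree)
    assert out.empty


# --------------------------------------------------------- mutation coupling


def test_mutation_association_perfect_coupling():
    muts = np.array([0, 0, 0, 1, 2, 3, 0, 4])
    changes = 10.0 * muts
    out = ed.mutation_association_test(changes, muts, n_perm=2000, seed=0)
    assert out["p_value"] < 0.05
    assert out["p_ranksum"] < 0.05


def test_mutation_association_zero_changes():
    muts = np.array([0, 1, 0, 2, 0, 1])
    out = ed.mutation_association_test(np.zeros(6), muts, n_perm=500, seed=0)
    assert out["statistic"] == 0.0
    assert out["p_value"] == 1.0


def test_mutation_association_null_is_moderate():
    rng = np.random.default_rng(5)
    changes = rng.poisson(20, 24).astype(float)
    muts = rng.poisson(1.0, 24)
    out = ed.mutation_association_test(changes, muts, n_perm=2000, seed=1)
    assert out["p_value"] > 0.01


def test_mutation_association_validations():
    with pytest.raises(ValueError):
        ed.mutation_association_test(np.zeros(3), np.zeros(3))
    with pytest.warns(RuntimeWarning):
        out = ed.mutation_association_test(np.ones(6), np.ones(6))
    assert np.isnan(out["p_value"])


# ----------------------------------------------------------------- peak level


def _bed(rows):
    return pd.DataFrame(rows, columns=["Chromosome", "Start", "End"])


def test_peak_matrix_merging_and_divergence(toy_pedigree):
    peaks = {
        "anc_r1": _bed([("chr1", 0, 100), ("chr1", 500, 600)]),
        "A5": _bed([("chr1", 50, 150), ("chr1", 500, 600)]),  # half-overlap merges
        "A20": _bed([("chr1", 500, 600)]),
        "B40": _bed([("chr1", 500, 600), ("chr1", 900, 950)]),
    }
    union, presence = ed.build_peak_matrix(peaks)
    assert len(union) == 3  # [0,150), [500,600), [900,950)
    pts = ed.peak_divergence(presence, toy_pedigree)
    lookup = {(r["sample_i"], r["sample_j"]): r["d"] for _, r in pts.iterrows()}
    # variable peaks: [0,150) and [900,950) -> anc vs A5 concordant
    assert lookup[("anc_r1", "A5")] == 0.0
    assert lookup[("A20", "B40")] == 0.5


def test_identical_peak_sets_zero_divergence(toy_pedigree):
    bed = _bed([("chr1", 0, 100)])
    union, presence = ed.build_peak_matrix({sid: bed.copy() for sid in ["anc_r1", "A5", "A20", "B40"]})
    pts = ed.peak_divergence(presence, toy_pedigree, variable_only=False)
    assert (pts["d"] == 0).all()


def test_private_peak_contribution():
    """A peak private to one of several samples contributes 1/n_variable to
    that sample's pairwise divergences."""
    n_var = 271
    rng = np.random.default_rng(7)
    base = np.zeros((4, n_var), dtype=np.int8)
    base[:, : n_var - 1] = rng.integers(0, 2, (1, n_var - 2 + 1))  # shared variable states
    base[0, n_var - 1] = 1  # private peak of sample 0
    d, n = ed.state_divergence(base[0], base[1])
    assert n == n_var
    assert d == pytest.approx(1 / n_var)


# ----------------------------------------------------------------- trend test


def test_trend_constant_divergence():
    rows = []
    ids = [f"s{i}" for i in range(6)]
    ped = ed.Pedigree()
    ped.add_node("root", line_id="ancestor", transfer=0)
    for k, sid in enumerate(ids):
        ped.add_node(sid, line_id=f"L{k}", transfer=5 * (k + 1), parent_id="root")
    states = np.zeros((6, 10), dtype=np.int8)
    pts = ed.assemble_divergence(states, ids, ped)
    out = ed.divergence_trend_test(pts, n_perm=500, seed=0)
    assert out["slope"] == 0.0
    assert out["p_value"] > 0.9


def test_trend_errors():
    pts = pd.DataFrame(
        {
            "sample_i": ["a"] * 5,
            "sample_j": list("bcdef"),
            "delta_t": [100] * 5,
            "d": [0.1, 0.2, 0.1, 0.3, 0.2],
        }
    )
    with pytest.raises(ValueError):
        ed.divergence_trend_test(pts)


# ---------------------------------------------------------------- H3K9 overlap


def test_dmr_h3k9_overlap_fractions():
    dmrs = _bed([("chr1", i * 200, i * 200 + 100) for i in range(10)])
    regions = _bed([("chr1", 0, 1000)])  # first 5 DMRs inside
    out = ed.dmr_h3k9_overlap(dmrs, regions)
    assert out["fraction_overlapping"] == 0.5
    assert ed.dmr_h3k9_overlap(dmrs, _bed([("chr1", 0, 5000)]))["fraction_overlapping"] == 1.0
    assert ed.dmr_h3k9_overlap(dmrs, _bed([("chr2", 0, 5000)]))["fraction_overlapping"] == 0.0
    with pytest.raises(ValueError):
        ed.dmr_h3k9_overlap(_bed([]), regions)
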