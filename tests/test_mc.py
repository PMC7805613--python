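"""Discretization, joint estimation and the MC_W estimator."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from neuromc.mc import (
    BinningPolicy,
    bin_channels,
    build_level_split,
    compute_mc,
    discretize,
    estimate_joint,
    estimate_joint_from_triples,
    mc_by_level,
    mc_w,
    mc_w_state_dependent,
    symbolize,
)
from neuromc.trace import LEVELS


def brute_force_cmi(dense: np.ndarray) -> float:
    """Independent triple-loop conditional mutual information I(W'; W | A)."""
    pa = dense.sum(axis=(0, 1))
    pwpa = dense.sum(axis=1)
    pwa = dense.sum(axis=0)
    out = 0.0
    nw, _, na = dense.shape
    for wp in range(nw):
        for w in range(nw):
            for a in range(na):
                p = dense[wp, w, a]
                if p > 0:
                    out += p * np.log2(p * pa[a] / (pwpa[wp, a] * pwa[w, a]))
    return out


# -------------------------------------------------------------- discretization

def test_constant_channel_collapses_to_single_symbol():
    x = np.column_stack([np.full(50, 3.7), np.linspace(0, 1, 50)])
    idx, edges = bin_channels(x, 4)
    assert np.all(idx[:, 0] == 0)
    sym, n = symbolize(idx)
    assert n == 4


def test_binary_channel_reproduces_sequence():
    seq = np.array([0, 1, 1, 0, 1, 0, 0, 1], dtype=float)
    idx, _ = bin_channels(seq[:, None], 2)
    sym, n = symbolize(idx)
    assert n == 2
    assert np.array_equal(sym, seq.astype(int))


def test_combined_alphabet_bound_and_equality():
    """3-sample crafted input: |alphabet| <= b1*b2, equality iff all combos occur."""
    x_partial = np.array([[0.0, 0.0], [1.0, 1.0], [0.0, 1.0]])
    idx, _ = bin_channels(x_partial, 2)
    _, n = symbolize(idx)
    assert n == 3 <= 4
    x_full = np.array([[0.0, 0.0], [0.0, 1.0], [1.0, 0.0], [1.0, 1.0]])
    _, n_full = symbolize(bin_channels(x_full, 2)[0])
    assert n_full == 4


def test_bin_edges_left_closed_right_open_max_in_last():
    x = np.linspace(0, 1, 11)[:, None]
    idx, _ = bin_channels(x, 5)
    assert idx[0, 0] == 0 and idx[-1, 0] == 4
    assert idx[:, 0].max() == 4


def test_discretize_rejects_bad_input():
    with pytest.raises(ValueError):
        bin_channels(np.empty((0, 2)), 4)
    with pytest.raises(ValueError):
        bin_channels(np.array([[np.nan]]), 4)
    with pytest.raises(ValueError):
        bin_channels(np.ones((5, 1)), 1)


# ------------------------------------------------------------- joint estimation

def test_joint_from_constant_sequences():
    s = discretize(np.zeros((3, 1)), np.zeros((3, 1)), 2, 2)
    j = estimate_joint(s)
    dense = j.to_dense()
    assert dense[0, 0, 0] == 1.0 and dense.sum() == 1.0


def test_joint_manual_count_on_toy_sequence():
    """Hand-counted transitions of w=(0,1,0,1,0), a=(0,0,1,1,0): N = T-1 = 4."""
    w = np.array([0, 1, 0, 1, 0])
    a = np.array([0, 0, 1, 1, 0])
    j = estimate_joint_from_triples(w[1:], w[:-1], a[:-1])
    dense = j.to_dense()
    # triples: (1,0,0), (0,1,0), (1,0,1), (0,1,1) -- each once
    assert dense[1, 0, 0] == pytest.approx(0.25)
    assert dense[0, 1, 0] == pytest.approx(0.25)
    assert dense[1, 0, 1] == pytest.approx(0.25)
    assert dense[0, 1, 1] == pytest.approx(0.25)
    assert dense.sum() == pytest.approx(1.0)
    assert j.n == 4


def test_marginal_consistency():
    rng = np.random.default_rng(0)
    w = rng.integers(0, 3, 500)
    a = rng.integers(0, 2, 500)
    j = estimate_joint_from_triples(w[1:], w[:-1], a[:-1])
    dense = j.to_dense()
    # p(w', a) by marginalizing over w equals a direct pair count
    direct = np.zeros((3, 2))
    for wp, aa in zip(w[1:], a[:-1]):
        direct[wp, aa] += 1
    assert np.allclose(dense.sum(axis=1), direct / j.n)
    assert dense.sum() == pytest.approx(1.0, abs=1e-12)


# ----------------------------------------------------------------------- MC_W

def test_mc_zero_when_world_is_ignorable():
    """p(w'|w,a) = p(w'|a): the log-ratio vanishes identically."""
    rng = np.random.default_rng(1)
    a = rng.integers(0, 3, 4000)
    w = rng.integers(0, 4, 4001)     # w' fresh i.i.d., independent of w given a
    j = estimate_joint_from_triples(w[1:] * 0, w[:-1] * 0 + rng.integers(0, 2, 4000), a)
    assert mc_w(j) == 0.0


@given(st.integers(0, 2 ** 31 - 1))
def test_mc_matches_bruteforce_cmi_and_is_nonnegative(seed):
    rng = np.random.default_rng(seed)
    n = rng.integers(50, 300)
    w = rng.integers(0, rng.integers(2, 5), n)
    a = rng.integers(0, rng.integers(2, 5), n)
    j = estimate_joint_from_triples(w[1:], w[:-1], a[:-1])
    val = mc_w(j)
    assert val >= 0.0
    assert val == pytest.approx(brute_force_cmi(j.to_dense()), abs=1e-10)


def test_state_dependent_mc_properties():
    rng = np.random.default_rng(5)
    w = rng.integers(0, 4, 1000)
    a = rng.integers(0, 3, 1000)
    j = estimate_joint_from_triples(w[1:], w[:-1], a[:-1])
    t = mc_w_state_dependent(j)
    assert len(t) == 999
    # plain average over steps equals the probability-weighted triple average
    assert np.mean(t) == pytest.approx(mc_w(j), abs=1e-10)
    # constant series: identically zero
    jc = estimate_joint_from_triples(np.zeros(9, int), np.zeros(9, int), np.zeros(9, int))
    assert np.allclose(mc_w_state_dependent(jc), 0.0)


def test_state_dependent_mc_on_deterministic_copy():
    """w' = w: every step contributes log2(1/p(w'|a)) >= 0."""
    rng = np.random.default_rng(8)
    w = rng.integers(0, 4, 5000)
    a = rng.integers(0, 3, 5000)
    j = estimate_joint_from_triples(w, w, a)
    t = mc_w_state_dependent(j)
    assert (t >= 0).all()
    expect = -np.log2(j.p_w_given_a[j.t_index])
    assert np.allclose(t, expect, atol=1e-12)


# ---------------------------------------------------------------- level splits

def test_selected_split_world_is_observable_state(p2p_study, osc_traces):
    sp = build_level_split(p2p_study[1][0], "selected", "u")
    assert len(sp.a_channels) == 6
    assert sp.w_channels == ["q_elbow", "q_shoulder"]
    sp_rod = build_level_split(osc_traces[0], "selected", "u")
    assert sp_rod.w_channels == ["q_elbow", "q_shoulder", "rod_x"]


def test_accumulated_split_structure(p2p_study):
    tr = p2p_study[1][0]
    bottom = build_level_split(tr, "accumulated", "T")
    # everything at/above the torque cut: 1 + 12 + 4*6 + 2 channels
    assert len(bottom.a_channels) == 39
    assert bottom.w_channels == ["q_elbow", "q_shoulder"]
    top = build_level_split(tr, "accumulated", "u_central")
    assert top.a_channels == ["u_central"]
    assert len(top.w_channels) == 40
    for lv in LEVELS:
        sp = build_level_split(tr, "accumulated", lv)
        assert not set(sp.w_channels) & set(sp.a_channels)
        assert "q_elbow" in sp.w_channels and "q_elbow" not in sp.a_channels
    with pytest.raises(ValueError):
        build_level_split(tr, "accumulated", "q")


def test_mc_table_shape_and_information_bound(p2p_study):
    _, traces = p2p_study
    table = mc_by_level(traces, "selected")
    assert table.shape == (3, 7)            # runs x hierarchy levels
    assert (table.to_numpy() >= 0).all()
    for lv in LEVELS:
        r = compute_mc(traces[0], "selected", lv)
        assert r.mc_w <= np.log2(r.alphabet_w) + 1e-9


def test_windowed_mc_uses_full_trace_bins(osc_traces):
    tr = osc_traces[0]
    r_full = compute_mc(tr, "accumulated", "T")
    r_late = compute_mc(tr, "accumulated", "T", window=(4.0, 6.0))
    assert r_late.bins_w == r_full.bins_w
    assert r_late.n_samples < r_full.n_samples


def test_binning_policy_resolutions():
    p = BinningPolicy()
    assert p.actuator_bins() == 30
    assert p.world_bins("selected", 41, 3000) == 30
    assert p.world_bins("accumulated", 41, 3000) == 2
    assert p.world_bins("accumulated", 3, 3000) == 8
    assert p.world_bins("accumulated", 2, 10 ** 9) == 30
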