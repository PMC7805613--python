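"""Quantifying morphological computation on discretized hierarchy traces.

Morphological computation of the world dynamics, MC_W, is the Kullback-Leibler
divergence between the world-dynamics kernel and its action-only reduction,

    MC_W = sum_{w',w,a} p(w', w, a) log2 [ p(w'|w, a) / p(w'|a) ]  ,

i.e. the conditional mutual information I(W'; W | A) of the empirical joint
distribution, estimated by frequency counts over the T-1 transition triples
(w_{t+1}, w_t, a_t) of a run.  The state-dependent variant evaluates the same
log-ratio along the trajectory instead of averaging it.

Two ways of splitting the hierarchy signals into actuator state A and world
state W are supported:

* ``selected`` -- A is exactly one hierarchy level; W is the observable
  mechanical state q (joint angles, plus the rod position when present).
* ``accumulated`` -- a clean cut: A collects every signal at or above the cut
  level, W every signal strictly below it (down to and including q).

Discretization: each channel is binned into uniform-width bins over its
observed range in the full trace (left-closed/right-open, maximum in the last
bin; constant channels collapse to a single bin), and a multi-channel state's
symbol is the combination of its per-channel bin indices.  When MC is
evaluated on a time window, the bins are still those of the full trace, so
"steady relative to the whole movement" stays steady in symbol space.

The actuator side always uses a fixed fine resolution (default 30 bins per
channel, mirroring the per-signal discretization used when analyzing
experimental recordings): A only ever conditions, so a finer A can only make
the action-only prediction better and never manufactures morphological
computation.  The world side is what the frequency estimator must model
jointly at two time steps; in selected mode it is the low-dimensional
observable state and uses the same fine resolution, while in accumulated mode
it can span dozens of channels, where a fine product binning is meaningless.
There the per-channel bin count is reduced to keep the expected occupancy of
the estimator at or above ``min_occupancy`` samples per cell, evaluated at
the full hierarchy dimension so that every cut of one trace is discretized at
the same resolution (never below 2 bins).  Comparisons are only ever made
between MC values computed under one policy.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .trace import LEVELS, WORLD_LEVEL, HierarchyTrace, level_channels


# ------------------------------------------------------------------- binning

@dataclass(frozen=True)
class BinningPolicy:
    """How many uniform bins each channel of a state receives."""

    bins: int = 30                #: fine per-channel resolution (A side, selected W)
    min_occupancy: float = 5.0    #: target samples per cell (accumulated W side)

    def actuator_bins(self) -> int:
        if self.bins < 2:
            raise ValueError("need at least 2 bins")
        return self.bins

    def world_bins(self, mode: str, n_total_channels: int, n_samples: int) -> int:
        """Per-channel bins of the world state.

        Accumulated mode uses one resolution per trace, from the occupancy
        rule at the full hierarchy dimension, so every cut is binned alike.
        """
        if self.bins < 2:
            raise ValueError("need at least 2 bins")
        if mode == "selected":
            return self.bins
        limit = int((n_samples / self.min_occupancy) ** (1.0 / n_total_channels))
        return max(2, min(self.bins, limit))


def bin_channels(x: np.ndarray, n_bins: int) -> tuple[np.ndarray, list[np.ndarray]]:
    """Per-channel uniform binning of a (T, n) array.

    Returns integer bin indices (T, n) and the bin edges per channel.
    Constant channels collapse to a single bin.
    """
    x = np.atleast_2d(np.asarray(x, dtype=float))
    if x.ndim != 2:
        raise ValueError("expected a (T, n_channels) array")
    if x.shape[0] == 0:
        raise ValueError("empty trace")
    if not np.isfinite(x).all():
        raise ValueError("non-finite channel values")
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    t, n = x.shape
    idx = np.zeros((t, n), dtype=np.int64)
    edges: list[np.ndarray] = []
    for j in range(n):
        lo, hi = x[:, j].min(), x[:, j].max()
        if hi <= lo:
            edges.append(np.array([lo, lo]))
            continue
        e = np.linspace(lo, hi, n_bins + 1)
        idx[:, j] = np.clip(((x[:, j] - lo) / (hi - lo) * n_bins).astype(np.int64),
                            0, n_bins - 1)
        edges.append(e)
    return idx, edges


def symbolize(bin_idx: np.ndarray) -> tuple[np.ndarray, int]:
    """Map rows of per-channel bin indices to dense integer symbols.

    The symbol of a multi-channel state is the combination of its per-channel
    bin indices; observed combinations are enumerated in lexicographic order.
    """
    _, inv = np.unique(bin_idx, axis=0, return_inverse=True)
    return inv.astype(np.int64), int(inv.max()) + 1


@dataclass
class DiscreteSeries:
    """Aligned symbol sequences for the world and actuator state of one run."""

    w: np.ndarray
    a: np.ndarray
    n_w: int
    n_a: int
    w_edges: list = field(default_factory=list)
    a_edges: list = field(default_factory=list)

    def __post_init__(self) -> None:
        if len(self.w) != len(self.a):
            raise ValueError("w and a must have equal length")
        if len(self.w) < 2:
            raise ValueError("need at least 2 samples (one transition)")


def discretize(w_values: np.ndarray, a_values: np.ndarray,
               bins_w: int, bins_a: int) -> DiscreteSeries:
    """Bin and symbolize the W and A channel blocks of one trace."""
    wi, we = bin_channels(w_values, bins_w)
    ai, ae = bin_channels(a_values, bins_a)
    w, n_w = symbolize(wi)
    a, n_a = symbolize(ai)
    return DiscreteSeries(w, a, n_w, n_a, we, ae)


# ------------------------------------------------------------- joint estimate

@dataclass
class JointDistribution:
    """Sparse empirical p(w', w, a) with the conditionals MC_W needs.

    ``triples`` holds the distinct observed (w', w, a) triples (K, 3) with
    ``counts`` occurrences out of ``n`` transition samples; ``t_index`` maps
    each transition step to its triple.  ``log_ratio`` is
    log2 p(w'|w,a) - log2 p(w'|a) per distinct triple.
    """

    triples: np.ndarray
    counts: np.ndarray
    n: int
    n_w: int
    n_a: int
    t_index: np.ndarray
    log_ratio: np.ndarray = field(init=False)
    p_w_given_wa: np.ndarray = field(init=False)
    p_w_given_a: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        wp, w, a = self.triples.T
        wa = w * self.n_a + a
        wpa = wp * self.n_a + a
        c_wa = np.bincount(wa, weights=self.counts)
        c_wpa = np.bincount(wpa, weights=self.counts)
        c_a = np.bincount(a, weights=self.counts)
        self.p_w_given_wa = self.counts / c_wa[wa]
        self.p_w_given_a = c_wpa[wpa] / c_a[a]
        self.log_ratio = np.log2(self.p_w_given_wa) - np.log2(self.p_w_given_a)

    @property
    def p(self) -> np.ndarray:
        return self.counts / self.n

    def to_dense(self) -> np.ndarray:
        """Dense p(w', w, a) array (tests / small alphabets only)."""
        dense = np.zeros((self.n_w, self.n_w, self.n_a))
        wp, w, a = self.triples.T
        dense[wp, w, a] = self.p
        return dense


def estimate_joint_from_triples(w_next: np.ndarray, w: np.ndarray, a: np.ndarray,
                                n_w: int | None = None, n_a: int | None = None
                                ) -> JointDistribution:
    trip = np.stack([np.asarray(w_next), np.asarray(w), np.asarray(a)], axis=1)
    uniq, inv, counts = np.unique(trip, axis=0, return_inverse=True,
                                  return_counts=True)
    n_w = n_w if n_w is not None else int(max(trip[:, 0].max(), trip[:, 1].max())) + 1
    n_a = n_a if n_a is not None else int(trip[:, 2].max()) + 1
    return JointDistribution(uniq, counts.astype(float), len(trip), n_w, n_a, inv)


def estimate_joint(series: DiscreteSeries) -> JointDistribution:
    """Frequency estimate of p(w_{t+1}, w_t, a_t) over the T-1 transitions."""
    return estimate_joint_from_triples(series.w[1:], series.w[:-1], series.a[:-1],
                                       series.n_w, series.n_a)


# ----------------------------------------------------------------------- MC_W

def mc_w(joint: JointDistribution) -> float:
    """Scalar morphological computation in bits (always >= 0)."""
    val = float(np.sum(joint.p * joint.log_ratio))
    if val < -1e-9:
        raise AssertionError(f"negative KL divergence {val}: estimator defect")
    return max(val, 0.0)


def mc_w_state_dependent(joint: JointDistribution) -> np.ndarray:
    """Per-transition log-ratio MC_W(t), length T-1; may be negative stepwise.

    Its probability-weighted average over distinct triples equals the scalar
    MC_W.
    """
    return joint.log_ratio[joint.t_index]


# ---------------------------------------------------------------- level splits

@dataclass
class LevelSplit:
    mode: str
    level: str
    w_channels: list[str]
    a_channels: list[str]

    def __post_init__(self) -> None:
        if not self.w_channels or not self.a_channels:
            raise ValueError("both W and A must be nonempty")
        if set(self.w_channels) & set(self.a_channels):
            raise ValueError("W and A must be disjoint")


def build_level_split(trace: HierarchyTrace, mode: str, level: str) -> LevelSplit:
    """Assign trace channels to W and A for one hierarchy level.

    The observable state q (and the rod position) is never part of A.
    """
    if mode not in ("selected", "accumulated"):
        raise ValueError("mode must be 'selected' or 'accumulated'")
    if level == WORLD_LEVEL:
        raise ValueError("cannot cut at the world level q: A would be empty")
    if level not in LEVELS:
        raise KeyError(f"unknown hierarchy level {level!r}")
    rod = trace.with_rod
    world = level_channels(WORLD_LEVEL, rod)
    if mode == "selected":
        return LevelSplit(mode, level, world, trace.channels(level))
    cut = LEVELS.index(level)
    a_ch = [c for lv in LEVELS[:cut + 1] for c in level_channels(lv, rod)]
    w_ch = [c for lv in LEVELS[cut + 1:] for c in level_channels(lv, rod)] + world
    return LevelSplit(mode, level, w_ch, a_ch)


@dataclass
class MCResult:
    mc_w: float
    mode: str
    level: str
    n_samples: int
    bins_w: int
    bins_a: int
    alphabet_w: int
    alphabet_a: int
    mc_w_t: np.ndarray | None = None


def total_hierarchy_channels(trace: HierarchyTrace) -> int:
    rod = trace.with_rod
    return sum(len(level_channels(lv, rod)) for lv in LEVELS + (WORLD_LEVEL,))


def compute_mc(trace: HierarchyTrace, mode: str, level: str,
               policy: BinningPolicy | None = None,
               window: tuple[float, float] | None = None,
               state_dependent: bool = False) -> MCResult:
    """Discretize one trace under a level split and return its MC_W.

    ``window`` restricts the transition samples to a time span; the bins are
    always those of the full trace, so windowed values stay comparable.
    """
    policy = policy or BinningPolicy()
    split = build_level_split(trace, mode, level)
    wv = trace.values(split.w_channels)
    av = trace.values(split.a_channels)
    bins_w = policy.world_bins(mode, total_hierarchy_channels(trace), wv.shape[0])
    bins_a = policy.actuator_bins()
    series = discretize(wv, av, bins_w, bins_a)
    w_sym, a_sym = series.w, series.a
    if window is not None:
        t = trace.time
        i0, i1 = np.searchsorted(t, window[0]), np.searchsorted(t, window[1])
        if i1 - i0 < 2:
            raise ValueError("window contains fewer than 2 samples")
        w_sym, a_sym = w_sym[i0:i1], a_sym[i0:i1]
    joint = estimate_joint_from_triples(w_sym[1:], w_sym[:-1], a_sym[:-1],
                                        series.n_w, series.n_a)
    res = MCResult(mc_w(joint), mode, level, joint.n, bins_w, bins_a,
                   series.n_w, series.n_a)
    if state_dependent:
        res.mc_w_t = mc_w_state_dependent(joint)
    return res


def mc_by_level(traces: list[HierarchyTrace], mode: str,
                policy: BinningPolicy | None = None,
                window: tuple[float, float] | None = None) -> pd.DataFrame:
    """MC_W for every run and every hierarchy level: rows = runs, columns = levels."""
    if not traces:
        raise ValueError("need at least one trace")
    rows = []
    for trace in traces:
        rows.append({lv: compute_mc(trace, mode, lv, policy, window).mc_w
                     for lv in LEVELS})
    df = pd.DataFrame(rows, columns=list(LEVELS))
    df.index.name = "run"
    return df
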