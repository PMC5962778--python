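"""Post-hoc analyses: cell assemblies, U-shaped development, trajectories.

A *cell assembly* is detected in the recurrent weight matrix as a maximal
set of hidden units that excite each other reciprocally — a maximal clique
of the undirected graph with an edge (i, j) whenever both ``W[i, j]`` and
``W[j, i]`` exceed a weight threshold (default 0: any mutual excitation).
This is a weight-based formalization of Hebb's verbal definition (a group
of neurons strongly coupled by excitatory synapses).

*U-shaped development* events are drops and recoveries in a success-rate
series: after light smoothing, a local peak -> trough -> peak triple whose
drop (on both flanks) reaches a minimum depth.

Trajectory metrics quantify the "general movements"-like character of hand
paths during such phases: mean absolute turning angle, direction reversals
and the net-to-gross displacement ratio over short (default 100-step)
windows.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
from scipy.signal import find_peaks


@dataclass(frozen=True)
class Assembly:
    """One assembly: its members and the mean of its reciprocal weights."""

    members: frozenset[int]
    mean_weight: float


@dataclass
class AssemblySet:
    """Maximal reciprocal-excitation cliques of a recurrent weight matrix."""

    assemblies: list[Assembly]
    threshold: float

    def __iter__(self):
        return iter(self.assemblies)

    def __len__(self) -> int:
        return len(self.assemblies)

    def member_sets(self) -> set[frozenset[int]]:
        return {a.members for a in self.assemblies}


def detect_assemblies(W_hid_hid: np.ndarray, weight_threshold: float = 0.0) -> AssemblySet:
    """Maximal cliques (size >= 2) of the reciprocal-excitation graph.

    Edge rule: (i, j) is an edge iff ``W[i, j] > threshold`` and
    ``W[j, i] > threshold`` for i != j.  Mean edge weight averages both
    directions over all member pairs.  Assemblies may overlap.
    """
    W = np.asarray(W_hid_hid, dtype=float)
    if W.ndim != 2 or W.shape[0] != W.shape[1]:
        raise ValueError(f"recurrent weight matrix must be square, got {W.shape}")
    n = W.shape[0]
    mutual = (W > weight_threshold) & (W.T > weight_threshold)
    np.fill_diagonal(mutual, False)
    g = nx.from_numpy_array(mutual)
    assemblies = []
    for clique in nx.find_cliques(g):
        if len(clique) < 2:
            continue
        members = frozenset(int(i) for i in clique)
        pairs = [(i, j) for i in members for j in members if i < j]
        mean_w = float(np.mean([(W[i, j] + W[j, i]) / 2.0 for i, j in pairs]))
        assemblies.append(Assembly(members, mean_w))
    assemblies.sort(key=lambda a: sorted(a.members))
    return AssemblySet(assemblies, weight_threshold)


def _best_jaccard(members: frozenset[int], others: "AssemblySet") -> float:
    best = 0.0
    for other in others:
        inter = len(members & other.members)
        union = len(members | other.members)
        best = max(best, inter / union)
    return best


def assembly_turnover(previous: AssemblySet, current: AssemblySet) -> float:
    """Turnover score in [0, 1] between two checkpoints' assembly sets.

    1 minus the mean best-match Jaccard similarity (symmetric over both
    directions).  Identical sets give 0; disjoint sets give 1.  Two empty
    sets give 0 (nothing changed); one empty set gives 1.
    """
    if not len(previous) and not len(current):
        return 0.0
    if not len(previous) or not len(current):
        return 1.0
    sims = [_best_jaccard(a.members, current) for a in previous]
    sims += [_best_jaccard(a.members, previous) for a in current]
    return 1.0 - float(np.mean(sims))


@dataclass(frozen=True)
class UShapeEvent:
    """One dip-and-recovery: peak -> trough -> peak in a success series."""

    start_step: int
    trough_step: int
    end_step: int
    depth: float  # start-peak rate minus trough rate
    recovery_height: float  # rate at the recovery peak


def _smooth(values: np.ndarray, window: int) -> np.ndarray:
    if window <= 1:
        return values.astype(float)
    if window % 2 == 0:
        window += 1  # centered average needs an odd window
    pad = window // 2
    padded = np.pad(values.astype(float), pad, mode="edge")
    return np.convolve(padded, np.ones(window) / window, mode="valid")


def detect_u_shapes(
    steps: np.ndarray,
    rates: np.ndarray,
    min_depth: float = 0.05,
    smoothing_window: int = 3,
) -> list[UShapeEvent]:
    """Find U-shaped drop/recovery events in a success-rate series.

    After a centered moving average (default 3 points), each local minimum
    bracketed by candidate peaks (local maxima, plus the series endpoints)
    with at least ``min_depth`` of drop on *both* flanks yields one event.
    Events are returned sorted by start step.
    """
    steps = np.asarray(steps)
    rates = np.asarray(rates, dtype=float)
    if len(rates) < 5:
        raise ValueError("series too short for U-shape detection (need >= 5 points)")
    s = _smooth(rates, smoothing_window)
    peak_idx = set(find_peaks(s)[0].tolist()) | {0, len(s) - 1}
    peaks = sorted(peak_idx)
    troughs = find_peaks(-s)[0]
    events: list[UShapeEvent] = []
    for ti in troughs:
        left = [p for p in peaks if p < ti]
        right = [p for p in peaks if p > ti]
        if not left or not right:
            continue
        start, end = left[-1], right[0]
        if min(s[start], s[end]) - s[ti] < min_depth:
            continue
        events.append(
            UShapeEvent(
                start_step=int(steps[start]),
                trough_step=int(steps[ti]),
                end_step=int(steps[end]),
                depth=float(s[start] - s[ti]),
                recovery_height=float(s[end]),
            )
        )
    events.sort(key=lambda e: e.start_step)
    return events


@dataclass(frozen=True)
class TrajectoryMetrics:
    """Shape statistics of one hand's path over a short window."""

    window: int  # number of displacement intervals
    mean_turning_angle: float  # degrees, over consecutive nonzero moves
    reversal_count: int  # 180-degree turns
    net_gross_ratio: float  # |net displacement| / summed step lengths


def trajectory_metrics(positions: np.ndarray) -> TrajectoryMetrics:
    """Turning angles, reversals and net/gross ratio of a position log.

    ``positions`` is an (N, 2) array of grid coordinates (N >= 2).  Angles
    are measured between consecutive *nonzero* displacement vectors; a
    reversal is an exact 180-degree turn.  An all-stationary window returns
    (0 angle, 0 reversals, ratio 1) by convention.
    """
    pos = np.asarray(positions, dtype=float)
    if pos.ndim != 2 or pos.shape[0] < 2 or pos.shape[1] != 2:
        raise ValueError("positions must be an (N>=2, 2) array")
    disp = np.diff(pos, axis=0)
    lengths = np.hypot(disp[:, 0], disp[:, 1])
    moving = lengths > 0
    window = disp.shape[0]
    if not moving.any():
        return TrajectoryMetrics(window, 0.0, 0, 1.0)
    v = disp[moving]
    angles = np.empty(0)
    reversals = 0
    if v.shape[0] >= 2:
        a, b = v[:-1], v[1:]
        dot = (a * b).sum(axis=1)
        cross = a[:, 0] * b[:, 1] - a[:, 1] * b[:, 0]
        angles = np.degrees(np.abs(np.arctan2(cross, dot)))
        reversals = int(np.sum((cross == 0) & (dot < 0)))
    net = float(np.hypot(*(pos[-1] - pos[0])))
    gross = float(lengths.sum())
    return TrajectoryMetrics(
        window=window,
        mean_turning_angle=float(angles.mean()) if angles.size else 0.0,
        reversal_count=reversals,
        net_gross_ratio=net / gross,
    )


def fluctuation_index(hidden_log: np.ndarray) -> np.ndarray:
    """Per-unit mean absolute step-to-step activation change.

    High values flag units whose activity flips every time step — the
    signature of assembly-forming units during U-shape phases.  Invariant
    to adding a constant to all activations.
    """
    acts = np.asarray(hidden_log, dtype=float)
    if acts.ndim != 2 or acts.shape[0] < 2:
        raise ValueError("hidden_log must be (T>=2, n_units)")
    return np.abs(np.diff(acts, axis=0)).mean(axis=0)
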