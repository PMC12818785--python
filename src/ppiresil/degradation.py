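"""Progressive-failure degradation trajectories and breakpoint estimation.

The degradation experiment asks how much resilience a network retains after
it has already lost a fraction ``f`` of its proteins: at each removal
fraction, a random node subset is *deleted*, the residual network's largest
connected component is taken as the surviving interactome, and its
integrated resilience R is computed by a nested Monte-Carlo simulation.
Averaging over outer replicates yields a trajectory R(f).

Bacterial interactomes show a biphasic trajectory — a gentle decline while
modular redundancy buffers the damage, then an accelerated collapse once
the inter-module bridges are depleted.  The crossover is estimated by a
two-segment continuous ("hinge") least-squares fit: every interior grid
point is tried as the candidate breakpoint, lines are fit to the two sides
with continuity enforced at the candidate, and the candidate minimizing the
total squared error is reported (as a percentage of nodes removed).
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass

import networkx as nx
import numpy as np

from ._kernels import component_roots
from .entropy import _as_arrays, _m_of_f, _make_grid, _simulate_curve_arrays
from .exceptions import DisconnectedGraphError, InsufficientDataError, ParameterError

__all__ = ["Trajectory", "BreakpointFit", "degradation_trajectory", "fit_breakpoint"]


@dataclass
class Trajectory:
    """Mean residual resilience per removal fraction."""

    grid: np.ndarray
    mean_R: np.ndarray
    sd_R: np.ndarray
    outer_reps: int
    inner_step: float
    inner_reps: int
    seed: int
    name: str = ""
    mode: str = "resilience"

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame({"f": self.grid, "mean_R": self.mean_R, "sd_R": self.sd_R})

    def to_tsv(self, path: str | os.PathLike) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


@dataclass
class BreakpointFit:
    """Two-segment continuous fit of a degradation trajectory.

    ``breakpoint`` is the estimated critical removal fraction (percent).
    ``no_acceleration`` is raised when the best fit does not steepen to the
    right of the breakpoint, i.e. when no resilience threshold is evident.
    """

    breakpoint: float  # percent of nodes removed
    left_slope: float
    right_slope: float
    left_intercept: float
    right_intercept: float
    value_at_break: float
    sse: float
    window: tuple
    no_acceleration: bool

    def to_dict(self) -> dict:
        return {
            "breakpoint_percent": float(self.breakpoint),
            "left_slope": float(self.left_slope),
            "right_slope": float(self.right_slope),
            "left_intercept": float(self.left_intercept),
            "right_intercept": float(self.right_intercept),
            "value_at_break": float(self.value_at_break),
            "sse": float(self.sse),
            "window": [float(self.window[0]), float(self.window[1])],
            "no_acceleration": bool(self.no_acceleration),
        }

    def to_json(self, path: str | os.PathLike) -> None:
        with open(path, "wt", encoding="utf-8") as fh:
            json.dump(self.to_dict(), fh, indent=1)


def _lcc_arrays(u, v, n, alive):
    """Edge arrays of the LCC of the alive-induced subgraph, reindexed.

    Ties between equal-size components break toward the smallest canonical
    node index, mirroring the lexicographic rule of ``extract_lcc``.
    """
    roots = component_roots(u, v, n, alive)
    alive_idx = np.flatnonzero(roots >= 0)
    if alive_idx.size == 0:
        return None, None, 0
    alive_roots = roots[alive_idx]
    sizes = np.bincount(alive_roots, minlength=n)
    candidates = np.flatnonzero(sizes == sizes.max())
    if candidates.size == 1:
        best = int(candidates[0])
    else:
        first_member = np.full(n, n, dtype=np.int64)
        np.minimum.at(first_member, alive_roots, alive_idx)
        best = int(candidates[np.argmin(first_member[candidates])])
    keep = roots == best
    size = int(sizes[best])
    index = np.cumsum(keep) - 1
    emask = keep[u] & keep[v]
    return (
        np.ascontiguousarray(index[u[emask]]),
        np.ascontiguousarray(index[v[emask]]),
        size,
    )


def degradation_trajectory(
    g: nx.Graph,
    outer_step: float = 0.01,
    outer_reps: int = 100,
    inner_step: float = 0.02,
    inner_reps: int = 10,
    seed: int = 0,
    mode: str = "resilience",
) -> Trajectory:
    """Residual resilience under progressive random node deletion.

    For each removal fraction on the outer grid and each outer replicate, a
    uniformly random subset of ``m(f)`` nodes is deleted, the residual LCC
    is extracted, and its resilience is computed with the (cheaper) inner
    grid and replicate count.  Residual graphs with fewer than 2 nodes score
    R = 0 by convention.  ``mode="entropy"`` replaces the nested resilience
    with the cheap proxy 1 - H_msh of the deletion partition itself.

    Every random draw descends deterministically from ``seed``, so the
    trajectory is bit-reproducible.
    """
    n = g.number_of_nodes()
    if n < 3:
        raise ParameterError("degradation trajectory needs N >= 3")
    if not nx.is_connected(g):
        raise DisconnectedGraphError("degradation trajectory is defined on a connected network")
    if outer_reps < 1 or inner_reps < 1:
        raise ParameterError("replicate counts must be >= 1")
    if mode not in ("resilience", "entropy"):
        raise ParameterError(f"unknown mode {mode!r}")
    _, u, v = _as_arrays(g)
    grid = _make_grid(outer_step)
    removal_rng = np.random.default_rng(np.random.SeedSequence([int(seed), 104729]))
    mean_R = np.empty(grid.size)
    sd_R = np.empty(grid.size)
    for i, f in enumerate(grid):
        m = _m_of_f(float(f), n)
        vals = np.empty(outer_reps)
        for r in range(outer_reps):
            alive = np.ones(n, dtype=bool)
            if m > 0:
                alive[removal_rng.permutation(n)[:m]] = False
            if mode == "entropy":
                vals[r] = _entropy_complement(u, v, n, alive)
                continue
            ru, rv, size = _lcc_arrays(u, v, n, alive)
            if size < 2:
                vals[r] = 0.0
                continue
            inner_rng = np.random.default_rng(np.random.SeedSequence([int(seed), i, r]))
            igrid, H = _simulate_curve_arrays(ru, rv, size, inner_step, inner_reps, inner_rng)
            vals[r] = 1.0 - float(np.trapezoid(H.mean(axis=1), igrid))
        mean_R[i] = vals.mean()
        sd_R[i] = vals.std(ddof=1) if outer_reps > 1 else 0.0
    return Trajectory(
        grid=grid,
        mean_R=mean_R,
        sd_R=sd_R,
        outer_reps=outer_reps,
        inner_step=inner_step,
        inner_reps=inner_reps,
        seed=seed,
        name=g.graph.get("name", ""),
        mode=mode,
    )


def _entropy_complement(u, v, n, alive):
    """1 - H_msh of the deletion partition, normalized by the residual size."""
    size = int(alive.sum())
    if size < 2:
        return 0.0
    roots = component_roots(u, v, n, alive)
    sizes = np.bincount(roots[roots >= 0], minlength=1)
    sizes = sizes[sizes > 1]
    acc = float(np.sum(sizes * np.log(sizes))) if sizes.size else 0.0
    return acc / (size * np.log(size))


def fit_breakpoint(t: Trajectory, window: tuple = (0.05, 0.95)) -> BreakpointFit:
    """Two-segment continuous least-squares fit of a trajectory.

    Candidates are the grid points strictly inside ``window`` with at least
    3 grid points on each side (within the window).  At a candidate ``c``
    the model is ``y = a + b_left*min(f-c, 0) + b_right*max(f-c, 0)``:
    linear in its three parameters, continuous at ``c``.  The candidate with
    the smallest residual sum of squares wins (first one on exact ties), so
    the fit is deterministic.  The estimate is invariant to positive affine
    rescaling of the trajectory values.
    """
    lo, hi = float(window[0]), float(window[1])
    if not 0.0 <= lo < hi <= 1.0:
        raise ParameterError(f"invalid window {window}")
    mask = (t.grid >= lo - 1e-12) & (t.grid <= hi + 1e-12)
    f = t.grid[mask]
    y = t.mean_R[mask]
    if f.size < 10:
        raise InsufficientDataError(
            f"breakpoint fit needs >= 10 grid points in the window, got {f.size}"
        )
    best = None
    for j in range(f.size):
        if j < 3 or f.size - 1 - j < 3:
            continue  # need 3 points strictly on each side
        c = f[j]
        d = f - c
        X = np.column_stack([np.ones_like(f), np.minimum(d, 0.0), np.maximum(d, 0.0)])
        coef, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
        sse = float(np.sum((y - X @ coef) ** 2))
        if best is None or sse < best[0]:
            best = (sse, c, coef)
    if best is None:
        raise InsufficientDataError("no candidate breakpoint with 3 points on each side")
    sse, c, (a, b_left, b_right) = best
    return BreakpointFit(
        breakpoint=100.0 * float(c),
        left_slope=float(b_left),
        right_slope=float(b_right),
        left_intercept=float(a - b_left * c),
        right_intercept=float(a - b_right * c),
        value_at_break=float(a),
        sse=sse,
        window=(lo, hi),
        # relative tolerance so numerically equal slopes (straight line) flag
        no_acceleration=bool(abs(b_right) <= abs(b_left) * (1 + 1e-9) + 1e-12),
    )
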