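"""Fitting the locus Pi(V) to a dataset by stochastic optimization.

Given data trees Z, the principal-component surface is the vertex set V
minimizing the sum of squared projection distances D^2_Z{Pi(V)}.  The
search is greedy: one vertex at a time is perturbed by a proposal
distribution (a uniform draw from the data, a beta-distributed point along
the geodesic from the vertex to a random data tree, or a random walk), and
the proposal is accepted whenever it lowers D^2, evaluated with the
geometric projection algorithm.  The search can stall in local minima, so
several independently seeded runs are performed and the best kept.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .frechet import _check_taxa
from .geodesic import Geodesic
from .locus import LocusFit, evaluate_locus, project_geometric
from .synthdata import random_walk
from .treespace import PhyloTree

__all__ = ["ProposalSpec", "FitReport", "propose", "default_proposals", "fit_locus"]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ProposalSpec:
    """One proposal family for the vertex search.

    kinds: ``data_sample`` (uniform draw from Z), ``beta_interpolate``
    (point a Beta(a, b)-distributed proportion along the geodesic from the
    vertex to a uniform data draw), ``random_walk`` (Gaussian walk from the
    vertex; ``walk_step_size=None`` defaults to 5% of the data's mean
    internal edge length).
    """

    kind: str
    beta_params: tuple[float, float] = (2.0, 2.0)
    walk_steps: int = 1
    walk_step_size: float | None = None

    def __post_init__(self):
        if self.kind not in {"data_sample", "beta_interpolate", "random_walk"}:
            raise ValueError(f"unknown proposal kind {self.kind!r}")
        if min(self.beta_params) <= 0:
            raise ValueError("beta parameters must be positive")
        if self.walk_steps < 1:
            raise ValueError("walk steps must be positive")
        if self.walk_step_size is not None and self.walk_step_size <= 0:
            raise ValueError("walk step size must be positive")


@dataclass
class FitReport:
    """Result of (possibly several runs of) the vertex search."""

    best: LocusFit
    trace: list[tuple[int, float]]
    runs: int
    seeds: list[int]


def _mean_internal_length(Z: Sequence[PhyloTree]) -> float:
    lengths = [l for z in Z for l in z.internal_edges().values()]
    return float(np.mean(lengths)) if lengths else 1.0


def propose(
    spec: ProposalSpec, v: PhyloTree, Z: Sequence[PhyloTree], seed=None
) -> PhyloTree:
    """Draw one candidate replacement for vertex ``v``."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if not Z and spec.kind in {"data_sample", "beta_interpolate"}:
        raise ValueError("data-based proposals need a nonempty dataset")
    if spec.kind == "data_sample":
        return Z[int(rng.integers(len(Z)))]
    if spec.kind == "beta_interpolate":
        z = Z[int(rng.integers(len(Z)))]
        t = float(rng.beta(*spec.beta_params))
        return Geodesic(v, z, internal_only=True).point(t)
    sigma = spec.walk_step_size
    if sigma is None:
        sigma = 0.05 * _mean_internal_length(Z)
    return random_walk(v, spec.walk_steps, sigma, rng)


def default_proposals(Z: Sequence[PhyloTree]) -> list[ProposalSpec]:
    """The three proposal families with default parameters.

    The walk proposals pair one long-step walk (broad moves) with a
    five-step short walk (local refinement), step sizes relative to the
    data's mean internal edge length.
    """
    scale = _mean_internal_length(Z)
    return [
        ProposalSpec("data_sample"),
        ProposalSpec("beta_interpolate", beta_params=(2.0, 2.0)),
        ProposalSpec("random_walk", walk_steps=1, walk_step_size=0.25 * scale),
        ProposalSpec("random_walk", walk_steps=5, walk_step_size=0.05 * scale),
    ]


def _d_squared(Z, V, rng, stop_above=None, **proj_kwargs) -> float:
    """Sum of squared geometric-projection distances, with early abort."""
    total = 0.0
    for z in Z:
        res = project_geometric(z, V, seed=rng, **proj_kwargs)
        total += res.distance**2
        if stop_above is not None and total >= stop_above:
            return math.inf
    return total


def fit_locus(
    Z: Sequence[PhyloTree],
    k: int = 2,
    proposals: Sequence[ProposalSpec] | None = None,
    V_init: Sequence[PhyloTree] | None = None,
    seed=None,
    rel_tol: float = 1e-3,
    window: int = 10,
    max_sweeps: int = 100,
    runs: int = 3,
    internal_only: bool = True,
    eps: float = 1e-3,
    max_iter: int = 5000,
    final_max_iter: int | None = None,
    restarts: int = 1,
    r2_mode: str = "explained",
) -> FitReport:
    """Greedy stochastic search for the vertices minimizing D^2_Z{Pi(V)}.

    Each sweep proposes, for every vertex in turn and every proposal family,
    a replacement vertex; improvements are accepted immediately and the
    sweep continues from the next (vertex, proposal) pair.  A run terminates
    when the relative decrease of D^2 over ``window`` sweeps falls below
    ``rel_tol`` (or after ``max_sweeps``); the best of ``runs`` seeded runs
    is returned, with projections and the r^2 statistic evaluated on the
    winning configuration.

    Candidate comparisons tolerate shallow projections (truncation bias is
    common-mode across candidates), so ``max_iter`` bounds the search-time
    projection depth while ``final_max_iter`` (default: same) sets the
    depth of the reported D^2, r^2 and projections.
    """
    if not Z:
        raise ValueError("empty dataset")
    if k != 2:
        raise ValueError("the search is implemented for k = 2 (three vertices)")
    _check_taxa(Z)
    if proposals is None:
        proposals = default_proposals(Z)
    master = np.random.default_rng(seed)
    run_seeds = [int(s) for s in master.integers(0, 2**31 - 1, size=runs)]
    proj_kwargs = dict(
        internal_only=internal_only, eps=eps, max_iter=max_iter, restarts=restarts
    )

    best_overall: tuple[float, list[PhyloTree], list[tuple[int, float]]] | None = None
    for run_seed in run_seeds:
        rng = np.random.default_rng(run_seed)
        if V_init is not None:
            if len(V_init) != k + 1:
                raise ValueError("V_init must contain k+1 trees")
            V = list(V_init)
        else:
            idx = rng.choice(len(Z), size=min(k + 1, len(Z)), replace=False)
            V = [Z[int(i)] for i in idx]
            while len(V) < k + 1:
                V.append(Z[int(rng.integers(len(Z)))])
        d2 = _d_squared(Z, V, rng, **proj_kwargs)
        trace = [(0, d2)]
        history = [d2]
        for sweep in range(1, max_sweeps + 1):
            for i in range(k + 1):
                for spec in proposals:
                    w = propose(spec, V[i], Z, rng)
                    cand = list(V)
                    cand[i] = w
                    d2c = _d_squared(Z, cand, rng, stop_above=d2, **proj_kwargs)
                    if d2c < d2:
                        logger.info(
                            "accepted %s move on vertex %d: D2 %.6g -> %.6g",
                            spec.kind, i, d2, d2c,
                        )
                        V, d2 = cand, d2c
                        trace.append((sweep, d2))
            history.append(d2)
            if d2 == 0.0:
                break
            if len(history) > window:
                past = history[-window - 1]
                if (past - d2) / max(past, 1e-300) < rel_tol:
                    break
        if best_overall is None or d2 < best_overall[0]:
            best_overall = (d2, V, trace)

    d2, V, trace = best_overall
    fit = evaluate_locus(
        Z,
        V,
        seed=np.random.default_rng(run_seeds[0]),
        internal_only=internal_only,
        r2_mode=r2_mode,
        eps=eps,
        max_iter=final_max_iter if final_max_iter is not None else max_iter,
        restarts=restarts,
    )
    return FitReport(best=fit, trace=trace, runs=runs, seeds=run_seeds)
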