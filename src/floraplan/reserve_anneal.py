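"""Simulated-annealing reserve selection with Marxan-style scoring.

The objective of a candidate reserve set R is

    score(R) = sum_{u in R} cost(u)
             + BLM * boundary(R)
             + sum_s SPF_s * max(0, (target_s - held_s) / target_s)

where boundary(R) is the total edge length between selected and unselected
planning units (plus exposed landscape edge, when the boundary list carries
self-pairs), held_s is the amount of species s inside R, and the shortfall
penalty is proportional (unit-free in SPF).  Targets with target_s = 0
contribute nothing.

Optimization is simulated annealing over single-PU flips with an adaptive
initial temperature (the SD of the score change over 100 random probe
flips), geometric cooling, and a final greedy improvement sweep; repeat runs
from different seeds are combined into a summed solution (selection
frequency, the classic irreplaceability surrogate).  The hot loop is
compiled with numba; score bookkeeping is incremental, and
:func:`objective_value` recomputes the score from scratch for verification.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numba import njit

from .planning_io import (
    STATUS_AVAILABLE,
    STATUS_LOCKED_IN,
    ConservationProblem,
)


def objective_value(problem: ConservationProblem, selected: np.ndarray) -> float:
    """Full from-scratch recomputation of the Marxan-form objective."""
    sel = np.asarray(selected, dtype=bool)
    grid = problem.grid
    if sel.size != grid.n_pu:
        raise ValueError("selection vector has the wrong length")
    cost_term = float(grid.cost[sel].sum())

    id1 = grid.boundary_id1 - 1
    id2 = grid.boundary_id2 - 1
    internal = id1 != id2
    cross = sel[id1[internal]] != sel[id2[internal]]
    boundary = float(grid.boundary_len[internal][cross].sum())
    self_rows = ~internal
    boundary += float(grid.boundary_len[self_rows][sel[id1[self_rows]]].sum())

    held = problem.amounts.amounts @ sel
    target = problem.target_area_km2
    with np.errstate(divide="ignore", invalid="ignore"):
        short = np.where(target > 0, np.maximum(0.0, (target - held) / target), 0.0)
    penalty = float((problem.targets.spf * short).sum())
    return cost_term + problem.blm * boundary + penalty


def boundary_length(problem: ConservationProblem, selected: np.ndarray) -> float:
    """Boundary length (km) of a selection, per the problem's boundary list."""
    sel = np.asarray(selected, dtype=bool)
    grid = problem.grid
    id1, id2 = grid.boundary_id1 - 1, grid.boundary_id2 - 1
    internal = id1 != id2
    cross = sel[id1[internal]] != sel[id2[internal]]
    total = float(grid.boundary_len[internal][cross].sum())
    self_rows = ~internal
    total += float(grid.boundary_len[self_rows][sel[id1[self_rows]]].sum())
    return total


@dataclass
class AnnealConfig:
    """Annealing schedule.

    iterations per run default to ``iter_factor * n_PU``; temperature starts
    at the SD of the score change over 100 random probe flips and is
    multiplied by ``cooling`` every ``n_PU`` iterations.
    """

    n_runs: int = 100
    iter_factor: int = 10_000
    iterations: int | None = None
    cooling: float = 0.95
    init_prob: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_runs < 1:
            raise ValueError("n_runs must be >= 1")
        if not 0 < self.cooling < 1:
            raise ValueError("cooling must be in (0, 1)")

    def n_iterations(self, n_pu: int) -> int:
        return self.iterations if self.iterations is not None else self.iter_factor * n_pu


@dataclass
class SelectionResult:
    """Per-run solutions plus the summed (selection-frequency) solution."""

    runs: np.ndarray            # (n_runs, n_pu) bool
    objectives: np.ndarray      # (n_runs,)
    incremental_scores: np.ndarray  # kernel-maintained scores, for auditing
    accepted_flips: np.ndarray  # (n_runs,) int
    summed: np.ndarray          # (n_pu,) int in [0, n_runs]

    @property
    def n_runs(self) -> int:
        return self.runs.shape[0]

    @property
    def best_index(self) -> int:
        return int(np.argmin(self.objectives))

    @property
    def best(self) -> np.ndarray:
        return self.runs[self.best_index]


@njit(cache=True)
def _rng_next(state):
    # splitmix64
    state = (state + np.uint64(0x9E3779B97F4A7C15)) & np.uint64(0xFFFFFFFFFFFFFFFF)
    z = state
    z = ((z ^ (z >> np.uint64(30))) * np.uint64(0xBF58476D1CE4E5B9)) & np.uint64(0xFFFFFFFFFFFFFFFF)
    z = ((z ^ (z >> np.uint64(27))) * np.uint64(0x94D049BB133111EB)) & np.uint64(0xFFFFFFFFFFFFFFFF)
    z = z ^ (z >> np.uint64(31))
    return state, z


@njit(cache=True)
def _rng_uniform(state):
    state, z = _rng_next(state)
    return state, (z >> np.uint64(11)) * (1.0 / 9007199254740992.0)


@njit(cache=True)
def _flip_delta(u, sel, cost, blm, adj_ptr, adj_idx, adj_len, exposure,
                sp_ptr, sp_idx, sp_amt, held, target, spf):
    adding = not sel[u]
    dcost = cost[u] if adding else -cost[u]
    db = exposure[u]
    for e in range(adj_ptr[u], adj_ptr[u + 1]):
        v = adj_idx[e]
        db += adj_len[e] * (1.0 - 2.0 * sel[v])
    if not adding:
        db = -db
    dpen = 0.0
    for e in range(sp_ptr[u], sp_ptr[u + 1]):
        s = sp_idx[e]
        t = target[s]
        if t <= 0.0:
            continue
        h_old = held[s]
        h_new = h_old + sp_amt[e] if adding else h_old - sp_amt[e]
        s_old = (t - h_old) / t
        if s_old < 0.0:
            s_old = 0.0
        s_new = (t - h_new) / t
        if s_new < 0.0:
            s_new = 0.0
        dpen += spf[s] * (s_new - s_old)
    return dcost + blm * db + dpen


@njit(cache=True)
def _apply_flip(u, sel, sp_ptr, sp_idx, sp_amt, held):
    adding = not sel[u]
    for e in range(sp_ptr[u], sp_ptr[u + 1]):
        s = sp_idx[e]
        held[s] += sp_amt[e] if adding else -sp_amt[e]
    sel[u] = not sel[u]


@njit(cache=True)
def _anneal_run(cost, status, blm, adj_ptr, adj_idx, adj_len, exposure,
                sp_ptr, sp_idx, sp_amt, target, spf,
                n_iter, cooling, cooling_interval, init_prob, seed):
    n_pu = cost.shape[0]
    n_sp = target.shape[0]
    state = np.uint64(seed) * np.uint64(2685821657736338717) + np.uint64(1)

    avail = np.empty(n_pu, dtype=np.int64)
    n_avail = 0
    sel = np.zeros(n_pu, dtype=np.bool_)
    for u in range(n_pu):
        if status[u] == 2:
            sel[u] = True
        elif status[u] == 0:
            avail[n_avail] = u
            n_avail += 1
            state, r = _rng_uniform(state)
            if r < init_prob:
                sel[u] = True

    held = np.zeros(n_sp)
    for u in range(n_pu):
        if sel[u]:
            for e in range(sp_ptr[u], sp_ptr[u + 1]):
                held[sp_idx[e]] += sp_amt[e]

    # initial score, computed once from scratch
    score = 0.0
    for u in range(n_pu):
        if sel[u]:
            score += cost[u]
            b = exposure[u]
            for e in range(adj_ptr[u], adj_ptr[u + 1]):
                if not sel[adj_idx[e]]:
                    b += adj_len[e]
            score += blm * b
    for s in range(n_sp):
        if target[s] > 0.0:
            sh = (target[s] - held[s]) / target[s]
            if sh > 0.0:
                score += spf[s] * sh

    n_accept = 0
    if n_avail == 0:
        return sel, score, n_accept

    # adaptive initial temperature: SD of delta over 100 random probe flips
    mean_d = 0.0
    m2 = 0.0
    for k in range(100):
        state, r = _rng_uniform(state)
        u = avail[int(r * n_avail)]
        d = _flip_delta(u, sel, cost, blm, adj_ptr, adj_idx, adj_len, exposure,
                        sp_ptr, sp_idx, sp_amt, held, target, spf)
        delta_m = d - mean_d
        mean_d += delta_m / (k + 1)
        m2 += delta_m * (d - mean_d)
    temp = np.sqrt(m2 / 100.0)
    if temp < 1e-8:
        temp = 1e-8

    for it in range(n_iter):
        state, r = _rng_uniform(state)
        u = avail[int(r * n_avail)]
        d = _flip_delta(u, sel, cost, blm, adj_ptr, adj_idx, adj_len, exposure,
                        sp_ptr, sp_idx, sp_amt, held, target, spf)
        accept = d <= 0.0
        if not accept:
            state, r = _rng_uniform(state)
            if r < np.exp(-d / temp):
                accept = True
        if accept:
            _apply_flip(u, sel, sp_ptr, sp_idx, sp_amt, held)
            score += d
            n_accept += 1
        if (it + 1) % cooling_interval == 0:
            temp *= cooling

    # final greedy improvement sweeps
    improved = True
    while improved:
        improved = False
        for i in range(n_avail):
            u = avail[i]
            d = _flip_delta(u, sel, cost, blm, adj_ptr, adj_idx, adj_len, exposure,
                            sp_ptr, sp_idx, sp_amt, held, target, spf)
            if d < -1e-12:
                _apply_flip(u, sel, sp_ptr, sp_idx, sp_amt, held)
                score += d
                n_accept += 1
                improved = True
    return sel, score, n_accept


def _kernel_arrays(problem: ConservationProblem):
    """Flatten a ConservationProblem into the CSR arrays the kernel wants."""
    grid = problem.grid
    n_pu = grid.n_pu
    id1, id2 = grid.boundary_id1 - 1, grid.boundary_id2 - 1
    lens = grid.boundary_len
    internal = id1 != id2

    deg = np.zeros(n_pu, dtype=np.int64)
    np.add.at(deg, id1[internal], 1)
    np.add.at(deg, id2[internal], 1)
    adj_ptr = np.zeros(n_pu + 1, dtype=np.int64)
    np.cumsum(deg, out=adj_ptr[1:])
    adj_idx = np.empty(adj_ptr[-1], dtype=np.int64)
    adj_len = np.empty(adj_ptr[-1])
    fill = adj_ptr[:-1].copy()
    for a, b, ln in zip(id1[internal], id2[internal], lens[internal]):
        adj_idx[fill[a]] = b
        adj_len[fill[a]] = ln
        fill[a] += 1
        adj_idx[fill[b]] = a
        adj_len[fill[b]] = ln
        fill[b] += 1

    exposure = np.zeros(n_pu)
    np.add.at(exposure, id1[~internal], lens[~internal])

    amounts = problem.amounts.amounts  # (S, U)
    sp_per_pu = amounts.T  # (U, S)
    u_idx, s_idx = np.nonzero(sp_per_pu)
    counts = np.bincount(u_idx, minlength=n_pu)
    sp_ptr = np.zeros(n_pu + 1, dtype=np.int64)
    np.cumsum(counts, out=sp_ptr[1:])
    sp_idx = s_idx.astype(np.int64)
    sp_amt = sp_per_pu[u_idx, s_idx]

    return (
        grid.cost.astype(float),
        grid.status.astype(np.int64),
        float(problem.blm),
        adj_ptr, adj_idx, adj_len, exposure,
        sp_ptr, sp_idx, sp_amt,
        problem.target_area_km2.astype(float),
        problem.targets.spf.astype(float),
    )


def _run_seed(master_seed: int, run_index: int) -> int:
    """Independent, replayable per-run seed derived from the master seed."""
    ss = np.random.SeedSequence(entropy=int(master_seed), spawn_key=(run_index,))
    return int(ss.generate_state(1, dtype=np.uint64)[0])


def anneal(
    problem: ConservationProblem, config: AnnealConfig, run_seed: int
) -> tuple[np.ndarray, float, int]:
    """One annealing run; returns (selection, incremental score, accepted flips)."""
    arrays = _kernel_arrays(problem)
    n_pu = problem.grid.n_pu
    n_iter = config.n_iterations(n_pu)
    sel, score, n_acc = _anneal_run(
        *arrays, n_iter, config.cooling, max(1, n_pu), config.init_prob,
        np.uint64(run_seed & 0xFFFFFFFFFFFFFFFF),
    )
    return np.asarray(sel, dtype=bool), float(score), int(n_acc)


def run_repeats(problem: ConservationProblem, config: AnnealConfig) -> SelectionResult:
    """Repeat annealing runs and assemble the summed solution.

    Locked-in PUs appear in every run (summed score = n_runs); locked-out
    PUs in none.  Per-run objectives are recomputed from scratch with
    :func:`objective_value`, independently of the kernel's incremental score.
    """
    arrays = _kernel_arrays(problem)
    n_pu = problem.grid.n_pu
    n_iter = config.n_iterations(n_pu)
    runs = np.zeros((config.n_runs, n_pu), dtype=bool)
    incr = np.empty(config.n_runs)
    acc = np.empty(config.n_runs, dtype=int)
    for r in range(config.n_runs):
        sel, score, n_acc = _anneal_run(
            *arrays, n_iter, config.cooling, max(1, n_pu), config.init_prob,
            np.uint64(_run_seed(config.seed, r)),
        )
        runs[r] = sel
        incr[r] = score
        acc[r] = n_acc
    objectives = np.array([objective_value(problem, runs[r]) for r in range(config.n_runs)])
    return SelectionResult(
        runs=runs,
        objectives=objectives,
        incremental_scores=incr,
        accepted_flips=acc,
        summed=runs.sum(axis=0).astype(int),
    )


def exhaustive_optimum(problem: ConservationProblem) -> tuple[np.ndarray, float]:
    """Exact optimum by enumeration of all subsets (test oracle; <= ~20 PUs)."""
    grid = problem.grid
    n_pu = grid.n_pu
    if n_pu > 22:
        raise ValueError("exhaustive search is for small instances only")
    free = np.where(grid.status == STATUS_AVAILABLE)[0]
    base = grid.status == STATUS_LOCKED_IN
    best_sel, best_val = None, np.inf
    for code in range(1 << free.size):
        sel = base.copy()
        for i in range(free.size):
            if code >> i & 1:
                sel[free[i]] = True
        val = objective_value(problem, sel)
        if val < best_val - 1e-12:
            best_val = val
            best_sel = sel
    return best_sel, float(best_val)
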