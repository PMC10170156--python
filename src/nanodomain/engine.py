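"""Lattice Monte-Carlo engine for single-receptor nanodomain dynamics.

One receptor performs a nearest-neighbour random walk on an ``n × n``
periodic lattice. Every timestep it attempts a move to one of the four
neighbours; a move that changes compartment membership succeeds with the
Metropolis probability exp(−ΔE/k_BT), where ΔE sums the applicable boundary
terms: an unliganded receptor pays ``E_entry_tet``/``E_exit_tet`` when
crossing a tetraspanin boundary inward/outward, a liganded receptor pays
``E_entry_cla``/``E_exit_cla`` at clathrin boundaries, and all other
boundary terms are zero. A rejected move leaves the receptor in place; time
advances by ``dt`` either way. Unliganded receptors inside a tetraspanin
domain bind ligand as a per-step Bernoulli event with probability
``k_bind·dt`` (irreversible; binding instantly lifts the tetraspanin
barriers); liganded receptors inside a clathrin domain are removed from the
membrane with probability ``k_remove·dt``. Within a timestep the order is:
diffusion attempt, binding check, removal check.

The hot loop (:func:`_run_kernel`) is numba-compiled with an inline
xorshift64* generator and a precomputed neighbour table; the pure-Python
single-step operations (:func:`attempt_step`, :func:`update_reactions`)
implement the same semantics on a numpy Generator and exist for direct
inspection and unit testing.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from numba import njit

from .domains import CLATHRIN, OUTSIDE, TETRASPANIN, DomainMap, membership, place_domains
from .params import SimParams

__all__ = [
    "ReceptorState",
    "TrajectoryRecord",
    "transition_barrier",
    "metropolis_accept",
    "attempt_step",
    "update_reactions",
    "simulate_trajectory",
    "simulate_positions",
    "child_seeds",
]


# ---------------------------------------------------------------------------
# state and record containers


@dataclass(frozen=True)
class ReceptorState:
    """Instantaneous state of the simulated receptor."""

    site: tuple[int, int]
    liganded: bool = False
    alive: bool = True
    t: float = 0.0


@dataclass
class TrajectoryRecord:
    """History of one receptor from insertion to removal or censoring.

    ``intervals`` is a contiguous event-compressed log (one row per maximal
    run of constant compartment and ligand state, columns ``t_start``,
    ``t_end``, ``compartment``, ``liganded``); ``time_in`` holds the exact
    per-(compartment, ligand state) residence times accumulated by the
    engine, indexed ``time_in[compartment, liganded]``, in seconds.
    """

    intervals: pd.DataFrame | None
    time_in: np.ndarray
    lifetime: float
    censored: bool
    t_bind: float | None
    t_remove: float | None
    t_first_tet: float | None
    seed: int
    domain_map: DomainMap | None = None

    def validate(self) -> None:
        """Check the interval-partition and event-placement invariants."""
        if self.intervals is not None:
            iv = self.intervals
            if len(iv) == 0:
                raise ValueError("empty interval log")
            if abs(iv.t_start.iloc[0]) > 1e-12:
                raise ValueError("intervals must start at 0")
            if not np.allclose(iv.t_end.iloc[:-1].to_numpy(), iv.t_start.iloc[1:].to_numpy()):
                raise ValueError("intervals have gaps or overlaps")
            if abs(iv.t_end.iloc[-1] - self.lifetime) > 1e-9:
                raise ValueError("last interval must end at the lifetime")
            if self.t_remove is not None:
                last = iv.iloc[-1]
                if not (last.compartment == CLATHRIN and last.liganded):
                    raise ValueError("removal outside a (clathrin, liganded) interval")
            if (iv.liganded.astype(int).diff().dropna() < 0).any():
                raise ValueError("ligand state may only flip unliganded -> liganded")
        if abs(float(self.time_in.sum()) - self.lifetime) > 1e-6 * max(self.lifetime, 1.0):
            raise ValueError("time_in does not sum to the lifetime")


# ---------------------------------------------------------------------------
# single-step semantics (reference implementation)


def _entry_barrier(comp: int, liganded: bool, params: SimParams) -> float:
    if comp == TETRASPANIN and not liganded:
        return params.E_entry_tet
    if comp == CLATHRIN and liganded:
        return params.E_entry_cla
    return 0.0


def _exit_barrier(comp: int, liganded: bool, params: SimParams) -> float:
    if comp == TETRASPANIN and not liganded:
        return params.E_exit_tet
    if comp == CLATHRIN and liganded:
        return params.E_exit_cla
    return 0.0


def transition_barrier(liganded: bool, from_comp: int, to_comp: int, params: SimParams) -> float:
    """Energy barrier (k_B·T) for a membership-changing move.

    The barrier is the sum of the boundary terms the move crosses: leaving
    ``from_comp`` plus entering ``to_comp``. Tetraspanin boundaries act only
    on unliganded receptors, clathrin boundaries only on liganded ones, so
    for moves between a domain and the outside this reduces to the four
    configured values (e.g. unliganded outside→tetraspanin costs
    ``E_entry_tet``, liganded clathrin→outside costs ``E_exit_cla``) and all
    other outside↔domain combinations are barrier-free. Rare direct
    tetraspanin↔clathrin moves (adjacent sites of two domains) sum both
    applicable terms, which keeps the equilibrium occupancy exactly at the
    detailed-balance value regardless of domain placement.
    """
    for c in (from_comp, to_comp):
        if c not in (OUTSIDE, TETRASPANIN, CLATHRIN):
            raise ValueError(f"unknown compartment code {c}")
    if from_comp == to_comp:
        raise ValueError("barrier is only defined on a membership change")
    return _exit_barrier(from_comp, liganded, params) + _entry_barrier(to_comp, liganded, params)


def metropolis_accept(dE: float, rng: np.random.Generator) -> bool:
    """Accept a barrier crossing with probability exp(−ΔE); ΔE ≥ 0."""
    if dE < 0:
        raise ValueError("the model has no negative barriers")
    if dE == 0:
        return True
    return rng.random() < math.exp(-dE)


_NEIGHBOURS = ((1, 0), (-1, 0), (0, 1), (0, -1))


def attempt_step(
    state: ReceptorState, domain_map: DomainMap, params: SimParams, rng: np.random.Generator
) -> ReceptorState:
    """One diffusion attempt: pick a neighbour uniformly, apply Metropolis.

    Time advances by ``dt`` whether or not the move is accepted.
    """
    if not state.alive:
        raise ValueError("receptor has been removed")
    n = params.n_side
    di, dj = _NEIGHBOURS[rng.integers(4)]
    target = ((state.site[0] + di) % n, (state.site[1] + dj) % n)
    here = membership(state.site, domain_map, params.dx)
    there = membership(target, domain_map, params.dx)
    new_site = state.site
    if here == there:
        new_site = target
    else:
        dE = transition_barrier(state.liganded, here, there, params)
        if metropolis_accept(dE, rng):
            new_site = target
    return replace(state, site=new_site, t=state.t + params.dt)


def update_reactions(
    state: ReceptorState, domain_map: DomainMap, params: SimParams, rng: np.random.Generator
) -> ReceptorState:
    """Binding then removal check for the current timestep.

    An unliganded receptor inside a tetraspanin domain binds ligand with
    probability ``k_bind·dt``; a liganded receptor inside a clathrin domain
    is removed with probability ``k_remove·dt``. Elsewhere nothing happens.
    """
    if not state.alive:
        raise ValueError("receptor has been removed")
    comp = membership(state.site, domain_map, params.dx)
    dt = params.dt
    if not state.liganded:
        if comp == TETRASPANIN and params.k_bind > 0 and rng.random() < params.k_bind * dt:
            return replace(state, liganded=True)
        return state
    if comp == CLATHRIN and params.k_remove > 0 and rng.random() < params.k_remove * dt:
        return replace(state, alive=False)
    return state


# ---------------------------------------------------------------------------
# compiled trajectory loop


def _acceptance_table(params: SimParams) -> np.ndarray:
    """acc[liganded, from, to] = Metropolis acceptance for a membership change."""
    acc = np.ones((2, 3, 3))
    for lig in (0, 1):
        for f in range(3):
            for t in range(3):
                if f != t:
                    acc[lig, f, t] = math.exp(-transition_barrier(bool(lig), f, t, params))
    return acc


_XMUL = np.uint64(2685821657736338717)  # xorshift64* output multiplier
_INV53 = 1.0 / 9007199254740992.0  # 2**-53


@njit(cache=True, inline="always")
def _xorshift(s):  # pragma: no cover
    s ^= s >> np.uint64(12)
    s ^= s << np.uint64(25)
    s ^= s >> np.uint64(27)
    return s


@njit(cache=True)
def _splitmix64(seed):  # pragma: no cover - RNG state initialisation
    z = (seed + np.uint64(0x9E3779B97F4A7C15)) & np.uint64(0xFFFFFFFFFFFFFFFF)
    z = (z ^ (z >> np.uint64(30))) * np.uint64(0xBF58476D1CE4E5B9)
    z = (z ^ (z >> np.uint64(27))) * np.uint64(0x94D049BB133111EB)
    z ^= z >> np.uint64(31)
    if z == np.uint64(0):
        z = np.uint64(0x9E3779B97F4A7C15)
    return z


@njit(cache=True)
def _run_kernel(
    gridflat,
    nbr,
    idx,
    acc,
    p_bind,
    p_remove,
    max_steps,
    stop_on_tet,
    ev_step,
    ev_comp,
    ev_lig,
    steps_in,
    seed,
):  # pragma: no cover - exercised via simulate_trajectory
    s = _splitmix64(seed)
    record = ev_step.shape[0] > 0
    lig = 0
    comp = gridflat[idx]
    bind_step = np.int64(-1)
    remove_step = np.int64(-1)
    first_tet_step = np.int64(-1)
    n_ev = 0
    if record:
        ev_step[0] = 0
        ev_comp[0] = comp
        ev_lig[0] = 0
        n_ev = 1
    overflow = False
    step = np.int64(0)
    while step < max_steps:
        # diffusion attempt: low 2 bits choose the neighbour, high bits the uniform
        s = _xorshift(s)
        r = s * _XMUL
        nidx = nbr[(idx << np.uint64(2)) | (r & np.uint64(3))]
        ncomp = gridflat[nidx]
        changed = False
        if ncomp == comp:
            idx = nidx
        else:
            a = acc[lig, comp, ncomp]
            if a >= 1.0 or float(r >> np.uint64(11)) * _INV53 < a:
                idx = nidx
                comp = ncomp
                changed = True
        # binding check
        if lig == 0:
            if comp == 1 and p_bind > 0.0:
                s = _xorshift(s)
                if float((s * _XMUL) >> np.uint64(11)) * _INV53 < p_bind:
                    lig = 1
                    bind_step = step + 1
                    changed = True
        # removal check
        elif comp == 2 and p_remove > 0.0:
            s = _xorshift(s)
            if float((s * _XMUL) >> np.uint64(11)) * _INV53 < p_remove:
                steps_in[comp, lig] += 1
                step += 1
                remove_step = step
                break
        steps_in[comp, lig] += 1
        step += 1
        if comp == 1 and first_tet_step < 0:
            first_tet_step = step
        if changed and record:
            if n_ev < ev_step.shape[0]:
                ev_step[n_ev] = step
                ev_comp[n_ev] = comp
                ev_lig[n_ev] = lig
                n_ev += 1
            else:
                overflow = True
        if stop_on_tet and comp == 1:
            break
    return step, bind_step, remove_step, first_tet_step, n_ev, overflow, idx


@njit(cache=True)
def _walk_positions_kernel(
    gridflat, nbr, n, idx, acc, lig, n_dumps, stride, out_ij, seed
):  # pragma: no cover - exercised via simulate_positions
    """Random walk dumping unwrapped (i, j) every ``stride`` steps."""
    s = _splitmix64(seed)
    comp = gridflat[idx]
    i = np.int64(idx // n)
    j = np.int64(idx % n)
    wi = np.int64(0)
    wj = np.int64(0)
    out_ij[0, 0] = i
    out_ij[0, 1] = j
    for d in range(1, n_dumps + 1):
        for _ in range(stride):
            s = _xorshift(s)
            r = s * _XMUL
            nidx = nbr[(np.uint64(i * n + j) << np.uint64(2)) | (r & np.uint64(3))]
            ncomp = gridflat[nidx]
            ok = True
            if ncomp != comp:
                a = acc[lig, comp, ncomp]
                ok = a >= 1.0 or float(r >> np.uint64(11)) * _INV53 < a
            if ok:
                ni = np.int64(nidx // n)
                nj = np.int64(nidx % n)
                if ni - i > 1:
                    wi -= 1
                elif i - ni > 1:
                    wi += 1
                if nj - j > 1:
                    wj -= 1
                elif j - nj > 1:
                    wj += 1
                i = ni
                j = nj
                comp = ncomp
        out_ij[d, 0] = wi * n + i
        out_ij[d, 1] = wj * n + j


@njit(cache=True)
def _acceptance_count(p, n_draws, seed):  # pragma: no cover - via empirical_acceptance
    s = _splitmix64(seed)
    cnt = np.int64(0)
    for _ in range(n_draws):
        s = _xorshift(s)
        if float((s * _XMUL) >> np.uint64(11)) * _INV53 < p:
            cnt += 1
    return cnt


def empirical_acceptance(dE: float, n_draws: int, seed: int = 0) -> float:
    """Empirical Metropolis acceptance rate of the engine's inline generator.

    Draws ``n_draws`` uniforms exactly as the compiled trajectory loop does
    and returns the fraction below exp(−ΔE) — the direct empirical check
    that barrier crossings occur at the Metropolis rate.
    """
    if dE < 0:
        raise ValueError("the model has no negative barriers")
    return _acceptance_count(math.exp(-dE), n_draws, np.uint64(seed)) / n_draws


def child_seeds(root_seed: int, n: int) -> np.ndarray:
    """Deterministic per-trajectory RNG seeds spawned from one root seed."""
    ss = np.random.SeedSequence(root_seed)
    return np.array([s.generate_state(1)[0] for s in ss.spawn(n)], np.uint32)


def _neighbour_table(n: int) -> np.ndarray:
    i, j = np.meshgrid(np.arange(n), np.arange(n), indexing="ij")
    nbr = np.empty((n * n, 4), np.uint32)
    nbr[:, 0] = (((i + 1) % n) * n + j).ravel()
    nbr[:, 1] = (((i - 1) % n) * n + j).ravel()
    nbr[:, 2] = (i * n + (j + 1) % n).ravel()
    nbr[:, 3] = (i * n + (j - 1) % n).ravel()
    return nbr.ravel()


def _uniform_outside_start(gridflat: np.ndarray, rng: np.random.Generator) -> int:
    outside = np.flatnonzero(gridflat == OUTSIDE)
    return int(outside[rng.integers(len(outside))])


def _events_to_intervals(
    ev_step: np.ndarray, ev_comp: np.ndarray, ev_lig: np.ndarray, n_ev: int, end_step: int, dt: float
) -> pd.DataFrame:
    starts = ev_step[:n_ev]
    ends = np.empty(n_ev, np.int64)
    ends[:-1] = starts[1:]
    ends[-1] = end_step
    keep = ends > starts  # a final event at end_step carries no duration
    return pd.DataFrame(
        {
            "t_start": starts[keep] * dt,
            "t_end": ends[keep] * dt,
            "compartment": ev_comp[:n_ev][keep],
            "liganded": ev_lig[:n_ev][keep].astype(bool),
        }
    )


def simulate_trajectory(
    params: SimParams,
    seed: int,
    domain_map: DomainMap | None = None,
    record_events: bool = True,
    stop_on_tet_entry: bool = False,
    max_events: int = 4_000_000,
) -> TrajectoryRecord:
    """Simulate one receptor from insertion to removal or censoring.

    The receptor starts unliganded at a uniformly chosen outside site on a
    freshly drawn domain placement (unless ``domain_map`` is given). The run
    ends at removal, at the censoring horizon ``params.T_max``, or — with
    ``stop_on_tet_entry`` — at the first entry into a tetraspanin domain
    (used for first-passage statistics). Bit-identical given ``seed`` and
    ``params``. With ``record_events`` the record carries the full interval
    log; residence-time totals in ``time_in`` are exact either way.
    """
    rng = np.random.default_rng(seed)
    if domain_map is None:
        domain_map = place_domains(params, rng)
    gridflat = np.ascontiguousarray(domain_map.membership_grid(params.dx).ravel())
    idx = _uniform_outside_start(gridflat, rng)
    dt = params.dt
    max_steps = int(round(params.T_max / dt))
    size = max_events if record_events else 0
    ev_step = np.empty(size, np.int64)
    ev_comp = np.empty(size, np.int8)
    ev_lig = np.empty(size, np.int8)
    steps_in = np.zeros((3, 2), np.int64)
    kernel_seed = np.uint64(rng.integers(0, 2**63))
    end_step, bind_step, remove_step, first_tet_step, n_ev, overflow, _ = _run_kernel(
        gridflat,
        _neighbour_table(params.n_side),
        np.uint64(idx),
        _acceptance_table(params),
        params.k_bind * dt,
        params.k_remove * dt,
        max_steps,
        stop_on_tet_entry,
        ev_step,
        ev_comp,
        ev_lig,
        steps_in,
        kernel_seed,
    )
    if overflow:
        raise RuntimeError("event log overflow; raise max_events or disable recording")
    intervals = None
    if record_events and end_step > 0:
        intervals = _events_to_intervals(ev_step, ev_comp, ev_lig, n_ev, end_step, dt)
    return TrajectoryRecord(
        intervals=intervals,
        time_in=steps_in * dt,
        lifetime=end_step * dt,
        censored=remove_step < 0 and not stop_on_tet_entry,
        t_bind=None if bind_step < 0 else bind_step * dt,
        t_remove=None if remove_step < 0 else remove_step * dt,
        t_first_tet=None if first_tet_step < 0 else first_tet_step * dt,
        seed=seed,
        domain_map=domain_map,
    )


def simulate_positions(
    params: SimParams,
    T: float,
    dump_interval: float = 0.05,
    seed: int = 0,
    domain_map: DomainMap | None = None,
    liganded: bool = False,
) -> np.ndarray:
    """Positions of a diffusing receptor sampled at a fixed frame interval.

    Runs the walk (no binding or removal; the fixed ligand state selects
    which barriers apply) for ``T`` seconds and returns unwrapped positions
    in μm, shape ``(n_frames + 1, 2)``, sampled every ``dump_interval``
    seconds — the analogue of a single-particle-tracking acquisition (the
    default 0.05 s matches a 20 Hz camera). Unwrapped coordinates make the
    output usable for mean-squared-displacement analysis.
    """
    if dump_interval < params.dt:
        raise ValueError("dump_interval must be at least one timestep")
    rng = np.random.default_rng(seed)
    if domain_map is None:
        domain_map = place_domains(params, rng)
    gridflat = np.ascontiguousarray(domain_map.membership_grid(params.dx).ravel())
    idx = _uniform_outside_start(gridflat, rng)
    stride = int(round(dump_interval / params.dt))
    n_dumps = int(round(T / dump_interval))
    out_ij = np.empty((n_dumps + 1, 2), np.int64)
    _walk_positions_kernel(
        gridflat,
        _neighbour_table(params.n_side),
        params.n_side,
        np.uint64(idx),
        _acceptance_table(params),
        int(liganded),
        n_dumps,
        stride,
        out_ij,
        np.uint64(rng.integers(0, 2**63)),
    )
    return out_ij * params.dx
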