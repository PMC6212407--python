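"""Stochastic simulator of convergent sense/antisense RNAPII transcription.

The locus is a 1D lattice of polymerase footprints.  Sense polymerases
initiate at site 0 and step rightward; antisense polymerases initiate at
site L-1 and step leftward.  The antisense transcription unit is short: it
covers only the distal ``anti_len`` sites of the sense unit, so an
antisense polymerase leaves the lattice (completes) after traversing its
unit, mirroring an antisense read-through transcript that terminates before
reaching far into the sense gene body.

Hard-core exclusion: at most one polymerase per site, and a polymerase may
only step into an empty site.  When a sense polymerase and an antisense
polymerase come to occupy adjacent sites facing each other, the pair stalls
(neither can move); the stall resolves at rate ``k_term``, applying the
collision rule: ``both_terminate`` removes both polymerases,
``sense_terminates`` removes only the sense polymerase (the antisense
polymerase resumes).  Stalled queues behind a collision are what produce
the characteristic pile-up of sense polymerases toward the 3' end of the
unit.

Dynamics are exact continuous-time Gillespie; all rates are per unit time
and the simulation is reproducible given its seed.  The kinetic rates are
phenomenological: the simulator makes qualitative, not quantitative,
claims.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

COLLISION_RULES = ("both_terminate", "sense_terminates")


@dataclass(frozen=True)
class LocusParams:
    L: int = 50
    k_init_sense: float = 1.0
    k_init_anti: float = 1.0
    k_elong: float = 10.0
    k_term: float = 1.0
    anti_len: int = 10
    collision_rule: str = "both_terminate"
    T: float = 100.0
    seed: int = 0

    def validate(self) -> None:
        if self.L < 2:
            raise ValueError("lattice length L must be >= 2")
        rates = (self.k_init_sense, self.k_init_anti, self.k_elong, self.k_term)
        if any(not math.isfinite(r) or r < 0 for r in rates):
            raise ValueError("rates must be finite and non-negative")
        if not 1 <= self.anti_len <= self.L:
            raise ValueError("anti_len must be in [1, L]")
        if self.collision_rule not in COLLISION_RULES:
            raise ValueError(f"unknown collision rule {self.collision_rule!r}")
        if self.T <= 0:
            raise ValueError("T must be positive")


@dataclass
class CollisionState:
    """Event counters and time-weighted occupancy of one simulation run."""

    params: LocusParams
    sense_initiated: int = 0
    sense_completed: int = 0
    sense_collided: int = 0
    anti_initiated: int = 0
    anti_completed: int = 0
    anti_collided: int = 0
    sense_resident: int = 0
    anti_resident: int = 0
    time: float = 0.0
    # rows: 0 = sense, 1 = antisense; columns: lattice sites
    occupancy_accum: np.ndarray = field(default=None)  # type: ignore[assignment]

    def check_conservation(self) -> None:
        if self.sense_initiated != (
            self.sense_completed + self.sense_collided + self.sense_resident
        ):
            raise AssertionError("sense polymerase counters do not balance")
        if self.anti_initiated != (
            self.anti_completed + self.anti_collided + self.anti_resident
        ):
            raise AssertionError("antisense polymerase counters do not balance")

    @property
    def sense_yield(self) -> float:
        """Fraction of initiated sense polymerases that produced a full-length transcript."""
        if self.sense_initiated == 0:
            return float("nan")
        return self.sense_completed / self.sense_initiated


def simulate(params: LocusParams, check_invariants: bool = False) -> CollisionState:
    """Run one exact Gillespie trajectory up to time T.

    With ``check_invariants`` the hard-core exclusion property (at most one
    polymerase per site, occupancy consistent with the polymerase lists) is
    asserted after every event; intended for tests, not production runs.
    """
    params.validate()
    L = params.L
    anti_exit = L - params.anti_len  # antisense pol stepping below this site leaves
    rng = np.random.default_rng(params.seed)

    occ = np.zeros(L, dtype=np.int8)  # 0 empty, +1 sense, -1 antisense
    stalled = np.zeros(L, dtype=bool)
    sense: list[int] = []
    anti: list[int] = []
    pairs: list[int] = []  # sense position of each stalled facing pair
    state = CollisionState(params=params, occupancy_accum=np.zeros((2, L)))
    t = 0.0

    def try_stall(i: int) -> None:
        if 0 <= i < L - 1 and occ[i] == 1 and occ[i + 1] == -1:
            stalled[i] = stalled[i + 1] = True
            pairs.append(i)

    while True:
        movable_s = [i for i in sense if not stalled[i] and (i + 1 >= L or occ[i + 1] == 0)]
        movable_a = [
            i for i in anti if not stalled[i] and (i - 1 < anti_exit or occ[i - 1] == 0)
        ]
        r_init_s = params.k_init_sense if occ[0] == 0 else 0.0
        r_init_a = params.k_init_anti if occ[L - 1] == 0 else 0.0
        r_move = params.k_elong * (len(movable_s) + len(movable_a))
        r_resolve = params.k_term * len(pairs)
        total = r_init_s + r_init_a + r_move + r_resolve
        if total == 0.0:
            dt_eff = params.T - t
            for i in sense:
                state.occupancy_accum[0, i] += dt_eff
            for i in anti:
                state.occupancy_accum[1, i] += dt_eff
            break
        dt = rng.exponential(1.0 / total)
        dt_eff = min(dt, params.T - t)
        for i in sense:
            state.occupancy_accum[0, i] += dt_eff
        for i in anti:
            state.occupancy_accum[1, i] += dt_eff
        t += dt
        if t >= params.T:
            break
        u = rng.random() * total
        if u < r_init_s:
            occ[0] = 1
            sense.append(0)
            state.sense_initiated += 1
            try_stall(0)
        elif u < r_init_s + r_init_a:
            occ[L - 1] = -1
            anti.append(L - 1)
            state.anti_initiated += 1
            try_stall(L - 2)
        elif u < r_init_s + r_init_a + r_move:
            k = int((u - r_init_s - r_init_a) / params.k_elong)
            k = min(k, len(movable_s) + len(movable_a) - 1)
            if k < len(movable_s):
                i = movable_s[k]
                sense.remove(i)
                occ[i] = 0
                if i + 1 >= L:
                    state.sense_completed += 1
                else:
                    occ[i + 1] = 1
                    sense.append(i + 1)
                    try_stall(i + 1)
            else:
                i = movable_a[k - len(movable_s)]
                anti.remove(i)
                occ[i] = 0
                if i - 1 < anti_exit:
                    state.anti_completed += 1
                else:
                    occ[i - 1] = -1
                    anti.append(i - 1)
                    try_stall(i - 2)
        else:
            k = int((u - r_init_s - r_init_a - r_move) / params.k_term)
            k = min(k, len(pairs) - 1)
            i = pairs.pop(k)
            stalled[i] = stalled[i + 1] = False
            sense.remove(i)
            occ[i] = 0
            state.sense_collided += 1
            if params.collision_rule == "both_terminate":
                anti.remove(i + 1)
                occ[i + 1] = 0
                state.anti_collided += 1
            # sense_terminates: the antisense polymerase resumes in place

        if check_invariants:
            assert len(sense) == len(set(sense)) and len(anti) == len(set(anti))
            assert not set(sense) & set(anti)
            assert sorted(sense) == sorted(np.flatnonzero(occ == 1).tolist())
            assert sorted(anti) == sorted(np.flatnonzero(occ == -1).tolist())

    state.time = params.T
    state.sense_resident = len(sense)
    state.anti_resident = len(anti)
    state.check_conservation()
    return state


def occupancy_profile(state: CollisionState) -> np.ndarray:
    """Time-averaged per-site occupancy, rows (sense, antisense); values in [0, 1]."""
    if state.time <= 0:
        raise ValueError("state has no elapsed time")
    return state.occupancy_accum / state.time


def derive_seed(master_seed: int, rep: int) -> int:
    """Deterministic per-replicate seed shared across conditions (paired seeds)."""
    ss = np.random.SeedSequence(entropy=master_seed, spawn_key=(rep,))
    return int(ss.generate_state(1)[0] % (2**31))


def yield_curve(
    base_params: LocusParams,
    anti_rates: list[float],
    reps: int = 100,
    master_seed: int = 0,
) -> pd.DataFrame:
    """Mean sense full-length yield across antisense initiation rates.

    One simulate call per (rate, rep); replicate r uses the same derived
    seed at every rate (common random numbers), so the curve is paired and
    deterministic given the master seed.
    """
    if reps < 1:
        raise ValueError("reps must be >= 1")
    rows = []
    yields = np.zeros((len(anti_rates), reps))
    for r in range(reps):
        seed = derive_seed(master_seed, r)
        for j, k_anti in enumerate(anti_rates):
            state = simulate(replace(base_params, k_init_anti=k_anti, seed=seed))
            yields[j, r] = state.sense_yield
    for j, k_anti in enumerate(anti_rates):
        rows.append(
            {
                "k_init_anti": k_anti,
                "mean_yield": float(np.mean(yields[j])),
                "sd_yield": float(np.std(yields[j], ddof=1)) if reps > 1 else 0.0,
                "reps": reps,
            }
        )
    return pd.DataFrame(rows)
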