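"""Individual-patient microsimulation of the care pathway.

Applies the same daily transition rules as the cohort model — geometric
baseline sojourns with probabilistic stage entry, per-day SWI hazard with
superficial/deep split, pause-and-resume extra stays, readmission of
out-of-hospital deep infections, in-hospital mortality — but by sampling
each patient's path instead of propagating state probabilities.  Serves
as an independent stochastic oracle: cohort-model burden outputs must
agree with microsimulation means within Monte-Carlo error.

Implementation is vectorised over patients with one pass over the daily
cycles; all branching is written directly from the calibrated parameters
(entry/exit probabilities, hazards) rather than from the cohort model's
assembled matrices.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .country_data import CountryInputRecord
from .incidence import calibrate_height, to_hazard_schedule
from .params import GlobalParams
from .pathway import (
    DSWI_H_BASE,
    GW,
    HOSPITAL_PHASES,
    ICU_MV,
    ICU_MVP,
    ICU_NOMV,
    N_BASE,
    OUT,
    P_BASE,
    S_DEAD,
    S_OUTP,
    S_READM,
    SSWI_H_BASE,
    SURG,
    SojournPlan,
    calibrate_sojourns,
    stage_probs,
)

__all__ = ["MicrosimResult", "simulate_patients"]


@dataclass
class MicrosimResult:
    """Per-patient outcome arrays from a microsimulation run."""

    n_patients: int
    swi: np.ndarray            # bool, had an SWI
    readmitted: np.ndarray     # bool, DSWI readmission
    swi_icu_days: np.ndarray   # SWI-attributable ICU days
    swi_gw_days: np.ndarray    # SWI-attributable GW days (incl. readmission)
    swi_cost: np.ndarray       # EUR, SWI-attributable

    def mean_se(self, name: str) -> tuple[float, float]:
        arr = np.asarray(getattr(self, name), dtype=float)
        return float(arr.mean()), float(arr.std(ddof=1) / np.sqrt(len(arr)))


def _sample_cascade(
    plan: SojournPlan, phase: int, n: int, rng: np.random.Generator
) -> np.ndarray:
    """Sample the next baseline phase for ``n`` patients leaving ``phase``."""
    e, f_p = plan.enter, plan.prolonged_mv_fraction
    dest = np.full(n, -1, dtype=np.int8)

    def try_enter(pending: np.ndarray, stage: int) -> np.ndarray:
        if pending.size == 0:
            return pending
        hit = rng.random(pending.size) < e[stage]
        dest[pending[hit]] = stage
        return pending[~hit]

    pending = np.arange(n)
    if phase == SURG:
        pending = try_enter(pending, ICU_MV)
        branch = rng.random(pending.size) < f_p
        left = try_enter(pending[branch], ICU_MVP)
        pending = np.concatenate([left, pending[~branch]])
        pending = try_enter(pending, ICU_NOMV)
        pending = try_enter(pending, GW)
    elif phase == ICU_MV:
        branch = rng.random(pending.size) < f_p
        left = try_enter(pending[branch], ICU_MVP)
        pending = np.concatenate([left, pending[~branch]])
        pending = try_enter(pending, ICU_NOMV)
        pending = try_enter(pending, GW)
    elif phase == ICU_MVP:
        pending = try_enter(pending, ICU_NOMV)
        pending = try_enter(pending, GW)
    elif phase == ICU_NOMV:
        pending = try_enter(pending, GW)
    elif phase == GW:
        pass
    else:
        raise ValueError(f"no successor cascade for phase {phase}")
    dest[pending] = OUT
    return dest


def simulate_patients(
    record: CountryInputRecord,
    gp: GlobalParams,
    n_patients: int,
    rng: np.random.Generator,
) -> MicrosimResult:
    """Simulate ``n_patients`` individual trajectories over the horizon."""
    horizon = gp.horizon_days
    curve = calibrate_height(
        record.swi_incidence, record.surveillance_days, (gp.hill_t50, gp.hill_n)
    )
    cap = None if gp.extrapolate_incidence else int(record.surveillance_days)
    schedule = to_hazard_schedule(
        curve, horizon, record.sswi_share, cap_day=cap
    )
    haz = schedule.hazards
    plan = calibrate_sojourns(record.mean_los_days, gp)

    m = gp.daily_mortality
    s = record.sswi_share
    e9, x9 = stage_probs(record.sswi_extra_los_days)
    e10, x10 = stage_probs(record.dswi_extra_los_days)
    readm_mu = (
        gp.readmission_los_days
        if gp.readmission_los_days is not None
        else record.dswi_extra_los_days
    )
    er, xr = stage_probs(readm_mu)
    f9 = gp.sswi_extra_icu_fraction
    f10 = gp.dswi_extra_icu_fraction

    n = int(n_patients)
    state = np.full(n, N_BASE + SURG, dtype=np.int8)
    paused = np.zeros(n, dtype=np.int8)
    swi = np.zeros(n, dtype=bool)
    readmitted = np.zeros(n, dtype=bool)
    swi_icu = np.zeros(n, dtype=np.int64)
    swi_gw = np.zeros(n, dtype=np.int64)

    naive_lo, naive_hi = N_BASE, N_BASE + 5  # naive hospital phases
    hosp_phase_set = np.zeros(25, dtype=bool)
    for p in HOSPITAL_PHASES:
        hosp_phase_set[N_BASE + p] = True
        hosp_phase_set[P_BASE + p] = True
        hosp_phase_set[SSWI_H_BASE + p] = True
        hosp_phase_set[DSWI_H_BASE + p] = True
    hosp_phase_set[S_READM] = True

    def baseline_step(idx: np.ndarray, phases: np.ndarray, layer_base: int):
        """Stay-or-leave move from baseline ``phases`` into ``layer_base``."""
        if idx.size == 0:
            return
        leave = rng.random(idx.size) < plan.exit[phases]
        stay_idx = idx[~leave]
        state[stay_idx] = layer_base + phases[~leave]
        go_idx = idx[leave]
        go_phases = phases[leave]
        for p in HOSPITAL_PHASES:
            sel = go_phases == p
            if not sel.any():
                continue
            dest = _sample_cascade(plan, p, int(sel.sum()), rng)
            state[go_idx[sel]] = layer_base + dest

    for d in range(horizon):
        # accrue SWI-attributable bed-days from the start-of-day state
        # (same convention as the cohort trace: day d occupancy, then the
        # day's boundary events)
        in_sswi = (state >= SSWI_H_BASE) & (state < SSWI_H_BASE + 5)
        in_dswi = (state >= DSWI_H_BASE) & (state < DSWI_H_BASE + 5)
        if in_sswi.any():
            icu_day = in_sswi & (rng.random(n) < f9)
            swi_icu[icu_day] += 1
            swi_gw[in_sswi & ~icu_day] += 1
        if in_dswi.any():
            icu_day = in_dswi & (rng.random(n) < f10)
            swi_icu[icu_day] += 1
            swi_gw[in_dswi & ~icu_day] += 1
        swi_gw[state == S_READM] += 1

        h = haz[d]
        state0 = state.copy()

        # 1. in-hospital mortality
        in_hosp = hosp_phase_set[state0]
        if m > 0 and in_hosp.any():
            dies = in_hosp & (rng.random(n) < m)
            state[dies] = S_DEAD
            state0_alive = ~dies
        else:
            state0_alive = np.ones(n, dtype=bool)

        # 2. SWI onset among naive survivors
        naive = (state0 >= naive_lo) & (state0 < naive_hi + 1) & state0_alive
        onset = naive & (rng.random(n) < h)
        if onset.any():
            swi[onset] = True
            sup = rng.random(n) < s
            phase0 = state0 - N_BASE
            in_hosp_onset = onset & (phase0 < OUT)
            out_onset = onset & (phase0 == OUT)

            for superficial, e_extra, base_extra in (
                (True, e9, SSWI_H_BASE),
                (False, e10, DSWI_H_BASE),
            ):
                grp = in_hosp_onset & (sup == superficial)
                if not grp.any():
                    continue
                enter = grp & (rng.random(n) < e_extra)
                state[enter] = base_extra + phase0[enter]
                paused[enter] = phase0[enter]
                resume = grp & ~enter  # zero/sub-day extra stay
                idx = np.flatnonzero(resume)
                baseline_step(idx, phase0[idx].astype(np.int8), P_BASE)

            outp = out_onset & sup
            state[outp] = S_OUTP
            readm = out_onset & ~sup
            if readm.any():
                readmitted[readm] = True
                enter = readm & (rng.random(n) < er)
                state[enter] = S_READM
                state[readm & ~enter] = P_BASE + OUT

        # 3. extra-stay process exits (patients in process at day start)
        for base_extra, x_extra in ((SSWI_H_BASE, x9), (DSWI_H_BASE, x10)):
            in_proc = (
                (state0 >= base_extra) & (state0 < base_extra + 5) & state0_alive
            )
            if not in_proc.any():
                continue
            exits = in_proc & (rng.random(n) < x_extra)
            idx = np.flatnonzero(exits)
            baseline_step(idx, paused[idx], P_BASE)

        in_readm = (state0 == S_READM) & state0_alive
        if in_readm.any():
            done = in_readm & (rng.random(n) < xr)
            state[done] = P_BASE + OUT

        state[(state0 == S_OUTP) & state0_alive] = P_BASE + OUT

        # 4. baseline moves for naive non-onset and post-layer patients
        # (out-of-hospital baseline states are absorbing while alive, so
        # only the five hospital phases of each layer need a move)
        for layer in (N_BASE, P_BASE):
            in_layer = (state0 >= layer) & (state0 < layer + 5) & state0_alive
            in_layer &= ~onset
            idx = np.flatnonzero(in_layer)
            baseline_step(idx, (state0[idx] - layer).astype(np.int8), layer)

    cost = (
        swi_icu * record.icu_day_cost
        + swi_gw * record.gw_day_cost
        + readmitted * gp.readmission_cost
    )
    return MicrosimResult(
        n_patients=n,
        swi=swi,
        readmitted=readmitted,
        swi_icu_days=swi_icu,
        swi_gw_days=swi_gw,
        swi_cost=cost.astype(float),
    )
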