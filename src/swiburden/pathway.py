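"""Daily-cycle Markov cohort model of the post-CABG care pathway.

Patients enter on the day of surgery, pass through intensive care (on
mechanical ventilation, optionally a prolonged-MV episode, then off the
ventilator), then the general ward, and are discharged.  On any day a
patient who has not yet had a sternal-wound infection can develop one
(superficial or deep, split by the country's superficial share) or die.
An in-hospital SWI adds the country's extra length of stay for that
infection type; an out-of-hospital deep SWI triggers a readmission;
out-of-hospital superficial SWIs are treated as outpatients at zero cost
(hospital perspective).

Sojourn times are geometric.  The extra stay of an SWI is modelled as
pause-and-resume: onset suspends the baseline phase, the extra-stay
process runs for its mean duration, and the patient then resumes with the
transition decision of the paused phase.  Because sojourns are memoryless
this leaves the expected infection-free stay untouched, so the additional
days attributable to the SWI equal the country's extra-LOS input exactly.

The trace separates SWI-attributable accruals (extra-stay days costed at
the ward split, readmission days and fees) from the infection-free
baseline, which is computed from an embedded companion run of the same
chain with the SWI hazard set to zero — the counterfactual cost of
post-CABG care without an infection.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .country_data import CountryDataError, CountryInputRecord
from .incidence import HazardSchedule, calibrate_height, to_hazard_schedule
from .params import GlobalParams

__all__ = [
    "PathwayState",
    "SojournPlan",
    "TransitionModel",
    "CohortTrace",
    "BurdenResult",
    "EuropeSummary",
    "calibrate_sojourns",
    "run_cohort",
    "compute_burden",
    "aggregate_europe",
]

# ---------------------------------------------------------------------------
# state space

# Within-layer phase indices of the baseline pathway.
SURG, ICU_MV, ICU_MVP, ICU_NOMV, GW, OUT = range(6)
HOSPITAL_PHASES = (SURG, ICU_MV, ICU_MVP, ICU_NOMV, GW)
ICU_PHASES = (SURG, ICU_MV, ICU_MVP, ICU_NOMV)  # surgery day counted as ICU

# Internal (expanded) state indices.  The naive layer holds patients with
# no SWI so far, the post layer patients after a resolved SWI; process
# states carry the paused baseline phase so the patient can resume it.
N_BASE = 0          # naive layer: 0..5 (phase index)
P_BASE = 6          # post layer: 6..11
SSWI_H_BASE = 12    # in-hospital SSWI extra stay, paused phase 0..4 -> 12..16
DSWI_H_BASE = 17    # in-hospital DSWI extra stay, paused phase 0..4 -> 17..21
S_READM = 22        # DSWI readmission (general ward)
S_OUTP = 23         # outpatient SSWI episode (zero cost)
S_DEAD = 24
N_STATES = 25

IN_HOSPITAL_STATES = tuple(
    list(range(N_BASE, N_BASE + 5))
    + list(range(P_BASE, P_BASE + 5))
    + list(range(SSWI_H_BASE, SSWI_H_BASE + 5))
    + list(range(DSWI_H_BASE, DSWI_H_BASE + 5))
    + [S_READM]
)


class PathwayState(enum.Enum):
    """Reported care-pathway states (aggregated over internal layers)."""

    SURGERY = "surgery"
    ICU_MV = "icu_mv"
    ICU_MV_PROLONGED = "icu_mv_prolonged"
    ICU_NO_MV = "icu_no_mv"
    GW = "gw"
    OUT_OF_HOSPITAL = "out_of_hospital"
    IN_HOSP_SSWI = "in_hosp_sswi"
    IN_HOSP_DSWI = "in_hosp_dswi"
    OUTPATIENT_SSWI = "outpatient_sswi"
    READMITTED_DSWI = "readmitted_dswi"
    DEAD = "dead"


PUBLIC_STATES: tuple[PathwayState, ...] = tuple(PathwayState)

# internal index -> position in PUBLIC_STATES
_PUBLIC_MAP = np.empty(N_STATES, dtype=int)
for _p, _pub in zip(range(6), range(6)):
    _PUBLIC_MAP[N_BASE + _p] = _pub
    _PUBLIC_MAP[P_BASE + _p] = _pub
for _p in range(5):
    _PUBLIC_MAP[SSWI_H_BASE + _p] = 6
    _PUBLIC_MAP[DSWI_H_BASE + _p] = 7
_PUBLIC_MAP[S_OUTP] = 8
_PUBLIC_MAP[S_READM] = 9
_PUBLIC_MAP[S_DEAD] = 10


# ---------------------------------------------------------------------------
# sojourn calibration

def stage_probs(mean_days: float) -> tuple[float, float]:
    """(entry probability, daily exit probability) for a target mean stay.

    Geometric sojourns cannot have a mean below one day, so sub-day targets
    are represented by probabilistic entry: enter with probability equal to
    the target and stay exactly one day.  Expected days in the stage equal
    the target exactly in both regimes.
    """
    if mean_days <= 0:
        return 0.0, 1.0
    if mean_days < 1.0:
        return float(mean_days), 1.0
    return 1.0, 1.0 / float(mean_days)


@dataclass(frozen=True)
class SojournPlan:
    """Calibrated stage entry/exit probabilities of the baseline pathway."""

    mean_los_days: float
    targets: dict  # phase index -> target mean days
    enter: np.ndarray  # per phase, entry probability (SURG always 1)
    exit: np.ndarray   # per phase, daily exit probability
    prolonged_mv_fraction: float

    def expected_los(self) -> float:
        """Closed-form expected infection-free hospital days (no death)."""
        e, x, f = self.enter, self.exit, self.prolonged_mv_fraction
        return (
            1.0
            + e[ICU_MV] / x[ICU_MV]
            + f * e[ICU_MVP] / x[ICU_MVP]
            + e[ICU_NOMV] / x[ICU_NOMV]
            + e[GW] / x[GW]
        )


def calibrate_sojourns(mean_los_days: float, gp: GlobalParams) -> SojournPlan:
    """Set geometric sojourns so the chain reproduces the country's mean LOS.

    The ICU target is ``icu_fraction_of_los * mean_los_days`` (including
    the fixed surgery day), split between ventilated and non-ventilated
    time by ``mv_fraction_of_icu``; the general ward takes the remainder.
    A prolonged-MV episode (entered with ``prolonged_mv_fraction``) doubles
    the expected ventilated time of those patients; the per-stage means are
    deflated so the cohort-average ICU time still meets the target.
    """
    if mean_los_days is None or mean_los_days < 1.0:
        raise CountryDataError(
            f"mean_los_days must be >= 1, got {mean_los_days}"
        )
    if gp.icu_fraction_of_los >= 1.0:
        raise ValueError("icu_fraction_of_los must be < 1")
    t_icu = gp.icu_fraction_of_los * mean_los_days
    r = max(t_icu - 1.0, 0.0)  # ICU time beyond the surgery day
    f_p = gp.prolonged_mv_fraction
    mu_mv = gp.mv_fraction_of_icu * r / (1.0 + f_p)
    mu_mvp = mu_mv
    mu_nomv = (1.0 - gp.mv_fraction_of_icu) * r
    mu_gw = mean_los_days - 1.0 - r

    targets = {SURG: 1.0, ICU_MV: mu_mv, ICU_MVP: mu_mvp,
               ICU_NOMV: mu_nomv, GW: mu_gw}
    enter = np.ones(6)
    exit_ = np.ones(6)
    for phase in (ICU_MV, ICU_MVP, ICU_NOMV, GW):
        enter[phase], exit_[phase] = stage_probs(targets[phase])
    return SojournPlan(
        mean_los_days=float(mean_los_days),
        targets=targets,
        enter=enter,
        exit=exit_,
        prolonged_mv_fraction=f_p,
    )


def _dist_after(plan: SojournPlan, phase: int) -> np.ndarray:
    """Distribution over the next baseline phase on leaving ``phase``.

    Encodes the care-pathway cascade SURG -> MV (-> prolonged MV) ->
    ICU-no-MV -> GW -> out, with probabilistic stage entry for sub-day
    targets (skipped stages fall through to the next one).
    """
    e, f_p = plan.enter, plan.prolonged_mv_fraction
    out = np.zeros(6)

    def enter_gw() -> np.ndarray:
        v = np.zeros(6)
        v[GW] += e[GW]
        v[OUT] += 1.0 - e[GW]
        return v

    def enter_nomv() -> np.ndarray:
        v = np.zeros(6)
        v[ICU_NOMV] += e[ICU_NOMV]
        v += (1.0 - e[ICU_NOMV]) * enter_gw()
        return v

    def enter_mvp() -> np.ndarray:
        v = np.zeros(6)
        v[ICU_MVP] += e[ICU_MVP]
        v += (1.0 - e[ICU_MVP]) * enter_nomv()
        return v

    if phase == SURG:
        after_mv = f_p * enter_mvp() + (1.0 - f_p) * enter_nomv()
        out[ICU_MV] += e[ICU_MV]
        out += (1.0 - e[ICU_MV]) * after_mv
    elif phase == ICU_MV:
        out += f_p * enter_mvp() + (1.0 - f_p) * enter_nomv()
    elif phase == ICU_MVP:
        out += enter_nomv()
    elif phase == ICU_NOMV:
        out += enter_gw()
    elif phase == GW:
        out[OUT] = 1.0
    else:
        raise ValueError(f"no successor cascade for phase {phase}")
    return out


def baseline_row(plan: SojournPlan, phase: int) -> np.ndarray:
    """One-day transition row of the baseline pathway, within a layer."""
    row = np.zeros(6)
    if phase == OUT:
        row[OUT] = 1.0
        return row
    x = plan.exit[phase]
    row[phase] += 1.0 - x
    row += x * _dist_after(plan, phase)
    return row


# ---------------------------------------------------------------------------
# transition model

@dataclass
class TransitionModel:
    """Time-varying daily transition matrices ``M(d) = M0 + h(d) * M1``.

    ``M0`` is the row-stochastic matrix with zero SWI hazard; ``M1`` is the
    (row-sum-zero) hazard sensitivity, so ``M0 + h*M1`` is row-stochastic
    for any hazard ``h`` in [0, 1].
    """

    M0: np.ndarray
    M1: np.ndarray
    hazards: np.ndarray  # h(1..horizon)
    state_names: Sequence[str] = field(
        default_factory=lambda: _internal_state_names()
    )

    def matrix(self, day: int) -> np.ndarray:
        """Transition matrix applied at the boundary into ``day`` (1-based)."""
        if not 1 <= day <= len(self.hazards):
            raise ValueError(f"day must be in 1..{len(self.hazards)}")
        return self.M0 + self.hazards[day - 1] * self.M1


def _internal_state_names() -> list[str]:
    phases = ["surgery", "icu_mv", "icu_mv_prolonged", "icu_no_mv", "gw", "out"]
    names = [f"naive:{p}" for p in phases] + [f"post:{p}" for p in phases]
    names += [f"sswi_h@{p}" for p in phases[:5]]
    names += [f"dswi_h@{p}" for p in phases[:5]]
    names += ["readmitted_dswi", "outpatient_sswi", "dead"]
    return names


def build_transition_model(
    record: CountryInputRecord,
    gp: GlobalParams,
    plan: SojournPlan,
    schedule: HazardSchedule,
) -> TransitionModel:
    """Assemble the expanded-state daily transition matrices."""
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

    M0 = np.zeros((N_STATES, N_STATES))
    M1 = np.zeros((N_STATES, N_STATES))

    def layer_row(phase: int, base: int) -> np.ndarray:
        full = np.zeros(N_STATES)
        full[base:base + 6] = baseline_row(plan, phase)
        return full

    # naive hospital phases: mortality, then SWI onset, else baseline move
    for p in HOSPITAL_PHASES:
        naive_move = layer_row(p, N_BASE)
        post_move = layer_row(p, P_BASE)
        onset = np.zeros(N_STATES)
        onset[SSWI_H_BASE + p] += s * e9
        onset += s * (1.0 - e9) * post_move
        onset[DSWI_H_BASE + p] += (1.0 - s) * e10
        onset += (1.0 - s) * (1.0 - e10) * post_move
        M0[N_BASE + p] = (1.0 - m) * naive_move
        M0[N_BASE + p, S_DEAD] = m
        M1[N_BASE + p] = (1.0 - m) * (onset - naive_move)

    # naive out of hospital: no mortality; onset -> outpatient or readmission
    M0[N_BASE + OUT, N_BASE + OUT] = 1.0
    onset_out = np.zeros(N_STATES)
    onset_out[S_OUTP] = s
    onset_out[S_READM] = (1.0 - s) * er
    onset_out[P_BASE + OUT] = (1.0 - s) * (1.0 - er)
    M1[N_BASE + OUT] = onset_out
    M1[N_BASE + OUT, N_BASE + OUT] -= 1.0

    # post layer: baseline pathway only
    for p in HOSPITAL_PHASES:
        M0[P_BASE + p] = (1.0 - m) * layer_row(p, P_BASE)
        M0[P_BASE + p, S_DEAD] = m
    M0[P_BASE + OUT, P_BASE + OUT] = 1.0

    # in-hospital extra-stay processes: on exit, resume the transition
    # decision of the paused phase (post layer)
    for p in HOSPITAL_PHASES:
        post_move = layer_row(p, P_BASE)
        row = np.zeros(N_STATES)
        row[SSWI_H_BASE + p] = (1.0 - m) * (1.0 - x9)
        row += (1.0 - m) * x9 * post_move
        row[S_DEAD] = m
        M0[SSWI_H_BASE + p] = row
        row = np.zeros(N_STATES)
        row[DSWI_H_BASE + p] = (1.0 - m) * (1.0 - x10)
        row += (1.0 - m) * x10 * post_move
        row[S_DEAD] = m
        M0[DSWI_H_BASE + p] = row

    M0[S_READM, S_READM] = (1.0 - m) * (1.0 - xr)
    M0[S_READM, P_BASE + OUT] = (1.0 - m) * xr
    M0[S_READM, S_DEAD] = m

    M0[S_OUTP, P_BASE + OUT] = 1.0
    M0[S_DEAD, S_DEAD] = 1.0

    assert np.allclose(M0.sum(axis=1), 1.0, atol=1e-12)
    assert np.allclose(M1.sum(axis=1), 0.0, atol=1e-12)
    return TransitionModel(M0=M0, M1=M1, hazards=schedule.hazards)


# ---------------------------------------------------------------------------
# cohort trace

@dataclass
class CohortTrace:
    """Daily occupancy and cumulative accruals for a unit cohort.

    All accrual arrays are cumulative over days 1..horizon and expressed
    per patient entering surgery.  Bed-day accruals attributable to SWIs
    (extra-stay and readmission days) are kept separate from the
    infection-free baseline, which comes from the embedded hazard-zero
    companion run.
    """

    horizon: int
    occupancy: np.ndarray          # (horizon, N_STATES) joint run
    baseline_occupancy: np.ndarray  # (horizon, N_STATES) hazard-zero run
    swi_icu_days: np.ndarray
    swi_gw_days: np.ndarray
    baseline_icu_days: np.ndarray
    baseline_gw_days: np.ndarray
    readmission_fees: np.ndarray   # EUR per patient, cumulative
    readmissions: np.ndarray       # events per patient, cumulative
    swi_events: np.ndarray         # all onsets, cumulative
    sswi_in_events: np.ndarray
    dswi_in_events: np.ndarray
    sswi_out_events: np.ndarray
    dswi_out_events: np.ndarray

    def public_occupancy(self) -> pd.DataFrame:
        """Occupancy aggregated to the reported care-pathway states."""
        agg = np.zeros((self.horizon, len(PUBLIC_STATES)))
        for internal in range(N_STATES):
            agg[:, _PUBLIC_MAP[internal]] += self.occupancy[:, internal]
        return pd.DataFrame(
            agg,
            index=pd.RangeIndex(1, self.horizon + 1, name="day"),
            columns=[st.value for st in PUBLIC_STATES],
        )

    @property
    def total_swi_icu_days(self) -> float:
        return float(self.swi_icu_days[-1])

    @property
    def total_swi_gw_days(self) -> float:
        return float(self.swi_gw_days[-1])

    @property
    def total_baseline_icu_days(self) -> float:
        return float(self.baseline_icu_days[-1])

    @property
    def total_baseline_gw_days(self) -> float:
        return float(self.baseline_gw_days[-1])

    @property
    def total_readmission_fees(self) -> float:
        return float(self.readmission_fees[-1])

    @property
    def total_readmissions(self) -> float:
        return float(self.readmissions[-1])

    @property
    def total_swi_events(self) -> float:
        return float(self.swi_events[-1])


def run_cohort(
    record: CountryInputRecord,
    gp: GlobalParams,
    hazard_schedule: Optional[HazardSchedule] = None,
) -> CohortTrace:
    """Propagate a unit cohort through the care pathway for the horizon.

    The record must be fully specified (no missing inputs).  A hazard
    schedule is built from the country's calibrated incidence curve unless
    one is supplied; a supplied schedule shorter than the horizon is an
    error.
    """
    if not record.is_complete:
        missing = [f for f in
                   ("population", "cabg_rate_per_100k", "mean_los_days",
                    "icu_day_cost", "gw_day_cost", "swi_incidence",
                    "surveillance_days", "sswi_share", "sswi_extra_los_days",
                    "dswi_extra_los_days")
                   if getattr(record, f) is None]
        raise CountryDataError(
            f"{record.country_id}: record not fully imputed; missing {missing}"
        )
    horizon = gp.horizon_days
    if hazard_schedule is None:
        curve = calibrate_height(
            record.swi_incidence,
            record.surveillance_days,
            (gp.hill_t50, gp.hill_n),
        )
        cap = None if gp.extrapolate_incidence else int(record.surveillance_days)
        hazard_schedule = to_hazard_schedule(
            curve, horizon, record.sswi_share, cap_day=cap
        )
    elif hazard_schedule.horizon < horizon:
        raise ValueError(
            f"hazard schedule covers {hazard_schedule.horizon} days, "
            f"horizon is {horizon}"
        )

    plan = calibrate_sojourns(record.mean_los_days, gp)
    model = build_transition_model(record, gp, plan, hazard_schedule)
    M0, M1 = model.M0, model.M1
    haz = hazard_schedule.hazards
    m = gp.daily_mortality
    s = record.sswi_share
    f9 = gp.sswi_extra_icu_fraction
    f10 = gp.dswi_extra_icu_fraction
    fee = gp.readmission_cost

    occ = np.zeros((horizon, N_STATES))
    base_occ = np.zeros((horizon, N_STATES))
    daily = {k: np.zeros(horizon) for k in (
        "swi_icu", "swi_gw", "b_icu", "b_gw", "fees", "readm",
        "ev", "sswi_in", "dswi_in", "sswi_out", "dswi_out")}

    naive_hosp = [N_BASE + p for p in HOSPITAL_PHASES]
    sswi_states = slice(SSWI_H_BASE, SSWI_H_BASE + 5)
    dswi_states = slice(DSWI_H_BASE, DSWI_H_BASE + 5)
    icu_states = [N_BASE + p for p in ICU_PHASES]

    # Day-d occupancy is the state at the start of day d (day 1: everyone
    # in surgery); the day's boundary then applies mortality, SWI onset
    # with hazard h(d), and the pathway transitions, yielding day d+1.
    o = np.zeros(N_STATES)
    o[N_BASE + SURG] = 1.0
    b = o.copy()
    for d in range(horizon):
        occ[d] = o
        base_occ[d] = b
        sswi_occ = o[sswi_states].sum()
        dswi_occ = o[dswi_states].sum()
        daily["swi_icu"][d] = f9 * sswi_occ + f10 * dswi_occ
        daily["swi_gw"][d] = (
            (1.0 - f9) * sswi_occ + (1.0 - f10) * dswi_occ + o[S_READM]
        )
        daily["b_icu"][d] = b[icu_states].sum()
        daily["b_gw"][d] = b[N_BASE + GW]

        h = haz[d]
        ev_in = h * (1.0 - m) * o[naive_hosp].sum()
        ev_out = h * o[N_BASE + OUT]
        daily["ev"][d] = ev_in + ev_out
        daily["sswi_in"][d] = s * ev_in
        daily["dswi_in"][d] = (1.0 - s) * ev_in
        daily["sswi_out"][d] = s * ev_out
        daily["dswi_out"][d] = (1.0 - s) * ev_out
        daily["readm"][d] = (1.0 - s) * ev_out
        daily["fees"][d] = fee * (1.0 - s) * ev_out

        o = o @ M0 + h * (o @ M1)
        b = b @ M0

    return CohortTrace(
        horizon=horizon,
        occupancy=occ,
        baseline_occupancy=base_occ,
        swi_icu_days=np.cumsum(daily["swi_icu"]),
        swi_gw_days=np.cumsum(daily["swi_gw"]),
        baseline_icu_days=np.cumsum(daily["b_icu"]),
        baseline_gw_days=np.cumsum(daily["b_gw"]),
        readmission_fees=np.cumsum(daily["fees"]),
        readmissions=np.cumsum(daily["readm"]),
        swi_events=np.cumsum(daily["ev"]),
        sswi_in_events=np.cumsum(daily["sswi_in"]),
        dswi_in_events=np.cumsum(daily["dswi_in"]),
        sswi_out_events=np.cumsum(daily["sswi_out"]),
        dswi_out_events=np.cumsum(daily["dswi_out"]),
    )


# ---------------------------------------------------------------------------
# burden outputs

@dataclass
class BurdenResult:
    """Annual SWI-attributable burden for one country."""

    country_id: str
    n_cabg: float
    total_swi_cost: float
    extra_icu_days: float
    extra_gw_days: float
    n_readmissions: float
    cost_per_swi: float  # NaN when no SWI mass was realised
    cost_per_swi_defined: bool
    baseline_cost: float
    relative_increase: float
    swi_incidence: float
    realised_swi_proportion: float

    def to_dict(self) -> dict:
        return {
            "country_id": self.country_id,
            "n_cabg": self.n_cabg,
            "total_swi_cost": self.total_swi_cost,
            "extra_icu_days": self.extra_icu_days,
            "extra_gw_days": self.extra_gw_days,
            "n_readmissions": self.n_readmissions,
            "cost_per_swi": self.cost_per_swi,
            "cost_per_swi_defined": self.cost_per_swi_defined,
            "baseline_cost": self.baseline_cost,
            "relative_increase": self.relative_increase,
            "swi_incidence": self.swi_incidence,
            "realised_swi_proportion": self.realised_swi_proportion,
        }


def compute_burden(trace: CohortTrace, record: CountryInputRecord) -> BurdenResult:
    """Scale per-patient accruals to the country's annual procedure volume."""
    n_cabg = record.population * record.cabg_rate_per_100k / 100_000.0
    pp_swi_cost = (
        trace.total_swi_icu_days * record.icu_day_cost
        + trace.total_swi_gw_days * record.gw_day_cost
        + trace.total_readmission_fees
    )
    pp_baseline_cost = (
        trace.total_baseline_icu_days * record.icu_day_cost
        + trace.total_baseline_gw_days * record.gw_day_cost
    )
    realised = trace.total_swi_events
    if realised > 0:
        cost_per_swi = pp_swi_cost / realised
        defined = True
    else:
        cost_per_swi = float("nan")
        defined = False
    total_swi_cost = pp_swi_cost * n_cabg
    baseline_cost = pp_baseline_cost * n_cabg
    return BurdenResult(
        country_id=record.country_id,
        n_cabg=n_cabg,
        total_swi_cost=total_swi_cost,
        extra_icu_days=trace.total_swi_icu_days * n_cabg,
        extra_gw_days=trace.total_swi_gw_days * n_cabg,
        n_readmissions=trace.total_readmissions * n_cabg,
        cost_per_swi=cost_per_swi,
        cost_per_swi_defined=defined,
        baseline_cost=baseline_cost,
        relative_increase=(
            total_swi_cost / baseline_cost if baseline_cost > 0 else 0.0
        ),
        swi_incidence=record.swi_incidence,
        realised_swi_proportion=realised,
    )


@dataclass
class EuropeSummary:
    """Cross-country aggregate of per-country burden results."""

    n_countries: int
    total_swi_cost: float
    extra_icu_days: float
    extra_gw_days: float
    n_readmissions: float
    swi_incidence_median: float
    swi_incidence_iqr: tuple[float, float]
    relative_increase_median: float
    relative_increase_iqr: tuple[float, float]

    def to_dict(self) -> dict:
        return {
            "n_countries": self.n_countries,
            "total_swi_cost": self.total_swi_cost,
            "extra_icu_days": self.extra_icu_days,
            "extra_gw_days": self.extra_gw_days,
            "n_readmissions": self.n_readmissions,
            "swi_incidence_median": self.swi_incidence_median,
            "swi_incidence_iqr": list(self.swi_incidence_iqr),
            "relative_increase_median": self.relative_increase_median,
            "relative_increase_iqr": list(self.relative_increase_iqr),
        }


def aggregate_europe(results: Sequence[BurdenResult]) -> EuropeSummary:
    """Sum absolute burden outputs and summarise rates across countries."""
    if len(results) == 0:
        raise ValueError("need at least one country result to aggregate")
    inc = np.array([r.swi_incidence for r in results])
    rel = np.array([r.relative_increase for r in results])
    return EuropeSummary(
        n_countries=len(results),
        total_swi_cost=float(sum(r.total_swi_cost for r in results)),
        extra_icu_days=float(sum(r.extra_icu_days for r in results)),
        extra_gw_days=float(sum(r.extra_gw_days for r in results)),
        n_readmissions=float(sum(r.n_readmissions for r in results)),
        swi_incidence_median=float(np.median(inc)),
        swi_incidence_iqr=(
            float(np.percentile(inc, 25)),
            float(np.percentile(inc, 75)),
        ),
        relative_increase_median=float(np.median(rel)),
        relative_increase_iqr=(
            float(np.percentile(rel, 25)),
            float(np.percentile(rel, 75)),
        ),
    )
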