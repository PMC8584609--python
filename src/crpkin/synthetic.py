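"""Seeded synthetic cohorts of postoperative CRP trajectories.

No patient-level data are distributed with this package, so the
generator emulates the statistical structure the analysis assumes: a
postoperative CRP peak near day 2-4, a one-phase exponential decay back
toward a plateau, sparse sampling (draws every ~2.4 days), covariate
distributions matched to the published cohort summaries, an infection
prevalence of 8/708, and infection-specific features (a secondary CRP
peak around day 8, late elevation from day 10, failure to decline).

CRP quantities are drawn log-normally (they are positive and strongly
right-skewed: cohort SDs are of the same order as the means),
moment-matched to the published mean/SD.  All randomness flows through
one ``numpy`` generator, so a spec plus a seed reproduces a cohort
byte-identically.

:func:`generate_worked_fixture` builds the deterministic eight-patient
infection cohort whose peaks, assessment-day values and
failure-to-decline verdicts match the published per-patient worked
example.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .cohort import CohortTable, CrpSeries, PatientRecord
from .kinetics import PUBLISHED_DECAY, DecayModel

__all__ = [
    "SyntheticCohortSpec",
    "generate_cohort",
    "generate_worked_fixture",
]


def _lognormal_params(mean: float, sd: float) -> tuple[float, float]:
    """(mu, sigma) of a log-normal with the given moments."""
    var = sd**2
    sigma2 = np.log(1.0 + var / mean**2)
    mu = np.log(mean) - sigma2 / 2.0
    return mu, float(np.sqrt(sigma2))


@dataclass(frozen=True)
class SyntheticCohortSpec:
    """All generator parameters; defaults mirror the published cohort.

    Group-specific pairs are (non-infected, infected).  Means/SDs are in
    the units of the quantity (mg/L for CRP, years, kg/m2, days).
    """

    n_patients: int = 708
    infection_prevalence: float = 8 / 708
    # sampling schedule
    sampling_interval_mean: float = 2.43
    sampling_interval_sd: float = 0.92
    # trajectory shape
    peak_days: tuple[int, ...] = (2, 3, 4)
    peak_day_weights: tuple[float, ...] = (0.25, 0.5, 0.25)
    peak_value_mean: tuple[float, float] = (97.60, 143.38)
    peak_value_sd: tuple[float, float] = (60.95, 72.31)
    preop_crp_mean: float = 13.07
    preop_crp_sd: float = 25.90
    decay: DecayModel = PUBLISHED_DECAY
    noise_cv: float = 0.15
    crp_floor: float = 0.5
    # infected-pattern parameters
    second_peak_prob: float = 0.50
    second_peak_day_mean: float = 8.25
    second_peak_day_sd: float = 3.20
    second_peak_amplitude: tuple[float, float] = (0.5, 0.9)
    second_peak_width_days: tuple[int, int] = (3, 5)
    late_elevation_from_day: int = 10
    late_elevation_multiplier: float = 1.8
    # covariates
    age_mean: float = 71.18
    age_sd: float = 11.92
    bmi_mean: float = 27.08
    bmi_sd: float = 5.40
    p_male: tuple[float, float] = (0.4486, 0.875)
    approach_weights: tuple[float, ...] = (0.5086, 0.4071, 0.0471, 0.0, 0.0014, 0.0029)
    p_trauma: tuple[float, float] = (0.3429, 0.375)
    days_until_surgery_mean: tuple[float, float] = (1.66, 3.38)
    days_until_surgery_sd: tuple[float, float] = (3.19, 5.01)
    postop_stay_mean: tuple[float, float] = (10.30, 25.86)
    postop_stay_sd: tuple[float, float] = (4.25, 20.95)

    def __post_init__(self) -> None:
        if self.n_patients <= 0:
            raise ValueError("n_patients must be positive")
        if not 0 <= self.infection_prevalence <= 1:
            raise ValueError("infection_prevalence must lie in [0, 1]")
        for name in ("second_peak_prob",):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must lie in [0, 1]")
        if any(w < 0 for w in self.approach_weights) or sum(self.approach_weights) <= 0:
            raise ValueError("approach_weights must be non-negative and not all zero")
        for name in (
            "sampling_interval_mean", "preop_crp_mean", "preop_crp_sd",
            "peak_value_mean", "peak_value_sd", "age_sd", "bmi_sd",
        ):
            v = getattr(self, name)
            vals = v if isinstance(v, tuple) else (v,)
            if any(x <= 0 for x in vals):
                raise ValueError(f"{name} must be positive")
        if self.noise_cv < 0:
            raise ValueError("noise_cv must be >= 0")


def _truncated_normal(rng, mean, sd, lo, hi=np.inf) -> float:
    for _ in range(1000):
        v = rng.normal(mean, sd)
        if lo <= v <= hi:
            return float(v)
    return float(min(max(lo, mean), hi))


def _latent_crp(
    day: float,
    baseline: float,
    peak_day: int,
    peak_value: float,
    decay: DecayModel,
    bumps: list[tuple[float, float, float]],
    late_from: float,
    late_mult: float,
    infected: bool,
) -> float:
    """Noise-free CRP at a given day.

    The decay branch is peak * f(x)/f(0) so the latent maximum equals the
    drawn peak value exactly (the drawn value emulates the *observed*
    postoperative maximum) and the curve is continuous at the peak day.
    """
    f0 = decay.span + decay.plateau
    if day <= 0:
        value = baseline
    elif day < peak_day:
        value = baseline + (peak_value - baseline) * day / peak_day
    else:
        x = day - peak_day
        value = peak_value * (
            decay.span * np.exp(-decay.rate_k * x) + decay.plateau
        ) / f0
    if infected:
        for center, half_width, amplitude in bumps:
            dist = abs(day - center)
            if dist < half_width:
                value += amplitude * (1.0 - dist / half_width)
        if day >= late_from:
            value *= late_mult
    return float(value)


def _sampling_days(rng, spec: SyntheticCohortSpec, last_day: int, peak_day: int) -> list[int]:
    """Integer draw days: one preop day, first postop draw day 1 or 2,
    then cumulated ~N(interval) gaps until discharge.

    The peak day itself is always drawn (labs are taken daily in the
    first postoperative days, and peak-normalization needs the maximum
    to be observed)."""
    days = [-1, int(rng.integers(1, 3))]
    while True:
        gap = max(1.0, rng.normal(spec.sampling_interval_mean, spec.sampling_interval_sd))
        nxt = int(round(days[-1] + gap))
        if nxt > last_day:
            break
        if nxt > days[-1]:
            days.append(nxt)
    if peak_day <= last_day and peak_day not in days:
        # snap the closest postoperative draw onto the peak day so the
        # draw count (and hence the mean sampling interval) is preserved
        postop = [d for d in days if d >= 1]
        closest = min(postop, key=lambda d: (abs(d - peak_day), d))
        days = sorted(set(days) - {closest} | {peak_day})
    return days


def generate_cohort(spec: SyntheticCohortSpec, seed: int) -> CohortTable:
    """Draw a full synthetic cohort, reproducible from (spec, seed)."""
    rng = np.random.default_rng(seed)
    aw = np.asarray(spec.approach_weights, dtype=float)
    aw = aw / aw.sum()
    records: list[PatientRecord] = []
    series: dict[str, CrpSeries] = {}

    for i in range(spec.n_patients):
        pid = f"P{i + 1:04d}"
        infected = bool(rng.random() < spec.infection_prevalence)
        g = 1 if infected else 0

        sex = 1 if rng.random() < spec.p_male[g] else 2
        age = _truncated_normal(rng, spec.age_mean, spec.age_sd, 18.001, 100)
        bmi = _truncated_normal(rng, spec.bmi_mean, spec.bmi_sd, 14, 60)
        approach = int(rng.choice(np.arange(1, 7), p=aw))
        trauma = bool(rng.random() < spec.p_trauma[g])
        days_until = max(
            0.0, rng.normal(spec.days_until_surgery_mean[g], spec.days_until_surgery_sd[g])
        )
        stay = float(round(_truncated_normal(
            rng, spec.postop_stay_mean[g], spec.postop_stay_sd[g], 4, 120
        )))

        mu_b, s_b = _lognormal_params(spec.preop_crp_mean, spec.preop_crp_sd)
        baseline = float(rng.lognormal(mu_b, s_b))
        mu_p, s_p = _lognormal_params(spec.peak_value_mean[g], spec.peak_value_sd[g])
        peak_value = float(rng.lognormal(mu_p, s_p))
        peak_value = max(peak_value, baseline + 1.0)
        peak_day = int(rng.choice(spec.peak_days, p=spec.peak_day_weights))

        bumps: list[tuple[float, float, float]] = []
        if infected and rng.random() < spec.second_peak_prob:
            center = _truncated_normal(
                rng, spec.second_peak_day_mean, spec.second_peak_day_sd,
                peak_day + 2, stay,
            )
            width = rng.integers(
                spec.second_peak_width_days[0], spec.second_peak_width_days[1] + 1
            )
            amplitude = rng.uniform(*spec.second_peak_amplitude) * peak_value
            # bump height on top of the decayed curve, capped below the peak
            x = center - peak_day
            under = peak_value * (
                spec.decay.span * np.exp(-spec.decay.rate_k * x) + spec.decay.plateau
            ) / (spec.decay.span + spec.decay.plateau)
            amplitude = min(amplitude, 0.95 * peak_value - under)
            if amplitude > 0:
                bumps.append((round(center), width / 2.0, amplitude))

        days = _sampling_days(rng, spec, stay, peak_day)
        values = []
        for d in days:
            latent = _latent_crp(
                d, baseline, peak_day, peak_value, spec.decay, bumps,
                spec.late_elevation_from_day, spec.late_elevation_multiplier,
                infected,
            )
            if spec.noise_cv > 0:
                mu_n, s_n = _lognormal_params(1.0, spec.noise_cv)
                latent *= rng.lognormal(mu_n, s_n)
            values.append(max(latent, spec.crp_floor))

        records.append(PatientRecord(
            patient_id=pid, age=age, sex=sex, bmi=bmi, approach=approach,
            indication_trauma=trauma, days_until_surgery=round(days_until, 2),
            postop_days_in_hospital=stay, infection=infected,
            organism="S. aureus" if infected else None,
        ))
        series[pid] = CrpSeries.from_pairs(pid, zip(days, values))

    return CohortTable(records=records, series=series)


# ---------------------------------------------------------------------------
# deterministic worked fixture


#: (peak_day, peak_mg_L, organism, second_peak_day, ftd_assessment_day,
#:  observed CRP at the assessment day or None)
_WORKED_PATIENTS = [
    (11, 256.4, "S. aureus", None, 4, None),
    (6, 91.5, "S. aureus", None, 4, None),
    (6, 105.1, "P. aeroginosa", None, 4, 96.60),
    (6, 63.4, "S. aureus", None, 4, None),
    (1, 139.1, "S. aureus", None, 4, 28.30),
    (5, 74.6, "Staphylococcus saccharolyticus", None, 3, 68.9),
    (14, 203.2, "Enterococcus", 11, 4, None),
    (1, 213.7, "P. aeroginosa", None, 4, 129.50),
]


def generate_worked_fixture() -> CohortTable:
    """The deterministic eight-patient infection cohort.

    Each patient's postoperative maximum sits at the published peak day
    and value; the published observed CRPs are placed exactly at the
    failure-to-decline assessment days, and patients without a published
    observation follow the cohort decay curve there (declining
    normally).  Patient 7 carries a secondary local peak at day 11 that
    precedes its primary maximum at day 14.
    """
    decay = PUBLISHED_DECAY
    records: list[PatientRecord] = []
    series: dict[str, CrpSeries] = {}
    for i, (peak_day, peak, organism, second_day, x_assess, observed) in enumerate(
        _WORKED_PATIENTS
    ):
        pid = f"W{i + 1}"
        f = lambda x: decay.span * np.exp(-decay.rate_k * x) + decay.plateau
        pts: dict[int, float] = {-1: 8.0}
        if peak_day > 1:
            pts[1] = round(0.45 * peak, 1)
        pts[peak_day] = peak
        # post-peak course: pure cohort decay, or - when a published
        # observation exists - a monotone decline through it (geometric
        # interpolation peak -> observed, then decay-shaped continuation),
        # so the override never manufactures an extra local peak
        for x in range(1, 8):
            d = peak_day + x
            if observed is None:
                pts[d] = round(peak * f(x), 1)
            elif x < x_assess:
                pts[d] = round(peak * (observed / peak) ** (x / x_assess), 1)
            elif x == x_assess:
                pts[d] = observed
            else:
                pts[d] = round(observed * f(x) / f(x_assess), 1)
        if second_day is not None:
            # secondary local maximum below the primary peak
            pts[second_day] = round(0.80 * peak, 1)
            pts[second_day - 1] = round(0.55 * peak, 1)
            pts[second_day + 1] = round(0.60 * peak, 1)
            # rebuild the primary maximum after the overrides
            pts[peak_day] = peak
        series[pid] = CrpSeries.from_pairs(pid, pts)
        records.append(PatientRecord(
            patient_id=pid, age=68.0, sex=1 if i < 7 else 2, bmi=27.6,
            approach=2 if i % 2 else 1, indication_trauma=bool(i % 3 == 0),
            days_until_surgery=3.0, postop_days_in_hospital=26.0,
            infection=True, organism=organism,
        ))
    return CohortTable(records=records, series=series)
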