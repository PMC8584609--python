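"""Per-patient feature derivation bridging raw series and the risk scores."""

from __future__ import annotations

import pandas as pd

from .cohort import CohortTable, CrpSeries, DerivedFeatures, PatientRecord, postoperative_subseries
from .kinetics import (
    PUBLISHED_DECAY,
    DecayModel,
    FailureToDeclineRule,
    detect_peaks,
    failure_to_decline,
)
from .scoring import RiskFeatures

__all__ = ["compute_derived_features", "risk_features", "features_frame"]


def compute_derived_features(
    series: CrpSeries,
    model: DecayModel = PUBLISHED_DECAY,
    rule: FailureToDeclineRule = FailureToDeclineRule(),
) -> DerivedFeatures:
    """Kinetic features of one patient: preop summaries, peak, second
    peak, failure-to-decline flags at 3 and 4 days after the peak."""
    preop = [m.value for m in series if m.day < 0]
    post = postoperative_subseries(series)
    peaks = detect_peaks(post)
    ftd = failure_to_decline(post, model, rule)
    return DerivedFeatures(
        crp_preop_mean=sum(preop) / len(preop) if preop else 0.0,
        crp_preop_max=max(preop) if preop else 0.0,
        crp_post_max=peaks.primary_peak[1],
        crp_post_max_day=peaks.primary_peak[0],
        second_peak=peaks.has_second_peak,
        second_peak_day=peaks.second_peak[0] if peaks.second_peak else None,
        failure_to_decline_d3=ftd[3].failed if 3 in ftd else False,
        failure_to_decline_d4=ftd[4].failed if 4 in ftd else False,
    )


def risk_features(record: PatientRecord, derived: DerivedFeatures) -> RiskFeatures:
    """Combine covariates and kinetic features into a score input."""
    return RiskFeatures(
        second_peak=int(derived.second_peak),
        crp_max=derived.crp_post_max,
        crp_max_day=derived.crp_post_max_day,
        bmi=record.bmi,
        sex=record.sex,
        crp_preop_mean=derived.crp_preop_mean,
        approach=record.approach,
        failure_to_decline_d4=int(derived.failure_to_decline_d4),
    )


def features_frame(
    cohort: CohortTable,
    model: DecayModel = PUBLISHED_DECAY,
    rule: FailureToDeclineRule = FailureToDeclineRule(),
) -> pd.DataFrame:
    """Score-ready feature table for a whole cohort.

    Patients without any postoperative measurement are skipped.
    """
    rows = []
    for record in cohort.records:
        post = postoperative_subseries(cohort.series[record.patient_id])
        if len(post) == 0:
            continue
        d = compute_derived_features(cohort.series[record.patient_id], model, rule)
        rf = risk_features(record, d)
        rows.append({"patient_id": record.patient_id, "infection": int(record.infection),
                     **rf.as_dict()})
    return pd.DataFrame(rows)
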