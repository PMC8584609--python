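"""Infection prediction scores and ROC analysis.

Three published predictors of early acute periprosthetic joint infection
after primary hip arthroplasty are provided as fixed linear scores:

* a single-variable cut-off on the maximum postoperative CRP
  (infection if CRP max > 91.20 mg/L);
* a binary-logistic-regression score over six features
  (cut-off > -4.725);
* a "multinomial"-logistic-regression score over five features
  (cut-off > -8.566).  With a binary outcome the multinomial model
  collapses to a single linear score, which is what is implemented;
  the published name is kept only in the model identifier.

Every classifier is oriented "score strictly greater than cut-off means
infection".  ROC analysis sweeps thresholds at midpoints between
consecutive unique scores (plus infinite endpoints) and integrates by
the trapezoid rule; the rank-statistic identity AUC = U / (n1*n0) is
exposed separately as an internal cross-check.

Logistic refitting (for new cohorts) is delegated to statsmodels
maximum likelihood, with an optional likelihood-ratio backward
elimination; the original SPSS "backward conditional" selection is
approximated, not reproduced.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from typing import Mapping, Optional, Sequence

import numpy as np
import statsmodels.api as sm
from scipy import stats

__all__ = [
    "RiskFeatures",
    "LinearScore",
    "RocResult",
    "LogisticFitReport",
    "ScoringError",
    "PUBLISHED_BINARY",
    "PUBLISHED_MULTINOMIAL",
    "CRP_MAX_CUTOFF",
    "published_binary_score",
    "published_multinomial_score",
    "crp_max_classifier",
    "roc_analysis",
    "auc_rank_statistic",
    "sens_spec_at_cutoff",
    "fit_logistic",
]

#: Published single-variable cut-off on maximum postoperative CRP (mg/L).
CRP_MAX_CUTOFF = 91.20


class ScoringError(ValueError):
    """Raised on invalid scoring inputs (missing features, single-class labels)."""


@dataclass
class RiskFeatures:
    """Feature bundle for the published scores.

    Encodings follow the published formulas: second_peak and
    failure_to_decline are 0/1, sex is 1 = male / 2 = female, approach is
    the ordinal access-route code 1-6.  ``failure_to_decline_d4`` is the
    rule evaluated 4 days after the peak (the later of the two assessment
    days).
    """

    second_peak: Optional[int] = None
    crp_max: Optional[float] = None
    crp_max_day: Optional[int] = None
    bmi: Optional[float] = None
    sex: Optional[int] = None
    crp_preop_mean: Optional[float] = None
    approach: Optional[int] = None
    failure_to_decline_d4: Optional[int] = None

    def as_dict(self) -> dict[str, float]:
        return {
            k: v for k, v in self.__dict__.items() if v is not None
        }


@dataclass
class LinearScore:
    """A named linear score with a classification cut-off.

    value(f) = sum(coefficients[name] * f[name]) + intercept;
    classify(f) is True (infection) iff value(f) > cutoff.
    """

    name: str
    coefficients: dict[str, float]
    intercept: float
    cutoff: float

    def value(self, features) -> float:
        feats = features.as_dict() if isinstance(features, RiskFeatures) else dict(features)
        total = self.intercept
        for fname, coef in self.coefficients.items():
            if fname not in feats:
                raise ScoringError(
                    f"score '{self.name}' requires feature '{fname}'"
                )
            total += coef * feats[fname]
        return total

    def classify(self, features) -> bool:
        return self.value(features) > self.cutoff

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {
                    "name": self.name,
                    "coefficients": self.coefficients,
                    "intercept": self.intercept,
                    "cutoff": self.cutoff,
                },
                fh,
                indent=2,
            )

    @classmethod
    def from_json(cls, path) -> "LinearScore":
        with open(path) as fh:
            d = json.load(fh)
        return cls(d["name"], d["coefficients"], d["intercept"], d["cutoff"])

    @classmethod
    def from_resource(cls, resource_name: str) -> "LinearScore":
        text = resources.files("crpkin.models").joinpath(resource_name).read_text()
        d = json.loads(text)
        return cls(d["name"], d["coefficients"], d["intercept"], d["cutoff"])


#: Published binary-logistic-regression score (cut-off > -4.725).
PUBLISHED_BINARY = LinearScore.from_resource("published_binary.json")

#: Published multinomial-logistic-regression score (cut-off > -8.566).
PUBLISHED_MULTINOMIAL = LinearScore.from_resource("published_multinomial.json")


def published_binary_score(features) -> float:
    """The published six-feature binary-regression score.

    -2.447*second_peak + 0.004*crp_max + 0.029*bmi - 1.504*sex
    + 0.381*crp_max_day + 0.024*crp_preop_mean - 5.85
    """
    return PUBLISHED_BINARY.value(features)


def published_multinomial_score(features) -> float:
    """The published five-feature multinomial-regression score.

    1.957*approach + 0.0041*crp_preop_mean + 0.611*crp_max_day
    - 18.57*sex + 1.965*failure_to_decline_d4 + 4.988
    """
    return PUBLISHED_MULTINOMIAL.value(features)


def crp_max_classifier(crp_max: float, cutoff: float = CRP_MAX_CUTOFF) -> bool:
    """Single-variable rule: infection iff maximum CRP strictly exceeds cutoff."""
    if crp_max < 0:
        raise ScoringError(f"crp_max must be >= 0, got {crp_max}")
    return crp_max > cutoff


@dataclass
class RocResult:
    """ROC sweep: thresholds with sensitivity/specificity at each, and AUC."""

    thresholds: np.ndarray
    sensitivity: np.ndarray
    specificity: np.ndarray
    auc: float


def _check_labels(scores, labels) -> tuple[np.ndarray, np.ndarray]:
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=bool)
    if s.shape != y.shape or s.ndim != 1:
        raise ScoringError("scores and labels must be 1-D and the same length")
    if y.all() or not y.any():
        raise ScoringError("need at least one positive and one negative label")
    return s, y


def sens_spec_at_cutoff(
    scores: Sequence[float], labels: Sequence[bool], cutoff: float
) -> tuple[float, float]:
    """Sensitivity and specificity of the rule "score > cutoff => positive"."""
    s, y = _check_labels(scores, labels)
    pred = s > cutoff
    tp = int(np.sum(pred & y))
    fn = int(np.sum(~pred & y))
    tn = int(np.sum(~pred & ~y))
    fp = int(np.sum(pred & ~y))
    return tp / (tp + fn), tn / (tn + fp)


def roc_analysis(scores: Sequence[float], labels: Sequence[bool]) -> RocResult:
    """ROC curve and trapezoid AUC for "score > threshold => positive".

    Thresholds are the midpoints between consecutive sorted unique scores
    plus -inf and +inf endpoints, so every achievable confusion table is
    visited exactly once.
    """
    s, y = _check_labels(scores, labels)
    uniq = np.unique(s)
    mids = (uniq[:-1] + uniq[1:]) / 2.0
    thresholds = np.concatenate(([-np.inf], mids, [np.inf]))
    sens = np.empty(thresholds.shape)
    spec = np.empty(thresholds.shape)
    n_pos, n_neg = int(y.sum()), int((~y).sum())
    for i, t in enumerate(thresholds):
        pred = s > t
        sens[i] = np.sum(pred & y) / n_pos
        spec[i] = np.sum(~pred & ~y) / n_neg
    # integrate the ROC polyline over FPR; the lexicographic sort keeps
    # the vertices of vertical segments (equal FPR) in curve order
    fpr = 1.0 - spec
    order = np.lexsort((sens, fpr))
    auc = float(np.trapezoid(sens[order], fpr[order]))
    return RocResult(thresholds=thresholds, sensitivity=sens,
                     specificity=spec, auc=auc)


def auc_rank_statistic(scores: Sequence[float], labels: Sequence[bool]) -> float:
    """AUC via the Mann-Whitney U identity: U / (n1 * n0), ties as 1/2.

    Independent of the threshold sweep; used to cross-check
    :func:`roc_analysis`.
    """
    s, y = _check_labels(scores, labels)
    pos, neg = s[y], s[~y]
    ranks = stats.rankdata(np.concatenate([pos, neg]))
    u = ranks[: len(pos)].sum() - len(pos) * (len(pos) + 1) / 2.0
    return float(u / (len(pos) * len(neg)))


@dataclass
class LogisticFitReport:
    """Refitted logistic model plus the usual fit statistics."""

    score: LinearScore
    log_likelihood: float
    null_log_likelihood: float
    cox_snell_r2: float
    nagelkerke_r2: float
    dropped: list[str] = field(default_factory=list)
    pvalues: dict[str, float] = field(default_factory=dict)


def _fit_logit(X: np.ndarray, y: np.ndarray):
    model = sm.Logit(y, sm.add_constant(X, has_constant="add"))
    try:
        res = model.fit(disp=0, maxiter=200)
    except (np.linalg.LinAlgError, sm.tools.sm_exceptions.PerfectSeparationError) as e:
        raise ScoringError(
            "logistic fit failed (perfect separation or singular design); "
            "consider a penalized fit"
        ) from e
    if not res.mle_retvals.get("converged", True):
        raise ScoringError("logistic fit did not converge")
    # statsmodels emits a warning (not always an exception) on separation:
    # detect it from an unbounded likelihood
    if np.isnan(res.llf) or np.any(np.abs(res.params) > 1e3):
        raise ScoringError(
            "logistic fit is degenerate (likely perfect separation); "
            "consider a penalized fit"
        )
    return res


def fit_logistic(
    features: "np.ndarray | Sequence[Sequence[float]]",
    labels: Sequence[bool],
    feature_names: Optional[Sequence[str]] = None,
    selection: str = "none",
    stay_p: float = 0.10,
    cutoff: float = 0.0,
) -> LogisticFitReport:
    """Maximum-likelihood logistic regression, optionally with backward
    elimination.

    selection="backward" repeatedly drops the term with the largest
    likelihood-ratio p-value until every remaining term has p < stay_p.
    Reports Cox-Snell R2 = 1 - exp(2*(LL0 - LLm)/n) and Nagelkerke
    R2 = Cox-Snell / (1 - exp(2*LL0/n)).

    The returned LinearScore classifies at ``cutoff`` on the linear
    predictor scale (0 corresponds to probability 1/2).
    """
    X = np.asarray(features, dtype=float)
    if X.ndim != 2:
        raise ScoringError("features must be a 2-D matrix (n x p)")
    y = np.asarray(labels, dtype=float)
    n, p = X.shape
    if n <= p:
        raise ScoringError(f"need more observations ({n}) than features ({p})")
    if np.any(np.ptp(X, axis=0) == 0):
        raise ScoringError("constant feature column(s); drop them before fitting")
    names = list(feature_names) if feature_names is not None else [
        f"x{i}" for i in range(p)
    ]
    if selection not in ("none", "backward"):
        raise ScoringError(f"unknown selection '{selection}'")

    keep = list(range(p))
    dropped: list[str] = []
    res = _fit_logit(X[:, keep], y)
    while selection == "backward" and len(keep) > 1:
        lr_p = {}
        for j in keep:
            sub = [k for k in keep if k != j]
            res_sub = _fit_logit(X[:, sub], y)
            lr = 2.0 * (res.llf - res_sub.llf)
            lr_p[j] = stats.chi2.sf(max(lr, 0.0), df=1)
        worst = max(keep, key=lambda j: lr_p[j])
        if lr_p[worst] < stay_p:
            break
        keep.remove(worst)
        dropped.append(names[worst])
        res = _fit_logit(X[:, keep], y)

    ll0 = float(sm.Logit(y, np.ones((n, 1))).fit(disp=0).llf)
    llm = float(res.llf)
    cox_snell = 1.0 - np.exp(2.0 * (ll0 - llm) / n)
    nagelkerke = cox_snell / (1.0 - np.exp(2.0 * ll0 / n))
    params = res.params  # [const, kept features...]
    coeffs = {names[j]: float(params[i + 1]) for i, j in enumerate(keep)}
    pvals = {names[j]: float(res.pvalues[i + 1]) for i, j in enumerate(keep)}
    score = LinearScore(
        name="refit-logistic",
        coefficients=coeffs,
        intercept=float(params[0]),
        cutoff=cutoff,
    )
    return LogisticFitReport(
        score=score,
        log_likelihood=llm,
        null_log_likelihood=ll0,
        cox_snell_r2=float(cox_snell),
        nagelkerke_r2=float(nagelkerke),
        dropped=dropped,
        pvalues=pvals,
    )
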