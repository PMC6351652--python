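"""Per-wave single-variant association tests.

Topic membership scores are treated as quantitative traits and regressed on
allele dosage under an additive model (OLS, Wald t for the dosage
coefficient).  Individual-code follow-up uses presence/absence as a binary
trait in logistic regression (Wald z, effect reported as log-odds per
allele).  Both adjust for the supplied covariates — the first 10 principal
components for the primary pass, plus BMI for the BMI-adjusted secondary
pass.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import statsmodels.api as sm
from statsmodels.tools.sm_exceptions import PerfectSeparationError

from .synthetic_data import CohortTable

logger = logging.getLogger(__name__)

__all__ = [
    "AssociationResult",
    "linear_assoc",
    "logistic_assoc",
    "run_topic_scan",
    "run_code_scan",
]

#: smallest reportable p-value; p is never reported as exactly 0
P_FLOOR = float(np.finfo(float).tiny)


@dataclass
class AssociationResult:
    """One trait/variant association in one wave.

    ``beta`` is the per-allele effect on the trait scale (log-odds for
    binary traits); ``stat`` is the Wald t (linear) or z (logistic).
    ``status`` is ``ok``, ``skipped_low_frequency`` or ``failed_separation``.
    """

    trait_id: str
    wave: str
    beta: float
    se: float
    stat: float
    p: float
    n: int
    model: str
    covariates: list[str] = field(default_factory=list)
    status: str = "ok"
    flags: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.status == "ok":
            if not self.se > 0:
                raise ValueError("se must be positive for status=ok")
            if not 0 < self.p <= 1:
                raise ValueError("p must lie in (0, 1]")

    @property
    def odds_ratio(self) -> float:
        """exp(beta); meaningful for logistic results."""
        return float(np.exp(self.beta)) if np.isfinite(self.beta) else float("nan")


def _skipped(trait_id, wave, n, model, covariates, status, flags=()):
    return AssociationResult(
        trait_id=trait_id, wave=wave, beta=float("nan"), se=float("nan"),
        stat=float("nan"), p=float("nan"), n=n, model=model,
        covariates=covariates, status=status, flags=flags,
    )


def _design(dosage, covariates):
    dosage = np.asarray(dosage, float)
    cols = [np.ones_like(dosage), dosage]
    names = ["const", "dosage"]
    if covariates is not None and np.size(covariates):
        cov = np.atleast_2d(np.asarray(covariates, float))
        if cov.shape[0] != dosage.shape[0]:
            cov = cov.T
        for j in range(cov.shape[1]):
            cols.append(cov[:, j])
            names.append(f"cov{j + 1}")
    X = np.column_stack(cols)
    return X, names


def _check_rank(X, names):
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # identify offending columns by incremental rank
        bad = []
        kept = X[:, :1]
        for j in range(1, X.shape[1]):
            trial = np.column_stack([kept, X[:, j]])
            if np.linalg.matrix_rank(trial) == kept.shape[1]:
                bad.append(names[j])
            else:
                kept = trial
        raise ValueError(f"rank-deficient design; collinear columns: {bad}")


def linear_assoc(
    y,
    dosage,
    covariates=None,
    wave: str = "all",
    trait_id: str = "trait",
) -> AssociationResult:
    """OLS of a quantitative trait on [intercept, dosage, covariates].

    Reports beta, SE and two-sided p for the dosage coefficient via a Wald
    t-test on the residual degrees of freedom.  A constant dosage (no
    variation in the wave) yields ``status=skipped_low_frequency``.
    """
    y = np.asarray(y, float)
    X, names = _design(dosage, covariates)
    if y.shape[0] != X.shape[0]:
        raise ValueError("y and dosage/covariates have different lengths")
    cov_names = names[2:]
    if X.shape[0] <= X.shape[1] + 2:
        raise ValueError(
            f"n={X.shape[0]} too small for {X.shape[1]} predictors"
        )
    if np.ptp(X[:, 1]) == 0:
        return _skipped(trait_id, wave, len(y), "linear", cov_names,
                        "skipped_low_frequency")
    _check_rank(X, names)
    res = sm.OLS(y, X).fit()
    p = max(float(res.pvalues[1]), P_FLOOR)
    return AssociationResult(
        trait_id=trait_id, wave=wave,
        beta=float(res.params[1]), se=float(res.bse[1]),
        stat=float(res.tvalues[1]), p=p, n=int(res.nobs),
        model="linear", covariates=cov_names,
    )


def logistic_assoc(
    present,
    dosage,
    covariates=None,
    min_cases: int = 10,
    wave: str = "all",
    trait_id: str = "trait",
) -> AssociationResult:
    """Logistic regression of code presence on dosage and covariates.

    ``beta`` is the log odds ratio per minor allele.  If the case count, or
    the carrier-case cross-cell of the 2x2 carrier-by-case table, is below
    ``min_cases``, the wave is reported as ``skipped_low_frequency`` (the
    rule behind 'frequency too low for regression result' cells).  Perfect
    separation or non-convergence is flagged ``failed_separation``.
    """
    y = np.asarray(present, float)
    if not set(np.unique(y)) <= {0.0, 1.0}:
        raise ValueError("present must be binary 0/1")
    d = np.asarray(dosage, float)
    X, names = _design(d, covariates)
    cov_names = names[2:]
    if y.shape[0] != X.shape[0]:
        raise ValueError("present and dosage/covariates have different lengths")
    n = len(y)
    n_cases = int(y.sum())
    carrier = d > 0
    carrier_cases = int(y[carrier].sum())
    if n_cases < min_cases or carrier_cases < min_cases:
        return _skipped(trait_id, wave, n, "logistic", cov_names,
                        "skipped_low_frequency")
    if np.ptp(X[:, 1]) == 0:
        return _skipped(trait_id, wave, n, "logistic", cov_names,
                        "skipped_low_frequency")
    _check_rank(X, names)
    try:
        # non-convergence/separation is detected and flagged below; the
        # warnings statsmodels emits on the way there are just noise
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = sm.Logit(y, X).fit(disp=0, maxiter=100)
    except (PerfectSeparationError, np.linalg.LinAlgError):
        return _skipped(trait_id, wave, n, "logistic", cov_names,
                        "failed_separation")
    converged = bool(res.mle_retvals.get("converged", False))
    beta = float(res.params[1])
    se = float(res.bse[1])
    if not converged or not np.isfinite(se) or abs(beta) > 15:
        return _skipped(trait_id, wave, n, "logistic", cov_names,
                        "failed_separation")
    p = max(float(res.pvalues[1]), P_FLOOR)
    return AssociationResult(
        trait_id=trait_id, wave=wave, beta=beta, se=se,
        stat=float(res.tvalues[1]), p=p, n=n,
        model="logistic", covariates=cov_names,
    )


def run_topic_scan(
    scores: np.ndarray,
    cohort: CohortTable,
    min_wave_n: int = 30,
) -> list[AssociationResult]:
    """Linear association of every topic with dosage, wave by wave.

    ``scores`` rows must align with ``cohort`` subjects.  Each wave is
    analysed on its own subjects with its own PC covariates; waves smaller
    than ``min_wave_n`` are flagged (``small_wave``) but never dropped.
    Returns K x W results keyed by (topic, wave).
    """
    scores = np.asarray(scores, float)
    if scores.shape[0] != cohort.n_subjects:
        raise ValueError("score rows do not align with cohort subjects")
    dosage = cohort.dosage()
    pcs = cohort.pcs()
    results = []
    for k in range(scores.shape[1]):
        for wave in cohort.waves:
            mask = cohort.wave_mask(wave)
            res = linear_assoc(
                scores[mask, k], dosage[mask], pcs[mask],
                wave=wave, trait_id=f"topic{k}",
            )
            if mask.sum() < min_wave_n:
                res.flags = res.flags + ("small_wave",)
            results.append(res)
    return results


def run_code_scan(
    presence: np.ndarray,
    code_ids: list[str],
    cohort: CohortTable,
    adjust_bmi: bool = False,
    min_cases: int = 10,
) -> list[AssociationResult]:
    """Logistic association of each code's presence with dosage, per wave.

    ``presence`` is an N x C binary matrix aligned with the cohort; PCs are
    always included, BMI additionally when ``adjust_bmi``.
    """
    presence = np.asarray(presence)
    if presence.shape[0] != cohort.n_subjects:
        raise ValueError("presence rows do not align with cohort subjects")
    dosage = cohort.dosage()
    cov = cohort.pcs()
    if adjust_bmi:
        cov = np.column_stack([cov, cohort.bmi()])
    results = []
    for j, code in enumerate(code_ids):
        for wave in cohort.waves:
            mask = cohort.wave_mask(wave)
            results.append(
                logistic_assoc(
                    presence[mask, j].astype(float), dosage[mask], cov[mask],
                    min_cases=min_cases, wave=wave, trait_id=code,
                )
            )
    return results
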