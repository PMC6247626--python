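"""Validation statistics for genomic prediction.

Reliability of prediction is the squared Pearson correlation between GEBV
and DRP in the validation cohort, divided by the mean DRP reliability:

    r2_GEBV = cor(GEBV, DRP)^2 / mean(r2_DRP),

reported on a 0-100 scale in tables. The standard error of the accuracy
(square root of the reliability) is approximated by
((1 - r2_GEBV) / sqrt(N - 2)) / rbar_DRP with N the training-set size and
rbar_DRP the square root of the mean DRP reliability. Scale bias of the
GEBV is the slope of the regression of DRP on GEBV,
b_hat = cov(DRP, GEBV) / var(GEBV); deviation from 1 indicates over- or
under-dispersion. Replicate summaries report mean and sd / sqrt(k).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


class EvaluationError(ValueError):
    pass


@dataclass
class EvaluationResult:
    """One scenario x strategy x replicate cell of the validation grid."""

    scenario: str
    strategy: str
    replicate: int
    reliability: float          # 0-1 scale (may exceed 1 when cor ~ 1 and r2_DRP < 1)
    accuracy: float
    accuracy_se: float
    bias_slope: float
    n_training: int
    n_validation: int
    mean_r2_drp: float
    variance_components: dict[str, float] = field(default_factory=dict)
    converged: bool = True
    note: str = ""

    @property
    def reliability_pct(self) -> float:
        return 100.0 * self.reliability


def reliability(gebv, drp, mean_r2_drp: float) -> float:
    gebv = np.asarray(gebv, dtype=np.float64)
    drp = np.asarray(drp, dtype=np.float64)
    if len(gebv) < 3 or len(gebv) != len(drp):
        raise EvaluationError("need >= 3 paired validation records")
    if not 0 < mean_r2_drp <= 1:
        raise EvaluationError("mean_r2_drp must be in (0, 1]")
    if np.var(gebv) == 0 or np.var(drp) == 0:
        raise EvaluationError("zero variance in GEBV or DRP")
    r = np.corrcoef(gebv, drp)[0, 1]
    return float(r * r / mean_r2_drp)


def accuracy_se(reliability: float, n_training: int, mean_r_drp: float) -> float:
    """Approximate SE of the accuracy; ``mean_r_drp`` is sqrt(mean r2_DRP)."""
    if n_training <= 2:
        raise EvaluationError("training size must exceed 2")
    if not 0 < mean_r_drp <= 1:
        raise EvaluationError("mean_r_drp must be in (0, 1]")
    return float((1.0 - reliability) / np.sqrt(n_training - 2) / mean_r_drp)


def bias_slope(gebv, drp) -> float:
    gebv = np.asarray(gebv, dtype=np.float64)
    drp = np.asarray(drp, dtype=np.float64)
    var_g = np.var(gebv, ddof=1)
    if var_g == 0:
        raise EvaluationError("zero-variance GEBV")
    cov = np.cov(drp, gebv, ddof=1)[0, 1]
    return float(cov / var_g)


def replicate_summary(values) -> tuple[float, float]:
    """Mean and standard error (sample sd / sqrt(k)) across replicates."""
    values = np.asarray(values, dtype=np.float64)
    if values.size < 2:
        raise EvaluationError("need at least 2 replicates")
    return float(values.mean()), float(values.std(ddof=1) / np.sqrt(values.size))


def heritability(genetic_variances, total_variance: float) -> float:
    """Sum of genetic variance components divided by the total variance."""
    if np.isscalar(genetic_variances):
        genetic_variances = [genetic_variances]
    gv = np.asarray(genetic_variances, dtype=np.float64)
    if total_variance <= 0:
        raise EvaluationError("total variance must be > 0")
    if np.any(gv < 0):
        raise EvaluationError("genetic variances must be >= 0")
    return float(gv.sum() / total_variance)
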