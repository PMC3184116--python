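"""Method-comparison statistics: Bland-Altman agreement and Pearson r.

Used to compare two measurements of the same quantity — e.g. automated
versus manual infarct scores, or measured versus ground-truth phantom
scores. Classic Bland-Altman formulation: the limits of agreement are
``bias +- 1.96 * sd`` of the paired differences; confidence intervals use
Student-t quantiles with the standard errors ``sd/sqrt(n)`` (bias) and
``sqrt(3*sd^2/n)`` (each limit).

Repeated measures are expected to be averaged *before* the analysis; no
repeated-measures correction is applied here.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
from scipy import stats

from .errors import UndefinedScoreError, ValidationError
from .types import AgreementResult

__all__ = ["bland_altman", "pearson_r"]


def _paired(a: Sequence[float], b: Sequence[float]) -> tuple[np.ndarray, np.ndarray]:
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    if a.ndim != 1 or a.shape != b.shape:
        raise ValidationError("paired inputs must be 1-D and equally long")
    if not (np.isfinite(a).all() and np.isfinite(b).all()):
        raise ValidationError("paired inputs must be finite")
    return a, b


def bland_altman(a: Sequence[float], b: Sequence[float]) -> AgreementResult:
    """Agreement between method a and method b on paired measurements.

    Differences are ``d_i = b_i - a_i`` (b relative to a). Confidence
    intervals require n >= 3 and are ``None`` below that; with zero variance
    they collapse to points.
    """
    a, b = _paired(a, b)
    n = a.size
    if n < 2:
        raise ValidationError("Bland-Altman needs at least 2 pairs")
    d = b - a
    bias = float(np.mean(d))
    sd = float(np.std(d, ddof=1))
    loa_low = bias - 1.96 * sd
    loa_high = bias + 1.96 * sd
    ci_bias = ci_lo = ci_hi = None
    if n >= 3:
        t = float(stats.t.ppf(0.975, n - 1))
        se_bias = sd / np.sqrt(n)
        se_loa = float(np.sqrt(3.0 * sd * sd / n))
        ci_bias = (bias - t * se_bias, bias + t * se_bias)
        ci_lo = (loa_low - t * se_loa, loa_low + t * se_loa)
        ci_hi = (loa_high - t * se_loa, loa_high + t * se_loa)
    return AgreementResult(
        n=int(n),
        bias=bias,
        sd_diff=sd,
        loa_low=loa_low,
        loa_high=loa_high,
        ci_bias=ci_bias,
        ci_loa_low=ci_lo,
        ci_loa_high=ci_hi,
    )


def pearson_r(a: Sequence[float], b: Sequence[float]) -> float:
    """Pearson product-moment correlation of two paired value lists."""
    a, b = _paired(a, b)
    if a.size < 2:
        raise ValidationError("correlation needs at least 2 pairs")
    da = a - a.mean()
    db = b - b.mean()
    denom = float(np.sqrt(np.sum(da * da) * np.sum(db * db)))
    if denom == 0.0:
        raise UndefinedScoreError("correlation undefined: a method has zero variance")
    return float(np.sum(da * db) / denom)
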