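"""Precision loss and study power.

Precision loss compares a reduced design's precision (reciprocal variance)
with the complete design's:

    loss% = 100 * (1 - var_complete / var_reduced),

so 0% means no loss and values approach 100% as the reduced design becomes
uninformative. Power uses the normal approximation for a two-sided Wald
test at level alpha,

    power = Phi( |theta| / sqrt(var) - z_{1 - alpha/2} ),

omitting the negligible opposite-tail term; no degrees-of-freedom
correction is applied, matching the known-correlation design-stage setting.
"""

from __future__ import annotations

from scipy.stats import norm

# Reduced variance may undershoot the complete variance by only rounding.
_MONOTONE_RTOL = 1e-9


def precision_loss(var_complete: float, var_reduced: float) -> float:
    """Percentage loss of precision of a reduced design vs the complete one."""
    if not (var_complete > 0 and var_reduced > 0):
        raise ValueError("variances must be finite and positive")
    if var_reduced < var_complete * (1.0 - _MONOTONE_RTOL):
        raise ValueError(
            f"var_reduced ({var_reduced}) < var_complete ({var_complete}): "
            "a design subset cannot gain precision"
        )
    return 100.0 * max(0.0, 1.0 - var_complete / var_reduced)


def power(variance: float, effect_size: float, alpha: float = 0.05) -> float:
    """Two-sided Wald-test power (percent) for a standardised effect size."""
    if variance <= 0:
        raise ValueError("variance must be positive")
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must lie in (0, 1)")
    z = norm.ppf(1.0 - alpha / 2.0)
    return 100.0 * float(norm.cdf(abs(effect_size) / variance**0.5 - z))
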