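"""AICc, Akaike weights, and model averaging with model-selection variance.

Model averaging follows the information-theoretic standard: weights are
renormalized over whatever subset of models is averaged, and the
unconditional standard error adds the between-model spread to each model's
conditional sampling variance,

    se_uncond = sum_i w_i * sqrt(var_i + (theta_i - theta_bar)^2).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

__all__ = ["ModelEstimate", "aic", "aicc", "akaike_weights", "model_average"]


@dataclass(frozen=True)
class ModelEstimate:
    """One model's point estimate with its conditional SE and criterion value."""

    label: str
    estimate: float
    se: float
    aicc_or_aic: float = np.nan
    weight: float = np.nan

    def __post_init__(self) -> None:
        if self.se < 0:
            raise ValueError("se must be >= 0")


def aic(loglik: float, k: int) -> float:
    return -2.0 * loglik + 2.0 * k


def aicc(loglik: float, k: int, n: int) -> float:
    """Second-order (small-sample) Akaike information criterion.

    AICc = -2 logL + 2k + 2k(k+1)/(n-k-1), with n the number of
    observations the likelihood is evaluated on (detected clusters here).
    """
    if n <= k + 1:
        raise ValueError(f"AICc requires n > k + 1 (got n={n}, k={k})")
    return aic(loglik, k) + 2.0 * k * (k + 1) / (n - k - 1)


def akaike_weights(criteria: Sequence[float]) -> np.ndarray:
    """Akaike weights w_i = exp(-delta_i/2) / sum_j exp(-delta_j/2).

    Invariant to adding a constant to every criterion value.
    """
    c = np.asarray(criteria, dtype=float)
    if c.size == 0:
        raise ValueError("at least one criterion value required")
    rel = np.exp(-0.5 * (c - c.min()))
    return rel / rel.sum()


def model_average(estimates: Sequence[ModelEstimate]) -> tuple[float, float]:
    """Weighted average and unconditional SE over a set of model estimates.

    Weights are renormalized to sum to one over the supplied set, so
    excluding a model and re-averaging is well defined.
    """
    if len(estimates) == 0:
        raise ValueError("cannot average an empty model set")
    w = np.array([e.weight for e in estimates], dtype=float)
    if np.any(~np.isfinite(w)) or w.sum() <= 0:
        raise ValueError("all estimates need finite positive weights")
    w = w / w.sum()
    theta = np.array([e.estimate for e in estimates], dtype=float)
    se = np.array([e.se for e in estimates], dtype=float)
    avg = float(w @ theta)
    se_uncond = float(w @ np.sqrt(se**2 + (theta - avg) ** 2))
    return avg, se_uncond
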