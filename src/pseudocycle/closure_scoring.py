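"""Closure scoring and the hallucination loss.

Deviations of the per-unit screw transform from ideal cyclic closure
(rise 0, rotation 360/N degrees) are rescaled logistically to [0, 1] and
averaged into a closure score (0 = perfect closure).  The hallucination
loss combines the closure score with predictor confidence (pLDDT).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

# Logistic midpoints/slopes for the two deltas; units are degrees for the
# rotation delta and Angstrom for the rise delta.
DEFAULT_ROTATION_PARAMS = (4.0, 1.5)
DEFAULT_RISE_PARAMS = (2.0, 2.0)

# Trajectory selection cutoffs (configurable; used by the pipeline to mark
# converged runs).
DEFAULT_CLOSURE_CUTOFF = 0.1
DEFAULT_PLDDT_CUTOFF = 80.0


@dataclass(frozen=True)
class ClosureDeltas:
    """Absolute deviations from ideal closure: rise from 0 (Angstrom) and
    per-unit rotation from 360/N (degrees)."""

    delta_rise_A: float
    delta_rotation_deg: float

    def __post_init__(self) -> None:
        for name, v in (("delta_rise_A", self.delta_rise_A),
                        ("delta_rotation_deg", self.delta_rotation_deg)):
            if not math.isfinite(v) or v < 0:
                raise ValueError(f"{name} must be finite and >= 0, got {v}")


@dataclass(frozen=True)
class LogisticParams:
    """Midpoint m (same units as its delta) and slope factor s > 0."""

    m: float
    s: float

    def __post_init__(self) -> None:
        if self.s <= 0:
            raise ValueError(f"slope factor must be positive, got {self.s}")


@dataclass(frozen=True)
class ClosureResult:
    rescaled_rise: float
    rescaled_rotation: float

    @property
    def closure_score(self) -> float:
        return (self.rescaled_rise + self.rescaled_rotation) / 2.0


@dataclass(frozen=True)
class ConfidenceMetrics:
    """Structure-predictor confidence: chain-mean pLDDT in [0, 100] and
    optional pTM in [0, 1]."""

    plddt: float
    ptm: Optional[float] = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.plddt <= 100.0:
            raise ValueError(f"plddt {self.plddt} outside [0, 100]")
        if self.ptm is not None and not 0.0 <= self.ptm <= 1.0:
            raise ValueError(f"ptm {self.ptm} outside [0, 1]")


@dataclass(frozen=True)
class LossWeights:
    w_closure: float = 1.0
    w_confidence: float = 1.0

    def __post_init__(self) -> None:
        if self.w_closure < 0 or self.w_confidence < 0:
            raise ValueError("loss weights must be non-negative")
        if self.w_closure == 0 and self.w_confidence == 0:
            raise ValueError("at least one loss weight must be positive")


def logistic_rescale(x: float, p: LogisticParams) -> float:
    """Logistic rescaling 1 / (1 + exp(-s (x - m))), strictly increasing
    in the delta x, with value 0.5 at the midpoint m."""
    if not math.isfinite(x):
        raise ValueError(f"delta value must be finite, got {x}")
    z = -p.s * (x - p.m)
    # guard exp overflow for very large deltas
    if z > 700:
        return 0.0
    return 1.0 / (1.0 + math.exp(z))


def closure_score(
    d: ClosureDeltas,
    rot_params: LogisticParams = LogisticParams(*DEFAULT_ROTATION_PARAMS),
    rise_params: LogisticParams = LogisticParams(*DEFAULT_RISE_PARAMS),
) -> ClosureResult:
    """Mean of the logistically rescaled rise and rotation deltas.

    With the default parameters a perfectly closed backbone scores
    (1/(1+e^4) + 1/(1+e^6))/2 ~ 0.0102, and deltas of (2 A, 4 deg) sit
    exactly at both midpoints, scoring 0.5.
    """
    return ClosureResult(
        rescaled_rise=logistic_rescale(d.delta_rise_A, rise_params),
        rescaled_rotation=logistic_rescale(d.delta_rotation_deg, rot_params),
    )


def hallucination_loss(c: ClosureResult, conf: ConfidenceMetrics,
                       w: LossWeights = LossWeights()) -> float:
    """Weighted hallucination loss; lower is better.

    loss = w_closure * closure_score + w_confidence * (1 - pLDDT/100).
    pTM is not part of the default loss.
    """
    return (w.w_closure * c.closure_score
            + w.w_confidence * (1.0 - conf.plddt / 100.0))
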