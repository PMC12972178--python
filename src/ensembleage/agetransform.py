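"""Age transformations used as regression targets for clock training.

Three kinds are supported:

``identity``
    f(a) = a.  Age in years is regressed directly.

``loglinear``
    A log-linear map commonly used for mouse clocks: logarithmic through
    development, linear in adulthood, with a continuous first derivative at
    the maturity knot ``m``::

        f(a) = log(a + k)                         for a <= m
        f(a) = log(m + k) + (a - m) / (m + k)     for a >  m

    Both branches evaluate to log(m + k) at a = m and both have derivative
    1 / (m + k) there, so f is C1.  Natural logarithm throughout.

``relative``
    Cross-species relative age, f(a) = a / L where L is the species maximum
    lifespan in years.  Two species at the same life fraction map to the
    same transformed value, which is what makes joint human-mouse training
    on shared CpGs possible.

All ages are in years for every species; the transforms are strictly
increasing and have exact closed-form inverses.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, asdict
from typing import Any, Mapping

import numpy as np

from .errors import ValidationError

KINDS = ("identity", "loglinear", "relative")

#: Default species maximum lifespans (years) for relative-age transforms.
#: These are configuration constants of this package, not measured values.
DEFAULT_MAX_LIFESPAN = {"mouse": 4.0, "human": 122.5}

#: Default mouse log-linear parameters (years).
DEFAULT_MATURITY = 0.16
DEFAULT_OFFSET = 0.06


@dataclass(frozen=True)
class AgeTransformSpec:
    """Parameters of an age transformation.

    Parameters
    ----------
    kind:
        One of ``identity``, ``loglinear``, ``relative``.
    maturity:
        Knot age m in years (log-linear only); must be > 0.
    offset:
        Shift k in years applied inside the logarithm (log-linear only);
        must be >= 0.
    max_lifespan:
        Species maximum lifespan L in years (relative only); must be > 0.
    """

    kind: str = "identity"
    maturity: float = DEFAULT_MATURITY
    offset: float = DEFAULT_OFFSET
    max_lifespan: float = DEFAULT_MAX_LIFESPAN["mouse"]

    def __post_init__(self) -> None:
        if self.kind not in KINDS:
            raise ValidationError(f"unknown transform kind {self.kind!r}")
        if self.kind == "loglinear":
            if self.maturity <= 0:
                raise ValidationError("loglinear maturity must be > 0")
            if self.offset < 0:
                raise ValidationError("loglinear offset must be >= 0")
        if self.kind == "relative" and self.max_lifespan <= 0:
            raise ValidationError("relative max_lifespan must be > 0")

    def to_dict(self) -> dict[str, Any]:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: Mapping[str, Any]) -> "AgeTransformSpec":
        return cls(**dict(d))


def transform(age, spec: AgeTransformSpec):
    """Map chronological age (years, > 0) to the transformed scale.

    Accepts a scalar or array; returns the same shape.  Strictly increasing
    in age for every spec kind.
    """
    a = np.asarray(age, dtype=float)
    if np.any(a <= 0):
        raise ValidationError("age must be > 0 years")
    if spec.kind == "identity":
        out = a.copy()
    elif spec.kind == "relative":
        out = a / spec.max_lifespan
    else:  # loglinear
        m, k = spec.maturity, spec.offset
        knot = math.log(m + k)
        out = np.where(a <= m, np.log(np.maximum(a + k, 1e-300)),
                       knot + (a - m) / (m + k))
    if np.isscalar(age):
        return float(out)
    return out


def inverse(t, spec: AgeTransformSpec):
    """Exact inverse of :func:`transform`; total on the real line for
    loglinear and relative kinds."""
    x = np.asarray(t, dtype=float)
    if spec.kind == "identity":
        out = x.copy()
    elif spec.kind == "relative":
        out = x * spec.max_lifespan
    else:
        m, k = spec.maturity, spec.offset
        knot = math.log(m + k)
        out = np.where(x <= knot, np.exp(x) - k, m + (x - knot) * (m + k))
    if np.isscalar(t):
        return float(out)
    return out
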