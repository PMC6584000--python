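"""Response transforms used to linearise distance-decay relationships.

Each pressure or response metric is modelled on a scale on which its mean is
approximately linear in log10(distance) and its residuals approximately
normal: turbidity/SSC on log10, daily light integrals on square-root, and
bounded indices or proportions on logit.  A :class:`Transform` bundles the
forward map, its inverse, and domain checks, so model-fitting and
effect-distance code can move between the natural and transformed scales
without metric-specific branching.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable

import numpy as np

__all__ = ["Transform", "get_transform", "empirical_logit_correction"]


def _logit(p: np.ndarray) -> np.ndarray:
    return np.log(p / (1.0 - p))


def _expit(t: np.ndarray) -> np.ndarray:
    # overflow-safe inverse logit
    out = np.empty_like(t, dtype=float)
    pos = t >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-t[pos]))
    ex = np.exp(t[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


@dataclass(frozen=True)
class Transform:
    """A strictly monotone response transform with inverse and domain.

    Attributes
    ----------
    name:
        One of ``identity``, ``log10``, ``sqrt``, ``logit``.
    forward, inverse:
        Vectorised maps; ``inverse(forward(y)) == y`` on the domain.
    domain:
        Open/closed interval ``(lo, hi)`` of valid natural-scale values.
    codomain:
        Interval of valid transformed-scale values for ``inverse``.
    """

    name: str
    forward: Callable[[np.ndarray], np.ndarray] = field(repr=False)
    inverse: Callable[[np.ndarray], np.ndarray] = field(repr=False)
    domain: tuple[float, float] = (-np.inf, np.inf)
    codomain: tuple[float, float] = (-np.inf, np.inf)

    def check_domain(self, values: np.ndarray) -> None:
        values = np.asarray(values, dtype=float)
        lo, hi = self.domain
        if np.any(~np.isfinite(values)):
            raise ValueError(f"{self.name}: non-finite values in input")
        if np.any(values < lo) or np.any(values > hi):
            raise ValueError(
                f"{self.name}: values outside domain [{lo}, {hi}]"
            )

    def __call__(self, values: np.ndarray) -> np.ndarray:
        self.check_domain(values)
        return self.forward(np.asarray(values, dtype=float))


_TRANSFORMS: dict[str, Transform] = {
    "identity": Transform(
        "identity", lambda y: np.asarray(y, float), lambda t: np.asarray(t, float)
    ),
    "log10": Transform(
        "log10",
        lambda y: np.log10(y),
        lambda t: np.power(10.0, t),
        domain=(np.nextafter(0.0, 1.0), np.inf),
    ),
    "sqrt": Transform(
        "sqrt",
        lambda y: np.sqrt(y),
        lambda t: np.square(t),
        domain=(0.0, np.inf),
        codomain=(0.0, np.inf),
    ),
    "logit": Transform(
        "logit",
        lambda p: _logit(np.asarray(p, float)),
        lambda t: _expit(np.asarray(t, float)),
        domain=(np.nextafter(0.0, 1.0), np.nextafter(1.0, 0.0)),
        codomain=(-np.inf, np.inf),
    ),
}


def get_transform(name: str) -> Transform:
    """Look up a transform by name (identity, log10, sqrt, logit)."""
    try:
        return _TRANSFORMS[name]
    except KeyError:
        raise ValueError(
            f"unknown transform {name!r}; expected one of {sorted(_TRANSFORMS)}"
        ) from None


def empirical_logit_correction(
    proportions: np.ndarray,
    counts: np.ndarray | int | None = None,
    c: float = 0.5,
) -> np.ndarray:
    """Shrink proportions away from exact 0/1 before a logit transform.

    Applies the empirical-logit correction ``(p*n + c) / (n + 2c)`` where
    ``n`` is the number of Bernoulli observations behind each proportion.
    When ``counts`` is None the correction is applied with ``n = 1`` and only
    to values that are exactly 0 or 1 (continuous indices that happen to hit
    their bounds), with a warning.
    """
    p = np.asarray(proportions, dtype=float)
    if np.any(p < 0) or np.any(p > 1):
        raise ValueError("proportions must lie in [0, 1]")
    if counts is None:
        out = p.copy()
        boundary = (p == 0.0) | (p == 1.0)
        if np.any(boundary):
            warnings.warn(
                "exact 0/1 proportions corrected with n=1 (no counts given)",
                stacklevel=2,
            )
            out[boundary] = (p[boundary] + c) / (1.0 + 2.0 * c)
        return out
    n = np.asarray(counts, dtype=float)
    if np.any(n <= 0):
        raise ValueError("counts must be positive")
    return (p * n + c) / (n + 2.0 * c)
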