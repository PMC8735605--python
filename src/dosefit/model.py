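"""Buildup-tail model of megavoltage photon percent depth dose.

The central-axis percent depth dose (PDD) of a flattened megavoltage
photon beam is represented as the product of two elementary functions of
depth ``d`` (cm):

* a *buildup* term ``d / (d^2 + n)`` — zero at the surface, rising to a
  single maximum at ``d = sqrt(n)``; the parameter ``n > 0`` grows with
  beam energy and plays the role of a beam-hardening factor, and
* a *tail* term ``exp(-mu * d)`` — an effective exponential attenuation
  with coefficient ``mu`` (cm^-1) that sets the slope of the descending
  part of the curve.

so that ``PDD(d) ∝ d / (d^2 + n) * exp(-mu * d)``.  An explicit
``amplitude`` factor maps the raw product onto the percent scale; the
conventional normalization sets the curve to 100% at the depth of dose
maximum (``max100``).

The depth of dose maximum of the product is the unique positive root of

    mu * d^3 + d^2 + mu * n * d - n = 0

which lies in ``(0, sqrt(n)]`` and collapses to ``sqrt(n)`` as
``mu -> 0``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
from scipy.optimize import brentq

__all__ = [
    "BeamModelParams",
    "DepthDoseCurve",
    "buildup",
    "tail",
    "pdd_raw",
    "d_max",
    "evaluate_pdd",
]


@dataclass(frozen=True)
class BeamModelParams:
    """Parameter triple (n, mu, amplitude) of one buildup-tail curve.

    Parameters
    ----------
    n : float
        Buildup / beam-hardening parameter; must be positive.  Larger
        ``n`` pushes the dose maximum deeper and lowers surface dose.
    mu : float
        Effective linear attenuation coefficient of the tail, cm^-1;
        non-negative.  ``mu = 0`` is admitted as the no-attenuation
        limit, in which case the dose maximum sits exactly at
        ``sqrt(n)``.
    amplitude : float, default 1.0
        Positive scale factor mapping the raw product to percent.
    """

    n: float
    mu: float
    amplitude: float = 1.0

    def __post_init__(self) -> None:
        if not np.isfinite(self.n) or self.n <= 0:
            raise ValueError(f"n must be finite and > 0, got {self.n!r}")
        if not np.isfinite(self.mu) or self.mu < 0:
            raise ValueError(f"mu must be finite and >= 0, got {self.mu!r}")
        if not np.isfinite(self.amplitude) or self.amplitude <= 0:
            raise ValueError(
                f"amplitude must be finite and > 0, got {self.amplitude!r}"
            )

    def with_amplitude(self, amplitude: float) -> "BeamModelParams":
        return replace(self, amplitude=amplitude)


@dataclass
class DepthDoseCurve:
    """A central-axis depth-dose scan (measured, modeled or synthetic).

    ``depths`` are in cm and must be strictly increasing with at least
    two points; ``values`` are on the percent scale.
    """

    depths: np.ndarray
    values: np.ndarray
    energy: str = ""
    field_size_cm: Optional[float] = None
    ssd_cm: float = 100.0
    source: str = "measured"
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.depths = np.asarray(self.depths, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.depths.ndim != 1 or self.values.ndim != 1:
            raise ValueError("depths and values must be one-dimensional")
        if self.depths.size != self.values.size:
            raise ValueError(
                f"length mismatch: {self.depths.size} depths vs "
                f"{self.values.size} values"
            )
        if self.depths.size < 2:
            raise ValueError("a depth-dose curve needs at least 2 points")
        if not np.all(np.isfinite(self.depths)) or not np.all(
            np.isfinite(self.values)
        ):
            raise ValueError("depths and values must be finite")
        if self.depths[0] < 0:
            raise ValueError("depths must be non-negative")
        if np.any(np.diff(self.depths) <= 0):
            raise ValueError("depths must be strictly increasing")

    def __len__(self) -> int:
        return int(self.depths.size)

    def value_at(self, depth: float, atol: float = 1e-9) -> float:
        """Exact-grid lookup of the dose value at ``depth`` (no interpolation)."""
        idx = np.nonzero(np.isclose(self.depths, depth, rtol=0.0, atol=atol))[0]
        if idx.size == 0:
            raise KeyError(f"depth {depth} cm is not on the curve's grid")
        return float(self.values[idx[0]])


def _as_depth(d) -> np.ndarray:
    d = np.asarray(d, dtype=float)
    if np.any(d < 0):
        raise ValueError("depth must be >= 0")
    return d


def buildup(d, n: float):
    """Buildup factor ``d / (d^2 + n)``.

    Zero at the surface, unimodal with maximum ``1 / (2 sqrt(n))`` at
    ``d = sqrt(n)``.  ``n`` must be positive (a non-positive ``n`` would
    put a pole on the depth axis).
    """
    if n <= 0:
        raise ValueError(f"n must be > 0, got {n!r}")
    d = _as_depth(d)
    out = d / (d * d + n)
    return out if out.ndim else float(out)


def tail(d, mu: float):
    """Attenuation factor ``exp(-mu * d)``; strictly decreasing for mu > 0."""
    if mu < 0:
        raise ValueError(f"mu must be >= 0, got {mu!r}")
    d = _as_depth(d)
    out = np.exp(-mu * d)
    return out if out.ndim else float(out)


def pdd_raw(d, params: BeamModelParams):
    """Raw buildup-tail product ``amplitude * buildup(d, n) * tail(d, mu)``."""
    out = params.amplitude * np.asarray(buildup(d, params.n)) * np.asarray(
        tail(d, params.mu)
    )
    return out if out.ndim else float(out)


def d_max(params: BeamModelParams) -> float:
    """Depth of dose maximum of the buildup-tail product, cm.

    Solves ``mu d^3 + d^2 + mu n d - n = 0`` on ``(0, sqrt(n)]`` by a
    bracketed root finder; the cubic's coefficient signs (+, +, +, -)
    guarantee exactly one positive root.  For ``mu = 0`` the closed form
    ``sqrt(n)`` is returned.
    """
    n, mu = params.n, params.mu
    if mu == 0.0:
        return float(np.sqrt(n))
    root_hi = float(np.sqrt(n))

    def cubic(d: float) -> float:
        return mu * d**3 + d * d + mu * n * d - n

    # cubic(0+) = -n < 0 and cubic(sqrt n) = 2 mu n^{3/2} > 0: valid bracket
    return float(brentq(cubic, 1e-300, root_hi, xtol=1e-12, rtol=1e-15))


_NORMALIZATIONS = ("max100", "at_depth", "raw")


def evaluate_pdd(
    params: BeamModelParams,
    depths,
    normalization: str = "max100",
    norm_depth: Optional[float] = None,
    energy: str = "",
) -> DepthDoseCurve:
    """Evaluate the buildup-tail model on a depth grid.

    Parameters
    ----------
    normalization : {"max100", "at_depth", "raw"}
        ``max100`` rescales so the model equals 100 at its analytic
        depth of dose maximum (the conventional PDD normalization);
        ``at_depth`` rescales so the value at ``norm_depth`` is 100;
        ``raw`` applies the amplitude only.
    """
    if normalization not in _NORMALIZATIONS:
        raise ValueError(
            f"normalization must be one of {_NORMALIZATIONS}, got {normalization!r}"
        )
    depths = _as_depth(np.asarray(depths, dtype=float))
    raw = np.asarray(pdd_raw(depths, params), dtype=float)
    if normalization == "max100":
        peak = pdd_raw(d_max(params), params)
        values = 100.0 * raw / peak
    elif normalization == "at_depth":
        if norm_depth is None:
            raise ValueError("normalization 'at_depth' requires norm_depth")
        ref = pdd_raw(float(norm_depth), params)
        if ref == 0.0:
            raise ValueError(
                f"model is zero at norm_depth={norm_depth}; cannot normalize"
            )
        values = 100.0 * raw / ref
    else:
        values = raw
    return DepthDoseCurve(
        depths=depths, values=values, energy=energy, source="modeled"
    )
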