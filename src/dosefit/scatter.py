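"""Collimator scatter factor (in-air output ratio) models.

Two parameterizations are provided:

* a two-coefficient power law in square field size ``FS`` (cm),

      S_c(FS) = n_E * FS ** (k * mu_E),          k = 0.63 by default,

  with the option of constraining ``n_E = 10 ** (-k * mu_E)`` so that
  the reference field 10 x 10 cm gives S_c = 1 exactly, and

* an asymmetric-jaw law attributing different weights to the upper and
  lower collimator pairs,

      S_c(U, L) = A * (U**w_upper * L**w_lower) ** p,

  whose weight asymmetry (w_upper > w_lower) reproduces the collimator
  exchange effect: swapping an asymmetric (U, L) setting changes S_c.

Both laws can be calibrated to measured tables by least squares on
relative deviations; the model classes follow the model/results split
(`ScPowerLawModel(table).fit()` returns a results object with the
coefficients, per-row percent deviations and a ``summary()``).

Note on identifiability of the jaw law: only the products ``p*w_upper``
and ``p*w_lower`` (and ``A``) are determined by data; fitted weights are
therefore reported normalised to ``w_upper + w_lower = 1``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Tuple, Union

import numpy as np
from scipy.optimize import least_squares

__all__ = [
    "ScPowerLaw",
    "JawScLaw",
    "ScTable",
    "JawScMatrix",
    "ScPowerLawModel",
    "ScPowerLawResult",
    "JawScModel",
    "JawScResult",
    "sc_square_eval",
    "sc_square_fit",
    "sc_jaw_eval",
    "sc_jaw_fit",
    "exchange_effect",
]

DEFAULT_K = 0.63


@dataclass(frozen=True)
class ScPowerLaw:
    """Coefficients of the square-field power law ``n_E * FS**(k*mu_E)``."""

    n_E: float
    mu_E: float
    k: float = DEFAULT_K
    constrained: bool = False

    def __post_init__(self) -> None:
        if self.n_E <= 0:
            raise ValueError(f"n_E must be > 0, got {self.n_E!r}")
        if self.constrained:
            expect = 10.0 ** (-self.k * self.mu_E)
            if not np.isclose(self.n_E, expect, rtol=1e-12, atol=0.0):
                raise ValueError(
                    "constrained law requires n_E == 10**(-k*mu_E) "
                    f"(got n_E={self.n_E!r}, expected {expect!r})"
                )

    @classmethod
    def from_mu(cls, mu_E: float, k: float = DEFAULT_K) -> "ScPowerLaw":
        """Constrained law with S_c(10) = 1 exactly."""
        return cls(n_E=10.0 ** (-k * mu_E), mu_E=mu_E, k=k, constrained=True)

    def sc(self, field_size):
        fs = np.asarray(field_size, dtype=float)
        if np.any(fs <= 0):
            raise ValueError("field size must be > 0")
        out = self.n_E * fs ** (self.k * self.mu_E)
        return out if out.ndim else float(out)

    __call__ = sc


@dataclass(frozen=True)
class JawScLaw:
    """Coefficients of the asymmetric-jaw law ``A*(U**wU * L**wL)**p``.

    Defaults are the published 6 MV calibration (A=0.88, w_upper=0.65,
    w_lower=0.35, p=0.06); note they are a stand-alone calibration and
    do not reproduce every measured jaw matrix (a refit path is
    provided).
    """

    A: float = 0.88
    w_upper: float = 0.65
    w_lower: float = 0.35
    p: float = 0.06

    def __post_init__(self) -> None:
        if self.A <= 0 or self.p <= 0:
            raise ValueError("A and p must be > 0")

    def sc(self, upper, lower):
        u = np.asarray(upper, dtype=float)
        l = np.asarray(lower, dtype=float)
        if np.any(u <= 0) or np.any(l <= 0):
            raise ValueError("jaw settings must be > 0")
        out = self.A * (u**self.w_upper * l**self.w_lower) ** self.p
        return out if out.ndim else float(out)

    __call__ = sc


@dataclass
class ScTable:
    """Measured S_c versus square field size (long form)."""

    field_sizes: np.ndarray
    sc: np.ndarray
    energy: str = ""
    machine: str = ""

    def __post_init__(self) -> None:
        self.field_sizes = np.asarray(self.field_sizes, dtype=float)
        self.sc = np.asarray(self.sc, dtype=float)
        if self.field_sizes.size != self.sc.size:
            raise ValueError("field_sizes and sc must have equal length")
        if np.any(self.field_sizes <= 0):
            raise ValueError("field sizes must be positive")
        if np.any(np.diff(self.field_sizes) <= 0):
            raise ValueError("field sizes must be strictly increasing")
        if np.any(self.sc <= 0):
            raise ValueError("sc values must be positive")

    def __len__(self) -> int:
        return int(self.field_sizes.size)


@dataclass
class JawScMatrix:
    """Measured S_c versus (upper, lower) jaw setting.

    Rows index the upper-jaw setting, columns the lower-jaw setting.
    """

    upper_sizes: np.ndarray
    lower_sizes: np.ndarray
    values: np.ndarray
    energy: str = ""
    machine: str = ""

    def __post_init__(self) -> None:
        self.upper_sizes = np.asarray(self.upper_sizes, dtype=float)
        self.lower_sizes = np.asarray(self.lower_sizes, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if np.any(self.upper_sizes <= 0) or np.any(self.lower_sizes <= 0):
            raise ValueError("jaw sizes must be positive")
        if np.any(np.diff(self.upper_sizes) <= 0) or np.any(
            np.diff(self.lower_sizes) <= 0
        ):
            raise ValueError("jaw sizes must be strictly increasing")
        if self.values.shape != (self.upper_sizes.size, self.lower_sizes.size):
            raise ValueError(
                f"matrix shape {self.values.shape} does not match "
                f"({self.upper_sizes.size}, {self.lower_sizes.size}) sizes"
            )
        if np.any(self.values <= 0):
            raise ValueError("sc values must be positive")

    def lookup(self, upper: float, lower: float, atol: float = 1e-9) -> float:
        """Exact-cell lookup; no interpolation between jaw settings."""
        iu = np.nonzero(np.isclose(self.upper_sizes, upper, rtol=0.0, atol=atol))[0]
        il = np.nonzero(np.isclose(self.lower_sizes, lower, rtol=0.0, atol=atol))[0]
        if iu.size == 0 or il.size == 0:
            raise KeyError(f"no cell for upper={upper}, lower={lower}")
        return float(self.values[iu[0], il[0]])


# ---------------------------------------------------------------- square law


@dataclass
class ScPowerLawResult:
    """Calibrated square-field power law with per-row diagnostics."""

    law: ScPowerLaw
    table: ScTable
    deviations_pct: np.ndarray
    max_abs_deviation_pct: float
    converged: bool

    def summary(self) -> str:
        lines = [
            "Square-field S_c power law",
            "==========================",
            f"energy:               {self.table.energy or '(unlabelled)'}",
            f"n_E:                  {self.law.n_E:.6g}",
            f"mu_E (cm^-1):         {self.law.mu_E:.6g}",
            f"k (fixed):            {self.law.k:.6g}",
            f"constrained Sc(10)=1: {self.law.constrained}",
            f"rows:                 {len(self.table)}",
            f"max |deviation| (%):  {self.max_abs_deviation_pct:.4f}",
        ]
        return "\n".join(lines)

    def to_dict(self) -> dict:
        return {
            "schema_version": 1,
            "kind": "sc_power_law",
            "energy": self.table.energy,
            "n_E": self.law.n_E,
            "mu_E": self.law.mu_E,
            "k": self.law.k,
            "constrained": self.law.constrained,
            "max_abs_deviation_pct": self.max_abs_deviation_pct,
        }


class ScPowerLawModel:
    """Power-law S_c model bound to one measured square-field table."""

    def __init__(self, table: ScTable, constrained: bool = False, k: float = DEFAULT_K):
        if len(table) < (2 if constrained else 3):
            raise ValueError(
                "need >= 3 rows (unconstrained) or >= 2 rows (constrained)"
            )
        self.table = table
        self.constrained = constrained
        self.k = k

    def fit(self) -> ScPowerLawResult:
        fs, sc = self.table.field_sizes, self.table.sc
        # log-log regression is the closed-form initializer
        b0, ln_a0 = np.polyfit(np.log(fs), np.log(sc), 1)
        if self.constrained:

            def resid(x):
                law = ScPowerLaw.from_mu(x[0], k=self.k)
                return (law.sc(fs) - sc) / sc

            res = least_squares(
                resid, [b0 / self.k], xtol=1e-14, ftol=1e-14, gtol=1e-14
            )
            law = ScPowerLaw.from_mu(float(res.x[0]), k=self.k)
        else:

            def resid(x):
                return (np.exp(x[1]) * fs ** (self.k * x[0]) - sc) / sc

            res = least_squares(
                resid, [b0 / self.k, ln_a0], xtol=1e-14, ftol=1e-14, gtol=1e-14
            )
            law = ScPowerLaw(
                n_E=float(np.exp(res.x[1])), mu_E=float(res.x[0]), k=self.k
            )
        dev = 100.0 * (law.sc(fs) - sc) / sc
        return ScPowerLawResult(
            law=law,
            table=self.table,
            deviations_pct=dev,
            max_abs_deviation_pct=float(np.max(np.abs(dev))),
            converged=bool(res.status > 0),
        )


# ------------------------------------------------------------------ jaw law


@dataclass
class JawScResult:
    """Calibrated asymmetric-jaw law with per-cell diagnostics."""

    law: JawScLaw
    matrix: JawScMatrix
    residuals_pct: np.ndarray
    max_abs_residual_pct: float
    converged: bool

    def summary(self) -> str:
        lines = [
            "Asymmetric-jaw S_c law",
            "======================",
            f"energy:              {self.matrix.energy or '(unlabelled)'}",
            f"A:                   {self.law.A:.6g}",
            f"w_upper:             {self.law.w_upper:.6g}",
            f"w_lower:             {self.law.w_lower:.6g}",
            f"p:                   {self.law.p:.6g}",
            f"cells:               {self.matrix.values.size}",
            f"max |residual| (%):  {self.max_abs_residual_pct:.4f}",
        ]
        return "\n".join(lines)

    def to_dict(self) -> dict:
        return {
            "schema_version": 1,
            "kind": "sc_jaw_law",
            "energy": self.matrix.energy,
            "A": self.law.A,
            "w_upper": self.law.w_upper,
            "w_lower": self.law.w_lower,
            "p": self.law.p,
            "max_abs_residual_pct": self.max_abs_residual_pct,
        }


class JawScModel:
    """Asymmetric-jaw S_c model bound to one measured jaw matrix.

    Only ``A`` and the products ``p*w_upper``, ``p*w_lower`` are
    identifiable; regardless of ``constrain_weights`` the fitted weights
    are reported normalised to sum to 1 (the flag is kept for interface
    symmetry and future constrained variants).
    """

    def __init__(self, matrix: JawScMatrix, constrain_weights: bool = True):
        if matrix.upper_sizes.size < 2 or matrix.lower_sizes.size < 2:
            raise ValueError("need at least a 2x2 jaw matrix")
        if (
            np.ptp(matrix.upper_sizes) == 0.0 or np.ptp(matrix.lower_sizes) == 0.0
        ):  # unreachable after validation; defensive
            raise ValueError("jaw sizes must vary to identify the exponents")
        self.matrix = matrix
        self.constrain_weights = constrain_weights

    def fit(self) -> JawScResult:
        m = self.matrix
        ln_u = np.log(m.upper_sizes)[:, None] + np.zeros_like(m.values)
        ln_l = np.log(m.lower_sizes)[None, :] + np.zeros_like(m.values)
        # log-linear init: ln sc = ln A + alpha ln U + beta ln L
        X = np.column_stack(
            [np.ones(m.values.size), ln_u.ravel(), ln_l.ravel()]
        )
        beta0, *_ = np.linalg.lstsq(X, np.log(m.values).ravel(), rcond=None)

        def resid(x):
            pred = np.exp(x[0]) * np.exp(x[1] * ln_u + x[2] * ln_l)
            return ((pred - m.values) / m.values).ravel()

        res = least_squares(resid, beta0, xtol=1e-14, ftol=1e-14, gtol=1e-14)
        ln_a, alpha, beta = res.x
        p = float(alpha + beta)
        law = JawScLaw(
            A=float(np.exp(ln_a)),
            w_upper=float(alpha / p),
            w_lower=float(beta / p),
            p=p,
        )
        pct = 100.0 * resid(res.x).reshape(m.values.shape)
        return JawScResult(
            law=law,
            matrix=m,
            residuals_pct=pct,
            max_abs_residual_pct=float(np.max(np.abs(pct))),
            converged=bool(res.status > 0),
        )


# ------------------------------------------------------------- functional API


def sc_square_eval(law: ScPowerLaw, field_size):
    """Evaluate a square-field power law at ``field_size`` (cm)."""
    return law.sc(field_size)


def sc_square_fit(
    table: ScTable, constrained: bool = False, k: float = DEFAULT_K
) -> Tuple[ScPowerLaw, np.ndarray]:
    """Calibrate the power law to a table; returns (law, percent deviations)."""
    res = ScPowerLawModel(table, constrained=constrained, k=k).fit()
    return res.law, res.deviations_pct


def sc_jaw_eval(law: JawScLaw, upper, lower):
    """Evaluate an asymmetric-jaw law at (upper, lower) jaw settings (cm)."""
    return law.sc(upper, lower)


def sc_jaw_fit(
    matrix: JawScMatrix, constrain_weights: bool = True
) -> Tuple[JawScLaw, np.ndarray]:
    """Calibrate the jaw law to a matrix; returns (law, percent residual matrix)."""
    res = JawScModel(matrix, constrain_weights=constrain_weights).fit()
    return res.law, res.residuals_pct


def exchange_effect(
    source: Union[JawScMatrix, JawScLaw], upper: float, lower: float
) -> float:
    """Collimator exchange effect ``S_c(U, L) - S_c(L, U)``.

    Antisymmetric under argument swap; zero for square settings and for
    symmetric jaw weights.  For a matrix source both orderings must be
    exact cells (no interpolation).
    """
    if isinstance(source, JawScMatrix):
        return source.lookup(upper, lower) - source.lookup(lower, upper)
    return float(source.sc(upper, lower) - source.sc(lower, upper))
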