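"""Synthetic scans and scatter tables with known ground truth.

The generator emulates a water-phantom central-axis scan: the
buildup-tail model is evaluated on a regular depth grid (default
0.1-23 cm at 0.1 cm steps, the usual scan geometry at SSD 100 cm),
normalised to 100% at the depth of dose maximum, and perturbed by iid
additive Gaussian noise on the percent scale (default sd 0.2%, the
order of chamber-scan repeatability).  Scatter-factor tables and jaw
matrices are generated the same way from a known power law or jaw law.

Because the ground truth is known exactly, these generators back the
parameter-recovery tests of the fitting and calibration routines.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence, Tuple, Union

import numpy as np

from .model import BeamModelParams, DepthDoseCurve, evaluate_pdd
from .scatter import JawScLaw, JawScMatrix, ScPowerLaw, ScTable

__all__ = ["SyntheticScanConfig", "gen_scan", "gen_sc_table"]


@dataclass(frozen=True)
class SyntheticScanConfig:
    """Ground-truth parameters plus noise spec for one synthetic scan."""

    true_params: BeamModelParams
    depth_start: float = 0.1
    depth_stop: float = 23.0
    depth_step: float = 0.1
    noise_sd: float = 0.2
    seed: Optional[int] = None
    normalization: str = "max100"
    energy: str = "synthetic"

    def __post_init__(self) -> None:
        if self.depth_step <= 0:
            raise ValueError("depth_step must be > 0")
        if self.depth_start < 0 or self.depth_stop <= self.depth_start:
            raise ValueError("need 0 <= depth_start < depth_stop")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.noise_sd > 0 and self.seed is None:
            raise ValueError("a seed is mandatory when noise_sd > 0")

    def grid(self) -> np.ndarray:
        n = int(np.floor((self.depth_stop - self.depth_start) / self.depth_step + 1e-9))
        return np.round(self.depth_start + self.depth_step * np.arange(n + 1), 10)


def gen_scan(config: SyntheticScanConfig) -> DepthDoseCurve:
    """Evaluate the model on the grid and add reproducible Gaussian noise."""
    curve = evaluate_pdd(
        config.true_params,
        config.grid(),
        normalization=config.normalization,
        energy=config.energy,
    )
    values = curve.values
    if config.noise_sd > 0:
        rng = np.random.default_rng(config.seed)
        values = values + rng.normal(0.0, config.noise_sd, values.size)
    return DepthDoseCurve(
        depths=curve.depths,
        values=values,
        energy=config.energy,
        source="synthetic",
    )


def gen_sc_table(
    model: Union[ScPowerLaw, JawScLaw],
    sizes: Union[Sequence[float], Tuple[Sequence[float], Sequence[float]]],
    noise_sd: float = 0.0,
    seed: Optional[int] = None,
) -> Union[ScTable, JawScMatrix]:
    """Generate a scatter-factor table (power law) or jaw matrix (jaw law).

    For a :class:`ScPowerLaw`, ``sizes`` is a sequence of square field
    sizes; for a :class:`JawScLaw` it is a ``(upper_sizes,
    lower_sizes)`` pair.  Noise is additive Gaussian on the S_c scale.
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    if noise_sd > 0 and seed is None:
        raise ValueError("a seed is mandatory when noise_sd > 0")
    rng = np.random.default_rng(seed) if noise_sd > 0 else None

    if isinstance(model, ScPowerLaw):
        fs = np.asarray(sizes, dtype=float)
        sc = np.asarray(model.sc(fs), dtype=float)
        if rng is not None:
            sc = sc + rng.normal(0.0, noise_sd, sc.size)
        return ScTable(field_sizes=fs, sc=sc, energy="synthetic")
    if isinstance(model, JawScLaw):
        upper, lower = (np.asarray(s, dtype=float) for s in sizes)
        grid = model.sc(upper[:, None], lower[None, :])
        if rng is not None:
            grid = grid + rng.normal(0.0, noise_sd, grid.shape)
        return JawScMatrix(
            upper_sizes=upper, lower_sizes=lower, values=grid, energy="synthetic"
        )
    raise TypeError(f"unsupported model type {type(model).__name__}")
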