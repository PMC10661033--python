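"""Saturation-binding analysis of equilibrium titration data.

Fits the monovalent single-site isotherm

    signal(c) = bmax * c / (Kd + c)

to (concentration, signal) titrations by nonlinear least squares with a
deterministic multi-start grid over Kd, and reports fold improvements as
Kd ratios.  No kinetics, no competitive-binding conversion.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit


@dataclass
class TitrationData:
    """Concentrations (molar) and normalized signals, paired."""

    concentrations: np.ndarray
    signals: np.ndarray

    def __post_init__(self) -> None:
        self.concentrations = np.asarray(self.concentrations, dtype=float)
        self.signals = np.asarray(self.signals, dtype=float)
        if len(self.concentrations) != len(self.signals):
            raise ValueError("concentrations and signals differ in length")
        if len(self.concentrations) < 4:
            raise ValueError("need at least 4 titration points")
        if np.any(self.concentrations <= 0):
            raise ValueError("concentrations must be positive")
        if np.allclose(self.concentrations, self.concentrations[0]):
            raise ValueError("concentrations must not all be equal")

    @classmethod
    def from_csv(cls, path) -> "TitrationData":
        df = pd.read_csv(path)
        return cls(df["concentration_molar"].to_numpy(), df["signal"].to_numpy())


@dataclass
class BindingFit:
    """Result of a saturation fit: Kd, bmax, RSS and curvature-based CIs."""

    kd: float
    bmax: float
    rss: float
    kd_ci_halfwidth: float
    bmax_ci_halfwidth: float

    def __post_init__(self) -> None:
        if self.kd <= 0 or self.bmax <= 0:
            raise ValueError("kd and bmax must be positive")

    def model(self, c) -> np.ndarray:
        c = np.asarray(c, dtype=float)
        return self.bmax * c / (self.kd + c)

    def normalized_signals(self, data: TitrationData) -> np.ndarray:
        """Signals scaled to fitted bmax (normalisation after fitting)."""
        return data.signals / self.bmax

    def to_tsv(self, path) -> None:
        pd.DataFrame(
            [
                {
                    "kd_molar": self.kd,
                    "bmax": self.bmax,
                    "rss": self.rss,
                    "kd_ci_halfwidth": self.kd_ci_halfwidth,
                    "bmax_ci_halfwidth": self.bmax_ci_halfwidth,
                }
            ]
        ).to_csv(path, sep="\t", index=False)


def _isotherm(c, bmax, kd):
    return bmax * c / (kd + c)


def _isotherm_logkd(c, bmax, log10_kd):
    # Kd spans many decades across screens; fitting log10(Kd) keeps the
    # optimizer well scaled regardless of the concentration regime
    return bmax * c / (10.0**log10_kd + c)


def fit_saturation(data: TitrationData, n_starts: int = 25) -> BindingFit:
    """Least-squares fit of the single-site isotherm.

    Initialisation is a deterministic log-spaced Kd grid spanning the
    concentration range (widened tenfold either side) with bmax seeded
    from the maximum signal; the converged fit with the lowest residual
    sum of squares wins and is verified to beat every grid start's own
    RSS.  Raises if no start converges or the signals are all zero.
    """
    c, y = data.concentrations, data.signals
    if np.allclose(y, 0.0):
        raise ValueError("signals are all zero; Kd is unidentifiable")
    bmax0 = float(np.max(y))
    kd_grid = np.geomspace(c.min() / 10.0, c.max() * 10.0, n_starts)
    best = None
    grid_rss = []
    for kd0 in kd_grid:
        start_rss = float(np.sum((y - _isotherm(c, bmax0, kd0)) ** 2))
        grid_rss.append(start_rss)
        try:
            popt, pcov = curve_fit(
                _isotherm_logkd,
                c,
                y,
                p0=[bmax0, np.log10(kd0)],
                bounds=([0.0, -np.inf], [np.inf, np.inf]),
                maxfev=10000,
            )
        except (RuntimeError, ValueError):
            continue
        rss = float(np.sum((y - _isotherm_logkd(c, *popt)) ** 2))
        if best is None or rss < best[0]:
            best = (rss, popt, pcov)
    if best is None:
        i = int(np.argmin(grid_rss))
        raise RuntimeError(
            f"saturation fit failed to converge from any start; best grid point "
            f"kd={kd_grid[i]:.3g}, rss={grid_rss[i]:.3g}"
        )
    rss, (bmax, log10_kd), pcov = best
    if rss > min(grid_rss) + 1e-9 * (1 + min(grid_rss)):
        raise RuntimeError("converged fit is worse than a grid start")
    kd = float(10.0**log10_kd)
    se = np.sqrt(np.clip(np.diag(pcov), 0.0, np.inf))
    # delta method: sd(kd) = kd * ln(10) * sd(log10 kd)
    return BindingFit(
        kd=kd,
        bmax=float(bmax),
        rss=rss,
        kd_ci_halfwidth=float(1.96 * kd * np.log(10.0) * se[1]),
        bmax_ci_halfwidth=float(1.96 * se[0]),
    )


def fold_improvement(kd_reference: float, kd_variant: float) -> float:
    """Affinity fold change: reference Kd over variant Kd (>1 means tighter)."""
    if kd_reference <= 0 or kd_variant <= 0:
        raise ValueError("Kd values must be positive")
    return kd_reference / kd_variant
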