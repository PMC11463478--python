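"""Pockels-cell transmission calibration.

An electro-optic modulator followed by a polarizer transmits

    P(V) = P0 * sin^2(pi * V / V0 + phi / 2)

where ``P0`` is the peak transmitted power, ``V0`` the half-wave voltage
period, and ``phi`` a phase offset set by the crystal orientation and bias.
This module fits that model to a measured voltage sweep and summarises the
calibration quality (RMSE, dynamic range over the sweep window).
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from .errors import DegenerateDataError, FitFailureError, InvalidParameterError

__all__ = [
    "PowerSweep",
    "PockelsFit",
    "transmission_model",
    "fit_transmission",
    "dynamic_range",
]

_TWO_PI = 2.0 * np.pi


@dataclass
class PowerSweep:
    """A voltage -> transmitted-power calibration sweep.

    voltage must be monotone non-decreasing; at least 6 points are required
    for the three-parameter fit; powers are non-negative (mW).
    """

    voltage: np.ndarray
    power: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.voltage = np.asarray(self.voltage, dtype=float)
        self.power = np.asarray(self.power, dtype=float)
        if self.voltage.ndim != 1 or self.voltage.shape != self.power.shape:
            raise InvalidParameterError("voltage and power must be equal-length 1-D arrays")
        if self.voltage.size < 6:
            raise InvalidParameterError("need at least 6 sweep points")
        if np.any(np.diff(self.voltage) < 0):
            raise InvalidParameterError("voltage must be monotone non-decreasing")
        if np.any(self.power < 0):
            raise InvalidParameterError("powers must be non-negative")

    @classmethod
    def from_csv(cls, path: str | Path) -> "PowerSweep":
        """Read a two-column CSV with header ``voltage_V,power_mW``."""
        df = pd.read_csv(path)
        missing = {"voltage_V", "power_mW"} - set(df.columns)
        if missing:
            raise InvalidParameterError(f"CSV missing columns: {sorted(missing)}")
        return cls(
            voltage=df["voltage_V"].to_numpy(),
            power=df["power_mW"].to_numpy(),
            meta={"source": str(path)},
        )

    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame({"voltage_V": self.voltage, "power_mW": self.power}).to_csv(
            path, index=False
        )


@dataclass
class PockelsFit:
    """Fitted sin^2 transmission curve and quality metrics.

    ``phase_rad`` is normalised to [0, 2*pi); ``dynamic_range`` is the
    max/min of the fitted model over the voltage range of the sweep
    (extinction-floored, see :func:`dynamic_range`).
    """

    p0_mW: float
    v0_V: float
    phase_rad: float
    rmse_mW: float
    dynamic_range: float
    stderr: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.p0_mW <= 0 or self.v0_V <= 0:
            raise InvalidParameterError("P0 and V0 must be positive")
        if not 0 <= self.phase_rad < _TWO_PI:
            raise InvalidParameterError("phase must be normalised to [0, 2*pi)")
        if self.dynamic_range < 1:
            raise InvalidParameterError("dynamic range must be >= 1")

    def to_dict(self) -> dict:
        return asdict(self)


def transmission_model(
    v: np.ndarray | float, p0: float, v0: float, phase: float
) -> np.ndarray | float:
    """Evaluate P0 * sin^2(pi V / V0 + phi/2)."""
    if p0 <= 0 or v0 <= 0:
        raise InvalidParameterError("P0 and V0 must be positive")
    return p0 * np.sin(np.pi * np.asarray(v, dtype=float) / v0 + phase / 2.0) ** 2


def _period_guess(voltage: np.ndarray, power: np.ndarray) -> float:
    """Estimate V0 from the dominant frequency of the sweep.

    P(V) is a raised cosine of period V0, so the spectrum of the detrended
    sweep (resampled to a uniform grid) peaks at 1/V0.  The peak bin is
    refined by parabolic interpolation of the log-magnitude.
    """
    n = max(256, 4 * voltage.size)
    grid = np.linspace(voltage[0], voltage[-1], n)
    p = np.interp(grid, voltage, power)
    p = p - p.mean()
    spec = np.abs(np.fft.rfft(p * np.hanning(n)))
    if spec.size < 3:
        raise DegenerateDataError("sweep too short for period estimation")
    k = int(np.argmax(spec[1:])) + 1
    # parabolic refinement on log magnitude (guard the edges)
    if 1 <= k < spec.size - 1 and spec[k - 1] > 0 and spec[k + 1] > 0:
        la, lb, lc = np.log(spec[k - 1]), np.log(spec[k]), np.log(spec[k + 1])
        denom = la - 2 * lb + lc
        if denom < 0:
            k = k + 0.5 * (la - lc) / denom
    span = grid[-1] - grid[0]
    freq = k / span
    return 1.0 / freq


def fit_transmission(sweep: PowerSweep, n_phase_starts: int = 8) -> PockelsFit:
    """Nonlinear least-squares fit of the sin^2 transmission model.

    Initialisation: P0 from the sweep maximum, V0 from the dominant spectral
    period, and the phase from a grid of ``n_phase_starts`` equispaced
    starting values; the lowest-RMSE converged solution is kept (ties broken
    by the smallest normalised phase).
    """
    v, p = sweep.voltage, sweep.power
    span = p.max() - p.min()
    if span <= 0 or span < 1e-9 * max(p.max(), 1.0):
        raise DegenerateDataError("powers are constant or nearly constant")

    p0_init = p.max()
    v0_init = _period_guess(v, p)

    best = None
    diagnostics = []
    for phase0 in np.linspace(0, _TWO_PI, n_phase_starts, endpoint=False):
        try:
            popt, pcov = curve_fit(
                lambda x, p0, v0, ph: p0 * np.sin(np.pi * x / v0 + ph / 2.0) ** 2,
                v,
                p,
                p0=[p0_init, v0_init, phase0],
                bounds=([1e-12, 1e-12, -4 * np.pi], [np.inf, np.inf, 4 * np.pi]),
                maxfev=5000,
            )
        except RuntimeError as exc:  # no convergence from this start
            diagnostics.append(str(exc))
            continue
        resid = p - popt[0] * np.sin(np.pi * v / popt[1] + popt[2] / 2.0) ** 2
        rmse = float(np.sqrt(np.mean(resid**2)))
        phase = float(np.mod(popt[2], _TWO_PI))
        key = (round(rmse, 12), phase)
        if best is None or key < best[0]:
            best = (key, popt, pcov, rmse, phase)
    if best is None:
        raise FitFailureError(
            "sin^2 fit did not converge from any phase start; " + "; ".join(diagnostics)
        )

    _, popt, pcov, rmse, phase = best
    p0_fit, v0_fit = float(popt[0]), float(popt[1])
    perr = np.sqrt(np.clip(np.diag(pcov), 0, np.inf))
    fit = PockelsFit(
        p0_mW=p0_fit,
        v0_V=v0_fit,
        phase_rad=phase,
        rmse_mW=rmse,
        dynamic_range=1.0,
        stderr={"p0_mW": float(perr[0]), "v0_V": float(perr[1]), "phase_rad": float(perr[2])},
    )
    fit.dynamic_range = dynamic_range(fit, float(v[0]), float(v[-1]))[0]
    return fit


def dynamic_range(
    fit: PockelsFit,
    v_min: float,
    v_max: float,
    extinction_floor: float = 1e-4,
) -> tuple[float, float, float]:
    """Max/min of the fitted model over [v_min, v_max].

    The minimum is floored at ``extinction_floor * P0`` because the ideal
    model reaches an exact null.  Returns (ratio, v_at_max, v_at_min).
    """
    if not v_min < v_max:
        raise InvalidParameterError("require v_min < v_max")
    # stationary points of sin^2: pi V / V0 + phi/2 = k pi / 2
    k_lo = np.ceil((np.pi * v_min / fit.v0_V + fit.phase_rad / 2) / (np.pi / 2))
    k_hi = np.floor((np.pi * v_max / fit.v0_V + fit.phase_rad / 2) / (np.pi / 2))
    ks = np.arange(k_lo, k_hi + 1)
    candidates = np.concatenate(
        [[v_min, v_max], (ks * np.pi / 2 - fit.phase_rad / 2) * fit.v0_V / np.pi]
    )
    candidates = candidates[(candidates >= v_min) & (candidates <= v_max)]
    values = transmission_model(candidates, fit.p0_mW, fit.v0_V, fit.phase_rad)
    i_max, i_min = int(np.argmax(values)), int(np.argmin(values))
    floor = extinction_floor * fit.p0_mW
    ratio = float(values[i_max] / max(values[i_min], floor))
    return max(ratio, 1.0), float(candidates[i_max]), float(candidates[i_min])
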