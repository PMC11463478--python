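"""Pulse-width estimation from a fluorescence-vs-dispersion sweep.

Two-photon fluorescence from a Gaussian pulse of transform-limited FWHM
``dtau`` scales inversely with the stretched pulse duration.  Sweeping the
laser's group-delay-dispersion (GDD) compensation ``phi`` against a fixed
system dispersion ``phi0`` gives

    I(phi) = I0 * [1 + alpha * (phi + phi0)^2 / dtau^4]^(-1/2),
    alpha  = 16 * ln(2)^2,

so a desk-top sweep of the compensation setting estimates both the system
dispersion and the pulse width without an autocorrelator.  Applied
compensation values are negative by convention; the fluorescence peak sits
at ``phi = -phi0`` and the fitted ``gdd0_fs2`` is the (positive) system
dispersion magnitude.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit
from scipy.stats import skew

from .errors import DegenerateDataError, FitFailureError, InvalidParameterError

__all__ = [
    "ALPHA",
    "GddSweep",
    "PulseFit",
    "fluorescence_model",
    "broadened_pulse_width",
    "fit_gdd_sweep",
]

#: Gaussian-pulse broadening constant 16 ln(2)^2 (dimensionless).
ALPHA: float = 16.0 * math.log(2.0) ** 2


@dataclass
class GddSweep:
    """Applied GDD compensation (fs^2) versus fluorescence (a.u.)."""

    gdd_fs2: np.ndarray
    fluorescence_au: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.gdd_fs2 = np.asarray(self.gdd_fs2, dtype=float)
        self.fluorescence_au = np.asarray(self.fluorescence_au, dtype=float)
        if self.gdd_fs2.ndim != 1 or self.gdd_fs2.shape != self.fluorescence_au.shape:
            raise InvalidParameterError("gdd and fluorescence must be equal-length 1-D arrays")
        if self.gdd_fs2.size < 8:
            raise InvalidParameterError("need at least 8 sweep points")
        if np.unique(self.gdd_fs2).size != self.gdd_fs2.size:
            raise InvalidParameterError("gdd values must be distinct")
        if np.any(self.fluorescence_au < 0):
            raise InvalidParameterError("fluorescence must be non-negative")

    @classmethod
    def from_csv(cls, path: str | Path) -> "GddSweep":
        """Read a two-column CSV with header ``gdd_fs2,fluorescence_au``."""
        df = pd.read_csv(path)
        missing = {"gdd_fs2", "fluorescence_au"} - set(df.columns)
        if missing:
            raise InvalidParameterError(f"CSV missing columns: {sorted(missing)}")
        return cls(
            gdd_fs2=df["gdd_fs2"].to_numpy(),
            fluorescence_au=df["fluorescence_au"].to_numpy(),
            meta={"source": str(path)},
        )

    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame(
            {"gdd_fs2": self.gdd_fs2, "fluorescence_au": self.fluorescence_au}
        ).to_csv(path, index=False)


@dataclass
class PulseFit:
    """Fitted dispersion curve: peak, system dispersion, pulse FWHM."""

    i0_au: float
    gdd0_fs2: float
    dtau_fs: float
    rmse: float
    stderr: dict = field(default_factory=dict)
    warnings: list = field(default_factory=list)
    residual_skewness: float = 0.0

    def __post_init__(self) -> None:
        if self.i0_au <= 0 or self.dtau_fs <= 0:
            raise InvalidParameterError("I0 and dtau must be positive")
        if not np.isfinite(self.gdd0_fs2):
            raise InvalidParameterError("gdd0 must be finite")

    def to_dict(self) -> dict:
        return asdict(self)


def fluorescence_model(
    gdd: np.ndarray | float, i0: float, gdd0: float, dtau: float
) -> np.ndarray | float:
    """I0 * [1 + alpha (phi + phi0)^2 / dtau^4]^(-1/2)."""
    if i0 <= 0 or dtau <= 0:
        raise InvalidParameterError("I0 and dtau must be positive")
    g = np.asarray(gdd, dtype=float)
    return i0 / np.sqrt(1.0 + ALPHA * (g + gdd0) ** 2 / dtau**4)


def broadened_pulse_width(dtau: float, net_gdd: float) -> float:
    """FWHM of a Gaussian pulse after accumulating ``net_gdd`` of dispersion.

    dtau_out = dtau * sqrt(1 + alpha * gdd^2 / dtau^4); the inverse of this
    broadening factor is exactly the fluorescence loss in
    :func:`fluorescence_model`.
    """
    if dtau <= 0:
        raise InvalidParameterError("dtau must be positive")
    return dtau * math.sqrt(1.0 + ALPHA * net_gdd**2 / dtau**4)


def _dtau_from_half_width(gdd: np.ndarray, fluor: np.ndarray) -> float | None:
    """Initial dtau from the sweep's half-maximum width.

    At half maximum the model bracket equals 4, i.e.
    |phi + phi0| = sqrt(3/alpha) * dtau^2, so dtau = (alpha x^2 / 3)^(1/4)
    with x the half-width at half maximum.
    """
    order = np.argsort(gdd)
    g, f = gdd[order], fluor[order]
    i_pk = int(np.argmax(f))
    half = f[i_pk] / 2.0
    left = right = None
    for i in range(i_pk, 0, -1):
        if f[i - 1] <= half:
            left = np.interp(half, [f[i - 1], f[i]], [g[i - 1], g[i]])
            break
    for i in range(i_pk, g.size - 1):
        if f[i + 1] <= half:
            right = np.interp(half, [f[i + 1], f[i]], [g[i + 1], g[i]])
            break
    widths = [abs(g[i_pk] - x) for x in (left, right) if x is not None]
    if not widths:
        return None
    x = float(np.mean(widths))
    return (ALPHA * x**2 / 3.0) ** 0.25


def fit_gdd_sweep(sweep: GddSweep) -> PulseFit:
    """Least-squares fit of (I0, phi0, dtau) to a dispersion sweep.

    Initialisation: I0 from the maximum, -phi0 from its location, dtau from
    the half-maximum width via the bracket=4 identity.  Standard errors come
    from the fit covariance.  A sweep whose maximum sits on the boundary
    (no interior peak) is fitted anyway but flagged with a warning.
    """
    g, f = sweep.gdd_fs2, sweep.fluorescence_au
    span = f.max() - f.min()
    if span <= 0 or span < 1e-9 * max(f.max(), 1.0):
        raise DegenerateDataError("fluorescence is constant or nearly constant")

    warnings: list[str] = []
    order = np.argsort(g)
    i_pk = int(np.argmax(f[order]))
    if i_pk in (0, g.size - 1):
        warnings.append("no_interior_maximum")

    i0_init = float(f.max())
    gdd0_init = -float(g[int(np.argmax(f))])
    dtau_init = _dtau_from_half_width(g, f)
    if dtau_init is None:
        # no half-max crossing inside the sweep: scale from the sweep span
        dtau_init = (ALPHA * (np.ptp(g) / 2.0) ** 2 / 3.0) ** 0.25
        warnings.append("half_width_not_bracketed")

    try:
        popt, pcov = curve_fit(
            lambda x, i0, g0, dt: i0 / np.sqrt(1.0 + ALPHA * (x + g0) ** 2 / dt**4),
            g,
            f,
            p0=[i0_init, gdd0_init, dtau_init],
            bounds=([1e-12, -np.inf, 1e-12], [np.inf, np.inf, np.inf]),
            maxfev=10000,
        )
    except RuntimeError as exc:
        raise FitFailureError(f"dispersion fit did not converge: {exc}") from exc

    resid = f - popt[0] / np.sqrt(1.0 + ALPHA * (g + popt[1]) ** 2 / popt[2] ** 4)
    perr = np.sqrt(np.clip(np.diag(pcov), 0, np.inf))
    return PulseFit(
        i0_au=float(popt[0]),
        gdd0_fs2=float(popt[1]),
        dtau_fs=float(abs(popt[2])),
        rmse=float(np.sqrt(np.mean(resid**2))),
        stderr={
            "i0_au": float(perr[0]),
            "gdd0_fs2": float(perr[1]),
            "dtau_fs": float(perr[2]),
        },
        warnings=warnings,
        residual_skewness=float(skew(resid)) if resid.size > 2 else 0.0,
    )
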