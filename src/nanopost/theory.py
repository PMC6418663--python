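"""Analytic confinement scaling for a chain in a channel-and-slit picture.

The interstitial space of the post array is approximated by a channel of
diameter ``d_c`` and the passage aperture by a slit of width ``w_p``.
This module collects the resulting scaling formulas: the free-energy
threshold for multi-cell occupancy, the Odijk and de Gennes channel
extensions, the deflection length, confinement-regime classification, and
the damped-oscillation model of tangent correlations in the Odijk regime
together with its nonlinear fit.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit

from .constants import ODIJK_A

__all__ = [
    "occupancy_threshold_ratio",
    "odijk_extension",
    "degennes_extension",
    "deflection_length",
    "deflection_correlation",
    "fit_deflection_correlation",
    "DeflectionFit",
    "classify_regime",
    "RegimeResult",
]


def occupancy_threshold_ratio(m: float = 5.0 / 3.0) -> float:
    """Critical d_c/w_p below which multi-cell occupancy becomes favorable.

    Balancing twice the channel confinement free energy against the slit
    free energy, with both scaling as size^(-m), gives the threshold
    2*d_c^(-m) = w_p^(-m), i.e. d_c/w_p = 2^(1/m).  For the de Gennes
    exponent m = 5/3 this is 2^(3/5) ~ 1.52.
    """
    if m <= 0:
        raise ValueError("scaling exponent m must be positive")
    return 2.0 ** (1.0 / m)


def odijk_extension(
    L: float,
    D: float,
    P: float,
    A: float = ODIJK_A,
    circular: bool = False,
) -> float:
    """Odijk (strong-confinement) axial extension R = L[1 - A(D/P)^(2/3)].

    Valid for D << P; a warning is emitted when D >= P.  For circular
    chains the two strands run side by side, so the extension is computed
    with L/2 (``circular=True``).
    """
    _check_positive(L=L, D=D, P=P)
    if D >= P:
        warnings.warn(
            "Odijk extension used outside its regime (D >= P)", stacklevel=2
        )
    Leff = 0.5 * L if circular else L
    return Leff * (1.0 - A * (D / P) ** (2.0 / 3.0))


def degennes_extension(L: float, D: float, P: float, w: float) -> float:
    """Blob-regime axial extension R = L (w P / D^2)^(1/3).

    Holds in both the classic and extended de Gennes regimes; the log-log
    slope versus D is exactly -2/3.  A warning is emitted when D <= P.
    """
    _check_positive(L=L, D=D, P=P, w=w)
    if D <= P:
        warnings.warn(
            "de Gennes extension used outside its regime (D <= P)", stacklevel=2
        )
    return L * (w * P / D**2) ** (1.0 / 3.0)


def deflection_length(P: float, D: float, c: float = 1.0) -> float:
    """Odijk deflection length lambda = c (P D^2)^(1/3)."""
    _check_positive(P=P, D=D)
    return c * (P * D * D) ** (1.0 / 3.0)


def deflection_correlation(n_s, l: float, P: float, lam: float):
    """Damped-oscillation tangent correlation of a strongly confined chain.

    C(n_s) = 1 - (lambda/2P) [1 + 2 exp(-n_s l/lambda) sin(n_s l/lambda - pi/4)]

    The oscillation period pi*lambda reflects successive deflections off
    the channel wall; the long-range plateau is 1 - lambda/(2P).
    """
    _check_positive(l=l, P=P, lam=lam)
    if P <= lam / 2.0:
        warnings.warn(
            "deflection correlation outside validity (P <= lambda/2)", stacklevel=2
        )
    n_s = np.asarray(n_s, dtype=float)
    x = n_s * l / lam
    out = 1.0 - (lam / (2.0 * P)) * (1.0 + 2.0 * np.exp(-x) * np.sin(x - np.pi / 4.0))
    return out if out.ndim else float(out)


@dataclass
class DeflectionFit:
    """Result of fitting the damped-oscillation correlation model."""

    P: float
    c: float
    P_err: float
    c_err: float
    covariance: np.ndarray
    residual_rms: float


def fit_deflection_correlation(
    n_s,
    C,
    l: float,
    D: float,
    P0: float = 19.4,
    c0: float = 1.0,
) -> DeflectionFit:
    """Nonlinear least squares for (P, c) with lambda = c (P D^2)^(1/3).

    ``D`` is the channel diameter standing in for the interstitial size
    d_c.  Default initial guesses are the nominal b*l persistence length
    and c = 1.
    """
    n_s = np.asarray(n_s, dtype=float)
    C = np.asarray(C, dtype=float)
    _check_positive(l=l, D=D)

    def model(ns, P, c):
        lam = c * (P * D * D) ** (1.0 / 3.0)
        x = ns * l / lam
        return 1.0 - (lam / (2.0 * P)) * (
            1.0 + 2.0 * np.exp(-x) * np.sin(x - np.pi / 4.0)
        )

    try:
        popt, pcov = curve_fit(model, n_s, C, p0=(P0, c0), maxfev=20000)
    except RuntimeError as exc:
        raise RuntimeError(
            f"deflection-correlation fit did not converge: {exc}"
        ) from exc
    resid = C - model(n_s, *popt)
    perr = np.sqrt(np.diag(pcov))
    return DeflectionFit(
        P=float(popt[0]),
        c=float(popt[1]),
        P_err=float(perr[0]),
        c_err=float(perr[1]),
        covariance=pcov,
        residual_rms=float(np.sqrt(np.mean(resid**2))),
    )


@dataclass
class RegimeResult:
    """Confinement regime and the expected structure-factor slope schedule."""

    regime: str
    slopes: dict[str, float]


#: Expected local log-log slopes of S(q) per regime, from the rod /
#: persistence scale down to the blob-string scale.
_SLOPE_SCHEDULES = {
    "odijk": {"all_q": -1.0},
    "extended_degennes": {"persistence": -1.0, "blob": -2.0, "blob_string": -1.0},
    "classic_degennes": {"persistence": -1.0, "blob": -5.0 / 3.0, "blob_string": -1.0},
}


def classify_regime(P: float, w: float, D: float) -> RegimeResult:
    """Confinement regime of a channel of diameter D.

    Odijk for D <= P (ties resolved to the stiffer regime), extended
    de Gennes for P < D <= P^2/w (anisometric blobs), classic de Gennes
    for D > P^2/w (isometric blobs).
    """
    _check_positive(P=P, w=w, D=D)
    if D <= P:
        regime = "odijk"
    elif D <= P * P / w:
        regime = "extended_degennes"
    else:
        regime = "classic_degennes"
    return RegimeResult(regime=regime, slopes=dict(_SLOPE_SCHEDULES[regime]))


def _check_positive(**kwargs: float) -> None:
    for name, value in kwargs.items():
        if value <= 0:
            raise ValueError(f"{name} must be positive, got {value}")
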