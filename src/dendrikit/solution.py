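"""Solution-scale observables: Guinier SAXS fits, Stokes-Einstein
hydrodynamics, shape-ratio classification and DOSY diffusion fitting.

The three relations implemented here:

* Guinier:        ln I(q) ~ ln I0 - (Rg**2 / 3) q**2, valid at low q
                  (q Rg <~ 1.3);
* Stokes-Einstein: R_H = k_B T / (6 pi eta D);
* Stejskal-Tanner: I(g) = I0 exp(-D (gamma delta g)**2 (Delta - delta/3))
                  for a bipolar-gradient (BPPLED-style) pulsed-field
                  gradient NMR decay.

The Rg/RH ratio classifies the overall shape: homogeneous spheres sit at
sqrt(3/5) ~ 0.775, and the conventional "sphere-like" band is 0.7-0.8.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Tuple, Union

import numpy as np
from scipy import constants as const
from scipy.optimize import curve_fit

__all__ = [
    "SAXSCurve",
    "GuinierFit",
    "HydroResult",
    "DOSYDecay",
    "DOSYFit",
    "GAMMA_1H",
    "guinier_fit",
    "q_from_angle",
    "stokes_einstein_rh",
    "stokes_einstein_d",
    "shape_ratio",
    "percent_change",
    "fit_dosy_diffusion",
    "solvent_viscosity",
]

#: 1H gyromagnetic ratio, rad s^-1 T^-1
GAMMA_1H = 2.6752218744e8

#: heuristic upper validity bound for a Guinier fit
QRG_MAX = 1.3


@dataclass
class SAXSCurve:
    """A scattering curve I(q); q in nm^-1, intensity in arbitrary units."""

    q: np.ndarray
    intensity: np.ndarray
    background: Optional["SAXSCurve"] = None

    def __post_init__(self) -> None:
        self.q = np.asarray(self.q, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.q.shape != self.intensity.shape:
            raise ValueError("q and intensity must have equal length")
        if np.any(np.diff(self.q) <= 0):
            raise ValueError("q must be strictly increasing")

    def net_intensity(self) -> np.ndarray:
        """Background-subtracted intensity on this curve's q grid (the
        background is linearly interpolated onto it if grids differ)."""
        if self.background is None:
            return self.intensity
        bg = np.interp(self.q, self.background.q, self.background.intensity)
        return self.intensity - bg

    @classmethod
    def from_file(cls, path, background=None) -> "SAXSCurve":
        data = np.loadtxt(path, delimiter=None)
        return cls(q=data[:, 0], intensity=data[:, 1], background=background)


@dataclass
class GuinierFit:
    rg: float                    # nm
    i0: float
    q_range: Tuple[float, float]
    r_squared: float
    q_rg_max: float
    n_points: int
    slope: float
    intercept: float


def _ols_guinier(q, i):
    x = q * q
    y = np.log(i)
    slope, intercept = np.polyfit(x, y, 1)
    resid = y - (slope * x + intercept)
    ss_tot = float(((y - y.mean()) ** 2).sum())
    r2 = 1.0 - float((resid ** 2).sum()) / ss_tot if ss_tot > 0 else 1.0
    return slope, intercept, r2


def _fit_in_range(q, i, lo_idx, hi_idx):
    qq, ii = q[lo_idx:hi_idx], i[lo_idx:hi_idx]
    slope, intercept, r2 = _ols_guinier(qq, ii)
    if slope >= 0:
        raise ValueError("no Guinier decay in range (non-negative slope)")
    rg = float(np.sqrt(-3.0 * slope))
    return GuinierFit(rg=rg, i0=float(np.exp(intercept)),
                      q_range=(float(qq[0]), float(qq[-1])),
                      r_squared=r2, q_rg_max=float(qq[-1] * rg),
                      n_points=qq.size, slope=float(slope),
                      intercept=float(intercept))


def guinier_fit(curve: SAXSCurve, q_range: Union[str, Tuple[float, float]] = "auto") -> GuinierFit:
    """Least-squares Guinier fit of ln I on q**2; Rg = sqrt(-3 slope).

    ``q_range="auto"`` expands from the 3 lowest-q points and keeps the
    longest prefix with q*Rg <= 1.3 and r**2 >= 0.99 -- a reproducible
    stand-in for a manual region choice. An explicit ``(q_min, q_max)``
    is used as given; a warning is raised when q_max*Rg exceeds 1.3.
    """
    q = curve.q
    i = curve.net_intensity()
    if q_range == "auto":
        best = None
        for hi in range(3, q.size + 1):
            if np.any(i[:hi] <= 0):
                break
            try:
                fit = _fit_in_range(q, i, 0, hi)
            except ValueError:
                continue  # a noisy short prefix may lack a decaying slope
            if fit.q_rg_max <= QRG_MAX and fit.r_squared >= 0.99:
                best = fit
            elif fit.q_rg_max > 2.0 * QRG_MAX:
                break  # far past the Guinier regime; it only gets worse
        if best is None:
            raise ValueError("auto range: no low-q window satisfies "
                             "q*Rg <= 1.3 and r^2 >= 0.99")
        return best
    qmin, qmax = q_range
    sel = (q >= qmin) & (q <= qmax)
    if sel.sum() < 3:
        raise ValueError("need at least 3 points in the fit range")
    if np.any(i[sel] <= 0):
        raise ValueError("non-positive intensity in the fit range; "
                         "check background subtraction")
    lo = int(np.argmax(sel))
    hi = lo + int(sel.sum())
    fit = _fit_in_range(q, i, lo, hi)
    if fit.q_rg_max > QRG_MAX:
        warnings.warn(f"Guinier validity: q_max*Rg = {fit.q_rg_max:.2f} > {QRG_MAX}")
    return fit


def q_from_angle(two_theta: float, wavelength: float) -> float:
    """Scattering vector q = 4 pi sin(theta) / lambda in nm^-1.

    ``two_theta`` is the scattering angle in degrees (0 < 2theta < 180);
    ``wavelength`` in Angstrom.
    """
    if not 0 < two_theta < 180:
        raise ValueError("two_theta must lie in (0, 180) degrees")
    theta = np.deg2rad(two_theta / 2.0)
    return float(4.0 * np.pi * np.sin(theta) / wavelength * 10.0)  # 1/A -> 1/nm


@dataclass
class HydroResult:
    d: float          # m^2/s
    temperature: float  # K
    eta: float        # Pa s
    rh: float         # nm
    ratio_rg_rh: Optional[float] = None


def stokes_einstein_rh(d: float, temperature: float, eta: float,
                       rg: Optional[float] = None) -> HydroResult:
    """Hydrodynamic radius R_H = k_B T / (6 pi eta D), in nm.

    Optionally attaches the Rg/RH ratio when ``rg`` (nm) is given.
    """
    if d <= 0 or temperature <= 0 or eta <= 0:
        raise ValueError("D, T and eta must all be positive")
    rh_m = const.k * temperature / (6.0 * np.pi * eta * d)
    rh = rh_m * 1e9
    ratio = rg / rh if rg is not None else None
    return HydroResult(d=d, temperature=temperature, eta=eta, rh=rh,
                       ratio_rg_rh=ratio)


def stokes_einstein_d(rh: float, temperature: float, eta: float) -> float:
    """Diffusion coefficient (m^2/s) from R_H (nm); inverse of the above."""
    if rh <= 0 or temperature <= 0 or eta <= 0:
        raise ValueError("RH, T and eta must all be positive")
    return const.k * temperature / (6.0 * np.pi * eta * rh * 1e-9)


def shape_ratio(rg: float, rh: float) -> Tuple[float, str]:
    """Rg/RH rounded (half-even) to 3 decimals with a shape label:
    "sphere-like" inside the conventional 0.7-0.8 band, else
    "non-spherical"."""
    if rg <= 0 or rh <= 0:
        raise ValueError("Rg and RH must be positive")
    ratio = round(rg / rh, 3)
    label = "sphere-like" if 0.7 <= ratio <= 0.8 else "non-spherical"
    return ratio, label


def percent_change(initial: float, final: float) -> float:
    """100*(final - initial)/initial, rounded half-even to 2 decimals."""
    if initial == 0:
        raise ValueError("initial value must be non-zero")
    return round(100.0 * (final - initial) / initial, 2)


# ---------------------------------------------------------------------------
# DOSY


@dataclass
class DOSYDecay:
    """PFG-NMR signal decay vs gradient strength.

    ``gradient`` in T/m (non-negative, increasing), ``delta`` the total
    bipolar gradient-pulse duration (s), ``big_delta`` the diffusion time
    (s), ``gamma`` the observed nucleus' gyromagnetic ratio (rad/s/T).
    """

    gradient: np.ndarray
    intensity: np.ndarray
    delta: float
    big_delta: float
    gamma: float = GAMMA_1H

    def __post_init__(self) -> None:
        self.gradient = np.asarray(self.gradient, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.gradient.shape != self.intensity.shape:
            raise ValueError("gradient and intensity must have equal length")
        if np.any(self.gradient < 0) or np.any(np.diff(self.gradient) <= 0):
            raise ValueError("gradient must be non-negative and increasing")
        if np.any(self.intensity <= 0):
            raise ValueError("intensities must be positive")
        if self.big_delta <= self.delta / 3.0:
            raise ValueError("need Delta > delta/3")

    def b_values(self) -> np.ndarray:
        """Stejskal-Tanner attenuation factors b = (gamma delta g)**2 (Delta - delta/3)."""
        return (self.gamma * self.delta * self.gradient) ** 2 * (self.big_delta - self.delta / 3.0)


@dataclass
class DOSYFit:
    d: float          # m^2/s
    i0: float
    r_squared: float
    rms_residual: float


def fit_dosy_diffusion(decay: DOSYDecay) -> DOSYFit:
    """Nonlinear least-squares fit of I = I0 exp(-D b) to a DOSY decay.

    Initialized from the log-linear regression of ln I on b, then refined
    with ``scipy.optimize.curve_fit``. Requires >= 4 points and an overall
    decreasing decay.
    """
    if decay.gradient.size < 4:
        raise ValueError("need at least 4 gradient points")
    if decay.intensity[-1] >= decay.intensity[0]:
        raise ValueError("decay is not decreasing overall")
    b = decay.b_values()
    y = decay.intensity
    slope, intercept = np.polyfit(b, np.log(y), 1)
    d0 = max(-slope, 1e-16)
    i00 = float(np.exp(intercept))

    def model(bv, d, i0):
        return i0 * np.exp(-d * bv)

    try:
        popt, _ = curve_fit(model, b, y, p0=[d0, i00], maxfev=10000)
    except RuntimeError as exc:
        resid = y - model(b, d0, i00)
        raise RuntimeError(
            f"DOSY fit did not converge (rms residual at init "
            f"{float(np.sqrt((resid ** 2).mean())):.3g})"
        ) from exc
    d, i0 = float(popt[0]), float(popt[1])
    if d <= 0:
        raise ValueError("fitted diffusion coefficient is non-positive")
    resid = y - model(b, d, i0)
    ss_tot = float(((y - y.mean()) ** 2).sum())
    r2 = 1.0 - float((resid ** 2).sum()) / ss_tot if ss_tot > 0 else 1.0
    return DOSYFit(d=d, i0=i0, r_squared=r2,
                   rms_residual=float(np.sqrt((resid ** 2).mean())))


# ---------------------------------------------------------------------------
# convenience: approximate solvent viscosity

# dynamic viscosity (Pa s) of pure liquids vs temperature; literature
# handbook values, intended only as a convenience for Eq.-of-Stokes use.
_ETA_H2O = {283.15: 1.3059e-3, 293.15: 1.0016e-3, 298.15: 0.8900e-3,
            303.15: 0.7972e-3, 310.15: 0.6913e-3, 313.15: 0.6527e-3}
_ETA_D2O = {283.15: 1.679e-3, 293.15: 1.2467e-3, 298.15: 1.0966e-3,
            303.15: 0.9694e-3, 310.15: 0.8413e-3, 313.15: 0.7905e-3}


def solvent_viscosity(temperature: float, d2o_fraction: float = 0.0) -> float:
    """APPROXIMATE water viscosity (Pa s) at ``temperature`` (K) for an
    H2O/D2O mixture, by linear interpolation in T and linear (ideal)
    mixing in volume fraction.

    Real H2O/D2O mixtures deviate from linear mixing by a few percent;
    measured viscosities should be preferred whenever available.
    """
    if not 0.0 <= d2o_fraction <= 1.0:
        raise ValueError("d2o_fraction must be in [0, 1]")
    th = np.array(sorted(_ETA_H2O))
    if not th[0] <= temperature <= th[-1]:
        raise ValueError(f"temperature {temperature} K outside table "
                         f"range {th[0]}..{th[-1]} K")
    eh = np.interp(temperature, th, [_ETA_H2O[t] for t in th])
    ed = np.interp(temperature, th, [_ETA_D2O[t] for t in th])
    return float((1.0 - d2o_fraction) * eh + d2o_fraction * ed)
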