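"""Spherical-indentation mechanics of soft gels.

Extracts from a load-and-hold indentation test:

* the initial (instantaneous) effective modulus ``E*_0`` by fitting Hertz's
  law ``F = (4/3) E* sqrt(R) d^(3/2)`` to the constant-rate loading segment,
* the stress-relaxation behaviour of the hold segment by a double-exponential
  fit ``F(t) = F_inf + F1 exp(-t/tau1) + F2 exp(-t/tau2)``,
* the residual (long-time) modulus ``E*_inf`` by inverting Hertz's law at the
  hold depth using the fitted residual force ``F_inf``,
* the power-law scaling of either modulus with gel concentration,
  ``E = a phi^b``, by ordinary least squares in log-log space.

Units at the interface: forces in N, depths and radii in mm, moduli in kPa,
times in s.  With those units Hertz's law carries a factor 1e-3:
``F[N] = (4/3) * E[kPa] * sqrt(R[mm]) * d[mm]^1.5 * 1e-3``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit
from sklearn.base import BaseEstimator, RegressorMixin
import statsmodels.api as sm

__all__ = [
    "IndentationCurve",
    "RelaxationFit",
    "PowerLawFit",
    "ConvergenceError",
    "hertz_force",
    "inverse_hertz_modulus",
    "HertzContactModel",
    "DoubleExponentialRelaxation",
    "PowerLawScaling",
    "fit_initial_modulus",
    "fit_relaxation",
    "residual_modulus",
    "fit_power_law",
]

# (4/3) * kPa * sqrt(mm) * mm^1.5 -> N
_HERTZ_UNIT = 1e-3


class ConvergenceError(RuntimeError):
    """Raised when the relaxation fit fails from every initialization."""

    def __init__(self, message: str, best_rss: float | None = None):
        super().__init__(message)
        self.best_rss = best_rss


def hertz_force(d, E_star, R):
    """Hertz contact force (N) of a rigid sphere on an elastic half-space.

    Parameters: d indentation depth (mm), E_star effective modulus (kPa),
    R indenter radius (mm).
    """
    d = np.asarray(d, dtype=float)
    if np.any(d < 0):
        raise ValueError("indentation depth must be >= 0")
    if E_star <= 0 or R <= 0:
        raise ValueError("E_star and R must be > 0")
    out = (4.0 / 3.0) * E_star * np.sqrt(R) * d**1.5 * _HERTZ_UNIT
    return float(out) if out.ndim == 0 else out


def inverse_hertz_modulus(F, d, R):
    """Effective modulus (kPa) from a Hertz force F (N) at depth d (mm)."""
    if d <= 0 or R <= 0:
        raise ValueError("d and R must be > 0")
    return 3.0 * F / (4.0 * np.sqrt(R) * d**1.5) / _HERTZ_UNIT


@dataclass
class IndentationCurve:
    """A sampled load-and-hold spherical indentation record.

    t in s (strictly increasing), d in mm (ramp to d_max, then constant),
    F in N; R the indenter radius (mm) and rate the displacement rate (mm/s).
    """

    t: np.ndarray
    d: np.ndarray
    F: np.ndarray
    R: float
    rate: float
    d_max: float

    def __post_init__(self):
        self.t = np.asarray(self.t, dtype=float)
        self.d = np.asarray(self.d, dtype=float)
        self.F = np.asarray(self.F, dtype=float)
        if not (self.t.shape == self.d.shape == self.F.shape):
            raise ValueError("t, d, F must have equal length")
        if np.any(np.diff(self.t) <= 0):
            raise ValueError("t must be strictly increasing")
        if self.d_max <= 0:
            raise ValueError("d_max must be > 0")

    @property
    def hold_start_index(self) -> int:
        """Index of the first sample at the hold depth."""
        at_max = np.flatnonzero(self.d >= self.d_max * (1.0 - 1e-9))
        if at_max.size == 0:
            raise ValueError("curve never reaches d_max; no hold segment")
        return int(at_max[0])

    def loading_segment(self):
        """(d, F) of the constant-rate loading ramp, including the peak."""
        i = self.hold_start_index
        return self.d[: i + 1], self.F[: i + 1]

    def hold_segment(self):
        """(t, F) of the relaxation hold, t re-zeroed at the hold start."""
        i = self.hold_start_index
        return self.t[i:] - self.t[i], self.F[i:]


@dataclass
class RelaxationFit:
    """Double-exponential stress-relaxation fit of the hold segment."""

    F_inf: float
    F1: float
    F2: float
    tau1: float
    tau2: float
    rss: float

    def __post_init__(self):
        if self.tau1 > self.tau2:  # canonical ordering tau1 < tau2
            self.tau1, self.tau2 = self.tau2, self.tau1
            self.F1, self.F2 = self.F2, self.F1

    def predict(self, t):
        t = np.asarray(t, dtype=float)
        return self.F_inf + self.F1 * np.exp(-t / self.tau1) + self.F2 * np.exp(-t / self.tau2)


@dataclass
class PowerLawFit:
    """Power law E = a * phi^b with a in kPa at phi = 1% and b dimensionless."""

    prefactor: float
    exponent: float
    se_exponent: float

    def predict(self, phi):
        return self.prefactor * np.asarray(phi, dtype=float) ** self.exponent


class HertzContactModel(BaseEstimator, RegressorMixin):
    """Hertz loading fit: force regressed on depth^(3/2) through the origin.

    Parameters
    ----------
    R : float
        Indenter radius in mm.

    Attributes
    ----------
    E0_star_ : float
        Initial effective modulus in kPa.
    slope_ : float
        Fitted slope of F vs d^(3/2) (N / mm^1.5).
    """

    def __init__(self, R: float = 1.565):
        self.R = R

    def fit(self, d, F):
        d = np.asarray(d, dtype=float).ravel()
        F = np.asarray(F, dtype=float).ravel()
        if d.size != F.size or d.size < 10:
            raise ValueError("need >= 10 loading samples of equal length")
        if np.any(np.diff(d) < 0):
            raise ValueError("loading depths must be non-decreasing")
        if self.R <= 0:
            raise ValueError("R must be > 0")
        x = d**1.5
        self.slope_ = float(x @ F / (x @ x))
        self.E0_star_ = 0.75 * self.slope_ / np.sqrt(self.R) / _HERTZ_UNIT
        return self

    def predict(self, d):
        return self.slope_ * np.asarray(d, dtype=float) ** 1.5


class DoubleExponentialRelaxation(BaseEstimator, RegressorMixin):
    """Multi-start nonlinear fit of F(t) = F_inf + F1 e^(-t/tau1) + F2 e^(-t/tau2).

    Relaxation times are initialized on an ``n_starts x n_starts`` log-spaced
    grid over ``tau_bounds`` (only ordered pairs tau1 < tau2 are tried); the
    best fit by residual sum of squares is kept and reported with tau1 < tau2.

    Attributes: ``F_inf_``, ``F1_``, ``F2_``, ``tau1_``, ``tau2_``, ``rss_``,
    and ``result_`` (a :class:`RelaxationFit`).
    """

    def __init__(self, tau_bounds=(10.0, 1e4), n_starts: int = 4,
                 nonnegative_amplitudes: bool = True):
        self.tau_bounds = tau_bounds
        self.n_starts = n_starts
        self.nonnegative_amplitudes = nonnegative_amplitudes

    @staticmethod
    def _model(t, F_inf, F1, F2, tau1, tau2):
        return F_inf + F1 * np.exp(-t / tau1) + F2 * np.exp(-t / tau2)

    def fit(self, t, F):
        t = np.asarray(t, dtype=float).ravel()
        F = np.asarray(F, dtype=float).ravel()
        if t.size != F.size or t.size < 50:
            raise ValueError("need >= 50 hold samples of equal length")

        amp = max(F[0] - F[-1], 0.0)
        f_inf0 = max(F[-1], 0.0)
        lo_amp = 0.0 if self.nonnegative_amplitudes else -np.inf
        bounds = (
            [0.0, lo_amp, lo_amp, 1e-6, 1e-6],
            [np.inf, np.inf, np.inf, np.inf, np.inf],
        )
        taus = np.geomspace(*self.tau_bounds, self.n_starts)
        best = None
        best_rss = np.inf
        for i, t1 in enumerate(taus):
            for t2 in taus[i + 1:]:
                p0 = [f_inf0, amp / 2.0, amp / 2.0, t1, t2]
                try:
                    popt, _ = curve_fit(self._model, t, F, p0=p0, bounds=bounds,
                                        maxfev=20000)
                except (RuntimeError, ValueError):
                    continue
                rss = float(np.sum((F - self._model(t, *popt)) ** 2))
                if rss < best_rss:
                    best_rss, best = rss, popt
        if best is None:
            raise ConvergenceError("relaxation fit failed from every start",
                                   best_rss=None)
        fit = RelaxationFit(F_inf=float(best[0]), F1=float(best[1]), F2=float(best[2]),
                            tau1=float(best[3]), tau2=float(best[4]), rss=best_rss)
        self.result_ = fit
        self.F_inf_, self.F1_, self.F2_ = fit.F_inf, fit.F1, fit.F2
        self.tau1_, self.tau2_, self.rss_ = fit.tau1, fit.tau2, fit.rss
        return self

    def predict(self, t):
        return self.result_.predict(t)


class PowerLawScaling(BaseEstimator, RegressorMixin):
    """OLS fit of log E on log phi: E = prefactor * phi^exponent.

    Attributes: ``prefactor_`` (kPa at phi = 1%), ``exponent_``,
    ``se_exponent_`` and ``result_`` (a :class:`PowerLawFit`).
    """

    def fit(self, phi, E):
        phi = np.asarray(phi, dtype=float).ravel()
        E = np.asarray(E, dtype=float).ravel()
        if phi.size != E.size or phi.size < 3:
            raise ValueError("need >= 3 (phi, E) points of equal length")
        if np.any(phi <= 0) or np.any(E <= 0):
            raise ValueError("phi and E must all be > 0 for a log-log fit")
        X = sm.add_constant(np.log(phi))
        res = sm.OLS(np.log(E), X).fit()
        self.prefactor_ = float(np.exp(res.params[0]))
        self.exponent_ = float(res.params[1])
        self.se_exponent_ = float(res.bse[1])
        self.result_ = PowerLawFit(self.prefactor_, self.exponent_, self.se_exponent_)
        return self

    def predict(self, phi):
        return self.result_.predict(phi)


# -- thin functional wrappers ------------------------------------------------

def fit_initial_modulus(curve: IndentationCurve) -> float:
    """Initial effective modulus E*_0 (kPa) from the loading segment."""
    d, F = curve.loading_segment()
    return HertzContactModel(R=curve.R).fit(d, F).E0_star_


def fit_relaxation(curve: IndentationCurve, discard_s: float = 1.0,
                   **estimator_kwargs) -> RelaxationFit:
    """Double-exponential fit of the hold segment.

    Time is re-zeroed at the hold start and the first ``discard_s`` seconds
    are discarded to avoid ramp-stop transients (the fitted time origin stays
    at the hold start, so amplitudes remain comparable across windows).
    """
    t, F = curve.hold_segment()
    keep = t >= discard_s
    return DoubleExponentialRelaxation(**estimator_kwargs).fit(t[keep], F[keep]).result_


def residual_modulus(fit: RelaxationFit, R: float, d_max: float) -> float:
    """Residual (long-time) modulus E*_inf (kPa) via inverse Hertz at d_max."""
    if fit.F_inf < 0:
        raise ValueError("residual force must be >= 0")
    return inverse_hertz_modulus(fit.F_inf, d_max, R)


def fit_power_law(phi, E) -> PowerLawFit:
    """Power-law scaling E = a phi^b of modulus with gel concentration."""
    return PowerLawScaling().fit(phi, E).result_
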