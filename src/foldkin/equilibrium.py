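"""Two-state equilibrium denaturation analysis (linear extrapolation method).

The observed signal of a two-state unfolding transition with linear
native and denatured baselines is

    S_obs(D) = f_N(D) * (a + b*D) + (1 - f_N(D)) * (c + d*D)

with the native fraction given by the linear extrapolation of the
unfolding free energy, dG(D) = dG_UN + M_UN * D:

    f_N(D) = 1 / (1 + exp(dG(D) / RT)).

With dG_UN negative for a stable protein f_N -> 1 at low urea and -> 0
past the midpoint D_1/2 = -dG_UN / M_UN. Inverting the signal model
recovers f_N from data:  f_N = (S_obs - B_D(D)) / (B_N(D) - B_D(D)).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import least_squares
from scipy.special import expit
from sklearn.base import BaseEstimator

from .conditions import DEFAULT_CONDITIONS, ExperimentConditions
from .datasets import EquilibriumCurve

__all__ = [
    "EquilibriumFit",
    "EquilibriumCurveFitter",
    "fit_equilibrium_curve",
    "equilibrium_signal",
    "fraction_native",
    "fraction_native_model",
]

_PARAM_NAMES = ["dG_UN", "M_UN", "bN_icpt", "bN_slope", "bD_icpt", "bD_slope"]


@dataclass
class EquilibriumFit:
    """Fitted LEM parameters with 1-sigma errors and covariance.

    ``baseline_N``/``baseline_D`` are (intercept, slope) pairs; in the
    conventional (a..d) notation a/b are the native intercept/slope and
    c/d the denatured ones.
    """

    dG_UN: float
    M_UN: float
    baseline_N: tuple[float, float]
    baseline_D: tuple[float, float]
    sigma: dict[str, float] = field(default_factory=dict)
    covariance: pd.DataFrame | None = None
    residual_rms: float = 0.0
    identifiable: bool = True
    success: bool = True
    probe: str = "fluorescence"

    @property
    def midpoint(self) -> float:
        """Denaturant concentration of half-unfolding, M."""
        return -self.dG_UN / self.M_UN


def fraction_native_model(dG_UN: float, M_UN: float, D, cond=DEFAULT_CONDITIONS):
    """f_N(D) = 1/(1 + exp((dG_UN + M_UN*D)/RT)), numerically stable."""
    D = np.asarray(D, dtype=float)
    return expit(-(dG_UN + M_UN * D) / cond.RT)


def equilibrium_signal(fit: EquilibriumFit, D, cond: ExperimentConditions = DEFAULT_CONDITIONS):
    """Model signal S_obs(D) for the fitted parameters."""
    D = np.asarray(D, dtype=float)
    fN = fraction_native_model(fit.dG_UN, fit.M_UN, D, cond)
    bN = fit.baseline_N[0] + fit.baseline_N[1] * D
    bD = fit.baseline_D[0] + fit.baseline_D[1] * D
    return fN * bN + (1.0 - fN) * bD


def fraction_native(S_obs, fit: EquilibriumFit, D):
    """Invert the signal model: f_N = (S - B_D)/(B_N - B_D).

    Noisy data may fall slightly outside [0, 1]; values are not clipped.
    """
    D = np.asarray(D, dtype=float)
    bN = fit.baseline_N[0] + fit.baseline_N[1] * D
    bD = fit.baseline_D[0] + fit.baseline_D[1] * D
    denom = bN - bD
    if np.any(denom == 0):
        raise ZeroDivisionError("native and denatured baselines coincide at some D")
    return (np.asarray(S_obs, dtype=float) - bD) / denom


class EquilibriumCurveFitter(BaseEstimator):
    """Least-squares fit of the six LEM parameters to one denaturation curve.

    Accepts an :class:`EquilibriumCurve` (or ``fit(D, signal)`` arrays).
    Fitted attributes: ``fit_`` (:class:`EquilibriumFit`), plus ``dG_UN_``,
    ``M_UN_`` shortcuts. ``fit_.identifiable`` is False when the fitted
    midpoint falls outside the data range or the data do not bracket the
    transition.
    """

    def __init__(self, conditions: ExperimentConditions | None = None, max_nfev: int = 5000):
        self.conditions = conditions
        self.max_nfev = max_nfev

    def fit(self, X, y=None):
        if isinstance(X, EquilibriumCurve):
            curve = X
        else:
            curve = EquilibriumCurve(np.asarray(X, float).ravel(), np.asarray(y, float))
        cond = self.conditions or DEFAULT_CONDITIONS
        D, S = curve.denaturant, curve.signal

        theta0 = self._initial_guess(D, S)

        def residuals(theta):
            dG, M, aN, bN, aD, bD = theta
            fN = fraction_native_model(dG, M, D, cond)
            model = fN * (aN + bN * D) + (1 - fN) * (aD + bD * D)
            return model - S

        lo = [-200.0, 1e-3, -np.inf, -np.inf, -np.inf, -np.inf]
        hi = [200.0, 50.0, np.inf, np.inf, np.inf, np.inf]
        sol = least_squares(
            residuals, theta0, bounds=(lo, hi), method="trf", x_scale="jac",
            ftol=1e-14, xtol=1e-14, gtol=1e-14, max_nfev=self.max_nfev,
        )

        J = sol.jac
        dof = max(len(D) - 6, 1)
        s2 = 2.0 * sol.cost / dof
        cov = np.linalg.pinv(J.T @ J) * s2
        cov_df = pd.DataFrame(cov, index=_PARAM_NAMES, columns=_PARAM_NAMES)
        diag = np.sqrt(np.clip(np.diag(cov), 0.0, np.inf))

        dG, M = float(sol.x[0]), float(sol.x[1])
        fN_data = fraction_native_model(dG, M, D, cond)
        midpoint = -dG / M
        identifiable = bool(
            D.min() <= midpoint <= D.max()
            and fN_data.min() < 0.2
            and fN_data.max() > 0.8
        )

        self.fit_ = EquilibriumFit(
            dG_UN=dG,
            M_UN=M,
            baseline_N=(float(sol.x[2]), float(sol.x[3])),
            baseline_D=(float(sol.x[4]), float(sol.x[5])),
            sigma=dict(zip(_PARAM_NAMES, diag)),
            covariance=cov_df,
            residual_rms=float(np.sqrt(np.mean(sol.fun**2))),
            identifiable=identifiable,
            success=bool(sol.success),
            probe=curve.probe,
        )
        self.dG_UN_ = dG
        self.M_UN_ = M
        return self

    @staticmethod
    def _initial_guess(D, S):
        n_edge = max(len(D) // 6, 2)
        order = np.argsort(D)
        Ds, Ss = D[order], S[order]
        bN = np.polyfit(Ds[:n_edge], Ss[:n_edge], 1)
        bD = np.polyfit(Ds[-n_edge:], Ss[-n_edge:], 1)
        # midpoint: crossing of the half-way signal
        mid_sig = 0.5 * (np.mean(Ss[:n_edge]) + np.mean(Ss[-n_edge:]))
        i_mid = int(np.argmin(np.abs(Ss - mid_sig)))
        D_mid = float(np.clip(Ds[i_mid], Ds[0] + 0.1, Ds[-1] - 0.1))
        M0 = 4.0
        return np.array([-M0 * D_mid, M0, bN[1], bN[0], bD[1], bD[0]])

    def predict(self, D):
        """Model signal at urea concentrations ``D``."""
        cond = self.conditions or DEFAULT_CONDITIONS
        return equilibrium_signal(self.fit_, D, cond)


def fit_equilibrium_curve(
    curve: EquilibriumCurve, cond: ExperimentConditions | None = None, **kwargs
) -> EquilibriumFit:
    """Functional wrapper around :class:`EquilibriumCurveFitter`."""
    return EquilibriumCurveFitter(conditions=cond, **kwargs).fit(curve).fit_
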