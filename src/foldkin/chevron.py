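"""Nonlinear least-squares fitting of chevron plots and kinetic traces.

The central objects are scikit-learn-style estimators:

* :class:`ThreeStateChevronFitter` — global fit of the slow observed rate
  plus burst-phase (initial) and endpoint fluorescence amplitudes to the
  on-pathway U<->I<->N scheme, with the fast U<->I step fixed by default
  to the continuous-flow values (k_UI = 1574 s^-1, m_UI = 1.23
  kJ mol^-1 M^-1) and the intermediate's stability carried by k_IU.
* :class:`TwoStateChevronFitter` — the same machinery for U<->N.
* :class:`ExponentialTraceFitter` — single/double exponential fits of raw
  stopped-flow traces.

Rate residuals are computed on ln k_obs (multiplicative noise;
chevrons are analysed in log space), amplitude residuals on the linear
normalised scale; unless per-point sigmas are given the two blocks are
re-weighted once by their per-block residual RMS. Rates are optimised in
log space (positivity), m-values linearly with a lower bound at zero.
1-sigma errors come from the Gauss-Newton covariance s^2 (J^T J)^-1 at
the optimum.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import least_squares
from scipy.stats import qmc
from sklearn.base import BaseEstimator

from .conditions import DEFAULT_CONDITIONS, ExperimentConditions
from .datasets import REFOLDING, UNFOLDING, ChevronDataset, KineticTrace
from .models import (
    KineticScheme,
    ThermoSummary,
    equilibrium_populations,
    make_three_state_scheme,
    make_two_state_scheme,
    observed_slow_rate,
    thermo_summary,
)

__all__ = [
    "FitConstraints",
    "FitResult",
    "ThreeStateChevronFitter",
    "TwoStateChevronFitter",
    "ExponentialTraceFitter",
    "TraceFit",
    "fit_chevron_three_state",
    "fit_chevron_two_state",
    "fit_exponential_trace",
    "amplitude_model",
    "normalize_signals",
]

#: fast-phase parameters from continuous-flow mixing, fixed by default
DEFAULT_FIXED_THREE_STATE = {"k_UI": 1574.0, "m_UI": 1.23}

_LN_RATE_LO, _LN_RATE_HI = math.log(1e-7), math.log(1e7)
_M_LO, _M_HI = 0.0, 10.0


# ---------------------------------------------------------------------------
# signal models


def amplitude_model(
    scheme: KineticScheme,
    D,
    direction: str,
    cond: ExperimentConditions = DEFAULT_CONDITIONS,
):
    """Initial and final fluorescence of a mixing experiment at urea D.

    The final signal is the population-weighted equilibrium baseline. The
    initial signal for refolding assumes the fast U<->I step is complete
    within the instrument dead time, so U and I are pre-equilibrated
    (weights 1 : K_UI(D)) while N is still unpopulated; for a two-state
    scheme there is no burst phase and the initial refolding signal is the
    unfolded baseline. For unfolding the initial signal is the native
    baseline.
    """
    D = np.asarray(D, dtype=float)
    pU, pI, pN = equilibrium_populations(scheme, D, cond)
    base = {sp: scheme.baseline(sp, D) for sp in scheme.species}
    if scheme.n_states == 3:
        final = pU * base["U"] + pI * base["I"] + pN * base["N"]
    else:
        final = pU * base["U"] + pN * base["N"]
    if direction == REFOLDING:
        if scheme.n_states == 3:
            # burst-phase U/I pre-equilibrium, numerically stable in log K
            logK = scheme.log_K_UI(D, cond)
            w = 1.0 / (1.0 + np.exp(-logK))  # = K/(1+K)
            initial = (1.0 - w) * base["U"] + w * base["I"]
        else:
            initial = base["U"] + np.zeros_like(D)
    elif direction == UNFOLDING:
        initial = base["N"] + np.zeros_like(D)
    else:
        raise ValueError(f"direction must be refolding/unfolding, got {direction!r}")
    return initial, final


def normalize_signals(raw, blank, reference):
    """(raw - blank)/(reference - blank); the 7.75 M reference maps to 1."""
    denom = reference - blank
    if denom == 0:
        raise ZeroDivisionError("reference signal equals the buffer blank")
    return (np.asarray(raw, dtype=float) - blank) / denom


# ---------------------------------------------------------------------------
# parameter bookkeeping


@dataclass(frozen=True)
class FitConstraints:
    """Fixed parameters, box bounds and an optional total-m-value range.

    ``fixed`` maps parameter names (natural units) to pinned values;
    ``bounds`` maps names to (lo, hi) in natural units; ``M_UN_range``
    softly constrains the kinetic M_UN sum to an interval determined in
    equilibrium experiments (used for variants whose chevron alone does
    not pin the total m-value).
    """

    fixed: Mapping[str, float] = field(default_factory=dict)
    bounds: Mapping[str, tuple[float, float]] = field(default_factory=dict)
    M_UN_range: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        overlap = set(self.fixed) & set(self.bounds)
        if overlap:
            raise ValueError(f"parameters both fixed and bounded: {sorted(overlap)}")
        for name, (lo, hi) in self.bounds.items():
            if not lo < hi:
                raise ValueError(f"bounds for {name} must satisfy lo < hi")
        if self.M_UN_range is not None and not self.M_UN_range[0] < self.M_UN_range[1]:
            raise ValueError("M_UN_range must satisfy lo < hi")


class _ParamSpace:
    """Maps between natural-unit parameter dicts and the internal vector.

    Rates live as ln(k) internally, m-values and signal coefficients
    linearly. Fixed parameters are excluded from the vector.
    """

    def __init__(self, names: Sequence[str], kinds: Mapping[str, str], fixed: Mapping[str, float]):
        self.all_names = list(names)
        self.kinds = dict(kinds)
        self.fixed = dict(fixed)
        unknown = set(fixed) - set(names)
        if unknown:
            raise ValueError(f"unknown fixed parameters {sorted(unknown)}")
        self.free_names = [n for n in names if n not in fixed]

    def to_internal(self, params: Mapping[str, float]) -> np.ndarray:
        out = []
        for n in self.free_names:
            v = params[n]
            out.append(math.log(v) if self.kinds[n] == "rate" else v)
        return np.asarray(out)

    def to_natural(self, theta: np.ndarray) -> dict[str, float]:
        params = dict(self.fixed)
        for n, v in zip(self.free_names, theta):
            params[n] = math.exp(v) if self.kinds[n] == "rate" else v
        return params

    def internal_bounds(self, user_bounds: Mapping[str, tuple[float, float]]):
        lo, hi = [], []
        for n in self.free_names:
            kind = self.kinds[n]
            if n in user_bounds:
                a, b = user_bounds[n]
                if kind == "rate":
                    a, b = math.log(max(a, 1e-300)), math.log(b)
            elif kind == "rate":
                a, b = _LN_RATE_LO, _LN_RATE_HI
            elif kind == "m":
                a, b = _M_LO, _M_HI
            else:
                a, b = -np.inf, np.inf
            lo.append(a)
            hi.append(b)
        return np.asarray(lo), np.asarray(hi)


@dataclass
class FitResult:
    """Best-fit parameters, uncertainties and derived thermodynamics.

    ``params``/``sigma`` are in natural units (s^-1, kJ mol^-1 M^-1,
    normalised fluorescence); ``covariance`` is a DataFrame over the free
    parameters in internal coordinates (ln k for rates, linear otherwise),
    which is the space in which the Gauss-Newton covariance is defined.
    ``propagate`` turns any scalar function of the parameter dict into a
    delta-method standard error using the full covariance.
    """

    scheme: KineticScheme
    params: dict[str, float]
    sigma: dict[str, float]
    covariance: pd.DataFrame
    thermo: ThermoSummary
    thermo_sigma: dict[str, float]
    residual_rms: dict[str, float]
    success: bool
    n_iterations: int
    n_starts: int
    seed: int | None
    fixed: dict[str, float]
    unidentifiable: list[str]
    at_bounds: list[str]
    _space: _ParamSpace = field(repr=False, default=None)

    @property
    def free_names(self) -> list[str]:
        return list(self.covariance.index)

    def propagate(self, func: Callable[[Mapping[str, float]], float], step: float = 1e-6) -> float:
        """1-sigma of ``func(params)`` by the delta method (numeric gradient)."""
        theta0 = self._space.to_internal(self.params)
        f0 = func(self._space.to_natural(theta0))
        grad = np.zeros_like(theta0)
        for i in range(theta0.size):
            h = step * max(1.0, abs(theta0[i]))
            tp = theta0.copy()
            tp[i] += h
            tm = theta0.copy()
            tm[i] -= h
            grad[i] = (func(self._space.to_natural(tp)) - func(self._space.to_natural(tm))) / (2 * h)
        cov = self.covariance.to_numpy()
        var = float(grad @ cov @ grad)
        del f0
        return math.sqrt(max(var, 0.0))


# ---------------------------------------------------------------------------
# chevron fitters


class _ChevronFitterBase(BaseEstimator):
    """Shared machinery: residual assembly, multistart, covariance."""

    _param_names: list[str] = []
    _param_kinds: dict[str, str] = {}
    _n_states = 0

    def __init__(
        self,
        conditions: ExperimentConditions | None = None,
        constraints: FitConstraints | None = None,
        n_starts: int = 8,
        use_signals: bool = True,
        weighting: str = "auto",
        random_state: int = 0,
    ):
        self.conditions = conditions
        self.constraints = constraints
        self.n_starts = n_starts
        self.use_signals = use_signals
        self.weighting = weighting
        self.random_state = random_state

    # subclass hooks ------------------------------------------------------
    def _default_fixed(self) -> dict[str, float]:
        return {}

    def _build_scheme(self, params: Mapping[str, float]) -> KineticScheme:
        raise NotImplementedError

    def _initial_guess(self, data: ChevronDataset, cond) -> dict[str, float]:
        raise NotImplementedError

    # machinery -----------------------------------------------------------
    def _space(self) -> _ParamSpace:
        cons = self.constraints or FitConstraints()
        fixed = dict(self._default_fixed())
        fixed.update(cons.fixed)
        return _ParamSpace(self._param_names, self._param_kinds, fixed)

    def _residual_fn(self, data: ChevronDataset, space, weights, cond):
        use_amp = self.use_signals and data.has_signals
        D = data.denaturant
        ln_kobs = np.log(data.kobs)
        refold = data.branch == REFOLDING
        w_rate, w_amp = weights
        if data.kobs_sigma is not None:
            sigma_ln = data.kobs_sigma / data.kobs
        else:
            sigma_ln = np.ones_like(ln_kobs)
        cons = self.constraints or FitConstraints()

        def residuals(theta):
            params = space.to_natural(theta)
            scheme = self._build_scheme(params)
            with np.errstate(over="ignore", invalid="ignore"):
                lam = observed_slow_rate(scheme, D, cond)
                r = [(ln_kobs - np.log(lam)) / (sigma_ln * w_rate)]
                if use_amp:
                    init_r, fin_r = amplitude_model(scheme, D[refold], REFOLDING, cond)
                    init_u, fin_u = amplitude_model(scheme, D[~refold], UNFOLDING, cond)
                    init = np.empty_like(D)
                    fin = np.empty_like(D)
                    init[refold], fin[refold] = init_r, fin_r
                    init[~refold], fin[~refold] = init_u, fin_u
                    r.append((data.initial_signal - init) / w_amp)
                    r.append((data.final_signal - fin) / w_amp)
                if cons.M_UN_range is not None:
                    M = thermo_summary(scheme, cond).M_UN
                    lo, hi = cons.M_UN_range
                    r.append(np.array([1e3 * max(lo - M, 0.0, M - hi)]))
            out = np.concatenate(r)
            out[~np.isfinite(out)] = 1e6
            return out

        return residuals, use_amp

    def _multistart_thetas(self, space, theta0, rng):
        thetas = [theta0]
        n_extra = max(self.n_starts - 1, 0)
        if n_extra:
            sampler = qmc.LatinHypercube(d=theta0.size, seed=rng)
            u = sampler.random(n_extra)
            for row in u:
                t = theta0.copy()
                for i, name in enumerate(space.free_names):
                    kind = space.kinds[name]
                    if kind == "rate":
                        t[i] += 3.0 * (row[i] - 0.5)  # +-1.5 nats
                    elif kind == "m":
                        t[i] *= 0.5 + row[i]  # x0.5 .. x1.5
                    else:
                        t[i] += 0.2 * (row[i] - 0.5)
                thetas.append(t)
        return thetas

    def fit(self, data: ChevronDataset, y=None):
        """Fit the scheme to one chevron dataset; returns self."""
        if isinstance(data, pd.DataFrame):
            data = ChevronDataset.from_dataframe(data)
        cond = self.conditions or DEFAULT_CONDITIONS
        space = self._space()
        cons = self.constraints or FitConstraints()
        rng = np.random.default_rng(self.random_state)

        guess = self._initial_guess(data, cond)
        theta0 = space.to_internal(guess)
        lo, hi = space.internal_bounds(cons.bounds)
        theta0 = np.clip(theta0, lo + 1e-9, hi - 1e-9)

        if isinstance(self.weighting, tuple):
            weight_passes = [self.weighting]
        elif self.weighting == "unit":
            weight_passes = [(1.0, 1.0)]
        else:  # auto: unit pass then per-block RMS reweighting
            weight_passes = [(1.0, 1.0), None]

        best = None
        n_iter_total = 0
        for ip, wts in enumerate(weight_passes):
            if wts is None:
                # reweight from the previous best solution's block residuals
                res_fn, use_amp = self._residual_fn(data, space, (1.0, 1.0), cond)
                r = res_fn(best.x)
                n = len(data)
                rms_rate = max(float(np.sqrt(np.mean(r[:n] ** 2))), 1e-4)
                if use_amp:
                    rms_amp = max(float(np.sqrt(np.mean(r[n : 3 * n] ** 2))), 1e-4)
                else:
                    rms_amp = 1.0
                wts = (rms_rate, rms_amp)
            res_fn, use_amp = self._residual_fn(data, space, wts, cond)
            starts = self._multistart_thetas(space, theta0, rng) if ip == 0 else [best.x]
            pass_best = None
            for t0 in starts:
                t0 = np.clip(t0, lo + 1e-12, hi - 1e-12)
                try:
                    sol = least_squares(
                        res_fn, t0, bounds=(lo, hi), method="trf", x_scale="jac",
                        ftol=1e-12, xtol=1e-12, gtol=1e-12, max_nfev=4000,
                    )
                except Exception:
                    continue
                n_iter_total += sol.nfev
                if pass_best is None or sol.cost < pass_best.cost:
                    pass_best = sol
            if pass_best is None:
                raise RuntimeError("all optimiser starts failed")
            best = pass_best
            final_weights = wts

        self._finalize(data, best, space, final_weights, cond)
        self.result_.n_iterations = n_iter_total
        return self

    def _finalize(self, data, sol, space, weights, cond):
        params = space.to_natural(sol.x)
        scheme = self._build_scheme(params)
        J = sol.jac
        n_res, n_par = J.shape
        dof = max(n_res - n_par, 1)
        s2 = 2.0 * sol.cost / dof
        JTJ = J.T @ J
        # SVD-based pseudo-inverse; near-null directions flag unidentifiable params
        U, sv, Vt = np.linalg.svd(JTJ)
        tol = sv[0] * 1e-12 if sv[0] > 0 else 1.0
        inv_sv = np.where(sv > tol, 1.0 / np.maximum(sv, tol), 0.0)
        cov = (Vt.T * inv_sv) @ Vt * s2
        cov_df = pd.DataFrame(cov, index=space.free_names, columns=space.free_names)

        sigma_internal = np.sqrt(np.clip(np.diag(cov), 0.0, np.inf))
        unidentifiable = []
        col_norm = np.linalg.norm(J, axis=0)
        for i, name in enumerate(space.free_names):
            huge_sigma = space.kinds[name] == "rate" and sigma_internal[i] > 5.0
            null_dir = col_norm[i] < 1e-8 * max(col_norm.max(), 1.0)
            rank_def = sv[min(i, len(sv) - 1)] <= tol and False  # rank handled below
            if huge_sigma or null_dir or rank_def:
                unidentifiable.append(name)
        if np.any(sv <= tol):
            # parameters loading on the null space are unidentifiable
            null_vecs = Vt[sv <= tol]
            for vec in null_vecs:
                j = int(np.argmax(np.abs(vec)))
                name = space.free_names[j]
                if name not in unidentifiable:
                    unidentifiable.append(name)

        lo, hi = space.internal_bounds((self.constraints or FitConstraints()).bounds)
        at_bounds = [
            n
            for i, n in enumerate(space.free_names)
            if np.isfinite(lo[i]) and (sol.x[i] - lo[i] < 1e-8 or hi[i] - sol.x[i] < 1e-8)
            and not (space.kinds[n] == "m" and abs(sol.x[i]) < 1e-8 and lo[i] == 0.0)
        ]

        sigma = {}
        for i, name in enumerate(space.free_names):
            s = sigma_internal[i]
            sigma[name] = params[name] * s if space.kinds[name] == "rate" else s

        # block residual RMS on the natural scales
        res_fn, use_amp = self._residual_fn(data, space, (1.0, 1.0), cond)
        r = res_fn(sol.x)
        n = len(data)
        residual_rms = {"rate_ln": float(np.sqrt(np.mean(r[:n] ** 2)))}
        if use_amp:
            residual_rms["initial_signal"] = float(np.sqrt(np.mean(r[n : 2 * n] ** 2)))
            residual_rms["final_signal"] = float(np.sqrt(np.mean(r[2 * n : 3 * n] ** 2)))

        result = FitResult(
            scheme=scheme,
            params=params,
            sigma=sigma,
            covariance=cov_df,
            thermo=thermo_summary(scheme, cond),
            thermo_sigma={},
            residual_rms=residual_rms,
            success=bool(sol.success),
            n_iterations=0,
            n_starts=self.n_starts,
            seed=self.random_state,
            fixed=dict(space.fixed),
            unidentifiable=unidentifiable,
            at_bounds=at_bounds,
            _space=space,
        )
        result.thermo_sigma = self._thermo_sigmas(result, cond)
        self.result_ = result
        self.scheme_ = scheme
        self.params_ = params
        self.sigma_ = sigma
        self.covariance_ = cov_df
        self.thermo_ = result.thermo
        return result

    def _thermo_sigmas(self, result: FitResult, cond) -> dict[str, float]:
        fields = [
            f
            for f in ("dG_UI", "dG_IN", "dG_UN", "M_UI", "M_UN", "beta_I", "beta_TS2", "K_UI")
            if getattr(result.thermo, f, None) is not None
        ]
        out = {}
        for f in fields:
            out[f] = result.propagate(
                lambda p, f=f: getattr(thermo_summary(self._build_scheme(p), cond), f)
            )
        return out

    def predict(self, D, branch=None):
        """Model observed rate k_obs at urea concentrations ``D``."""
        cond = self.conditions or DEFAULT_CONDITIONS
        return observed_slow_rate(self.scheme_, np.asarray(D, dtype=float), cond)

    def predict_signals(self, D, direction=REFOLDING):
        """Model (initial, final) fluorescence at urea concentrations ``D``."""
        cond = self.conditions or DEFAULT_CONDITIONS
        return amplitude_model(self.scheme_, np.asarray(D, dtype=float), direction, cond)


def _linear_fit(x, y):
    """Least-squares slope/intercept, tolerant of short inputs."""
    if len(x) < 2:
        return 0.0, float(np.mean(y)) if len(y) else 0.0
    slope, intercept = np.polyfit(x, y, 1)
    return float(slope), float(intercept)


class ThreeStateChevronFitter(_ChevronFitterBase):
    """Global fit of a chevron + amplitudes to the on-pathway U<->I<->N scheme.

    Free parameters (defaults): k_IU(0), m_IU, k_IN(0), m_IN, k_NI(0),
    m_NI and six signal-baseline coefficients (intercept + slope per
    state); k_UI and m_UI are fixed to the continuous-flow wild-type
    values unless the constraints say otherwise.
    """

    _param_names = [
        "k_UI", "m_UI", "k_IU", "m_IU", "k_IN", "m_IN", "k_NI", "m_NI",
        "sig_U_icpt", "sig_U_slope", "sig_I_icpt", "sig_I_slope", "sig_N_icpt", "sig_N_slope",
    ]
    _param_kinds = {
        **{n: "rate" for n in ("k_UI", "k_IU", "k_IN", "k_NI")},
        **{n: "m" for n in ("m_UI", "m_IU", "m_IN", "m_NI")},
        **{n: "lin" for n in (
            "sig_U_icpt", "sig_U_slope", "sig_I_icpt", "sig_I_slope", "sig_N_icpt", "sig_N_slope")},
    }
    _n_states = 3

    def _default_fixed(self):
        return dict(DEFAULT_FIXED_THREE_STATE)

    def _build_scheme(self, p):
        coeffs = {
            "U": (p["sig_U_icpt"], p["sig_U_slope"]),
            "I": (p["sig_I_icpt"], p["sig_I_slope"]),
            "N": (p["sig_N_icpt"], p["sig_N_slope"]),
        }
        return make_three_state_scheme(
            p["k_UI"], p["m_UI"], p["k_IU"], p["m_IU"],
            p["k_IN"], p["m_IN"], p["k_NI"], p["m_NI"], coeffs,
        )

    def _initial_guess(self, data, cond):
        cons = self.constraints or FitConstraints()
        fixed = dict(self._default_fixed())
        fixed.update(cons.fixed)
        k_UI = fixed.get("k_UI", 1574.0)
        m_UI = fixed.get("m_UI", 1.23)
        D, lnk = data.denaturant, np.log(data.kobs)
        unfold_mask = D >= np.percentile(D, 60)
        slope_u, icpt_u = _linear_fit(D[unfold_mask], lnk[unfold_mask])
        m_NI = float(np.clip(slope_u * cond.RT, 0.05, 2.0))
        k_NI = float(np.clip(math.exp(icpt_u), 1e-4, 1e3))
        refold_mask = data.branch == REFOLDING
        k_IN = float(np.clip(np.max(data.kobs[refold_mask]) * 1.2, 1.0, 2e3))
        K_UI0 = 100.0
        p = {
            "k_UI": k_UI, "m_UI": m_UI,
            "k_IU": k_UI / K_UI0, "m_IU": 3.0,
            "k_IN": k_IN, "m_IN": 0.5, "k_NI": k_NI, "m_NI": m_NI,
            "sig_U_icpt": 0.8, "sig_U_slope": 0.025,
            "sig_I_icpt": 1.3, "sig_I_slope": 0.0,
            "sig_N_icpt": 0.35, "sig_N_slope": 0.01,
        }
        if data.has_signals:
            lowD = D <= np.percentile(D, 30)
            highD = D >= np.percentile(D, 70)
            s, i = _linear_fit(D[highD], data.final_signal[highD])
            p["sig_U_slope"], p["sig_U_icpt"] = s, i
            s, i = _linear_fit(D[lowD], data.final_signal[lowD])
            p["sig_N_slope"], p["sig_N_icpt"] = s, i
            p["sig_I_icpt"] = float(np.max(data.initial_signal[lowD]))
        return p


class TwoStateChevronFitter(_ChevronFitterBase):
    """Simultaneous fit of rates + amplitudes to the two-state U<->N scheme."""

    _param_names = [
        "k_UN", "m_UN", "k_NU", "m_NU",
        "sig_U_icpt", "sig_U_slope", "sig_N_icpt", "sig_N_slope",
    ]
    _param_kinds = {
        "k_UN": "rate", "k_NU": "rate", "m_UN": "m", "m_NU": "m",
        "sig_U_icpt": "lin", "sig_U_slope": "lin", "sig_N_icpt": "lin", "sig_N_slope": "lin",
    }
    _n_states = 2

    def _build_scheme(self, p):
        coeffs = {
            "U": (p["sig_U_icpt"], p["sig_U_slope"]),
            "N": (p["sig_N_icpt"], p["sig_N_slope"]),
        }
        return make_two_state_scheme(p["k_UN"], p["m_UN"], p["k_NU"], p["m_NU"], coeffs)

    def _initial_guess(self, data, cond):
        D, lnk = data.denaturant, np.log(data.kobs)
        i_min = int(np.argmin(lnk))
        D_min = D[i_min]
        fold_mask = D <= D_min
        unfold_mask = D >= D_min
        sf, bf = _linear_fit(D[fold_mask], lnk[fold_mask])
        su, bu = _linear_fit(D[unfold_mask], lnk[unfold_mask])
        p = {
            "k_UN": float(np.clip(math.exp(bf), 1e-3, 1e5)),
            "m_UN": float(np.clip(-sf * cond.RT, 0.1, 8.0)),
            "k_NU": float(np.clip(math.exp(bu), 1e-6, 1e4)),
            "m_NU": float(np.clip(su * cond.RT, 0.05, 4.0)),
            "sig_U_icpt": 0.8, "sig_U_slope": 0.025,
            "sig_N_icpt": 0.35, "sig_N_slope": 0.01,
        }
        if data.has_signals:
            lowD = D <= np.percentile(D, 30)
            highD = D >= np.percentile(D, 70)
            s, i = _linear_fit(D[highD], data.final_signal[highD])
            p["sig_U_slope"], p["sig_U_icpt"] = s, i
            s, i = _linear_fit(D[lowD], data.final_signal[lowD])
            p["sig_N_slope"], p["sig_N_icpt"] = s, i
        return p


def fit_chevron_three_state(
    data: ChevronDataset,
    constraints: FitConstraints | None = None,
    cond: ExperimentConditions | None = None,
    **kwargs,
) -> FitResult:
    """Functional wrapper around :class:`ThreeStateChevronFitter`."""
    fitter = ThreeStateChevronFitter(conditions=cond, constraints=constraints, **kwargs)
    return fitter.fit(data).result_


def fit_chevron_two_state(
    data: ChevronDataset,
    cond: ExperimentConditions | None = None,
    **kwargs,
) -> FitResult:
    """Functional wrapper around :class:`TwoStateChevronFitter`."""
    fitter = TwoStateChevronFitter(conditions=cond, **kwargs)
    return fitter.fit(data).result_


# ---------------------------------------------------------------------------
# exponential trace fitting


@dataclass
class TraceFit:
    """Result of a single/double exponential trace fit.

    Model: S(t) = offset + sum_i A_i exp(-k_i t), rates sorted descending.
    The trace's initial signal is S(0) = offset + sum(A) and its endpoint
    is the offset.
    """

    rates: np.ndarray
    amplitudes: np.ndarray
    offset: float
    sigma_rates: np.ndarray
    sigma_amplitudes: np.ndarray
    sigma_offset: float
    residual_rms: float
    n_phases: int
    success: bool
    collapsed: bool = False

    @property
    def initial_signal(self) -> float:
        return float(self.offset + np.sum(self.amplitudes))

    @property
    def final_signal(self) -> float:
        return float(self.offset)


class ExponentialTraceFitter(BaseEstimator):
    """Multistart least-squares fit of 1-2 exponential phases to a trace."""

    def __init__(self, n_phases: int = 1, random_state: int = 0):
        self.n_phases = n_phases
        self.random_state = random_state

    def fit(self, trace: KineticTrace, y=None):
        if self.n_phases not in (1, 2):
            raise ValueError("n_phases must be 1 or 2")
        n_min = 3 * self.n_phases + 1
        if len(trace) < n_min:
            raise ValueError(
                f"a {self.n_phases}-phase fit needs >= {n_min} points, trace has {len(trace)}"
            )
        t, s = trace.times, trace.signal
        span = t[-1] - t[0]
        offset0 = float(np.mean(s[-max(len(s) // 5, 1):]))
        amp0 = float(s[0] - offset0)

        # candidate rates spanning the observable decades of the time grid
        k_lo = 0.3 / span
        dt = np.min(np.diff(t))
        k_hi = 1.0 / max(dt, 1e-12)
        k_cands = np.geomspace(k_lo, k_hi, 6)

        def model(theta):
            off = theta[0]
            out = np.full_like(t, off)
            for i in range(self.n_phases):
                A, lnk = theta[1 + 2 * i], theta[2 + 2 * i]
                out = out + A * np.exp(-np.exp(lnk) * t)
            return out

        def residuals(theta):
            return model(theta) - s

        starts = []
        if self.n_phases == 1:
            for k in k_cands:
                starts.append(np.array([offset0, amp0, math.log(k)]))
        else:
            for i, kf in enumerate(k_cands):
                for ks in k_cands[:i]:
                    starts.append(
                        np.array([offset0, amp0 / 2, math.log(kf), amp0 / 2, math.log(ks)])
                    )
        best = None
        for t0 in starts:
            try:
                sol = least_squares(residuals, t0, method="lm", max_nfev=2000)
            except Exception:
                continue
            if best is None or sol.cost < best.cost:
                best = sol
        if best is None or not np.all(np.isfinite(best.x)):
            raise RuntimeError("exponential trace fit failed to converge")

        self.result_ = self._package(best, t, s)
        if self.n_phases == 2 and not self.result_.collapsed:
            k1, k2 = self.result_.rates
            if k2 > 0 and k1 / k2 < 1.5:
                warnings.warn(
                    "two-phase rates collapsed (ratio < 1.5); falling back to one phase",
                    RuntimeWarning,
                )
                one = ExponentialTraceFitter(n_phases=1, random_state=self.random_state)
                one.fit(trace)
                self.result_ = one.result_
                self.result_.collapsed = True
        return self

    def _package(self, sol, t, s) -> TraceFit:
        theta = sol.x
        offset = float(theta[0])
        amps = np.array([theta[1 + 2 * i] for i in range(self.n_phases)])
        rates = np.array([math.exp(theta[2 + 2 * i]) for i in range(self.n_phases)])
        order = np.argsort(rates)[::-1]
        rates, amps = rates[order], amps[order]

        J = sol.jac
        dof = max(len(t) - len(theta), 1)
        s2 = 2.0 * sol.cost / dof
        try:
            cov = np.linalg.pinv(J.T @ J) * s2
        except np.linalg.LinAlgError:
            cov = np.full((len(theta), len(theta)), np.nan)
        diag = np.sqrt(np.clip(np.diag(cov), 0.0, np.inf))
        sig_off = float(diag[0])
        sig_amp = np.array([diag[1 + 2 * i] for i in range(self.n_phases)])[order]
        sig_k = (np.array([diag[2 + 2 * i] for i in range(self.n_phases)]) *
                 np.array([math.exp(theta[2 + 2 * i]) for i in range(self.n_phases)]))[order]
        rms = float(np.sqrt(np.mean(sol.fun**2)))
        return TraceFit(
            rates=rates, amplitudes=amps, offset=offset,
            sigma_rates=sig_k, sigma_amplitudes=sig_amp, sigma_offset=sig_off,
            residual_rms=rms, n_phases=self.n_phases, success=bool(sol.success),
        )


def fit_exponential_trace(trace: KineticTrace, n_phases: int = 1, **kwargs) -> TraceFit:
    """Functional wrapper around :class:`ExponentialTraceFitter`."""
    return ExponentialTraceFitter(n_phases=n_phases, **kwargs).fit(trace).result_
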