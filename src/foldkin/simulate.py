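"""Synthetic stopped-flow and equilibrium data with controlled noise.

Generators are pure functions of (parameters, grid, seed): two calls with
the same arguments give bit-identical datasets. Noise defaults emulate a
well-behaved stopped-flow experiment: 3% multiplicative (lognormal) noise
on observed rates, which span three decades, and 0.01 additive Gaussian
noise on normalised fluorescence amplitudes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize_scalar

from .chevron import amplitude_model
from .conditions import DEFAULT_CONDITIONS, ExperimentConditions
from .datasets import REFOLDING, UNFOLDING, ChevronDataset, EquilibriumCurve, KineticTrace
from .equilibrium import EquilibriumFit, equilibrium_signal
from .models import KineticScheme, observed_slow_rate, rate_matrix

__all__ = [
    "NoiseModel",
    "DEFAULT_REFOLDING_GRID",
    "DEFAULT_UNFOLDING_GRID",
    "generate_chevron",
    "generate_trace",
    "generate_equilibrium_curve",
    "chevron_minimum",
]

#: experimental urea grids: refolding 0.75-8.0 M, unfolding 3.0-8.0 M
DEFAULT_REFOLDING_GRID = np.round(np.linspace(0.75, 8.0, 16), 4)
DEFAULT_UNFOLDING_GRID = np.round(np.linspace(3.0, 8.0, 11), 4)


@dataclass(frozen=True)
class NoiseModel:
    """Noise magnitudes and the seed that makes a dataset reproducible."""

    kobs_rel: float = 0.03
    signal_abs: float = 0.01
    trace_abs: float = 0.01
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("kobs_rel", "signal_abs", "trace_abs"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


NOISELESS = NoiseModel(0.0, 0.0, 0.0, seed=0)


def chevron_minimum(
    scheme: KineticScheme,
    cond: ExperimentConditions = DEFAULT_CONDITIONS,
    bounds: tuple[float, float] = (0.0, 10.0),
) -> float:
    """Urea concentration at which the observed rate is smallest."""
    res = minimize_scalar(
        lambda D: float(np.log(observed_slow_rate(scheme, D, cond))),
        bounds=bounds, method="bounded",
    )
    return float(res.x)


def generate_chevron(
    scheme: KineticScheme,
    urea_grid=None,
    noise: NoiseModel = NoiseModel(),
    cond: ExperimentConditions = DEFAULT_CONDITIONS,
    variant: str = "",
) -> ChevronDataset:
    """Simulate one chevron dataset (rates + amplitude signals).

    With an explicit ``urea_grid`` each observation's branch is assigned
    by comparing its urea concentration to the chevron minimum. With the
    default (None) the experimental design is mimicked: a refolding
    series over 0.75-8.0 M and an unfolding series over 3.0-8.0 M, the
    branch given by the mixing direction.
    """
    if urea_grid is not None:
        D = np.asarray(urea_grid, dtype=float)
        if D.size == 0:
            raise ValueError("urea grid is empty")
        if np.any((D < 0) | (D > 10)):
            raise ValueError("urea grid must lie within [0, 10] M")
        D_min = chevron_minimum(scheme, cond)
        branch = np.where(D < D_min, REFOLDING, UNFOLDING).astype(object)
    else:
        D = np.concatenate([DEFAULT_REFOLDING_GRID, DEFAULT_UNFOLDING_GRID])
        branch = np.array(
            [REFOLDING] * DEFAULT_REFOLDING_GRID.size + [UNFOLDING] * DEFAULT_UNFOLDING_GRID.size,
            dtype=object,
        )
    rng = noise.rng()
    kobs = np.asarray(observed_slow_rate(scheme, D, cond), dtype=float)
    if noise.kobs_rel > 0:
        kobs = kobs * np.exp(rng.normal(0.0, noise.kobs_rel, size=D.size))
    refold = branch == REFOLDING
    initial = np.empty_like(D)
    final = np.empty_like(D)
    initial[refold], final[refold] = amplitude_model(scheme, D[refold], REFOLDING, cond)
    initial[~refold], final[~refold] = amplitude_model(scheme, D[~refold], UNFOLDING, cond)
    if noise.signal_abs > 0:
        initial = initial + rng.normal(0.0, noise.signal_abs, size=D.size)
        final = final + rng.normal(0.0, noise.signal_abs, size=D.size)
    return ChevronDataset(
        denaturant=D, kobs=kobs, branch=branch,
        initial_signal=initial, final_signal=final, variant=variant,
    )


def generate_trace(
    scheme: KineticScheme,
    D: float,
    direction: str = REFOLDING,
    duration: float | None = None,
    n_points: int = 200,
    noise: NoiseModel = NoiseModel(),
    cond: ExperimentConditions = DEFAULT_CONDITIONS,
    t_start: float = 0.0,
) -> KineticTrace:
    """Simulate a stopped-flow trace by propagating the full rate matrix.

    The initial condition is all-unfolded (refolding) or all-native
    (unfolding); the signal is the population-weighted sum of the species
    baselines at the final urea concentration. ``t_start`` emulates the
    instrument dead time (points before it are not recorded).
    """
    lam_slow = float(observed_slow_rate(scheme, D, cond))
    if duration is None:
        duration = 5.0 / lam_slow
    if duration < 3.0 / lam_slow:
        warnings.warn("trace duration covers < 3 relaxation times", RuntimeWarning)
    A = rate_matrix(scheme, D, cond)
    n = A.shape[0]
    p0 = np.zeros(n)
    if direction == REFOLDING:
        p0[0] = 1.0
    elif direction == UNFOLDING:
        p0[-1] = 1.0
    else:
        raise ValueError(f"direction must be refolding/unfolding, got {direction!r}")
    evals, V = np.linalg.eig(A)
    c = np.linalg.solve(V, p0)
    t = np.linspace(t_start, t_start + duration, n_points)
    # p(t) = V @ (c * exp(lambda t)); eigenvalues are real and <= 0
    pt = np.real(V @ (c[:, None] * np.exp(np.real(evals)[:, None] * t[None, :])))
    baselines = np.array([scheme.baseline(sp, D) for sp in scheme.species])
    signal = baselines @ pt
    if noise.trace_abs > 0:
        signal = signal + noise.rng().normal(0.0, noise.trace_abs, size=t.size)
    return KineticTrace(times=t, signal=signal, denaturant=float(D), direction=direction)


def generate_equilibrium_curve(
    params: EquilibriumFit,
    urea_grid=None,
    noise: NoiseModel = NoiseModel(),
    cond: ExperimentConditions = DEFAULT_CONDITIONS,
) -> EquilibriumCurve:
    """Simulate an equilibrium denaturation curve (0-8 M, 0.2 M steps).

    ``params`` carries the generating dG_UN, M_UN and the two linear
    baselines; Gaussian noise of magnitude ``noise.signal_abs`` (in the
    curve's signal units) is added pointwise.
    """
    if urea_grid is None:
        urea_grid = np.round(np.arange(0.0, 8.0 + 1e-9, 0.2), 10)
    D = np.asarray(urea_grid, dtype=float)
    signal = np.asarray(equilibrium_signal(params, D, cond), dtype=float)
    if noise.signal_abs > 0:
        signal = signal + noise.rng().normal(0.0, noise.signal_abs, size=D.size)
    return EquilibriumCurve(denaturant=D, signal=signal, probe=params.probe)
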