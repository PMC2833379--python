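"""Closed-form kinetics and thermodynamics of two- and three-state folding.

The three-state on-pathway scheme

    U  <-- k_IU / k_UI -->  I  <-- k_NI / k_IN -->  N

and the two-state scheme U <-> N are described by microscopic rate
constants whose logarithms depend linearly on denaturant concentration
(the kinetic linear free-energy relationship):

    k_xy(D) = k_xy(0) * exp(-m_xy * D / RT)   for folding steps,
    k_xy(D) = k_xy(0) * exp(+m_xy * D / RT)   for unfolding steps,

with the kinetic m-value m_xy stored as a non-negative magnitude and the
sign carried by an explicit direction flag. Free energies follow the
convention that the more folded species is more stable when dG < 0, so a
stable native protein has dG_UN ~ -25 kJ mol^-1 and destabilising
mutations give positive ddG.

The observable slow relaxation rate of the three-state scheme is the
smaller non-zero eigenvalue magnitude of the 3x3 rate matrix; with

    s = k_UI + k_IU + k_IN + k_NI
    p = k_UI*k_IN + k_UI*k_NI + k_IU*k_NI

the two relaxation rates are lambda_+- = (s +- sqrt(s^2 - 4p)) / 2.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

from .conditions import DEFAULT_CONDITIONS, ExperimentConditions

__all__ = [
    "FOLDING",
    "UNFOLDING",
    "RateLaw",
    "KineticScheme",
    "ThermoSummary",
    "rate_at_denaturant",
    "three_state_relaxation_rates",
    "two_state_kobs",
    "equilibrium_populations",
    "thermo_summary",
    "rate_matrix",
]

FOLDING = "folding"
UNFOLDING = "unfolding"

_DIRECTION_SIGN = {FOLDING: -1.0, UNFOLDING: +1.0}

#: transition label -> required direction
THREE_STATE_TRANSITIONS = {"UI": FOLDING, "IU": UNFOLDING, "IN": FOLDING, "NI": UNFOLDING}
TWO_STATE_TRANSITIONS = {"UN": FOLDING, "NU": UNFOLDING}

THREE_STATE_SPECIES = ("U", "I", "N")
TWO_STATE_SPECIES = ("U", "N")


@dataclass(frozen=True)
class RateLaw:
    """Exponential denaturant dependence of one microscopic rate constant.

    Parameters
    ----------
    rate0 : float
        Rate constant at zero denaturant, s^-1 (must be positive).
    m_kin : float
        Kinetic m-value magnitude, kJ mol^-1 M^-1 (non-negative).
    direction : {"folding", "unfolding"}
        Folding rates decay, unfolding rates grow with denaturant.
    """

    rate0: float
    m_kin: float
    direction: str

    def __post_init__(self) -> None:
        if self.direction not in _DIRECTION_SIGN:
            raise ValueError(f"direction must be 'folding' or 'unfolding', got {self.direction!r}")
        if not self.rate0 > 0:
            raise ValueError(f"rate0 must be > 0, got {self.rate0}")
        if self.m_kin < 0:
            raise ValueError(f"m_kin must be >= 0, got {self.m_kin}")

    def log_at(self, D, cond: ExperimentConditions = DEFAULT_CONDITIONS):
        """ln k(D); vectorised over D."""
        D = np.asarray(D, dtype=float)
        if np.any(D < 0):
            raise ValueError("denaturant concentration must be >= 0")
        return math.log(self.rate0) + _DIRECTION_SIGN[self.direction] * self.m_kin * D / cond.RT

    def at(self, D, cond: ExperimentConditions = DEFAULT_CONDITIONS):
        """k(D) in s^-1; vectorised over D, strictly positive."""
        return np.exp(self.log_at(D, cond))


def rate_at_denaturant(law: RateLaw, D, cond: ExperimentConditions = DEFAULT_CONDITIONS):
    """Evaluate a rate law at denaturant concentration ``D`` (molar)."""
    return law.at(D, cond)


@dataclass(frozen=True)
class KineticScheme:
    """A two- or three-state folding scheme plus fluorescence coefficients.

    ``rate_laws`` must hold exactly the transitions {UI, IU, IN, NI} for a
    three-state scheme or {UN, NU} for a two-state one, each with the
    correct direction. ``signal_coeffs`` maps each species to a linear
    fluorescence baseline ``(intercept, slope)`` in normalised units (the
    experimental convention normalises the 7.75 M urea sample to 1).
    """

    n_states: int
    rate_laws: Mapping[str, RateLaw]
    signal_coeffs: Mapping[str, tuple[float, float]] | None = None

    def __post_init__(self) -> None:
        if self.n_states not in (2, 3):
            raise ValueError(f"n_states must be 2 or 3, got {self.n_states}")
        required = THREE_STATE_TRANSITIONS if self.n_states == 3 else TWO_STATE_TRANSITIONS
        if set(self.rate_laws) != set(required):
            raise ValueError(
                f"{self.n_states}-state scheme requires transitions {sorted(required)}, "
                f"got {sorted(self.rate_laws)}"
            )
        for label, direction in required.items():
            if self.rate_laws[label].direction != direction:
                raise ValueError(f"transition {label} must have direction {direction!r}")
        if self.signal_coeffs is not None:
            missing = set(self.species) - set(self.signal_coeffs)
            if missing:
                raise ValueError(f"signal_coeffs missing species {sorted(missing)}")

    @property
    def species(self) -> tuple[str, ...]:
        return THREE_STATE_SPECIES if self.n_states == 3 else TWO_STATE_SPECIES

    def law(self, label: str) -> RateLaw:
        return self.rate_laws[label]

    def baseline(self, species: str, D):
        """Linear fluorescence baseline of one species at denaturant D."""
        if self.signal_coeffs is None:
            raise ValueError("scheme carries no signal coefficients")
        intercept, slope = self.signal_coeffs[species]
        return intercept + slope * np.asarray(D, dtype=float)

    def log_K_UI(self, D, cond: ExperimentConditions = DEFAULT_CONDITIONS):
        """ln K_UI(D) = ln k_UI(D) - ln k_IU(D) (three-state only)."""
        return self.law("UI").log_at(D, cond) - self.law("IU").log_at(D, cond)


def three_state_relaxation_rates(
    scheme: KineticScheme, D, cond: ExperimentConditions = DEFAULT_CONDITIONS
):
    """Both non-zero relaxation rates of the three-state scheme at D.

    Returns ``(lambda_fast, lambda_slow)`` in s^-1, the magnitudes of the
    two non-zero eigenvalues of the rate matrix. lambda_slow is evaluated
    as 2p / (s + sqrt(s^2 - 4p)) to avoid the cancellation that the naive
    (s - sqrt)/2 form suffers when the phases are well separated.
    """
    if scheme.n_states != 3:
        raise ValueError("three_state_relaxation_rates requires a three-state scheme")
    k_ui = scheme.law("UI").at(D, cond)
    k_iu = scheme.law("IU").at(D, cond)
    k_in = scheme.law("IN").at(D, cond)
    k_ni = scheme.law("NI").at(D, cond)
    s = k_ui + k_iu + k_in + k_ni
    p = k_ui * k_in + k_ui * k_ni + k_iu * k_ni
    disc = s * s - 4.0 * p
    if np.any(disc < 0):
        # impossible for positive rates; only round-off can land here
        if np.any(disc < -1e-8 * s * s):
            warnings.warn("discriminant significantly negative; clamping to 0", RuntimeWarning)
        disc = np.maximum(disc, 0.0)
    root = np.sqrt(disc)
    lam_fast = 0.5 * (s + root)
    lam_slow = 2.0 * p / (s + root)
    return lam_fast, lam_slow


def pre_equilibrium_slow_rate(
    scheme: KineticScheme, D, cond: ExperimentConditions = DEFAULT_CONDITIONS
):
    """Approximate slow rate k_IN*K_UI/(1+K_UI) + k_NI.

    Valid when U <-> I equilibrates much faster than the I -> N step; kept
    alongside the exact eigenvalue for comparison, the exact form being
    the default everywhere.
    """
    K = np.exp(scheme.log_K_UI(D, cond))
    return scheme.law("IN").at(D, cond) * K / (1.0 + K) + scheme.law("NI").at(D, cond)


def two_state_kobs(scheme: KineticScheme, D, cond: ExperimentConditions = DEFAULT_CONDITIONS):
    """Observed relaxation rate k_UN(D) + k_NU(D) of a two-state scheme."""
    if scheme.n_states != 2:
        raise ValueError("two_state_kobs requires a two-state scheme")
    return scheme.law("UN").at(D, cond) + scheme.law("NU").at(D, cond)


def observed_slow_rate(scheme: KineticScheme, D, cond: ExperimentConditions = DEFAULT_CONDITIONS):
    """The observable (slow-phase) relaxation rate for either scheme size."""
    if scheme.n_states == 3:
        return three_state_relaxation_rates(scheme, D, cond)[1]
    return two_state_kobs(scheme, D, cond)


def _log_population_weights(scheme, D, cond):
    """Log Boltzmann weights of the species, from detailed balance."""
    D = np.asarray(D, dtype=float)
    zeros = np.zeros_like(D)
    if scheme.n_states == 3:
        log_K = scheme.log_K_UI(D, cond)
        log_K_IN = scheme.law("IN").log_at(D, cond) - scheme.law("NI").log_at(D, cond)
        return np.stack([zeros, log_K, log_K + log_K_IN])
    log_K_UN = scheme.law("UN").log_at(D, cond) - scheme.law("NU").log_at(D, cond)
    return np.stack([zeros, log_K_UN])


def equilibrium_populations(
    scheme: KineticScheme, D, cond: ExperimentConditions = DEFAULT_CONDITIONS
):
    """Equilibrium populations (pU, pI, pN) at denaturant D.

    Computed from detailed balance (pU : pI : pN = 1 : K_UI : K_UI*k_IN/k_NI)
    with a log-space softmax for numerical safety. For a two-state scheme
    pI is identically zero. Populations sum to 1.
    """
    logw = _log_population_weights(scheme, D, cond)
    logw -= logw.max(axis=0)
    w = np.exp(logw)
    w /= w.sum(axis=0)
    if scheme.n_states == 3:
        return w[0], w[1], w[2]
    return w[0], np.zeros_like(w[0]), w[1]


@dataclass(frozen=True)
class ThermoSummary:
    """Free energies, m-value sums and Tanford beta values of a scheme.

    dG values are in kJ mol^-1 (negative = the more folded species is
    more stable), M values in kJ mol^-1 M^-1. beta_I and beta_TS2 are the
    fractional solvent burial of the intermediate and of the rate-limiting
    transition state relative to native; beta_I is None for a two-state
    scheme, where no intermediate exists.
    """

    dG_UN: float
    M_UN: float
    K_UI: float | None = None
    dG_UI: float | None = None
    dG_IN: float | None = None
    M_UI: float | None = None
    beta_I: float | None = None
    beta_TS2: float | None = None


def thermo_summary(
    scheme: KineticScheme, cond: ExperimentConditions = DEFAULT_CONDITIONS
) -> ThermoSummary:
    """Equilibrium thermodynamics implied by the zero-denaturant rates.

    Three-state: dG_UI = -RT ln(k_UI/k_IU), dG_IN = -RT ln(k_IN/k_NI),
    dG_UN = dG_UI + dG_IN (exact by construction); M_UI = m_UI + m_IU,
    M_UN = M_UI + m_IN + m_NI; beta_I = M_UI/M_UN and
    beta_TS2 = (M_UI + m_IN)/M_UN. Two-state: dG_UN = -RT ln(k_UN/k_NU),
    M_UN = m_UN + m_NU, beta_TS2 = m_UN/M_UN.
    """
    RT = cond.RT
    if scheme.n_states == 3:
        k = {t: scheme.law(t) for t in THREE_STATE_TRANSITIONS}
        K_UI = k["UI"].rate0 / k["IU"].rate0
        dG_UI = -RT * math.log(K_UI)
        dG_IN = -RT * math.log(k["IN"].rate0 / k["NI"].rate0)
        M_UI = k["UI"].m_kin + k["IU"].m_kin
        M_UN = M_UI + k["IN"].m_kin + k["NI"].m_kin
        return ThermoSummary(
            dG_UN=dG_UI + dG_IN,
            M_UN=M_UN,
            K_UI=K_UI,
            dG_UI=dG_UI,
            dG_IN=dG_IN,
            M_UI=M_UI,
            beta_I=M_UI / M_UN,
            beta_TS2=(M_UI + k["IN"].m_kin) / M_UN,
        )
    k_un, k_nu = scheme.law("UN"), scheme.law("NU")
    M_UN = k_un.m_kin + k_nu.m_kin
    return ThermoSummary(
        dG_UN=-RT * math.log(k_un.rate0 / k_nu.rate0),
        M_UN=M_UN,
        beta_TS2=k_un.m_kin / M_UN,
    )


def rate_matrix(scheme: KineticScheme, D, cond: ExperimentConditions = DEFAULT_CONDITIONS):
    """The generator matrix A of dp/dt = A p at a single denaturant D.

    Species order (U, I, N) for three-state or (U, N) for two-state.
    Columns sum to zero; used for trace simulation.
    """
    D = float(D)
    if scheme.n_states == 3:
        k_ui = float(scheme.law("UI").at(D, cond))
        k_iu = float(scheme.law("IU").at(D, cond))
        k_in = float(scheme.law("IN").at(D, cond))
        k_ni = float(scheme.law("NI").at(D, cond))
        return np.array(
            [
                [-k_ui, k_iu, 0.0],
                [k_ui, -(k_iu + k_in), k_ni],
                [0.0, k_in, -k_ni],
            ]
        )
    k_un = float(scheme.law("UN").at(D, cond))
    k_nu = float(scheme.law("NU").at(D, cond))
    return np.array([[-k_un, k_nu], [k_un, -k_nu]])


def make_three_state_scheme(
    k_UI: float,
    m_UI: float,
    k_IU: float,
    m_IU: float,
    k_IN: float,
    m_IN: float,
    k_NI: float,
    m_NI: float,
    signal_coeffs: Mapping[str, tuple[float, float]] | None = None,
) -> KineticScheme:
    """Convenience constructor from the eight kinetic parameters."""
    return KineticScheme(
        n_states=3,
        rate_laws={
            "UI": RateLaw(k_UI, m_UI, FOLDING),
            "IU": RateLaw(k_IU, m_IU, UNFOLDING),
            "IN": RateLaw(k_IN, m_IN, FOLDING),
            "NI": RateLaw(k_NI, m_NI, UNFOLDING),
        },
        signal_coeffs=signal_coeffs,
    )


def make_two_state_scheme(
    k_UN: float,
    m_UN: float,
    k_NU: float,
    m_NU: float,
    signal_coeffs: Mapping[str, tuple[float, float]] | None = None,
) -> KineticScheme:
    """Convenience constructor for the two-state scheme."""
    return KineticScheme(
        n_states=2,
        rate_laws={
            "UN": RateLaw(k_UN, m_UN, FOLDING),
            "NU": RateLaw(k_NU, m_NU, UNFOLDING),
        },
        signal_coeffs=signal_coeffs,
    )
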