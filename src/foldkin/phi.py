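"""Phi-value analysis: mutant-vs-reference free-energy comparisons.

For a variant and its reference (wild type, or a pseudo-wild-type such
as I54V for IV54T) the mutation-induced changes are

    ddG_UI  = dG_UI(mut)  - dG_UI(ref)
    ddG_UN  = dG_UN(mut)  - dG_UN(ref)
    phi_I   = ddG_UI / ddG_UN
    phi_TS2 = [ddG_UI - RT ln(k_IN_mut / k_IN_ref)] / ddG_UN

with the bracketed numerator equal to ddG_U-TS2, the destabilisation of
the rate-limiting transition state. Destabilising mutations give
positive ddG under the convention that stable states have negative dG.

Phi-values are only reported when |ddG_UN| >= 2.5 kJ mol^-1; below that
the ratio is dominated by fit noise and the result is flagged ND.

Error propagation is first order (delta method) over the independent
measurement blocks (K_UI), (k_IN) and (k_NI) of each protein: the
numerator and denominator of a phi-value share the ddG_UI contribution,
so their errors are propagated jointly, not in naive quadrature. Variant
and reference errors are treated as independent (separate experiments).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .conditions import DEFAULT_CONDITIONS, ExperimentConditions

__all__ = [
    "DDG_DETERMINABILITY_THRESHOLD",
    "PHI_LOW_MAX",
    "PHI_MID_MAX",
    "VariantRecord",
    "PhiResult",
    "delta_delta_G",
    "phi_I",
    "phi_TS2",
    "compute_phi",
    "classify_phi",
    "check_m_value_consistency",
    "build_report",
    "format_report",
]

#: minimum |ddG_UN| (kJ mol^-1) for a phi-value to be reported
DDG_DETERMINABILITY_THRESHOLD = 2.5

#: classification bin edges (boundary values fall in the lower bin)
PHI_LOW_MAX = 0.4
PHI_MID_MAX = 0.7


@dataclass
class VariantRecord:
    """Thermodynamic summary of one variant, with 1-sigma errors.

    Three-state records carry ``dG_UI`` plus the zero-denaturant ``k_IN``
    and ``k_NI``; ``dG_UN`` is derived. Two-state records carry ``dG_UN``
    directly. The optional m-value fields feed the report columns and the
    total-m-value quality check.
    """

    name: str
    model: str = "three_state"  # or "two_state"
    position: str = ""
    reference_name: str | None = None
    dG_UI: float | None = None
    dG_UI_sigma: float = 0.0
    k_IN: float | None = None
    k_IN_sigma: float = 0.0
    k_NI: float | None = None
    k_NI_sigma: float = 0.0
    dG_UN_explicit: float | None = None
    dG_UN_sigma_explicit: float = 0.0
    K_UI: float | None = None
    K_UI_sigma: float | None = None
    M_UI: float | None = None
    m_IN: float | None = None
    m_NI: float | None = None
    M_UN: float | None = None
    M_UN_sigma: float = 0.0

    def __post_init__(self) -> None:
        if self.model not in ("three_state", "two_state"):
            raise ValueError(f"model must be three_state/two_state, got {self.model!r}")
        if self.reference_name == self.name:
            raise ValueError(f"variant {self.name!r} may not reference itself")
        if self.model == "three_state":
            missing = [f for f in ("dG_UI", "k_IN", "k_NI") if getattr(self, f) is None]
            if missing:
                raise ValueError(f"three-state record {self.name!r} missing {missing}")
        elif self.dG_UN_explicit is None:
            raise ValueError(f"two-state record {self.name!r} needs dG_UN_explicit")

    # derived thermodynamics ---------------------------------------------
    def dG_IN(self, cond: ExperimentConditions = DEFAULT_CONDITIONS) -> float:
        return -cond.RT * math.log(self.k_IN / self.k_NI)

    def dG_IN_sigma(self, cond: ExperimentConditions = DEFAULT_CONDITIONS) -> float:
        return cond.RT * math.hypot(
            self.k_IN_sigma / self.k_IN, self.k_NI_sigma / self.k_NI
        )

    def dG_UN(self, cond: ExperimentConditions = DEFAULT_CONDITIONS) -> float:
        if self.model == "two_state":
            return self.dG_UN_explicit
        return self.dG_UI + self.dG_IN(cond)

    def dG_UN_sigma(self, cond: ExperimentConditions = DEFAULT_CONDITIONS) -> float:
        if self.model == "two_state":
            return self.dG_UN_sigma_explicit
        return math.hypot(self.dG_UI_sigma, self.dG_IN_sigma(cond))

    @property
    def beta_I(self) -> float | None:
        if None in (self.M_UI, self.M_UN):
            return None
        return self.M_UI / self.M_UN

    @property
    def beta_TS2(self) -> float | None:
        if self.model == "two_state" or None in (self.M_UI, self.m_IN, self.M_UN):
            return None
        return (self.M_UI + self.m_IN) / self.M_UN

    @classmethod
    def from_fit_result(
        cls,
        name: str,
        result,
        reference_name: str | None = None,
        position: str = "",
        cond: ExperimentConditions = DEFAULT_CONDITIONS,
    ) -> "VariantRecord":
        """Build a record from a chevron :class:`~foldkin.chevron.FitResult`."""
        p, s, th = result.params, result.sigma, result.thermo
        if result.scheme.n_states == 3:
            return cls(
                name=name,
                model="three_state",
                position=position,
                reference_name=reference_name,
                dG_UI=th.dG_UI,
                dG_UI_sigma=result.thermo_sigma.get("dG_UI", 0.0),
                k_IN=p["k_IN"],
                k_IN_sigma=s.get("k_IN", 0.0),
                k_NI=p["k_NI"],
                k_NI_sigma=s.get("k_NI", 0.0),
                K_UI=th.K_UI,
                K_UI_sigma=result.thermo_sigma.get("K_UI"),
                M_UI=th.M_UI,
                m_IN=p["m_IN"],
                m_NI=p["m_NI"],
                M_UN=th.M_UN,
                M_UN_sigma=result.thermo_sigma.get("M_UN", 0.0),
            )
        return cls(
            name=name,
            model="two_state",
            position=position,
            reference_name=reference_name,
            dG_UN_explicit=th.dG_UN,
            dG_UN_sigma_explicit=result.thermo_sigma.get("dG_UN", 0.0),
            M_UN=th.M_UN,
            M_UN_sigma=result.thermo_sigma.get("M_UN", 0.0),
        )


@dataclass(frozen=True)
class PhiValue:
    """A phi-value with its 1-sigma error and determinability flag."""

    value: float
    sigma: float
    determinable: bool


@dataclass(frozen=True)
class PhiResult:
    """All mutant-vs-reference comparisons for one variant."""

    name: str
    reference: str
    ddG_UI: float
    ddG_UI_sigma: float
    ddG_UN: float
    ddG_UN_sigma: float
    ddG_U_TS2: float
    ddG_U_TS2_sigma: float
    phi_I: float
    phi_I_sigma: float
    phi_TS2: float
    phi_TS2_sigma: float
    determinable: bool
    classification: str  # low | mid | high | ND


def delta_delta_G(mut: float, mut_sigma: float, ref: float, ref_sigma: float):
    """ddG = dG(mut) - dG(ref); error in quadrature (independent fits)."""
    if not (math.isfinite(mut) and math.isfinite(ref)):
        raise ValueError("dG values must be finite")
    return mut - ref, math.hypot(mut_sigma, ref_sigma)


def _ratio_sigma(num, num_sigma, tail, tail_sigma):
    """1-sigma of num/(num + tail) with independent num and tail."""
    denom = num + tail
    return math.sqrt(tail**2 * num_sigma**2 + num**2 * tail_sigma**2) / denom**2


def _require_three_state(*records: VariantRecord) -> None:
    for rec in records:
        if rec.model != "three_state":
            raise ValueError(f"record {rec.name!r} is not three-state; phi-values undefined")


def phi_I(
    variant: VariantRecord,
    reference: VariantRecord,
    cond: ExperimentConditions = DEFAULT_CONDITIONS,
    force: bool = False,
) -> PhiValue:
    """phi_I = ddG_UI / ddG_UN; ND (NaN) when |ddG_UN| < 2.5 kJ mol^-1."""
    _require_three_state(variant, reference)
    u, su = delta_delta_G(variant.dG_UI, variant.dG_UI_sigma, reference.dG_UI, reference.dG_UI_sigma)
    w, sw = delta_delta_G(
        variant.dG_IN(cond), variant.dG_IN_sigma(cond),
        reference.dG_IN(cond), reference.dG_IN_sigma(cond),
    )
    ddG_UN = u + w
    if ddG_UN == 0:
        raise ZeroDivisionError("ddG_UN is zero; phi_I undefined")
    determinable = abs(ddG_UN) >= DDG_DETERMINABILITY_THRESHOLD
    if not determinable and not force:
        return PhiValue(math.nan, math.nan, False)
    return PhiValue(u / ddG_UN, _ratio_sigma(u, su, w, sw), determinable)


def phi_TS2(
    variant: VariantRecord,
    reference: VariantRecord,
    cond: ExperimentConditions = DEFAULT_CONDITIONS,
    force: bool = False,
) -> PhiValue:
    """phi_TS2 = [ddG_UI - RT ln(k_IN_mut/k_IN_ref)] / ddG_UN."""
    _require_three_state(variant, reference)
    RT = cond.RT
    u, su = delta_delta_G(variant.dG_UI, variant.dG_UI_sigma, reference.dG_UI, reference.dG_UI_sigma)
    t = RT * math.log(variant.k_IN / reference.k_IN)
    st = RT * math.hypot(variant.k_IN_sigma / variant.k_IN, reference.k_IN_sigma / reference.k_IN)
    a, sa = u - t, math.hypot(su, st)
    v = RT * math.log(variant.k_NI / reference.k_NI)
    sv = RT * math.hypot(variant.k_NI_sigma / variant.k_NI, reference.k_NI_sigma / reference.k_NI)
    ddG_UN = a + v
    if ddG_UN == 0:
        raise ZeroDivisionError("ddG_UN is zero; phi_TS2 undefined")
    determinable = abs(ddG_UN) >= DDG_DETERMINABILITY_THRESHOLD
    if not determinable and not force:
        return PhiValue(math.nan, math.nan, False)
    return PhiValue(a / ddG_UN, _ratio_sigma(a, sa, v, sv), determinable)


def compute_phi(
    variant: VariantRecord,
    reference: VariantRecord,
    cond: ExperimentConditions = DEFAULT_CONDITIONS,
    force: bool = False,
) -> PhiResult:
    """Full comparison of a three-state variant against its reference."""
    _require_three_state(variant, reference)
    RT = cond.RT
    u, su = delta_delta_G(variant.dG_UI, variant.dG_UI_sigma, reference.dG_UI, reference.dG_UI_sigma)
    ddG_UN, s_ddG_UN = delta_delta_G(
        variant.dG_UN(cond), variant.dG_UN_sigma(cond),
        reference.dG_UN(cond), reference.dG_UN_sigma(cond),
    )
    t = RT * math.log(variant.k_IN / reference.k_IN)
    st = RT * math.hypot(variant.k_IN_sigma / variant.k_IN, reference.k_IN_sigma / reference.k_IN)
    a, sa = u - t, math.hypot(su, st)
    p_i = phi_I(variant, reference, cond, force)
    p_ts2 = phi_TS2(variant, reference, cond, force)
    determinable = abs(ddG_UN) >= DDG_DETERMINABILITY_THRESHOLD
    classification = classify_phi(p_i.value) if (determinable or force) else "ND"
    return PhiResult(
        name=variant.name,
        reference=reference.name,
        ddG_UI=u,
        ddG_UI_sigma=su,
        ddG_UN=ddG_UN,
        ddG_UN_sigma=s_ddG_UN,
        ddG_U_TS2=a,
        ddG_U_TS2_sigma=sa,
        phi_I=p_i.value,
        phi_I_sigma=p_i.sigma,
        phi_TS2=p_ts2.value,
        phi_TS2_sigma=p_ts2.sigma,
        determinable=determinable,
        classification=classification,
    )


def classify_phi(phi: float) -> str:
    """Bin a phi-value: low (<= 0.4), mid (<= 0.7) or high (> 0.7).

    Boundary values are assigned to the lower bin by convention.
    """
    if not math.isfinite(phi):
        return "ND"
    if phi <= PHI_LOW_MAX:
        return "low"
    if phi <= PHI_MID_MAX:
        return "mid"
    return "high"


def check_m_value_consistency(
    variant_M_UN: float, reference_M_UN: float, tolerance_fraction: float = 0.10
) -> bool:
    """True when the variant's total m-value is within the tolerance band.

    The pass band is the open interval |v - r|/r < tolerance (a variant
    sitting exactly on the 10% boundary is flagged): with a wild-type
    reference of 5.4 kJ mol^-1 M^-1 the band is (4.86, 5.94).
    """
    if variant_M_UN <= 0 or reference_M_UN <= 0:
        raise ValueError("m-values must be positive")
    return abs(variant_M_UN - reference_M_UN) / reference_M_UN < tolerance_fraction


def _resolve_reference(name, record, reference_map, by_name):
    ref_name = None
    if reference_map:
        ref_name = reference_map.get(name)
    if ref_name is None:
        ref_name = record.reference_name
    if ref_name is None and reference_map:
        ref_name = reference_map.get("default")
    if ref_name is None:
        ref_name = "WT"
    return ref_name


def build_report(
    records: Iterable[VariantRecord],
    reference_map: Mapping[str, str] | None = None,
    cond: ExperimentConditions = DEFAULT_CONDITIONS,
) -> pd.DataFrame:
    """One row per variant: rates, free energies, phi- and beta-values.

    ``reference_map`` may name a per-variant reference and a ``"default"``
    entry; it overrides each record's own ``reference_name``. A reference
    that resolves to no record raises a KeyError naming the variant.
    Reference rows (records nobody, including themselves, compares
    against a resolvable reference — i.e. the wild type itself) get NaN
    phi columns with status ``reference``.
    """
    records = list(records)
    by_name = {r.name: r for r in records}
    rows = []
    for rec in records:
        row = {
            "variant": rec.name,
            "position": rec.position,
            "model": rec.model,
            "K_UI": rec.K_UI,
            "M_UI": rec.M_UI,
            "k_IN": rec.k_IN,
            "m_IN": rec.m_IN,
            "k_NI": rec.k_NI,
            "m_NI": rec.m_NI,
            "dG_UI": rec.dG_UI,
            "dG_UN": rec.dG_UN(cond),
            "M_UN": rec.M_UN,
            "beta_I": rec.beta_I,
            "beta_TS2": rec.beta_TS2,
        }
        ref_name = _resolve_reference(rec.name, rec, reference_map, by_name)
        if ref_name == rec.name:
            row.update(
                ddG_UI=np.nan, ddG_UN=np.nan, ddG_U_TS2=np.nan,
                phi_I=np.nan, phi_I_sigma=np.nan, phi_TS2=np.nan, phi_TS2_sigma=np.nan,
                status="reference", reference="",
            )
            rows.append(row)
            continue
        if ref_name not in by_name:
            raise KeyError(
                f"variant {rec.name!r} references {ref_name!r}, which is not among the records"
            )
        ref = by_name[ref_name]
        row["reference"] = ref_name
        if rec.model == "two_state":
            ddG_UN, s = delta_delta_G(
                rec.dG_UN(cond), rec.dG_UN_sigma(cond), ref.dG_UN(cond), ref.dG_UN_sigma(cond)
            )
            row.update(
                ddG_UI=np.nan, ddG_UN=ddG_UN, ddG_U_TS2=np.nan,
                phi_I=np.nan, phi_I_sigma=np.nan, phi_TS2=np.nan, phi_TS2_sigma=np.nan,
                status="two_state",
            )
        else:
            res = compute_phi(rec, ref, cond)
            row.update(
                ddG_UI=res.ddG_UI, ddG_UN=res.ddG_UN, ddG_U_TS2=res.ddG_U_TS2,
                phi_I=res.phi_I, phi_I_sigma=res.phi_I_sigma,
                phi_TS2=res.phi_TS2, phi_TS2_sigma=res.phi_TS2_sigma,
                status="ok" if res.determinable else "ND",
            )
        rows.append(row)
    return pd.DataFrame(rows).set_index("variant")


def format_report(report: pd.DataFrame, sig_figs: int = 4) -> str:
    """Aligned text table with ND / em-dash markers for missing phi cells."""
    df = report.copy()

    def fmt(x, status):
        if isinstance(x, float) and not math.isfinite(x):
            return "ND" if status == "ND" else "—"
        if isinstance(x, float):
            return f"{x:.{sig_figs}g}"
        return "" if x is None else str(x)

    out = df.copy()
    for col in df.columns:
        if col in ("position", "model", "status", "reference"):
            continue
        out[col] = [
            fmt(v, st) if isinstance(v, float) or v is None else v
            for v, st in zip(df[col], df["status"])
        ]
        out[col] = [("—" if v is None else v) for v in out[col]]
    return out.to_string()
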