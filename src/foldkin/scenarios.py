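"""Named parameter sets for wild-type Im7 and its core variants.

The packaged JSON library transcribes the best-fit kinetic parameters of
the solvation (Val->Thr, Phe->Tyr) and overpacking (->Phe/Ile) variant
series, plus equilibrium-only parameter sets for the variants that do
not fold to the native state. These sets serve as generating truth for
synthetic data and as inputs for recomputing the derived thermodynamic
columns (dG, ddG, phi, beta).

The three-state sets are stored as (K_UI, M_UI) plus the I->N / N->I
rate laws; the microscopic k_IU and m_IU follow from the fixed fast-phase
values k_UI = 1574 s^-1 and m_UI = 1.23 kJ mol^-1 M^-1 (k_IU = k_UI/K_UI,
m_IU = M_UI - m_UI). Fluorescence baseline coefficients are a synthetic
canonical set (the intermediate more fluorescent than U and N, unfolded
baseline 1 at the 7.75 M urea reference); they are not published values.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from importlib import resources
from typing import Mapping

from .conditions import DEFAULT_CONDITIONS, ExperimentConditions
from .equilibrium import EquilibriumFit
from .models import KineticScheme, make_three_state_scheme, make_two_state_scheme
from .phi import VariantRecord

__all__ = ["Scenario", "ScenarioLibrary", "load_scenario_library"]


@dataclass(frozen=True)
class Scenario:
    """One named kinetic parameter set with 1-sigma literature errors."""

    name: str
    model: str
    table: int
    position: str
    reference: str | None
    params: Mapping[str, float]
    printed: Mapping[str, float | None]
    k_UI_fixed: float
    m_UI_fixed: float
    signal_coeffs: Mapping[str, tuple[float, float]]
    M_UN_range: tuple[float, float] | None = None

    def to_scheme(self) -> KineticScheme:
        """Materialise the full kinetic scheme (with signal baselines)."""
        p = self.params
        coeffs = {k: tuple(v) for k, v in self.signal_coeffs.items()}
        if self.model == "three_state":
            k_IU = self.k_UI_fixed / p["K_UI"]
            m_IU = p["M_UI"] - self.m_UI_fixed
            return make_three_state_scheme(
                self.k_UI_fixed, self.m_UI_fixed, k_IU, m_IU,
                p["k_IN"], p["m_IN"], p["k_NI"], p["m_NI"],
                {k: coeffs[k] for k in ("U", "I", "N")},
            )
        return make_two_state_scheme(
            p["k_UN"], p["m_UN"], p["k_NU"], p["m_NU"],
            {k: coeffs[k] for k in ("U", "N")},
        )

    def to_record(self, cond: ExperimentConditions = DEFAULT_CONDITIONS) -> VariantRecord:
        """Variant record with dG values derived from the rate constants.

        Free energies and their errors come from the delta method on the
        independent blocks (K_UI), (k_IN), (k_NI) — e.g.
        sigma(dG_UI) = RT * sigma(K_UI)/K_UI.
        """
        p = self.params
        if self.model == "two_state":
            dG = -cond.RT * math.log(p["k_UN"] / p["k_NU"])
            s = cond.RT * math.hypot(
                p["k_UN_sigma"] / p["k_UN"], p["k_NU_sigma"] / p["k_NU"]
            )
            M_UN = p["m_UN"] + p["m_NU"]
            return VariantRecord(
                name=self.name, model="two_state", position=self.position,
                reference_name=self.reference,
                dG_UN_explicit=dG, dG_UN_sigma_explicit=s,
                M_UN=M_UN, M_UN_sigma=math.hypot(p["m_UN_sigma"], p["m_NU_sigma"]),
            )
        dG_UI = -cond.RT * math.log(p["K_UI"])
        M_UN = p["M_UI"] + p["m_IN"] + p["m_NI"]
        return VariantRecord(
            name=self.name, model="three_state", position=self.position,
            reference_name=self.reference,
            dG_UI=dG_UI, dG_UI_sigma=cond.RT * p["K_UI_sigma"] / p["K_UI"],
            k_IN=p["k_IN"], k_IN_sigma=p["k_IN_sigma"],
            k_NI=p["k_NI"], k_NI_sigma=p["k_NI_sigma"],
            K_UI=p["K_UI"], K_UI_sigma=p["K_UI_sigma"],
            M_UI=p["M_UI"], m_IN=p["m_IN"], m_NI=p["m_NI"],
            M_UN=M_UN,
            M_UN_sigma=math.hypot(
                p["M_UI_sigma"], math.hypot(p["m_IN_sigma"], p["m_NI_sigma"])
            ),
        )


@dataclass
class ScenarioLibrary:
    """All named scenarios plus the equilibrium-only parameter sets."""

    scenarios: dict[str, Scenario]
    equilibrium: dict[str, EquilibriumFit]
    aliases: dict[str, str]
    defaults: dict

    def __getitem__(self, name: str) -> Scenario:
        return self.scenarios[self.aliases.get(name, name)]

    def __contains__(self, name: str) -> bool:
        return self.aliases.get(name, name) in self.scenarios

    @property
    def names(self) -> list[str]:
        return list(self.scenarios)

    def table(self, number: int) -> list[Scenario]:
        return [s for s in self.scenarios.values() if s.table == number]

    def records(self, names=None, cond: ExperimentConditions = DEFAULT_CONDITIONS):
        names = names if names is not None else self.names
        return [self[n].to_record(cond) for n in names]


def load_scenario_library() -> ScenarioLibrary:
    """Load the packaged scenario library."""
    raw = json.loads(
        resources.files("foldkin.data").joinpath("scenarios.json").read_text()
    )
    defaults = raw["defaults"]
    coeffs = {k: tuple(v) for k, v in defaults["signal_coeffs"].items()}
    scenarios: dict[str, Scenario] = {}
    aliases: dict[str, str] = {}
    for name, entry in raw["scenarios"].items():
        for alias in entry.get("aliases", []):
            aliases[alias] = name
        params = {
            k: v
            for k, v in entry.items()
            if isinstance(v, (int, float)) and k not in ("table",)
        }
        scenarios[name] = Scenario(
            name=name,
            model=entry["model"],
            table=entry["table"],
            position=entry.get("position", ""),
            reference=entry.get("reference"),
            params=params,
            printed=entry.get("printed", {}),
            k_UI_fixed=defaults["k_UI"],
            m_UI_fixed=defaults["m_UI"],
            signal_coeffs=coeffs,
            M_UN_range=tuple(entry["M_UN_range"]) if "M_UN_range" in entry else None,
        )
    equilibrium = {
        name: EquilibriumFit(
            dG_UN=e["dG_UN"],
            M_UN=e["M_UN"],
            baseline_N=tuple(e["baseline_N"]),
            baseline_D=tuple(e["baseline_D"]),
            sigma={"dG_UN": e["dG_UN_sigma"], "M_UN": e["M_UN_sigma"]},
            probe=e.get("probe", "fluorescence"),
        )
        for name, e in raw["equilibrium"].items()
    }
    return ScenarioLibrary(
        scenarios=scenarios, equilibrium=equilibrium, aliases=aliases, defaults=defaults
    )
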