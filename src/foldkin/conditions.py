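"""Experimental conditions shared by every model in the package."""

from __future__ import annotations

from dataclasses import dataclass

#: Gas constant in kJ mol^-1 K^-1.
GAS_CONSTANT_KJ = 0.0083145


@dataclass(frozen=True)
class ExperimentConditions:
    """Temperature and gas constant defining the thermal energy RT.

    All free energies in the package are in kJ mol^-1 and all denaturant
    dependencies (m-values) in kJ mol^-1 M^-1, so RT is the only place
    where units meet. The default temperature, 283.15 K (10 degrees C),
    is the standard condition for stopped-flow studies of Im7 folding and
    gives RT ~= 2.354 kJ mol^-1.
    """

    temperature_K: float = 283.15
    gas_constant: float = GAS_CONSTANT_KJ

    def __post_init__(self) -> None:
        if self.temperature_K <= 0:
            raise ValueError(f"temperature_K must be > 0, got {self.temperature_K}")
        if self.gas_constant <= 0:
            raise ValueError(f"gas_constant must be > 0, got {self.gas_constant}")

    @property
    def RT(self) -> float:
        """Thermal energy, kJ mol^-1."""
        return self.gas_constant * self.temperature_K


#: Conditions used throughout unless the caller overrides them.
DEFAULT_CONDITIONS = ExperimentConditions()
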