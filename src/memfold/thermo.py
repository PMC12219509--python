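"""Thermodynamic context: temperature and the gas constant.

All free energies in the package are in kcal/mol, so the default gas
constant is R = 1.987e-3 kcal mol^-1 K^-1.  Three temperatures recur:

* 297.65 K (24.5 C): the room temperature of the steric-trapping and
  bicelle experiments; RT = 0.591 kcal/mol, the thermal energy used for
  the cooperativity cutoffs (rounded to 0.6 kcal/mol in figure legends).
* 310 K: the MD simulation thermostat, used for amphiphile solvation
  free energies.
* 310.15 K (37 C): the OmpLA chemical-denaturation incubation.
"""

from __future__ import annotations

from dataclasses import dataclass

from .errors import DomainError

GAS_CONSTANT_KCAL = 1.987e-3  # kcal / (mol K)

ROOM_TEMPERATURE_K = 297.65   # 24.5 C steric-trapping experiments
SIMULATION_TEMPERATURE_K = 310.0
DENATURATION_TEMPERATURE_K = 310.15  # 37 C OmpLA titrations


@dataclass(frozen=True)
class ThermoContext:
    """Absolute temperature plus gas constant; provides RT in kcal/mol."""

    temperature: float = ROOM_TEMPERATURE_K
    gas_constant: float = GAS_CONSTANT_KCAL

    def __post_init__(self):
        if not self.temperature > 0:
            raise DomainError(f"temperature must be > 0 K, got {self.temperature}")
        if not self.gas_constant > 0:
            raise DomainError(f"gas constant must be > 0, got {self.gas_constant}")

    @property
    def rt(self) -> float:
        """Thermal energy R*T in kcal/mol."""
        return self.gas_constant * self.temperature


ROOM_CONTEXT = ThermoContext(ROOM_TEMPERATURE_K)
SIMULATION_CONTEXT = ThermoContext(SIMULATION_TEMPERATURE_K)
DENATURATION_CONTEXT = ThermoContext(DENATURATION_TEMPERATURE_K)
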