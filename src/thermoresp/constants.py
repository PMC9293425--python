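"""Physical constants and temperature-unit helpers.

All internal computation is in SI units (J mol⁻¹, J mol⁻¹ K⁻¹, K, Pa).
Temperatures cross the package boundary in °C (field and incubation data
are recorded in °C) and are converted once, here.
"""

from __future__ import annotations

from dataclasses import dataclass, fields

ZERO_CELSIUS = 273.15


@dataclass(frozen=True)
class ThermoConstants:
    """Physical constants injected into every model computation.

    The two Lloyd & Taylor constants are the canonical zero-rate
    temperature (227.13 K) and reference span (56.02 K); their sum is
    283.15 K, which makes the basal-rate parameter exactly the rate at
    10 °C.  All fields are configurable so alternative conventions can
    be studied without touching call sites.

    Attributes
    ----------
    R_gas : float
        Universal gas constant, J mol⁻¹ K⁻¹.
    k_B : float
        Boltzmann constant, J K⁻¹.
    h_planck : float
        Planck constant, J s.
    T0 : float
        Reference temperature for the activation parameters, K
        (298.15 K, i.e. 25 °C; keeps °C↔K conversion exact).
    P_atm : float
        Headspace pressure for the ideal-gas conversion, Pa.
    lt_T0_offset : float
        Lloyd & Taylor zero-rate temperature, K.
    lt_ref_span : float
        Lloyd & Taylor reference span, K.
    """

    R_gas: float = 8.314
    k_B: float = 1.380649e-23
    h_planck: float = 6.62607015e-34
    T0: float = 298.15
    P_atm: float = 101325.0
    lt_T0_offset: float = 227.13
    lt_ref_span: float = 56.02

    def __post_init__(self) -> None:
        for f in fields(self):
            if not getattr(self, f.name) > 0:
                raise ValueError(f"{f.name} must be strictly positive")
        if not self.T0 > self.lt_T0_offset:
            raise ValueError("T0 must exceed the Lloyd & Taylor zero-rate temperature")


#: Module-wide default constants.
DEFAULT_CONSTANTS = ThermoConstants()


def celsius_to_kelvin(t_celsius):
    """Convert °C to K (scalar or array)."""
    return t_celsius + ZERO_CELSIUS


def kelvin_to_celsius(t_kelvin):
    """Convert K to °C (scalar or array)."""
    return t_kelvin - ZERO_CELSIUS
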