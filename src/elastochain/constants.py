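"""Physical constants in the package's unit system (pN, Å, K, ps)."""

#: Boltzmann constant in pN·Å/K (SI value 1.380649e-23 J/K; 1 J = 1e22 pN·Å).
BOLTZMANN_PN_ANGSTROM: float = 0.1380649


def thermal_energy(temperature: float) -> float:
    """k_B·T in pN·Å for a temperature in kelvin."""
    if temperature <= 0:
        raise ValueError(f"temperature must be positive, got {temperature}")
    return BOLTZMANN_PN_ANGSTROM * temperature
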