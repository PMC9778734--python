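"""Physical constants in the package's unit system (Å, ps, kcal·mol⁻¹, K)."""

#: Boltzmann constant, kcal·mol⁻¹·K⁻¹.
KB_KCAL = 0.0019872041

#: Boltzmann constant, J·K⁻¹ (SI, for the Eyring prefactor).
KB_SI = 1.380649e-23

#: Planck constant, J·s.
PLANCK_SI = 6.62607015e-34

#: Default simulation/analysis temperature, K.
DEFAULT_TEMPERATURE = 310.0


def beta(temperature: float) -> float:
    """Inverse thermal energy 1/(kB·T) in mol·kcal⁻¹."""
    if temperature <= 0:
        raise ValueError(f"temperature must be positive, got {temperature}")
    return 1.0 / (KB_KCAL * temperature)
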