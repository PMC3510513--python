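"""Unit helpers.

Everything inside the package is SI: seconds and molar. Experimental
descriptions use the field's idiom (µM for concentrations, ms for diffusion
times, minutes for incubation times); these helpers convert at the interfaces.
"""

MICROMOLAR = 1e-6  # M
NANOMOLAR = 1e-9  # M
MILLISECOND = 1e-3  # s
MINUTE = 60.0  # s


def uM(value: float) -> float:
    """Micromolar -> molar."""
    return value * MICROMOLAR


def nM(value: float) -> float:
    """Nanomolar -> molar."""
    return value * NANOMOLAR


def ms(value: float) -> float:
    """Milliseconds -> seconds."""
    return value * MILLISECOND


def minutes(value: float) -> float:
    """Minutes -> seconds."""
    return value * MINUTE
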