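"""Monoisotopic atomic masses for the element set handled by the pipeline.

One constant table shared by the formula parser, the mass/formula
consistency check, and the synthetic-data generators, so every mass in the
toolchain traces to a single source of truth.
"""

from __future__ import annotations

# Mass of the most abundant isotope, in Da (unified atomic mass units).
MONOISOTOPIC_MASS: dict[str, float] = {
    "C": 12.000000,
    "H": 1.0078250319,
    "N": 14.0030740052,
    "O": 15.9949146221,
    "S": 31.97207069,
    "P": 30.97376151,
    "Cl": 34.96885271,
}

KNOWN_ELEMENTS = frozenset(MONOISOTOPIC_MASS)


def monoisotopic_mass(counts: dict[str, int]) -> float:
    """Neutral monoisotopic mass of an element-count map, in Da.

    Raises KeyError for elements outside the supported set.
    """
    return sum(MONOISOTOPIC_MASS[el] * n for el, n in counts.items())
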