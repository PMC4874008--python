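"""Monoisotopic masses of the 20 standard amino-acid residues and related constants.

All masses are in daltons. Residue masses are the masses of the amino acid
minus one water (the form they take inside a peptide chain); a peptide's
neutral monoisotopic mass is the sum of its residue masses plus one water.
"""

from __future__ import annotations

import math

WATER_MONO: float = 18.0105646863
PROTON_MONO: float = 1.007276466879

#: Monoisotopic residue masses (Da). Leucine and isoleucine are isobaric.
AA_MONO: dict[str, float] = {
    "G": 57.02146372957,
    "A": 71.03711378471,
    "S": 87.03202840427,
    "P": 97.05276384885,
    "V": 99.06841391299,
    "T": 101.04767846841,
    "C": 103.00918478471,
    "L": 113.08406397713,
    "I": 113.08406397713,
    "N": 114.04292744114,
    "D": 115.02694302383,
    "Q": 128.05857750528,
    "K": 128.09496301399,
    "E": 129.04259308797,
    "M": 131.04048491299,
    "H": 137.05891185845,
    "F": 147.06841391299,
    "R": 156.10111102359,
    "Y": 163.06332853255,
    "W": 186.07931294985,
}

STANDARD_AA = frozenset(AA_MONO)

#: DSS / BS3 cross-linker mass added to a linked peptide pair (Da).
DSS_LINKER_MASS: float = 138.06808


def peptide_mass(sequence: str) -> float:
    """Neutral monoisotopic mass of a peptide, including one water.

    Uses exact (correctly rounded) summation so that permutations of a
    sequence — in particular a peptide and its decoy — have bit-identical
    masses.
    """
    return math.fsum([AA_MONO[aa] for aa in sequence] + [WATER_MONO])


def mass_to_mz(neutral_mass: float, charge: int) -> float:
    """m/z of an ion with the given neutral mass carrying ``charge`` protons."""
    return (neutral_mass + charge * PROTON_MONO) / charge


def mz_to_neutral_mass(mz: float, charge: int) -> float:
    """Neutral mass corresponding to an observed m/z at the given charge."""
    return (mz - PROTON_MONO) * charge
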