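"""Theoretical CID fragmentation of a linked chain.

Under CID a cross-linked pair dissociates along either backbone, giving b/y
ions of two kinds per chain: *linear* ions made of that chain's residues
only, and *cross-linking* ions that additionally carry the linker and the
entire partner chain.  A cross-linking ion's neutral mass is the linear
fragment mass shifted by ``p - c`` (precursor mass minus the chain's own
mass), which equals the partner chain mass plus the linker mass — so the
shift can be computed from the spectrum alone, without knowing the partner.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, NamedTuple

import numpy as np

from .constants import AA_MONO, PROTON_MONO, WATER_MONO
from .sparse import SparseVector, from_bins
from .sequence_db import Chain


@dataclass(frozen=True)
class LinkedChain:
    """A chain together with the residue position carrying the linker."""

    chain: Chain
    link_site: int  # 1-based

    def __post_init__(self) -> None:
        if self.link_site not in self.chain.link_sites:
            raise ValueError(
                f"site {self.link_site} is not a link site of "
                f"{self.chain.sequence}"
            )


class Ion(NamedTuple):
    neutral_mass: float
    is_crosslinking: bool
    series: str  # "b" or "y"
    index: int   # 1-based fragment index within the series


def linear_fragment_masses(sequence: str) -> tuple[np.ndarray, np.ndarray]:
    """Neutral b- and y-fragment masses of a peptide.

    b_i is the sum of the first i residue masses (i = 1..m-1); y_j is the sum
    of the last j residue masses plus one water (j = 1..m-1).
    """
    if len(sequence) < 2:
        raise ValueError("need at least 2 residues to fragment")
    residues = np.array([AA_MONO[aa] for aa in sequence])
    b = np.cumsum(residues[:-1])
    y = np.cumsum(residues[::-1][:-1]) + WATER_MONO
    return b, y


def classify_and_shift(linked: LinkedChain, precursor_mass: float) -> list[Ion]:
    """All b/y ions of a linked chain with cross-linking ions mass-shifted.

    A b_i ion is cross-linking iff its prefix contains the linked residue
    (i >= link_site); a y_j ion iff its suffix does (j >= m - link_site + 1).
    Cross-linking ions get mass ``p - c + l``; linear ions keep ``l``.
    """
    seq = linked.chain.sequence
    m = len(seq)
    site = linked.link_site
    shift = precursor_mass - linked.chain.neutral_mass
    b, y = linear_fragment_masses(seq)
    ions: list[Ion] = []
    for i in range(1, m):
        xl = i >= site
        mass = b[i - 1] + shift if xl else b[i - 1]
        ions.append(Ion(float(mass), xl, "b", i))
    for j in range(1, m):
        xl = j >= m - site + 1
        mass = y[j - 1] + shift if xl else y[j - 1]
        ions.append(Ion(float(mass), xl, "y", j))
    return ions


def theoretical_ion_mzs(linked: LinkedChain, precursor_mass: float,
                        fragment_charges: Iterable[int]) -> list[float]:
    """m/z of every b/y ion (linear and cross-linking) at each charge."""
    ions = classify_and_shift(linked, precursor_mass)
    return [
        (ion.neutral_mass + z * PROTON_MONO) / z
        for ion in ions
        for z in fragment_charges
    ]


def build_half_vector(linked: LinkedChain, precursor_mass: float,
                      precursor_charge: int, config) -> SparseVector:
    """Sparse theoretical half-spectrum of one chain at one link site.

    Ion m/z values are binned with the same width as experimental vectors;
    a bin's intensity is the number of ions falling into it.
    """
    mzs = theoretical_ion_mzs(
        linked, precursor_mass, config.fragment_charges(precursor_charge)
    )
    width = config.bin_width
    bins = np.floor(np.asarray(mzs) / width).astype(np.int64)
    return from_bins(bins)
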