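"""Protein database handling: FASTA input, tryptic digestion, decoys, chain index.

A "chain" is one of the two peptides of a cross-linked pair.  The database
stage digests every target protein, builds a mass-preserving decoy for each
tryptic peptide (sequence reversal with lysine and arginine held in place),
keeps the chains that carry at least one linkable lysine, and indexes them by
neutral monoisotopic mass so that the search can answer mass-window queries
with binary search.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
from pyteomics import fasta as _fasta

from .constants import STANDARD_AA, peptide_mass

logger = logging.getLogger(__name__)

DECOY_PREFIX = "DECOY_"


@dataclass(frozen=True)
class Protein:
    accession: str
    sequence: str
    is_decoy: bool = False


@dataclass
class Chain:
    """A digested peptide considered for cross-linking.

    ``neutral_mass`` is the monoisotopic mass including one water;
    ``link_sites`` are 1-based positions of linkable residues.
    """

    sequence: str
    neutral_mass: float
    link_sites: tuple[int, ...]
    missed_cleavages: int
    is_decoy: bool
    parent_accessions: frozenset[str]
    is_protein_nterm: bool = False
    is_protein_cterm: bool = False

    def target_parent_accessions(self) -> frozenset[str]:
        """Parent accessions with any decoy prefix stripped."""
        return frozenset(
            acc[len(DECOY_PREFIX):] if acc.startswith(DECOY_PREFIX) else acc
            for acc in self.parent_accessions
        )


def read_fasta(path) -> list[Protein]:
    """Read a FASTA file into Proteins.

    The accession is the header token before the first whitespace. Records
    whose sequence contains a letter outside the 20 standard amino acids are
    skipped with a warning. An unreadable file or a file with no valid record
    raises.
    """
    proteins: list[Protein] = []
    seen: set[str] = set()
    with _fasta.read(str(path)) as reader:
        for description, sequence in reader:
            accession = description.split()[0]
            seq = sequence.upper()
            if not seq or not set(seq) <= STANDARD_AA:
                bad = sorted(set(seq) - STANDARD_AA)
                logger.warning(
                    "skipping record %s: non-standard letters %s", accession, bad
                )
                continue
            if accession in seen:
                raise ValueError(f"duplicate accession in FASTA: {accession}")
            seen.add(accession)
            proteins.append(
                Protein(accession, seq, is_decoy=accession.startswith(DECOY_PREFIX))
            )
    if not proteins:
        raise ValueError(f"no valid FASTA records in {path}")
    return proteins


def cleavage_positions(sequence: str, cleave_after: str = "KR",
                       no_cleave_before: str = "P") -> list[int]:
    """0-based positions after which the enzyme cuts (trypsin by default)."""
    return [
        i + 1
        for i in range(len(sequence) - 1)
        if sequence[i] in cleave_after and sequence[i + 1] not in no_cleave_before
    ]


def digest(protein: Protein, max_missed: int, min_len: int, max_len: int,
           cleave_after: str = "KR", no_cleave_before: str = "P") -> list[Chain]:
    """Tryptic digest of one protein into Chains.

    Returns every peptide with 0..max_missed internal missed cleavage sites
    and length within [min_len, max_len]. Duplicate sequences arising from
    repeated regions of the same protein are merged (keeping the minimum
    missed-cleavage count and the union of terminal flags).
    """
    seq = protein.sequence
    bounds = [0] + cleavage_positions(seq, cleave_after, no_cleave_before) + [len(seq)]
    by_seq: dict[str, Chain] = {}
    for a in range(len(bounds) - 1):
        for b in range(a + 1, min(a + 2 + max_missed, len(bounds))):
            pep = seq[bounds[a]:bounds[b]]
            if not (min_len <= len(pep) <= max_len):
                continue
            missed = b - a - 1
            is_nterm = bounds[a] == 0
            is_cterm = bounds[b] == len(seq)
            prior = by_seq.get(pep)
            if prior is None:
                by_seq[pep] = Chain(
                    sequence=pep,
                    neutral_mass=peptide_mass(pep),
                    link_sites=(),
                    missed_cleavages=missed,
                    is_decoy=protein.is_decoy,
                    parent_accessions=frozenset({protein.accession}),
                    is_protein_nterm=is_nterm,
                    is_protein_cterm=is_cterm,
                )
            else:
                prior.missed_cleavages = min(prior.missed_cleavages, missed)
                prior.is_protein_nterm = prior.is_protein_nterm or is_nterm
                prior.is_protein_cterm = prior.is_protein_cterm or is_cterm
    chains = list(by_seq.values())
    for chain in chains:
        chain.link_sites = find_link_sites(chain)
    return chains


def make_decoy(chain_sequence: str) -> str:
    """Reverse a peptide with every K and R fixed in place.

    The output has identical length, composition (hence mass) and identical
    K/R positions, so decoy chains carry the same linkable sites as their
    targets. The operation is an involution.
    """
    if not chain_sequence:
        raise ValueError("empty sequence")
    fixed = [aa in "KR" for aa in chain_sequence]
    movable = [aa for aa, fx in zip(chain_sequence, fixed) if not fx]
    it = iter(reversed(movable))
    return "".join(
        aa if fx else next(it) for aa, fx in zip(chain_sequence, fixed)
    )


def find_link_sites(chain: Chain, allow_nterm: bool = False) -> tuple[int, ...]:
    """1-based linkable positions of a chain.

    Every lysine is linkable except one at the chain C-terminus: a lysine
    carrying a linker blocks tryptic cleavage, so a linked C-terminal K can
    only occur when the chain ends the protein. Optionally the first residue
    of a protein N-terminal peptide is linkable through the alpha-amine.
    """
    seq = chain.sequence
    last = len(seq) - 1
    sites = [
        i + 1
        for i, aa in enumerate(seq)
        if aa == "K" and (i < last or chain.is_protein_cterm)
    ]
    if allow_nterm and chain.is_protein_nterm and 1 not in sites:
        sites.insert(0, 1)
    return tuple(sites)


class ChainIndex:
    """Chains sorted by neutral mass with half-open mass-range queries."""

    def __init__(self, chains: list[Chain]):
        if not chains:
            raise ValueError("empty chain index")
        self.entries = sorted(
            chains, key=lambda c: (c.neutral_mass, c.sequence, c.is_decoy)
        )
        self._masses = np.array([c.neutral_mass for c in self.entries])

    def __len__(self) -> int:
        return len(self.entries)

    def range_bounds(self, lo: float, hi: float) -> tuple[int, int]:
        """Positions [start, stop) of chains with lo <= mass < hi."""
        start = int(np.searchsorted(self._masses, lo, side="left"))
        stop = int(np.searchsorted(self._masses, hi, side="left"))
        return start, stop

    def range_query(self, lo: float, hi: float) -> list[Chain]:
        start, stop = self.range_bounds(lo, hi)
        return self.entries[start:stop]


def build_chain_index(proteins: list[Protein], config) -> ChainIndex:
    """Digest targets, generate per-peptide decoys, and index linkable chains.

    Chains sharing a sequence across proteins are merged with the union of
    parent accessions. A decoy sequence that collides with any target
    sequence is dropped (the shared sequence stays labelled target). Only
    chains with at least one link site enter the index.
    """
    target_by_seq: dict[str, Chain] = {}
    decoy_by_seq: dict[str, Chain] = {}

    def merge(pool: dict[str, Chain], chain: Chain) -> None:
        prior = pool.get(chain.sequence)
        if prior is None:
            pool[chain.sequence] = chain
        else:
            prior.parent_accessions = prior.parent_accessions | chain.parent_accessions
            prior.missed_cleavages = min(prior.missed_cleavages, chain.missed_cleavages)
            prior.is_protein_nterm = prior.is_protein_nterm or chain.is_protein_nterm
            prior.is_protein_cterm = prior.is_protein_cterm or chain.is_protein_cterm

    for protein in proteins:
        chains = digest(
            protein, config.max_missed, config.min_len, config.max_len,
            config.cleave_after, config.no_cleave_before,
        )
        pool = decoy_by_seq if protein.is_decoy else target_by_seq
        for chain in chains:
            merge(pool, chain)
            if not protein.is_decoy and config.generate_decoys:
                decoy = replace(
                    chain,
                    sequence=make_decoy(chain.sequence),
                    is_decoy=True,
                    parent_accessions=frozenset(
                        DECOY_PREFIX + acc for acc in chain.parent_accessions
                    ),
                )
                merge(decoy_by_seq, decoy)

    for seq in list(decoy_by_seq):
        if seq in target_by_seq:
            del decoy_by_seq[seq]

    all_chains: list[Chain] = []
    for pool in (target_by_seq, decoy_by_seq):
        for chain in pool.values():
            chain.link_sites = find_link_sites(chain, config.allow_nterm_link)
            if chain.link_sites:
                all_chains.append(chain)
    if not all_chains:
        raise ValueError("no linkable chains in database")
    logger.info(
        "chain index: %d chains (%d target, %d decoy)",
        len(all_chains),
        sum(not c.is_decoy for c in all_chains),
        sum(c.is_decoy for c in all_chains),
    )
    return ChainIndex(all_chains)
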