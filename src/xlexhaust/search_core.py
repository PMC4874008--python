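"""Exhaustive cross-linked peptide search.

For every spectrum, every mass-compatible (chain, site) pair is scored with
the normalized cross correlation between the assembled theoretical spectrum
X = X1 + X2 and the unit-normalised experimental spectrum Ỹ:

    score = (X1ᵀỸ + X2ᵀỸ) / ||X||

The additive decomposition lets the engine cache X1ᵀỸ once per
(chain, link site, spectrum) and reuse it across every partner chain, which
is what makes exhaustive enumeration affordable.  The loop structure:

  * outer loop over chains with mass <= half the largest precursor mass, in
    ascending mass order, so each unordered pair is visited exactly once
    with the lighter chain on the outside;
  * per outer chain c, spectra with precursor mass p >= 2c + r - o are
    eligible (r = linker mass, o = per-spectrum absolute tolerance);
  * per spectrum, partner chains lie in the half-open mass window
    [p - o - c - r, p + o - c - r);
  * every (site, site) combination is scored and only the best-scoring
    match per spectrum is kept.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

from .config import SearchConfig  # noqa: F401  (re-exported: part of this surface)
from .fragmentation import LinkedChain, build_half_vector
from .sequence_db import Chain, ChainIndex
from .spectra import ProcessedSpectrum, SpectrumIndex
from .sparse import SparseVector, sparse_add, sparse_dot, norm

logger = logging.getLogger(__name__)


@dataclass
class PSM:
    """Best-scoring cross-linked peptide-spectrum match for one scan."""

    scan_id: str
    alpha: Chain
    site_alpha: int
    beta: Chain
    site_beta: int
    score: float
    psm_class: str = ""   # TT / TD / DD
    topology: str = ""    # intra / inter
    fdr: float = math.nan
    q_value: float = math.nan

    def __post_init__(self) -> None:
        if not self.psm_class:
            self.psm_class = classify_pair(self.alpha.is_decoy, self.beta.is_decoy)
        if not self.topology:
            shared = (self.alpha.target_parent_accessions()
                      & self.beta.target_parent_accessions())
            self.topology = "intra" if shared else "inter"

    def pair_key(self) -> tuple:
        """Unordered (sequence, site) pair identity for redundancy removal."""
        a = (self.alpha.sequence, self.site_alpha)
        b = (self.beta.sequence, self.site_beta)
        return (a, b) if a <= b else (b, a)


def classify_pair(alpha_is_decoy: bool, beta_is_decoy: bool) -> str:
    """TT if both chains are target, DD if both decoy, TD otherwise."""
    if alpha_is_decoy and beta_is_decoy:
        return "DD"
    if alpha_is_decoy or beta_is_decoy:
        return "TD"
    return "TT"


def score_pair(x1: SparseVector, x2: SparseVector,
               spectrum: ProcessedSpectrum) -> float:
    """Decomposed score (X1ᵀỸ + X2ᵀỸ) / ||X1 + X2||."""
    d1 = sparse_dot(x1, spectrum.vector)
    d2 = sparse_dot(x2, spectrum.vector)
    return _score_from_dots(d1, d2, x1, x2)


def _score_from_dots(d1: float, d2: float,
                     x1: SparseVector, x2: SparseVector) -> float:
    nx = norm(sparse_add(x1, x2))
    if nx == 0.0:
        logger.warning("zero theoretical vector; score set to 0")
        return 0.0
    return (d1 + d2) / nx


def direct_score(x1: SparseVector, x2: SparseVector,
                 spectrum: ProcessedSpectrum) -> float:
    """Normalized cross correlation computed on the assembled X (oracle form)."""
    x = sparse_add(x1, x2)
    nx = norm(x)
    if nx == 0.0:
        return 0.0
    return sparse_dot(x, spectrum.vector) / nx


def spectrum_admitted(p: float, o: float, c: float, r: float) -> bool:
    """Eligibility of a spectrum for an outer chain: p >= 2c + r - o."""
    return p >= 2.0 * c + r - o

def partner_mass_window(p: float, o: float, c: float, r: float) -> tuple[float, float]:
    """Half-open partner-chain mass window [p - o - c - r, p + o - c - r)."""
    return (p - o - c - r, p + o - c - r)


def _canonical(chain_a: Chain, site_a: int, chain_b: Chain, site_b: int):
    """Order a pair so alpha is the lighter chain (ties by sequence, site)."""
    ka = (chain_a.neutral_mass, chain_a.sequence, site_a)
    kb = (chain_b.neutral_mass, chain_b.sequence, site_b)
    if ka <= kb:
        return chain_a, site_a, chain_b, site_b
    return chain_b, site_b, chain_a, site_a


class _Best:
    """Per-scan running best with a deterministic tie rule.

    Equal top scores resolve to the lexicographically smallest
    (alpha sequence, beta sequence, alpha site, beta site).
    """

    __slots__ = ("score", "key", "psm_args")

    def __init__(self):
        self.score = -math.inf
        self.key = None
        self.psm_args = None

    def offer(self, score, chain_a, site_a, chain_b, site_b):
        a, sa, b, sb = _canonical(chain_a, site_a, chain_b, site_b)
        key = (a.sequence, b.sequence, sa, sb)
        if score > self.score or (score == self.score and key < self.key):
            self.score = score
            self.key = key
            self.psm_args = (a, sa, b, sb)


def search(chain_index: ChainIndex, spectrum_index: SpectrumIndex,
           config: SearchConfig) -> list[PSM]:
    """Exhaustively score all mass-compatible chain pairs against all spectra.

    Returns one PSM per spectrum that has at least one admissible pair,
    sorted by scan id. The result equals the brute-force maximum of the
    score over every admissible (chain, site, chain, site) combination.
    """
    spectra = spectrum_index.spectra
    max_p = spectrum_index.largest_precursor_mass()
    r = config.linker_mass
    ppm = config.precursor_tol_ppm * 1e-6

    # o, and per-spectrum window bounds, are precomputed once
    p_arr = [s.precursor_neutral_mass for s in spectra]
    o_arr = [p * ppm for p in p_arr]

    best: dict[str, _Best] = {}
    # X·Ỹ and the half-vector are cached per (chain position, site, spectrum
    # position); the same cache serves a chain in the outer and inner role.
    cache: dict[tuple[int, int, int], tuple[SparseVector, float]] = {}

    def half(chain_pos: int, chain: Chain, site: int, spec_pos: int):
        key = (chain_pos, site, spec_pos)
        hit = cache.get(key)
        if hit is None:
            spec = spectra[spec_pos]
            vec = build_half_vector(
                LinkedChain(chain, site), spec.precursor_neutral_mass,
                spec.precursor_charge, config,
            )
            hit = (vec, sparse_dot(vec, spec.vector))
            cache[key] = hit
        return hit

    entries = chain_index.entries
    for a_pos, chain_a in enumerate(entries):
        c = chain_a.neutral_mass
        if c > max_p / 2.0:
            break
        # slightly relaxed sorted-array cut, then the exact per-spectrum test
        lower = (2.0 * c + r) * (1.0 - 2.0 * ppm)
        for s_pos in range(spectrum_index.first_position_at_least(lower),
                           len(spectra)):
            p = p_arr[s_pos]
            o = o_arr[s_pos]
            if not spectrum_admitted(p, o, c, r):
                continue
            lo, hi = partner_mass_window(p, o, c, r)
            start, stop = chain_index.range_bounds(lo, hi)
            start = max(start, a_pos)  # lighter chain is always the outer one
            if start >= stop:
                continue
            spec = spectra[s_pos]
            slot = best.setdefault(spec.scan_id, _Best())
            for b_pos in range(start, stop):
                chain_b = entries[b_pos]
                for site_a in chain_a.link_sites:
                    x1, d1 = half(a_pos, chain_a, site_a, s_pos)
                    for site_b in chain_b.link_sites:
                        x2, d2 = half(b_pos, chain_b, site_b, s_pos)
                        score = _score_from_dots(d1, d2, x1, x2)
                        slot.offer(score, chain_a, site_a, chain_b, site_b)

    psms = [
        PSM(scan_id, slot.psm_args[0], slot.psm_args[1],
            slot.psm_args[2], slot.psm_args[3], slot.score)
        for scan_id, slot in best.items()
        if slot.psm_args is not None
    ]
    psms.sort(key=lambda m: m.scan_id)
    logger.info("search produced %d PSMs from %d spectra", len(psms), len(spectra))
    return psms


def brute_force_search(chains: list[Chain], spectra: list[ProcessedSpectrum],
                       config: SearchConfig) -> list[PSM]:
    """Reference search: enumerate every chain pair and site pair directly.

    Scores through the un-decomposed normalized cross correlation on the
    assembled theoretical vector, with the same admission window and tie
    rule as :func:`search`. Quadratic in the number of chains; for tests.
    """
    r = config.linker_mass
    ppm = config.precursor_tol_ppm * 1e-6
    best: dict[str, _Best] = {}
    for spec in spectra:
        p = spec.precursor_neutral_mass
        o = p * ppm
        slot = _Best()
        for i, chain_a in enumerate(chains):
            for chain_b in chains[i:]:
                total = chain_a.neutral_mass + chain_b.neutral_mass + r
                if not (p - o <= total < p + o):
                    continue
                for site_a in chain_a.link_sites:
                    x1 = build_half_vector(
                        LinkedChain(chain_a, site_a), p,
                        spec.precursor_charge, config,
                    )
                    for site_b in chain_b.link_sites:
                        x2 = build_half_vector(
                            LinkedChain(chain_b, site_b), p,
                            spec.precursor_charge, config,
                        )
                        score = direct_score(x1, x2, spec)
                        slot.offer(score, chain_a, site_a, chain_b, site_b)
        if slot.psm_args is not None:
            best[spec.scan_id] = slot
    psms = [
        PSM(scan_id, slot.psm_args[0], slot.psm_args[1],
            slot.psm_args[2], slot.psm_args[3], slot.score)
        for scan_id, slot in best.items()
    ]
    psms.sort(key=lambda m: m.scan_id)
    return psms


RESULT_COLUMNS = [
    "scan_id", "alpha_sequence", "alpha_site", "beta_sequence", "beta_site",
    "alpha_proteins", "beta_proteins", "score", "class", "topology",
    "fdr", "q_value",
]


def write_results_tsv(psms: list[PSM], path) -> None:
    """Write PSMs as a TSV with one row per scan."""
    with open(path, "w") as fh:
        fh.write("\t".join(RESULT_COLUMNS) + "\n")
        for m in psms:
            row = [
                m.scan_id,
                m.alpha.sequence, str(m.site_alpha),
                m.beta.sequence, str(m.site_beta),
                ";".join(sorted(m.alpha.parent_accessions)),
                ";".join(sorted(m.beta.parent_accessions)),
                repr(m.score),
                m.psm_class,
                m.topology,
                repr(m.fdr),
                repr(m.q_value),
            ]
            fh.write("\t".join(row) + "\n")
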