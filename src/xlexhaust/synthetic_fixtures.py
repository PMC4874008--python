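"""Synthetic databases and spectra with planted cross-linked pairs.

The generator inverts the engine's own fragmentation model: it picks linkable
tryptic chains from a randomly generated protein database, forms a
cross-linked pair, and emits an MGF scan whose peaks sit at every theoretical
linear and cross-linking b/y m/z (signal intensity 100 per ion) plus
uniform-random noise peaks at intensity 1.  Because the noise intensity is a
single repeated value, the modal-intensity de-noising step provably removes
exactly the noise whenever noise peaks outnumber signal peaks — the generator
enforces that by planting short chains at precursor charge 2 when noise is
requested.  A truth manifest records every planted pair for evaluation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import NamedTuple, Sequence

import numpy as np

from .config import SearchConfig
from .constants import PROTON_MONO, mass_to_mz
from .fragmentation import LinkedChain, theoretical_ion_mzs
from .sequence_db import Chain, Protein, digest, find_link_sites, make_decoy
from .spectra import RawSpectrum

logger = logging.getLogger(__name__)

_AA = "ACDEFGHILMNPQSTVWY"  # the 18 non-K/R standard residues


class PlantedPair(NamedTuple):
    seq_alpha: str
    site_alpha: int
    seq_beta: str
    site_beta: int
    charge: int
    noise_peaks: int

    def key(self) -> tuple:
        a = (self.seq_alpha, self.site_alpha)
        b = (self.seq_beta, self.site_beta)
        return (a, b) if a <= b else (b, a)


@dataclass
class PlantedTruth:
    """scan_id -> planted pair manifest."""

    entries: dict[str, PlantedPair]

    def write_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("scan_id\tseq_alpha\tsite_alpha\tseq_beta\tsite_beta"
                     "\tcharge\tnoise_peaks\n")
            for scan_id in sorted(self.entries):
                e = self.entries[scan_id]
                fh.write(f"{scan_id}\t{e.seq_alpha}\t{e.site_alpha}\t"
                         f"{e.seq_beta}\t{e.site_beta}\t{e.charge}\t"
                         f"{e.noise_peaks}\n")

    @classmethod
    def read_tsv(cls, path) -> "PlantedTruth":
        entries: dict[str, PlantedPair] = {}
        with open(path) as fh:
            next(fh)
            for line in fh:
                scan_id, sa, ia, sb, ib, z, npk = line.rstrip("\n").split("\t")
                entries[scan_id] = PlantedPair(sa, int(ia), sb, int(ib),
                                               int(z), int(npk))
        return cls(entries)


def generate_proteins(n_proteins: int, length_range: tuple[int, int],
                      rng: np.random.Generator,
                      k_freq: float = 0.06, r_freq: float = 0.06) -> list[Protein]:
    """Random proteins with K/R enriched (~12 % combined) for tryptic realism."""
    if n_proteins < 0:
        raise ValueError("n_proteins must be >= 0")
    probs = [k_freq, r_freq] + [(1.0 - k_freq - r_freq) / len(_AA)] * len(_AA)
    alphabet = np.array(list("KR" + _AA))
    proteins = []
    for i in range(n_proteins):
        length = int(rng.integers(length_range[0], length_range[1] + 1))
        seq = "".join(rng.choice(alphabet, size=length, p=probs))
        proteins.append(Protein(f"SYN{i + 1:04d}", seq))
    return proteins


def generate_fasta(path, n_proteins: int, length_range: tuple[int, int] = (60, 180),
                   seed: int = 0,
                   extra_sequences: Sequence[tuple[str, str]] = ()) -> list[Protein]:
    """Write a reproducible random FASTA, optionally appending fixed records.

    ``extra_sequences`` are (accession, sequence) pairs appended verbatim,
    e.g. known synthetic peptides planted alongside a background database.
    """
    rng = np.random.default_rng(seed)
    proteins = generate_proteins(n_proteins, length_range, rng)
    proteins += [Protein(acc, seq) for acc, seq in extra_sequences]
    with open(path, "w") as fh:
        for prot in proteins:
            fh.write(f">{prot.accession}\n")
            for start in range(0, len(prot.sequence), 60):
                fh.write(prot.sequence[start:start + 60] + "\n")
    return proteins


def generate_spectrum(linked_alpha: LinkedChain, linked_beta: LinkedChain,
                      charge: int, noise_peaks: int,
                      rng: np.random.Generator, config: SearchConfig,
                      scan_id: str = "scan_0",
                      signal_intensity: float = 100.0,
                      noise_intensity: float = 1.0,
                      hard_noise: bool = False) -> tuple[RawSpectrum, PlantedPair]:
    """One MGF-ready scan of a planted cross-linked pair plus its truth entry.

    Signal peaks sit at the exact theoretical m/z of every linear and
    cross-linking b/y ion of both chains at fragment charges 1..charge-1;
    ions sharing an exact m/z are merged with summed intensity, so the binned
    spectrum is exactly proportional to the theoretical vector. ``hard_noise``
    draws noise intensities from the signal intensity scale instead of the
    fixed quantised floor, defeating the modal filter on purpose.
    """
    if charge < 2:
        raise ValueError("planted precursor charge must be >= 2")
    p = (linked_alpha.chain.neutral_mass + linked_beta.chain.neutral_mass
         + config.linker_mass)
    charges = config.fragment_charges(charge)
    mzs = (theoretical_ion_mzs(linked_alpha, p, charges)
           + theoretical_ion_mzs(linked_beta, p, charges))
    merged: dict[float, float] = {}
    for mz in mzs:
        merged[mz] = merged.get(mz, 0.0) + signal_intensity
    mz_list = list(merged)
    int_list = [merged[mz] for mz in mz_list]
    if noise_peaks:
        hi = max(mz_list) * 1.05
        noise_mz = rng.uniform(100.0, hi, size=noise_peaks)
        if hard_noise:
            noise_int = rng.uniform(0.5, 1.5, size=noise_peaks) * signal_intensity
        else:
            noise_int = np.full(noise_peaks, noise_intensity)
        mz_list = mz_list + noise_mz.tolist()
        int_list = int_list + noise_int.tolist()
    raw = RawSpectrum(
        scan_id=scan_id,
        precursor_mz=mass_to_mz(p, charge),
        precursor_charge=charge,
        mz=np.array(mz_list),
        intensity=np.array(int_list),
    )
    truth = PlantedPair(
        linked_alpha.chain.sequence, linked_alpha.link_site,
        linked_beta.chain.sequence, linked_beta.link_site,
        charge, noise_peaks,
    )
    return raw, truth


def linkable_chains(proteins: list[Protein], config: SearchConfig,
                    max_len: int | None = None,
                    decoys: bool = False) -> list[Chain]:
    """Linkable tryptic chains of the target proteins, optionally decoyed."""
    out: list[Chain] = []
    seen: set[str] = set()
    for protein in proteins:
        for chain in digest(protein, config.max_missed, config.min_len,
                            config.max_len, config.cleave_after,
                            config.no_cleave_before):
            if decoys:
                chain.sequence = make_decoy(chain.sequence)
                chain.is_decoy = True
                chain.link_sites = find_link_sites(chain, config.allow_nterm_link)
            if not chain.link_sites:
                continue
            if max_len is not None and len(chain.sequence) > max_len:
                continue
            if chain.sequence in seen:
                continue
            seen.add(chain.sequence)
            out.append(chain)
    return sorted(out, key=lambda c: c.sequence)


def _collision_free(chain_a: Chain, site_a: int, chain_b: Chain, site_b: int,
                    charge: int, config: SearchConfig) -> bool:
    """True if no two theoretical ions of the pair share an m/z bin."""
    p = chain_a.neutral_mass + chain_b.neutral_mass + config.linker_mass
    charges = config.fragment_charges(charge)
    mzs = (theoretical_ion_mzs(LinkedChain(chain_a, site_a), p, charges)
           + theoretical_ion_mzs(LinkedChain(chain_b, site_b), p, charges))
    bins = [int(mz // config.bin_width) for mz in mzs]
    return len(set(bins)) == len(bins)


def generate_dataset(n_proteins: int, n_spectra: int, seed: int,
                     noise_peaks: int = 0, config: SearchConfig | None = None,
                     charges: Sequence[int] = (2, 3),
                     extra_sequences: Sequence[tuple[str, str]] = (),
                     decoy_fraction: float = 0.0,
                     length_range: tuple[int, int] = (60, 180),
                     ) -> tuple[list[Protein], list[RawSpectrum], PlantedTruth]:
    """A full in-memory fixture: database, planted scans, truth manifest.

    Planted pairs are drawn collision-free: every theoretical ion of the
    pair occupies its own m/z bin, so the planted spectrum is exactly
    proportional to the theoretical vector and its true match scores 1.
    When noise is requested, pairs are drawn from chains of at most 12
    residues at precursor charge 2, which keeps the signal peak count below
    the noise peak count so the modal-intensity filter isolates the signal.
    ``decoy_fraction`` plants that fraction of spectra from decoy-only pairs
    to exercise TD/DD bookkeeping.
    """
    if config is None:
        config = SearchConfig()
    rng = np.random.default_rng(seed)
    proteins = generate_proteins(n_proteins, length_range, rng)
    proteins += [Protein(acc, seq) for acc, seq in extra_sequences]

    noisy = noise_peaks >= 2
    max_len = 12 if noisy else 25
    pool = linkable_chains(proteins, config, max_len=max_len)
    decoy_pool = (linkable_chains(proteins, config, max_len=max_len, decoys=True)
                  if decoy_fraction > 0 else [])
    if len(pool) < 2:
        raise ValueError("database yields too few linkable chains to plant pairs")

    spectra: list[RawSpectrum] = []
    truth_entries: dict[str, PlantedPair] = {}
    for i in range(n_spectra):
        use_decoys = decoy_fraction > 0 and rng.random() < decoy_fraction
        chains = decoy_pool if use_decoys else pool
        charge = 2 if noisy else int(rng.choice(list(charges)))
        for _ in range(1000):
            ia, ib = rng.integers(0, len(chains), size=2)
            chain_a, chain_b = chains[ia], chains[ib]
            n_states = len(config.fragment_charges(charge))
            n_signal = 2 * (len(chain_a.sequence) + len(chain_b.sequence) - 2) * n_states
            if noisy and n_signal >= noise_peaks:
                continue
            site_a = int(rng.choice(chain_a.link_sites))
            site_b = int(rng.choice(chain_b.link_sites))
            if _collision_free(chain_a, site_a, chain_b, site_b, charge, config):
                break
        else:
            raise RuntimeError("could not sample a collision-free pair "
                               "compatible with the noise level")
        scan_id = f"scan_{i:05d}"
        raw, planted = generate_spectrum(
            LinkedChain(chain_a, site_a), LinkedChain(chain_b, site_b),
            charge, noise_peaks, rng, config, scan_id=scan_id,
        )
        spectra.append(raw)
        truth_entries[scan_id] = planted
    return proteins, spectra, PlantedTruth(truth_entries)


def write_mgf(spectra: list[RawSpectrum], path) -> None:
    """Write scans as MGF, with full-precision (round-tripping) floats."""
    with open(path, "w") as fh:
        for spec in spectra:
            fh.write("BEGIN IONS\n")
            fh.write(f"TITLE={spec.scan_id}\n")
            fh.write(f"PEPMASS={spec.precursor_mz!r}\n")
            fh.write(f"CHARGE={spec.precursor_charge}+\n")
            for mz, inten in zip(spec.mz, spec.intensity):
                fh.write(f"{float(mz)!r} {float(inten)!r}\n")
            fh.write("END IONS\n")


def write_mzml(spectra: list[RawSpectrum], path) -> None:
    """Write scans as a plain (non-indexed) mzML 1.1 document.

    Peak arrays are 64-bit floats, base64-encoded without compression, so
    values round-trip exactly through the reader.
    """
    import base64

    def b64(arr):
        return base64.b64encode(
            np.asarray(arr, dtype=np.float64).tobytes()
        ).decode()

    with open(path, "w") as fh:
        fh.write('<?xml version="1.0" encoding="utf-8"?>\n')
        fh.write('<mzML xmlns="http://psi.hupo.org/ms/mzml" version="1.1.0">\n')
        fh.write(f'  <run id="run1">\n    <spectrumList count="{len(spectra)}">\n')
        for i, spec in enumerate(spectra):
            mz_b64 = b64(spec.mz)
            int_b64 = b64(spec.intensity)
            fh.write(
                f'      <spectrum index="{i}" id="{spec.scan_id}" '
                f'defaultArrayLength="{len(spec)}">\n'
                '        <cvParam cvRef="MS" accession="MS:1000511" '
                'name="ms level" value="2"/>\n'
                '        <cvParam cvRef="MS" accession="MS:1000127" '
                'name="centroid spectrum" value=""/>\n'
                '        <precursorList count="1"><precursor>'
                '<selectedIonList count="1"><selectedIon>\n'
                '          <cvParam cvRef="MS" accession="MS:1000744" '
                f'name="selected ion m/z" value="{spec.precursor_mz!r}"/>\n'
                '          <cvParam cvRef="MS" accession="MS:1000041" '
                f'name="charge state" value="{spec.precursor_charge}"/>\n'
                '        </selectedIon></selectedIonList></precursor>'
                '</precursorList>\n'
                '        <binaryDataArrayList count="2">\n'
                f'          <binaryDataArray encodedLength="{len(mz_b64)}">\n'
                '            <cvParam cvRef="MS" accession="MS:1000523" '
                'name="64-bit float" value=""/>\n'
                '            <cvParam cvRef="MS" accession="MS:1000576" '
                'name="no compression" value=""/>\n'
                '            <cvParam cvRef="MS" accession="MS:1000514" '
                'name="m/z array" value=""/>\n'
                f'            <binary>{mz_b64}</binary>\n'
                '          </binaryDataArray>\n'
                f'          <binaryDataArray encodedLength="{len(int_b64)}">\n'
                '            <cvParam cvRef="MS" accession="MS:1000523" '
                'name="64-bit float" value=""/>\n'
                '            <cvParam cvRef="MS" accession="MS:1000576" '
                'name="no compression" value=""/>\n'
                '            <cvParam cvRef="MS" accession="MS:1000515" '
                'name="intensity array" value=""/>\n'
                f'            <binary>{int_b64}</binary>\n'
                '          </binaryDataArray>\n'
                '        </binaryDataArrayList>\n'
                '      </spectrum>\n'
            )
        fh.write('    </spectrumList>\n  </run>\n</mzML>\n')


def evaluate(psms, truth: PlantedTruth) -> dict[str, float]:
    """Recall / precision of search results against the planted truth.

    A planted scan counts as recovered iff its reported (sequence, site)
    pair matches the planted pair, unordered.
    """
    by_scan = {m.scan_id: m for m in psms}
    recovered = 0
    reported_on_truth = 0
    for scan_id, planted in truth.entries.items():
        m = by_scan.get(scan_id)
        if m is None:
            continue
        reported_on_truth += 1
        if m.pair_key() == planted.key():
            recovered += 1
    n_truth = len(truth.entries)
    return {
        "recall": recovered / n_truth if n_truth else 0.0,
        "precision": (recovered / reported_on_truth
                      if reported_on_truth else 0.0),
        "n_truth": float(n_truth),
        "n_recovered": float(recovered),
    }
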