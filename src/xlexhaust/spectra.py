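"""Experimental spectrum handling: reading, de-noising, vectorization, indexing.

Centroided CID MS2 scans are read from MGF or mzML, stripped of their most
frequent ("modal") intensity value — ion-trap noise floors are heavily
quantised, so the most frequent intensity is the noise — then binned into a
sparse unit-norm vector with bin width twice the fragment tolerance.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from collections import Counter

import base64
import zlib

import numpy as np
from lxml import etree
from pyteomics import mgf as _mgf

from .constants import mz_to_neutral_mass
from .sparse import SparseVector, from_bins

logger = logging.getLogger(__name__)


@dataclass
class RawSpectrum:
    """A centroided MS2 scan; peaks are sorted by m/z ascending."""

    scan_id: str
    precursor_mz: float
    precursor_charge: int
    mz: np.ndarray
    intensity: np.ndarray

    def __post_init__(self) -> None:
        self.mz = np.asarray(self.mz, dtype=np.float64)
        self.intensity = np.asarray(self.intensity, dtype=np.float64)
        order = np.argsort(self.mz, kind="stable")
        self.mz = self.mz[order]
        self.intensity = self.intensity[order]

    def __len__(self) -> int:
        return len(self.mz)


@dataclass
class ProcessedSpectrum:
    """A de-noised, binned, unit-normalised spectrum ready for scoring."""

    scan_id: str
    precursor_neutral_mass: float
    precursor_charge: int
    vector: SparseVector


def read_spectra(path, format: str | None = None) -> list[RawSpectrum]:
    """Read MS2 scans from an MGF or mzML file.

    Scans with precursor charge below 2 are skipped (a cross-linked pair
    carries at least two protons), as are scans without a known charge;
    skipped counts are logged.
    """
    fmt = format
    if fmt is None:
        name = str(path).lower()
        fmt = "mzml" if name.endswith((".mzml", ".mzml.gz")) else "mgf"
    if fmt == "mgf":
        spectra = _read_mgf(path)
    elif fmt == "mzml":
        spectra = _read_mzml(path)
    else:
        raise ValueError(f"unknown spectrum format: {fmt}")
    if not spectra:
        logger.warning("no usable MS2 scans in %s", path)
    return spectra


def _read_mgf(path) -> list[RawSpectrum]:
    out: list[RawSpectrum] = []
    skipped_charge = 0
    with _mgf.read(str(path), use_index=False) as reader:
        for i, scan in enumerate(reader):
            params = scan["params"]
            title = str(params.get("title", f"index={i}"))
            charge_list = params.get("charge")
            if not charge_list:
                logger.warning("scan %s has no charge; skipped", title)
                continue
            charge = int(charge_list[0])
            if charge < 2:
                skipped_charge += 1
                continue
            pepmass = params.get("pepmass")
            if pepmass is None:
                logger.warning("scan %s has no precursor m/z; skipped", title)
                continue
            out.append(
                RawSpectrum(
                    scan_id=title,
                    precursor_mz=float(pepmass[0]),
                    precursor_charge=charge,
                    mz=scan["m/z array"],
                    intensity=scan["intensity array"],
                )
            )
    if skipped_charge:
        logger.info("skipped %d scans with precursor charge < 2", skipped_charge)
    return out


# mzML controlled-vocabulary accessions used by the reader
_CV_MS_LEVEL = "MS:1000511"
_CV_SELECTED_MZ = "MS:1000744"
_CV_CHARGE = "MS:1000041"
_CV_MZ_ARRAY = "MS:1000514"
_CV_INTENSITY_ARRAY = "MS:1000515"
_CV_FLOAT64 = "MS:1000523"
_CV_FLOAT32 = "MS:1000521"
_CV_ZLIB = "MS:1000574"


def _decode_binary_array(bda: etree._Element) -> tuple[str | None, np.ndarray]:
    """Decode one <binaryDataArray>: returns (kind, values).

    ``kind`` is "mz", "intensity" or None. Supports 32/64-bit floats with
    or without zlib compression.
    """
    dtype = np.float64
    compressed = False
    kind = None
    for cv in bda.iter("{*}cvParam"):
        acc = cv.get("accession")
        if acc == _CV_FLOAT32:
            dtype = np.float32
        elif acc == _CV_ZLIB:
            compressed = True
        elif acc == _CV_MZ_ARRAY:
            kind = "mz"
        elif acc == _CV_INTENSITY_ARRAY:
            kind = "intensity"
    binary = bda.find("{*}binary")
    text = binary.text if binary is not None else None
    if not text:
        return kind, np.empty(0)
    data = base64.b64decode(text)
    if compressed:
        data = zlib.decompress(data)
    return kind, np.frombuffer(data, dtype=dtype).astype(np.float64)


def _read_mzml(path) -> list[RawSpectrum]:
    """Minimal mzML 1.1 reader (indexed or plain) for centroided MS2 scans.

    Parses only what the search needs: ms level, scan id, selected-ion m/z
    and charge, and the m/z / intensity arrays.
    """
    out: list[RawSpectrum] = []
    skipped_charge = 0
    for _, spectrum in etree.iterparse(str(path), tag="{*}spectrum"):
        params = {
            cv.get("accession"): cv.get("value")
            for cv in spectrum.iter("{*}cvParam")
        }
        if params.get(_CV_MS_LEVEL) != "2":
            spectrum.clear()
            continue
        scan_id = spectrum.get("id", "")
        precursor_mz = None
        charge = None
        for ion in spectrum.iter("{*}selectedIon"):
            for cv in ion.iter("{*}cvParam"):
                if cv.get("accession") == _CV_SELECTED_MZ:
                    precursor_mz = float(cv.get("value"))
                elif cv.get("accession") == _CV_CHARGE:
                    charge = int(cv.get("value"))
        if precursor_mz is None or charge is None:
            logger.warning("scan %s lacks precursor m/z or charge; skipped",
                           scan_id)
            spectrum.clear()
            continue
        if charge < 2:
            skipped_charge += 1
            spectrum.clear()
            continue
        mz_array = intensity_array = None
        for bda in spectrum.iter("{*}binaryDataArray"):
            kind, values = _decode_binary_array(bda)
            if kind == "mz":
                mz_array = values
            elif kind == "intensity":
                intensity_array = values
        spectrum.clear()
        if mz_array is None or intensity_array is None:
            logger.warning("scan %s lacks peak arrays; skipped", scan_id)
            continue
        out.append(
            RawSpectrum(
                scan_id=scan_id,
                precursor_mz=precursor_mz,
                precursor_charge=charge,
                mz=mz_array,
                intensity=intensity_array,
            )
        )
    if skipped_charge:
        logger.info("skipped %d scans with precursor charge < 2", skipped_charge)
    return out


def denoise(spectrum: RawSpectrum) -> RawSpectrum:
    """Remove the peaks whose intensity value occurs most frequently.

    The modal intensity (exact-value mode) is treated as the quantised noise
    floor. Ties at the top frequency remove all tied values. Two guards keep
    the filter from destroying signal in degenerate cases: if every intensity
    is unique there is no mode to speak of and the spectrum is returned
    unchanged; likewise if removal would delete every peak (e.g. a spectrum
    with a single repeated intensity) the spectrum is returned unchanged.
    """
    if len(spectrum) == 0:
        raise ValueError("cannot de-noise an empty spectrum")
    counts = Counter(spectrum.intensity.tolist())
    top = max(counts.values())
    if top <= 1:
        return spectrum
    modal = {value for value, freq in counts.items() if freq == top}
    keep = ~np.isin(spectrum.intensity, list(modal))
    if not keep.any():
        return spectrum
    return RawSpectrum(
        scan_id=spectrum.scan_id,
        precursor_mz=spectrum.precursor_mz,
        precursor_charge=spectrum.precursor_charge,
        mz=spectrum.mz[keep],
        intensity=spectrum.intensity[keep],
    )


def vectorize(spectrum: RawSpectrum, fragment_tol: float,
              sqrt_intensity: bool = False) -> ProcessedSpectrum:
    """Bin a de-noised spectrum and normalise it to unit Euclidean norm.

    Bin width is ``2 * fragment_tol``; a peak at m/z falls in bin
    ``floor(mz / width)`` and co-binned peaks have their intensities summed.
    The precursor neutral mass is ``(precursor_mz - proton) * charge``.
    """
    if len(spectrum) == 0:
        raise ValueError("cannot vectorize an empty spectrum")
    width = 2.0 * fragment_tol
    bins = np.floor(spectrum.mz / width).astype(np.int64)
    weights = spectrum.intensity
    if sqrt_intensity:
        weights = np.sqrt(weights)
    vec = from_bins(bins, weights)
    nrm = math.sqrt(float(np.dot(vec.values, vec.values)))
    if nrm == 0.0:
        raise ValueError(f"spectrum {spectrum.scan_id} has zero total intensity")
    vec = SparseVector(vec.indices, vec.values / nrm)
    return ProcessedSpectrum(
        scan_id=spectrum.scan_id,
        precursor_neutral_mass=mz_to_neutral_mass(
            spectrum.precursor_mz, spectrum.precursor_charge
        ),
        precursor_charge=spectrum.precursor_charge,
        vector=vec,
    )


class SpectrumIndex:
    """Processed spectra sorted by precursor neutral mass."""

    def __init__(self, spectra: list[ProcessedSpectrum]):
        if not spectra:
            raise ValueError("empty spectrum index")
        self.spectra = sorted(
            spectra, key=lambda s: (s.precursor_neutral_mass, s.scan_id)
        )
        self._masses = np.array(
            [s.precursor_neutral_mass for s in self.spectra]
        )

    def __len__(self) -> int:
        return len(self.spectra)

    def first_position_at_least(self, threshold: float) -> int:
        """Position of the first spectrum with precursor mass >= threshold."""
        return int(np.searchsorted(self._masses, threshold, side="left"))

    def query_min_mass(self, threshold: float) -> list[ProcessedSpectrum]:
        """All spectra with precursor mass >= threshold (boundary included)."""
        return self.spectra[self.first_position_at_least(threshold):]

    def largest_precursor_mass(self) -> float:
        return float(self._masses[-1])


def process_spectra(raw: list[RawSpectrum], config) -> list[ProcessedSpectrum]:
    """De-noise and vectorize a batch of raw scans, dropping unusable ones."""
    processed: list[ProcessedSpectrum] = []
    for spectrum in raw:
        if len(spectrum) == 0:
            logger.warning("scan %s is empty; discarded", spectrum.scan_id)
            continue
        cleaned = denoise(spectrum)
        processed.append(
            vectorize(cleaned, config.fragment_tol, config.sqrt_intensity)
        )
    return processed
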