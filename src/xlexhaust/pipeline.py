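"""End-to-end convenience wrappers: files in, confidence-scored PSMs out."""

from __future__ import annotations

import logging
from pathlib import Path

from .config import SearchConfig
from .fdr import assign_confidence, filter_results
from .search_core import PSM, search, write_results_tsv
from .sequence_db import Protein, build_chain_index, read_fasta
from .spectra import RawSpectrum, SpectrumIndex, process_spectra, read_spectra

logger = logging.getLogger(__name__)


def run_pipeline(proteins: list[Protein], raw_spectra: list[RawSpectrum],
                 config: SearchConfig) -> list[PSM]:
    """Index, search, and score confidence on in-memory inputs."""
    chain_index = build_chain_index(proteins, config)
    processed = process_spectra(raw_spectra, config)
    if not processed:
        logger.warning("no usable spectra after preprocessing")
        return []
    spectrum_index = SpectrumIndex(processed)
    psms = search(chain_index, spectrum_index, config)
    assign_confidence(psms)
    return psms


def run_files(fasta_path, spectra_paths, config: SearchConfig, out_dir) -> list[PSM]:
    """Search spectrum files against a FASTA and write result tables.

    Writes ``results.tsv`` (every spectrum's best PSM with FDR/q-value),
    ``accepted.tsv`` (target-target PSMs passing the q cut-off) and
    ``pairs.tsv`` (non-redundant accepted peptide pairs) into ``out_dir``.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    proteins = read_fasta(fasta_path)
    raw: list[RawSpectrum] = []
    for path in spectra_paths:
        raw.extend(read_spectra(path))
    psms = run_pipeline(proteins, raw, config)
    write_results_tsv(psms, out / "results.tsv")
    accepted, pairs = filter_results(psms, config.q_value_threshold)
    write_results_tsv(accepted, out / "accepted.tsv")
    with open(out / "pairs.tsv", "w") as fh:
        fh.write("alpha_sequence\talpha_site\tbeta_sequence\tbeta_site\n")
        for (seq_a, site_a), (seq_b, site_b) in pairs:
            fh.write(f"{seq_a}\t{site_a}\t{seq_b}\t{site_b}\n")
    logger.info("%d PSMs, %d accepted, %d non-redundant pairs",
                len(psms), len(accepted), len(pairs))
    return psms
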