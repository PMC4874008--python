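# xlexhaust

Exhaustive identification of cross-linked peptide pairs from tandem mass
spectra.

Chemical cross-linking mass spectrometry (CX-MS) probes protein–protein
interactions and structural proximity: a bifunctional reagent such as DSS
covalently joins pairs of lysine residues, the linked proteins are digested
with trypsin, and the resulting cross-linked peptide pairs are fragmented by
collision-induced dissociation. Identifying a spectrum then means finding the
*pair* of peptides (with their link sites) that produced it — a search space
quadratic in the peptide database. Most tools prune that space heuristically;
`xlexhaust` searches it exhaustively and exactly, and controls error rates
with a three-class target-decoy estimator.

## Method in brief

Let `Y` be the observed spectrum vectorized on an m/z grid, and `X` the
theoretical spectrum of a candidate pair, split by chain as `X = X1 + X2`.
The score is the normalized cross correlation

    S = XᵀY / (‖X‖ ‖Y‖)  =  (X1ᵀỸ + X2ᵀỸ) / ‖X1 + X2‖,   Ỹ = Y/‖Y‖.

The additive decomposition on the right is what makes exhaustive search
affordable: each chain's dot product `XᵢᵀỸ` against a spectrum is computed
once and reused across every pair that contains that chain. For a pair with
precursor neutral mass `p` and one chain of mass `c`, every fragment that
retains the link site carries the *entire* partner chain and linker, so its
mass is the linear fragment mass shifted by the constant `p − c` — the
theoretical spectrum of a chain is therefore independent of which partner it
is paired with, only `p` matters.

The search enumerates chains in ascending mass order; for each chain it
selects the spectra whose precursor admits it (`p ≥ 2c + r − o`, with linker
mass `r` and per-spectrum tolerance `o`) and the partner chains whose mass
falls in the half-open window `[p − o − c − r, p − o − c − r + 2o)`. Every
mass-compatible (chain, chain, spectrum) triple is scored; the top-scoring
pair per spectrum is reported. Confidence is assigned per topology stratum
(intra- vs inter-protein) with the three-class estimator

    FDR(s) = (#TD(≥s) − #DD(≥s)) / #TT(≥s),    q(t) = min_{s≤t} FDR(s),

where decoys are peptide reversals that fix K/R positions (mass-preserving
and involutive). See [docs/methods.md](docs/methods.md) for the full model,
parameter defaults, and numerical choices.

## Worked example

Simulate a small dataset with planted cross-linked pairs, search it, and
compare against the planted truth:

```sh
xlexhaust simulate --n-proteins 20 --n-spectra 50 --noise-peaks 60 --seed 7 --out demo
xlexhaust search --fasta demo/database.fasta --spectra demo/spectra.mgf --out demo/results
xlexhaust evaluate --results demo/results/results.tsv --truth demo/truth.tsv
```

On this dataset the search builds a 619-chain index (310 target, 309 decoy),
produces one peptide-spectrum match per scan, and recovers every planted
pair:

```
recall      1.0
precision   1.0
n_truth     50.0
n_recovered 50.0
```

`demo/results/results.tsv` holds one row per scan with both sequences, link
sites, parent proteins, score, target/decoy class, topology, and FDR/q-value;
`accepted.tsv` and `pairs.tsv` hold the q ≤ 0.05 subset and the
non-redundant pair list. Spectra may be provided as MGF or mzML. The same
pipeline is available programmatically via `xlexhaust.pipeline.run_files`.

## Layout

- `src/xlexhaust/` — `sequence_db` (FASTA, digestion, decoys, chain index),
  `spectra` (MGF/mzML reading, de-noising, vectorization), `fragmentation`
  (b/y ions, cross-linking classification, mass shifting), `search_core`
  (scoring and the exhaustive double loop), `fdr` (three-class estimator),
  `synthetic_fixtures` (planted-truth simulation), `pipeline`, `cli`.
- `tests/` — unit tests plus `test_acceptance.py` with end-to-end checks.
- `docs/methods.md` — model, parameters, and numerical decisions.
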