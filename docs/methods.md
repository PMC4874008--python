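# Methods

This note records the model implemented by `xlexhaust`, the default
parameters and why they were chosen, what the synthetic-data generator does
and does not emulate, and the numerical decisions that matter for
reproducibility.

## Model

### Peptide chains

Proteins are digested in silico with trypsin rules: cleavage after K or R,
suppressed when the next residue is P, with up to `max_missed` (default 2)
missed cleavages, length `min_len`–`max_len` (default 5–60). Monoisotopic
chain mass is the sum of residue masses plus one water. Cross-link sites are
lysines; a C-terminal lysine is excluded (its side chain would have been
consumed by cleavage) unless the peptide ends the protein. Optionally the
peptide N-terminus can be allowed as a site (`allow_nterm_link`, off by
default).

Decoy chains are built per target peptide by reversing the sequence while
keeping K and R fixed in place. This is an involution (applying it twice
returns the original) and conserves mass exactly, so decoys compete in
precisely the same precursor windows as their targets. Decoy sequences that
collide with a target sequence are dropped.

### Spectra

MGF and mzML files are read; scans with precursor charge < 2 or missing
charge are skipped (a cross-linked pair at charge 1 is not observable in
practice and its fragment-charge set would be empty). Precursor neutral mass
is `p = (m/z − m_proton) · z`.

De-noising removes the modal intensity: the most frequent exact intensity
value (and all values tied with it) is deleted, on the rationale that
electronic noise populates one intensity level far more often than true
fragment peaks do. Guards: if all intensities are distinct the spectrum is
unchanged, and if removal would delete every peak the spectrum is also left
unchanged rather than discarded.

Each spectrum is binned on a grid of width `2 × fragment_tol` (default
1.0 Th) by `bin = floor(mz / width)`, accumulated into a sparse vector, and
normalized to unit Euclidean norm once; that normalized vector `Ỹ` is reused
for every candidate pair.

### Theoretical spectra and the cross-linking shift

For a chain of length `m` linked at residue `k` (1-based), singly-charged
neutral b/y fragment masses are generated for indices 1..m−1. A fragment is
*cross-linking* iff it contains the link site: `b_i` iff `i ≥ k`, `y_j` iff
`j ≥ m − k + 1`. Cross-linking fragments carry the whole partner chain plus
linker, i.e. their mass is the linear mass plus `p − c` where `p` is the
precursor neutral mass and `c` the chain's own mass — by construction
`p − c = partner mass + linker mass` for any mass-compatible partner. Ions
are emitted at fragment charges `1..min(4, z−1)` for precursor charge `z`,
binned on the same grid as the spectrum with intensity equal to ion
multiplicity per bin.

Because the theoretical half-vector of a chain depends only on `(chain, link
site, p, z)` and not on the partner, the dot product `X1ᵀỸ` is cached per
(chain, site, spectrum) and reused across all partners.

### Exhaustive search

Chains are sorted by ascending mass. For each outer chain of mass `c`
(stopping once `c` exceeds half the largest precursor mass), the admitted
spectra are those with `p ≥ 2c + r − o`, where `r` is the linker mass and
`o = p · ppm · 1e−6` the per-spectrum precursor tolerance. For each admitted
spectrum, partner chains are taken from the half-open mass window
`[p − o − c − r, p + o − c − r)` by binary search, restricted to positions at
or after the outer chain so each unordered pair is visited exactly once. All
link-site combinations on both chains are scored with

    S = (X1ᵀỸ + X2ᵀỸ) / ‖X1 + X2‖,

and the best-scoring pair per spectrum is kept. Ties are broken
deterministically by the lexicographically smallest
`(alpha sequence, beta sequence, alpha site, beta site)` after canonical
ordering (alpha = smaller `(mass, sequence, site)`). A brute-force
implementation that enumerates all pairs and scores the assembled vector
directly is kept as a testing oracle.

### Confidence estimation

Each match is classed TT, TD, or DD by its chains' target/decoy status, and
intra-protein vs inter-protein by whether the chains share a (target) parent
protein. Within each topology stratum independently,

    FDR(s) = (#TD(score ≥ s) − #DD(score ≥ s)) / #TT(score ≥ s),

clamped to [0, 1] with FDR = 1 when no TT scores ≥ s, and
`q(t) = min_{s ≤ t} FDR(s)` computed as a running minimum over ascending
scores. The `≥ s` (inclusive) counting convention is used consistently.
Reported identifications are TT matches with `q ≤ q_value_threshold`
(default 0.05), plus a non-redundant list of unordered (sequence, site)
pairs.

## Default parameters

| Parameter | Default | Rationale |
| --- | --- | --- |
| `linker_mass` | 138.06808 | DSS/BS3 monoisotopic cross-linker mass |
| `precursor_tol_ppm` | 10 | typical high-resolution precursor accuracy |
| `fragment_tol` | 0.5 Th | CID ion-trap fragment accuracy; bin width 1.0 |
| `max_missed` | 2 | cross-linked peptides necessarily retain a missed cleavage at the linked lysine |
| `min_len`/`max_len` | 5 / 60 | shorter peptides are uninformative; longer are unobservable |
| `max_fragment_charge` | 4 | fragment charges 1..min(4, z−1) |
| `q_value_threshold` | 0.05 | conventional reporting threshold |

## Synthetic data generator

`synthetic_fixtures` plants ground-truth cross-linked pairs: random proteins
(K and R at 6% each, other residues uniform) are digested, two linkable
chains are drawn, and a spectrum is emitted containing every theoretical
fragment m/z of the pair at intensity 100 plus optional uniform-random noise
peaks at intensity 1, with the precursor mass set exactly to
`m_alpha + m_beta + linker`. Planted pairs are resampled until no two
theoretical ions share a bin ("collision-free"), so a noiseless planted
spectrum scores exactly 1 against its true pair and the modal-intensity
filter removes exactly the noise. Noisy datasets use charge-2 precursors and
chains ≤ 12 residues so the noise level remains the modal intensity. A
truth manifest (TSV) records the planted pair per scan for evaluation
(recall/precision by unordered pair identity).

The generator deliberately does **not** emulate: isotope envelopes, peak
intensity models, fragmentation propensities, co-isolation/chimeric spectra,
post-translational modifications, mono-links or loop-links, or retention
time. It exists to give the engine planted ground truth with known answers,
not to imitate an instrument.

## Numerical decisions

- Peptide masses use `math.fsum` over residue masses, which is correctly
  rounded and therefore permutation-invariant: a decoy's mass equals its
  target's mass *bitwise*, not just approximately.
- Binning is `floor(mz / width)` with width `2 × fragment_tol`; spectrum and
  theory share the grid, so a match requires falling in the same bin.
- The partner-mass window is half-open `[lo, hi)` and spectrum admission is
  inclusive (`p ≥ 2c + r − o`); both are covered by tests built from exactly
  binary-representable boundary values.
- Sparse vectors store sorted unique int64 bin indices with float64 values;
  dot products use a two-pointer merge, and all scores are accumulated and
  returned as Python floats.
- All randomness flows through `numpy.random.default_rng` with explicit
  seeds; repeated runs produce byte-identical result tables (floats are
  written with `repr`, which round-trips).
- Scoring with the cached `X1ᵀỸ` values is bit-identical to fresh
  recomputation (asserted in tests), and agrees with the directly computed
  normalized cross correlation to < 1e-12 (the residual is pure
  floating-point reassociation).

## Problem sizes used in testing

Oracle comparisons run on 10 proteins × 20 spectra (≈60+ chains); planted
recovery on 20 × 30; the calibration check on 40 proteins with 100 planted
plus 100 pure-noise spectra, pooled over three seeds; the determinism/scale
check on 100 proteins × 1000 spectra (≈15 s). These sizes were chosen to
exercise the quadratic pair loop meaningfully while keeping the full suite
under a minute.

## Limitations

- Only lysine–lysine amine-reactive linkers (e.g. DSS/BS3) with a single
  fixed mass; no cleavable linkers, mono-links, or loop-links.
- Only b/y ions; no neutral losses, a-ions, or immonium ions.
- One match per spectrum (rank 1 only); no rescoring or machine-learned
  post-processing.
- The modal-intensity de-noising is a simple heuristic aimed at flat
  electronic noise; profile-mode or highly structured noise should be
  centroided/cleaned upstream.
- The mzML reader supports plain and zlib-compressed 32/64-bit float binary
  arrays; vendor-specific compression schemes are not handled.
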