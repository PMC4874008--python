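"""Search configuration shared across the engine."""

from __future__ import annotations

from dataclasses import dataclass


@dataclass
class SearchConfig:
    """Parameters of a cross-linked peptide search.

    Attributes
    ----------
    linker_mass:
        Mass added by the cross-linker to the peptide pair (Da). The default
        is DSS/BS3, the common amine-reactive non-cleavable linker.
    precursor_tol_ppm:
        Precursor mass tolerance in parts per million; converted to an
        absolute tolerance ``o = p * ppm * 1e-6`` per spectrum.
    fragment_tol:
        Fragment (tandem) mass tolerance in Da. Spectrum vectors are binned
        with width ``2 * fragment_tol``.
    max_missed:
        Maximum number of missed tryptic cleavages per chain.
    min_len, max_len:
        Chain length bounds (residues) retained after digestion.
    max_fragment_charge:
        Cap on fragment charge; fragments are generated at charges
        1..min(cap, precursor_charge - 1), minimum 1.
    q_value_threshold:
        q-value cut-off applied to target-target identifications.
    allow_nterm_link:
        Whether a protein N-terminal amine counts as a linkable site.
    generate_decoys:
        Build a decoy chain per target chain (reversal with K/R fixed).
    sqrt_intensity:
        Apply a square-root transform to experimental intensities before
        normalisation (off by default: raw intensities are used).
    cleave_after, no_cleave_before:
        Enzyme rule; the default is trypsin (cut C-terminal to K/R, never
        before P).
    """

    linker_mass: float = 138.06808
    precursor_tol_ppm: float = 10.0
    fragment_tol: float = 0.5
    max_missed: int = 2
    min_len: int = 5
    max_len: int = 60
    max_fragment_charge: int = 4
    q_value_threshold: float = 0.05
    allow_nterm_link: bool = False
    generate_decoys: bool = True
    sqrt_intensity: bool = False
    cleave_after: str = "KR"
    no_cleave_before: str = "P"

    def __post_init__(self) -> None:
        if self.linker_mass <= 0:
            raise ValueError("linker_mass must be positive")
        if self.precursor_tol_ppm <= 0 or self.fragment_tol <= 0:
            raise ValueError("tolerances must be positive")
        if self.max_missed < 0:
            raise ValueError("max_missed must be non-negative")
        if not (1 <= self.min_len <= self.max_len):
            raise ValueError("need 1 <= min_len <= max_len")

    @property
    def bin_width(self) -> float:
        """Bin width of the sparse spectrum vectors (Da per bin)."""
        return 2.0 * self.fragment_tol

    def precursor_tol(self, precursor_neutral_mass: float) -> float:
        """Absolute precursor tolerance o at the given precursor mass (Da)."""
        return precursor_neutral_mass * self.precursor_tol_ppm * 1e-6

    def fragment_charges(self, precursor_charge: int) -> range:
        """Fragment charge states considered for a precursor of this charge."""
        top = max(1, min(self.max_fragment_charge, precursor_charge - 1))
        return range(1, top + 1)
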