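"""Three-class target-decoy FDR and q-value estimation."""

import numpy as np
import pytest

from xlexhaust.fdr import (
    assign_confidence, classify_psm, estimate_fdr, fdr_to_qvalue,
    filter_results,
)
from xlexhaust.search_core import PSM, classify_pair
from xlexhaust.sequence_db import Chain
from xlexhaust.constants import peptide_mass


def _chain(seq="AAKAA", decoy=False, parents=("P1",)):
    return Chain(seq, peptide_mass(seq), (3,), 0, decoy, frozenset(parents))


def _psm(score, cls, topology="inter", scan_id=None):
    decoy_a = cls in ("DD",)
    decoy_b = cls in ("DD", "TD")
    m = PSM(
        scan_id or f"s{score}",
        _chain("AAKAA", decoy_a), 3,
        _chain("EEKEE", decoy_b), 3,
        score,
    )
    m.topology = topology
    assert m.psm_class == cls
    return m


HAND_EXAMPLE = [
    _psm(0.9, "TT"), _psm(0.8, "TD"), _psm(0.7, "TT"),
    _psm(0.6, "TD"), _psm(0.5, "DD"),
]


class TestClassify:
    def test_three_classes(self):
        assert classify_pair(False, False) == "TT"
        assert classify_pair(True, True) == "DD"
        assert classify_pair(False, True) == "TD"
        assert classify_pair(True, False) == "TD"
        assert classify_psm(_psm(0.5, "TD")) == "TD"


class TestEstimateFdr:
    def test_hand_example(self):
        fdr = estimate_fdr(HAND_EXAMPLE)
        assert fdr[0.9] == 0.0
        assert fdr[0.8] == 1.0
        assert fdr[0.7] == 0.5
        assert fdr[0.6] == 1.0
        assert fdr[0.5] == 0.5

    def test_all_target_gives_zero(self):
        fdr = estimate_fdr([_psm(s, "TT") for s in (0.2, 0.5, 0.9)])
        assert all(v == 0.0 for v in fdr.values())

    def test_negative_estimate_clamped(self):
        # more decoy-decoy than target-decoy at the top: f - d < 0 -> 0
        fdr = estimate_fdr([_psm(0.9, "DD"), _psm(0.5, "TT")])
        assert fdr[0.5] == 0.0

    def test_no_target_above_threshold_gives_one(self):
        fdr = estimate_fdr([_psm(0.9, "TD"), _psm(0.5, "TT")])
        assert fdr[0.9] == 1.0

    def test_empty_stratum(self):
        assert estimate_fdr([], topology_filter="intra") == {}


class TestQValues:
    def test_hand_example(self):
        q = fdr_to_qvalue(estimate_fdr(HAND_EXAMPLE))
        assert q[0.9] == 0.0
        assert q[0.8] == q[0.7] == q[0.6] == q[0.5] == 0.5

    def test_q_below_fdr_and_monotone_random(self, rng):
        for _ in range(1000):
            n = int(rng.integers(2, 30))
            psms = [
                _psm(float(rng.uniform()), str(rng.choice(["TT", "TD", "DD"])),
                     scan_id=f"r{i}")
                for i, _ in enumerate(range(n))
            ]
            if not any(m.psm_class == "TT" for m in psms):
                psms.append(_psm(0.5, "TT", scan_id="pad"))
            fdr = estimate_fdr(psms)
            q = fdr_to_qvalue(fdr)
            scores = sorted(q)
            for s in scores:
                assert q[s] <= fdr[s]
            qs = [q[s] for s in scores]
            assert all(a >= b for a, b in zip(qs, qs[1:]))

    def test_constant_fdr_map(self):
        q = fdr_to_qvalue({0.1: 0.3, 0.5: 0.3, 0.9: 0.3})
        assert set(q.values()) == {0.3}


class TestFilterResults:
    def _scored(self):
        psms = [
            _psm(0.9, "TT", scan_id="a"), _psm(0.8, "TD", scan_id="b"),
            _psm(0.7, "TT", scan_id="c"), _psm(0.6, "TD", scan_id="d"),
            _psm(0.5, "DD", scan_id="e"),
        ]
        assign_confidence(psms)
        return psms

    def test_hand_example_threshold(self):
        accepted, pairs = filter_results(self._scored(), 0.05)
        assert [m.scan_id for m in accepted] == ["a"]
        assert len(pairs) == 1

    def test_threshold_one_accepts_all_tt(self):
        accepted, _ = filter_results(self._scored(), 1.0)
        assert sorted(m.scan_id for m in accepted) == ["a", "c"]

    def test_decoys_never_reported(self):
        accepted, _ = filter_results(self._scored(), 1.0)
        assert all(m.psm_class == "TT" for m in accepted)

    def test_duplicate_pair_deduplicated(self):
        psms = [_psm(0.9, "TT", scan_id="a"), _psm(0.9, "TT", scan_id="b")]
        assign_confidence(psms)
        accepted, pairs = filter_results(psms, 0.05)
        assert len(accepted) == 2 and len(pairs) == 1


class TestCalibration:
    def test_empirical_fdp_controlled_on_mixed_fixture(self):
        """Among PSMs accepted at q <= 0.05 on a mix of planted-pair spectra
        and pure-noise spectra, the realised false-discovery proportion
        stays within the estimator's expected range (loose bound: 0.10,
        pooled over three simulations)."""
        from xlexhaust.config import SearchConfig
        from xlexhaust.constants import mass_to_mz
        from xlexhaust.pipeline import run_pipeline
        from xlexhaust.spectra import RawSpectrum
        from xlexhaust.synthetic_fixtures import (
            generate_dataset, linkable_chains,
        )

        cfg = SearchConfig()
        total_accepted = total_false = 0
        for seed in (1, 2, 3):
            rng = np.random.default_rng(seed + 100)
            proteins, spectra, truth = generate_dataset(
                40, 100, seed=seed, noise_peaks=50, config=cfg)
            pool = linkable_chains(proteins, cfg)
            for i in range(100):
                a, b = rng.choice(len(pool), 2)
                p = (pool[a].neutral_mass + pool[b].neutral_mass
                     + cfg.linker_mass)
                mz = rng.uniform(100, 2000, 80)
                inten = rng.uniform(2, 200, 80)
                spectra.append(RawSpectrum(
                    f"rand_{i:04d}", mass_to_mz(p, 2), 2, mz, inten))
            psms = run_pipeline(proteins, spectra, cfg)
            accepted, _ = filter_results(psms, cfg.q_value_threshold)
            total_accepted += len(accepted)
            for m in accepted:
                planted = truth.entries.get(m.scan_id)
                if planted is None or m.pair_key() != planted.key():
                    total_false += 1
        assert total_accepted > 0
        assert total_false / total_accepted <= 0.10


class TestStratumIndependence:
    def test_intra_qvalues_ignore_inter_psms(self):
        intra = [_psm(0.9, "TT", "intra", "i1"), _psm(0.4, "TD", "intra", "i2")]
        inter_a = [_psm(0.8, "TD", "inter", "j1")]
        inter_b = [_psm(0.95, "DD", "inter", "j1"), _psm(0.2, "TT", "inter", "j2")]
        first = [
            _psm(m.score, m.psm_class, m.topology, m.scan_id)
            for m in intra
        ] + inter_a
        second = [
            _psm(m.score, m.psm_class, m.topology, m.scan_id)
            for m in intra
        ] + inter_b
        assign_confidence(first)
        assign_confidence(second)
        q_first = {m.scan_id: m.q_value for m in first if m.topology == "intra"}
        q_second = {m.scan_id: m.q_value for m in second if m.topology == "intra"}
        assert q_first == q_second
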