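"""Search engine: sparse scoring, window semantics, exhaustive double loop."""

import numpy as np
import pytest

from xlexhaust.config import SearchConfig
from xlexhaust.constants import peptide_mass
from xlexhaust.fragmentation import LinkedChain, build_half_vector
from xlexhaust.search_core import (
    brute_force_search, direct_score, partner_mass_window, score_pair,
    search, spectrum_admitted, write_results_tsv,
)
from xlexhaust.sequence_db import Chain, ChainIndex, build_chain_index
from xlexhaust.sparse import SparseVector, from_bins, norm, sparse_add, sparse_dot
from xlexhaust.spectra import ProcessedSpectrum, SpectrumIndex, process_spectra
from xlexhaust.synthetic_fixtures import generate_dataset


def _vec(pairs):
    idx = sorted(pairs)
    return SparseVector(np.array(idx), np.array([pairs[i] for i in idx], float))


def _random_sparse(rng, n_max=60, value_scale=5.0):
    n = int(rng.integers(1, n_max))
    idx = rng.choice(2000, size=n, replace=False)
    vals = rng.uniform(0.1, value_scale, size=n)
    return _vec(dict(zip(idx.tolist(), vals.tolist())))


def _spectrum(vec, p=2000.0, charge=3, scan_id="s"):
    unit = SparseVector(vec.indices, vec.values / norm(vec))
    return ProcessedSpectrum(scan_id, p, charge, unit)


class TestSparseDot:
    def test_arithmetic(self):
        assert sparse_dot(_vec({1: 1, 3: 2}), _vec({3: 4, 5: 1})) == 8

    def test_disjoint_supports(self):
        assert sparse_dot(_vec({1: 1}), _vec({2: 1})) == 0.0

    def test_equals_dense_dot(self, rng):
        for _ in range(1000):
            a = _random_sparse(rng)
            b = _random_sparse(rng)
            da = np.zeros(2000)
            db = np.zeros(2000)
            da[a.indices] = a.values
            db[b.indices] = b.values
            assert sparse_dot(a, b) == pytest.approx(float(da @ db), abs=1e-9)


class TestScorePair:
    def test_self_match_scores_one(self, rng):
        x1 = _random_sparse(rng)
        x2 = _random_sparse(rng)
        spec = _spectrum(sparse_add(x1, x2))
        assert score_pair(x1, x2, spec) == pytest.approx(1.0, abs=1e-12)

    def test_orthogonal_scores_zero(self):
        x1 = _vec({1: 1.0})
        x2 = _vec({2: 1.0})
        spec = _spectrum(_vec({10: 1.0}))
        assert score_pair(x1, x2, spec) == 0.0

    def test_decomposition_equals_direct_form(self, rng):
        for _ in range(1000):
            x1 = _random_sparse(rng)
            x2 = _random_sparse(rng)
            spec = _spectrum(_random_sparse(rng))
            assert abs(score_pair(x1, x2, spec)
                       - direct_score(x1, x2, spec)) < 1e-12

    def test_symmetry_and_bounds(self, rng):
        for _ in range(100):
            x1 = _random_sparse(rng)
            x2 = _random_sparse(rng)
            spec = _spectrum(_random_sparse(rng))
            s12 = score_pair(x1, x2, spec)
            s21 = score_pair(x2, x1, spec)
            assert s12 == s21
            assert 0.0 <= s12 <= 1.0 + 1e-12


class TestWindowSemantics:
    # exact binary-float boundary construction: p=1024, o=1 (ppm chosen so
    # o = p * 2**-10), r=24
    PPM = 2.0 ** -10 * 1e6
    P, O, R = 1024.0, 1.0, 24.0

    def test_partner_window_half_open(self):
        c = 499.5
        lo, hi = partner_mass_window(self.P, self.O, c, self.R)
        assert lo == 499.5 and hi == 501.5
        # pair mass p - o admitted, pair mass p + o excluded
        assert lo <= 499.5 < hi          # total = p - o
        assert not (lo <= 501.5 < hi)    # total = p + o

    def test_spectrum_admission_boundary_inclusive(self):
        c = 500.5
        assert 2 * c + self.R - self.O == self.P
        assert spectrum_admitted(self.P, self.O, c, self.R)
        assert not spectrum_admitted(
            np.nextafter(self.P, 0.0), self.O, c, self.R)

    def _run(self, partner_mass):
        config = SearchConfig(linker_mass=self.R, precursor_tol_ppm=self.PPM,
                              min_len=1)
        outer = Chain("AAKAA", 499.5, (3,), 0, False, frozenset({"P1"}))
        inner = Chain("AVKVA", partner_mass, (3,), 0, False, frozenset({"P2"}))
        index = ChainIndex([outer, inner])
        spec = _spectrum(_vec({5: 1.0}), p=self.P, charge=2)
        return search(index, SpectrumIndex([spec]), config)

    def test_end_to_end_pair_at_lower_edge_admitted(self):
        # total mass = p - o exactly
        psms = self._run(self.P - self.O - 499.5 - self.R)
        assert len(psms) == 1

    def test_end_to_end_pair_at_upper_edge_excluded(self):
        # total mass = p + o exactly: half-open window rejects it
        psms = self._run(self.P + self.O - 499.5 - self.R)
        assert psms == [] or all(
            m.beta.sequence != "AVKVA" for m in psms)


@pytest.fixture(scope="module")
def fixture10():
    config = SearchConfig()
    proteins, raw, truth = generate_dataset(
        10, 20, seed=11, noise_peaks=60, config=config)
    index = build_chain_index(proteins, config)
    spectra = process_spectra(raw, config)
    return config, index, spectra, truth


class TestSearch:
    def test_matches_brute_force_oracle(self, fixture10):
        config, index, spectra, _ = fixture10
        fast = search(index, SpectrumIndex(spectra), config)
        slow = brute_force_search(index.entries, spectra, config)
        assert len(fast) == len(slow) > 0
        for a, b in zip(fast, slow):
            assert a.scan_id == b.scan_id
            assert a.pair_key() == b.pair_key()
            assert abs(a.score - b.score) < 1e-12

    def test_repeat_run_identical(self, fixture10, tmp_path):
        config, index, spectra, _ = fixture10
        p1, p2 = tmp_path / "a.tsv", tmp_path / "b.tsv"
        write_results_tsv(search(index, SpectrumIndex(spectra), config), p1)
        write_results_tsv(search(index, SpectrumIndex(spectra), config), p2)
        assert p1.read_bytes() == p2.read_bytes()

    def test_classes_and_topology_assigned(self, fixture10):
        config, index, spectra, _ = fixture10
        psms = search(index, SpectrumIndex(spectra), config)
        assert {m.psm_class for m in psms} <= {"TT", "TD", "DD"}
        assert {m.topology for m in psms} <= {"intra", "inter"}

    def test_brute_force_empty_chain_list(self, fixture10):
        config, _, spectra, _ = fixture10
        assert brute_force_search([], spectra, config) == []

    def test_cached_scores_bit_identical_to_fresh_recomputation(self, fixture10):
        # the X1·Y cache must not change a single bit of any reported score
        config, index, spectra, _ = fixture10
        by_scan = {s.scan_id: s for s in spectra}
        for m in search(index, SpectrumIndex(spectra), config):
            spec = by_scan[m.scan_id]
            x1 = build_half_vector(
                LinkedChain(m.alpha, m.site_alpha),
                spec.precursor_neutral_mass, spec.precursor_charge, config)
            x2 = build_half_vector(
                LinkedChain(m.beta, m.site_beta),
                spec.precursor_neutral_mass, spec.precursor_charge, config)
            assert score_pair(x1, x2, spec) == m.score

    def test_homodimeric_self_pairing_allowed(self):
        config = SearchConfig()
        chain = Chain("AAKAAVLA", peptide_mass("AAKAAVLA"), (3,), 0, False,
                      frozenset({"P1"}))
        p = 2 * chain.neutral_mass + config.linker_mass
        x = build_half_vector(LinkedChain(chain, 3), p, 3, config)
        spec = _spectrum(sparse_add(x, x), p=p, charge=3, scan_id="homo")
        psms = search(ChainIndex([chain]), SpectrumIndex([spec]), config)
        assert len(psms) == 1
        assert psms[0].alpha.sequence == psms[0].beta.sequence == "AAKAAVLA"
        assert psms[0].score == pytest.approx(1.0, abs=1e-9)
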