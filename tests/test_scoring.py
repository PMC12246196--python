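import itertools

import numpy as np
import pytest

from glycoscreen.chemcore import Adduct
from glycoscreen.glycolib import SimulatedLibraryEntry
from glycoscreen.msio import PeakSpectrum
from glycoscreen.scoring import (
    MatchResult,
    ScoringConfig,
    assign_candidate,
    call_products,
    cosine_greedy,
    exclude_controls,
)
from glycoscreen.specproc import Feature

from conftest import random_spectrum


def optimal_matching_score(q_mz, q_int, r_mz, r_int, tol=0.15):
    """Independent oracle: maximum-weight one-to-one peak matching by
    exhaustive enumeration (viable only for tiny spectra)."""
    q_w = np.asarray(q_int, float) / max(q_int)
    r_w = np.asarray(r_int, float) / max(r_int)

    def best(qi, used_r):
        if qi == len(q_mz):
            return 0.0
        score = best(qi + 1, used_r)  # leave peak qi unmatched
        for ri in range(len(r_mz)):
            if ri not in used_r and abs(q_mz[qi] - r_mz[ri]) <= tol:
                score = max(
                    score, q_w[qi] * r_w[ri] + best(qi + 1, used_r | {ri})
                )
        return score

    norm = np.sqrt((q_w**2).sum()) * np.sqrt((r_w**2).sum())
    return best(0, frozenset()) / norm


class TestCosineGreedy:
    def test_identical_spectra_score_one(self):
        mz = np.array([100.0, 150.0, 200.0])
        inten = np.array([1.0, 0.5, 0.2])
        score, n = cosine_greedy(mz, inten, mz, inten)
        assert score == pytest.approx(1.0)
        assert n == 3

    def test_disjoint_spectra_score_zero(self):
        score, n = cosine_greedy(
            np.array([100.0]), np.array([1.0]), np.array([200.0]), np.array([1.0])
        )
        assert (score, n) == (0.0, 0)

    def test_hand_worked_partial_match(self):
        # single pair (100.00, 100.05) within 0.15 Da: 1.0 / (1.25) = 0.8
        score, n = cosine_greedy(
            np.array([100.00, 200.00]), np.array([1.0, 0.5]),
            np.array([100.05, 300.00]), np.array([1.0, 0.5]),
        )
        assert score == pytest.approx(0.8)
        assert n == 1

    def test_empty_input(self):
        assert cosine_greedy(
            np.array([]), np.array([]), np.array([100.0]), np.array([1.0])
        ) == (0.0, 0)

    def test_symmetry_and_bounds_fuzzed(self):
        rng = np.random.default_rng(5)
        for _ in range(200):
            a_mz, a_int = random_spectrum(rng, int(rng.integers(1, 20)))
            b_mz, b_int = random_spectrum(rng, int(rng.integers(1, 20)))
            s_ab, n_ab = cosine_greedy(a_mz, a_int, b_mz, b_int)
            s_ba, n_ba = cosine_greedy(b_mz, b_int, a_mz, a_int)
            assert s_ab == pytest.approx(s_ba, abs=1e-12)
            assert n_ab == n_ba
            assert 0.0 <= s_ab <= 1.0

    def test_greedy_never_exceeds_optimal_matching(self):
        rng = np.random.default_rng(17)
        for _ in range(500):
            n_q, n_r = rng.integers(1, 7, size=2)
            q_mz, q_int = random_spectrum(rng, int(n_q), mz_range=(100.0, 102.0))
            r_mz, r_int = random_spectrum(rng, int(n_r), mz_range=(100.0, 102.0))
            greedy, _ = cosine_greedy(q_mz, q_int, r_mz, r_int)
            optimal = optimal_matching_score(q_mz, q_int, r_mz, r_int)
            assert greedy <= optimal + 1e-12

    def test_agrees_with_matchms_reference_implementation(self):
        matchms = pytest.importorskip("matchms")
        from matchms.similarity import CosineGreedy as MatchmsCosineGreedy

        rng = np.random.default_rng(23)
        oracle = MatchmsCosineGreedy(tolerance=0.15, mz_power=0.0, intensity_power=1.0)
        for _ in range(100):
            a_mz, a_int = random_spectrum(rng, int(rng.integers(2, 40)))
            b_mz, b_int = random_spectrum(rng, int(rng.integers(2, 40)))
            ours, n_ours = cosine_greedy(a_mz, a_int, b_mz, b_int)
            sa = matchms.Spectrum(
                mz=a_mz, intensities=a_int, metadata_harmonization=False
            )
            sb = matchms.Spectrum(
                mz=b_mz, intensities=b_int, metadata_harmonization=False
            )
            res = oracle.pair(sa, sb)
            assert ours == pytest.approx(float(res["score"]), abs=1e-6)
            assert n_ours == int(res["matches"])

    def test_top_k_truncation(self):
        # 60 identical-intensity peaks: only the 50 lowest-m/z survive on each
        # side, so a reference shifted beyond them shares exactly 40 peaks
        config = ScoringConfig(top_k_peaks=50)
        mz = np.arange(100.0, 160.0)
        inten = np.ones(60)
        score, n = cosine_greedy(mz, inten, mz + 10.0, inten, config)
        assert n == 40


def _entry(compound_id, degree, adduct_label, expected, mz, inten, entry_id=None):
    return SimulatedLibraryEntry(
        entry_id=entry_id or f"{compound_id}|k{degree}|{adduct_label}",
        compound_id=compound_id,
        source_record_id="R",
        degree=degree,
        adduct=Adduct(adduct_label, 1, 1.00728),
        expected_precursor_mz=expected,
        reference_mz=np.asarray(mz, float),
        reference_intensity=np.asarray(inten, float),
    )


def _feature(precursor, mz, inten, rt=1.0, scan_id="s1"):
    spec = PeakSpectrum(
        mz=mz, intensity=inten, level=2, precursor_mz=precursor,
        retention_time=rt, scan_id=scan_id,
    )
    return Feature(
        run_id="r", scan_id=scan_id, precursor_mz=precursor, retention_time=rt,
        spectrum=spec, matched_target=("F", 1, "[M+H]+"), target_mz=precursor,
    )


class TestAssignCandidate:
    def test_good_match_assigned(self):
        entry = _entry("F", 1, "[M+H]+", 431.1342, [100.0, 150.0], [1.0, 0.5])
        feature = _feature(431.1340, [100.0, 150.0], [1.0, 0.5])
        match = assign_candidate(feature, [entry])
        assert match is not None
        assert match.cosine_score == pytest.approx(1.0)
        assert match.entry.compound_id == "F"

    def test_storage_cutoff_is_strict(self):
        # orthogonal-ish spectra engineered to score exactly 0.5:
        # one of two equal peaks matches -> 0.5/ (1*1)... use 2x2 construction
        entry = _entry("F", 1, "[M+H]+", 431.1342, [100.0, 200.0], [1.0, 1.0])
        feature = _feature(431.1342, [100.0, 300.0], [1.0, 1.0])
        match_raw, _ = cosine_greedy(
            feature.spectrum.mz, feature.spectrum.intensity,
            entry.reference_mz, entry.reference_intensity,
        )
        assert match_raw == pytest.approx(0.5)
        assert assign_candidate(feature, [entry]) is None

    def test_no_candidate_within_ppm(self):
        entry = _entry("F", 1, "[M+H]+", 500.0, [100.0], [1.0])
        feature = _feature(431.1342, [100.0], [1.0])
        assert assign_candidate(feature, [entry]) is None

    def test_best_of_multiple_candidates_wins(self):
        near = _entry("F", 1, "[M+H]+", 431.1342, [100.0, 150.0], [1.0, 0.5])
        far = _entry("G", 1, "[M+H]+", 431.1345, [400.0], [1.0])
        feature = _feature(431.1342, [100.0, 150.0], [1.0, 0.5])
        match = assign_candidate(feature, [far, near])
        assert match.entry.compound_id == "F"


class TestCallProducts:
    def _matches(self, scores):
        out = []
        for i, s in enumerate(scores):
            entry = _entry("F", 1, "[M+H]+", 431.1342, [100.0], [1.0])
            out.append(
                MatchResult(_feature(431.1342, [100.0], [1.0], scan_id=f"s{i}"),
                            entry, s, 1, 0.5)
            )
        return out

    def test_threshold_boundary_is_inclusive(self):
        calls = call_products(self._matches([0.84, 0.85, 0.96]), threshold=0.85)
        assert len(calls) == 2

    def test_zero_threshold_calls_everything(self):
        assert len(call_products(self._matches([0.6, 0.7]), threshold=0.0)) == 2

    def test_empty(self):
        assert call_products([], threshold=0.85) == []

    def test_monotone_in_threshold(self):
        matches = self._matches([0.5, 0.76, 0.81, 0.86, 0.91, 0.99])
        counts = [
            len(call_products(matches, threshold=t))
            for t in (0.75, 0.80, 0.85, 0.90)
        ]
        assert counts == sorted(counts, reverse=True)


class TestExcludeControls:
    def _call(self, compound_id, degree=1, mix="mix1", enzyme="E1"):
        return call_products(
            [MatchResult(
                _feature(431.1342, [100.0], [1.0]),
                _entry(compound_id, degree, "[M+H]+", 431.1342, [100.0], [1.0]),
                0.9, 1, 0.5)],
            threshold=0.85, enzyme=enzyme, mix=mix,
        )[0]

    def test_control_product_removed_everywhere_in_mix(self):
        calls = [self._call("S7", enzyme="E1"), self._call("S7", enzyme="E2"),
                 self._call("S8")]
        controls = [self._call("S7", enzyme="GFP")]
        kept, report = exclude_controls(calls, controls)
        assert [c.compound_id for c in kept] == ["S8"]
        assert report.n_removed_control == 2

    def test_control_in_other_mix_not_removed(self):
        calls = [self._call("S7", mix="mix2")]
        controls = [self._call("S7", mix="mix1")]
        kept, _ = exclude_controls(calls, controls)
        assert len(kept) == 1

    def test_blacklist_removes_compound(self):
        calls = [self._call("tryptamine"), self._call("S8")]
        kept, report = exclude_controls(calls, [], {"tryptamine"})
        assert [c.compound_id for c in kept] == ["S8"]
        assert report.n_removed_blacklist == 1

    def test_identity_with_no_controls(self):
        calls = [self._call("S8")]
        kept, report = exclude_controls(calls, [], [])
        assert kept == calls
        assert report.n_removed_control == report.n_removed_blacklist == 0
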