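import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from pyteomics import mass as pt_mass

from glycoscreen.chemcore import (
    Adduct,
    CompoundRecord,
    FEATURE_ADDUCTS,
    GlycoShift,
    HEXOSE_SHIFT,
    Pool,
    PoolingConfig,
    PoolingInfeasibleError,
    expected_precursor_mz,
    glycoside_neutral_mass,
    make_inclusion_list,
    pool_compounds,
    ppm_window,
    reaction_grid,
)

MH = Adduct("[M+H]+", 1, 1.00728)

# formononetin: elemental-summation oracle for the worked mass example
FORMONONETIN = pt_mass.calculate_mass(formula="C16H12O4")


class TestGlycosideMass:
    def test_formononetin_monoglucoside(self):
        assert FORMONONETIN == pytest.approx(268.0736, abs=1e-4)
        assert glycoside_neutral_mass(268.0736, 1) == pytest.approx(430.1269, abs=1e-4)

    def test_degree_zero_is_identity(self):
        assert glycoside_neutral_mass(268.0736, 0) == 268.0736

    def test_double_shift_is_twice_single(self):
        shift = GlycoShift()
        assert shift.delta(2) == pytest.approx(2 * shift.delta(1))
        assert shift.delta(2) == pytest.approx(324.1066, abs=1e-9)
        assert HEXOSE_SHIFT == 162.0533

    def test_unsupported_degree_raises(self):
        with pytest.raises(ValueError, match="degree"):
            glycoside_neutral_mass(268.0736, 3)

    @given(st.floats(min_value=50, max_value=2000))
    @settings(derandomize=True)
    def test_degree_difference_is_exactly_one_unit(self, m):
        assert glycoside_neutral_mass(m, 2) - glycoside_neutral_mass(m, 1) == (
            pytest.approx(HEXOSE_SHIFT, abs=1e-9)
        )


class TestPrecursorMz:
    def test_protonated_glycoside(self):
        assert expected_precursor_mz(430.1269, MH) == pytest.approx(431.1342, abs=1e-4)

    def test_doubly_charged(self):
        assert expected_precursor_mz(100.0, Adduct("[M+2H]2+", 2, 2.01456)) == (
            pytest.approx(51.00728)
        )

    def test_sodiated(self):
        assert expected_precursor_mz(430.1269, Adduct("[M+Na]+", 1, 22.98922)) == (
            pytest.approx(453.1161, abs=1e-4)
        )

    @given(st.floats(min_value=51, max_value=2000), st.floats(min_value=50, max_value=2000))
    @settings(derandomize=True)
    def test_strictly_increasing_in_mass(self, m1, m2):
        for adduct in FEATURE_ADDUCTS:
            lo, hi = sorted([m1, m2])
            if hi > lo:
                assert expected_precursor_mz(hi, adduct) > expected_precursor_mz(lo, adduct)


class TestPpmWindow:
    def test_fifty_ppm_halfwidth(self):
        lo, hi = ppm_window(431.1342, 50)
        assert hi - lo == pytest.approx(2 * 431.1342 * 50e-6)
        assert lo < 431.1342 < hi

    def test_zero_width(self):
        assert ppm_window(431.1342, 0) == (431.1342, 431.1342)

    def test_degenerate_large_ppm(self):
        assert ppm_window(100.0, 1e6) == (0.0, 200.0)


def _compounds(masses):
    return [
        CompoundRecord(f"S{i}", f"compound {i}", float(m))
        for i, m in enumerate(masses)
    ]


class TestPooling:
    def test_study_sized_library_gives_twelve_pools(self):
        comps = _compounds(np.linspace(150.0, 800.0, 453))
        pools = pool_compounds(comps, PoolingConfig(capacity=40, min_separation=0.01))
        assert len(pools) == 12
        assert sum(len(p.members) for p in pools) == 453

    def test_single_pool_when_everything_fits(self):
        comps = _compounds(np.linspace(200, 600, 40))
        assert len(pool_compounds(comps, PoolingConfig(capacity=40))) == 1

    def test_separation_forces_split(self):
        comps = _compounds([100.000, 100.003])
        pools = pool_compounds(comps, PoolingConfig(capacity=40, min_separation=0.006))
        assert len(pools) == 2

    def test_infeasible_when_pool_budget_exhausted(self):
        # three identical masses need three pools; a budget of two must fail
        comps = _compounds([100.0, 100.0, 100.0, 300.0])
        with pytest.raises(PoolingInfeasibleError, match="100.0"):
            pool_compounds(
                comps, PoolingConfig(capacity=2, min_separation=0.01, max_pools=2)
            )
        # unbounded escalation resolves the same input via singleton pools
        pools = pool_compounds(comps, PoolingConfig(capacity=2, min_separation=0.01))
        assert len(pools) == 3

    @given(
        st.lists(
            st.floats(min_value=150, max_value=800),
            min_size=1,
            max_size=60,
            unique=True,
        ),
        st.integers(min_value=1, max_value=40),
    )
    @settings(derandomize=True, max_examples=60, deadline=None)
    def test_cover_disjoint_separation(self, masses, capacity):
        config = PoolingConfig(capacity=capacity, min_separation=0.01)
        comps = _compounds(masses)
        try:
            pools = pool_compounds(comps, config)
        except PoolingInfeasibleError:
            return
        seen = [cid for p in pools for cid in p.members]
        assert sorted(seen) == sorted(c.compound_id for c in comps)
        assert len(seen) == len(set(seen))
        by_id = {c.compound_id: c.neutral_mass for c in comps}
        for p in pools:
            assert len(p.members) <= capacity
            ms = sorted(by_id[c] for c in p.members)
            assert all(b - a >= 0.01 for a, b in zip(ms, ms[1:]))
        assert len(pools) >= math.ceil(len(comps) / capacity)


class TestInclusionList:
    def test_entry_count_and_sorting(self):
        comps = {c.compound_id: c for c in _compounds(np.linspace(200, 600, 40))}
        pool = Pool("mix1", list(comps), 40, 0.01)
        entries = make_inclusion_list(pool, comps)
        assert len(entries) == 40 * 2 * len(FEATURE_ADDUCTS)
        mzs = [e[3] for e in entries]
        assert mzs == sorted(mzs)

    def test_contains_expected_product_ion(self):
        comp = CompoundRecord("F", "formononetin", 268.0736)
        pool = Pool("mix1", ["F"], 40, 0.01)
        entries = make_inclusion_list(pool, {"F": comp})
        match = [e for e in entries if e[1] == 1 and e[2] == "[M+H]+"]
        assert match[0][3] == pytest.approx(431.1342, abs=1e-4)

    def test_empty_adducts(self):
        comp = CompoundRecord("F", "formononetin", 268.0736)
        pool = Pool("mix1", ["F"], 40, 0.01)
        assert make_inclusion_list(pool, {"F": comp}, adducts=()) == []

    def test_unknown_member_raises(self):
        pool = Pool("mix1", ["nope"], 40, 0.01)
        with pytest.raises(KeyError):
            make_inclusion_list(pool, {})


@pytest.mark.parametrize(
    "n_enzymes,n_substrates,n_pools,expected",
    [(85, 453, 12, (38505, 1020)), (1, 0, 0, (0, 0)), (2, 80, 2, (160, 4))],
)
def test_reaction_grid(n_enzymes, n_substrates, n_pools, expected):
    assert reaction_grid(n_enzymes, n_substrates, n_pools) == expected
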