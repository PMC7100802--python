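"""Signal-model correctness: closed forms, propagation oracle, invariants."""

import math

import numpy as np
import pytest

import _oracles
from despotsim.exceptions import (
    DegenerateInputError,
    InvalidParameterError,
)
from despotsim.signal_model import (
    PARAM_NAMES,
    SignalVector,
    TissueParams,
    bssfp_two_pool,
    forward_signals,
    normalize,
    spgr_single_pool,
    spgr_two_pool,
)


from hypothesis import given, settings
from hypothesis import strategies as st


class TestTissueParams:
    @settings(derandomize=True, max_examples=50)
    @given(
        mwf=st.floats(min_value=0.0, max_value=0.999),
        kfs=st.floats(min_value=0.0, max_value=100.0),
    )
    def test_detailed_balance_holds(self, mwf, kfs):
        t = TissueParams(t1f=0.45, t1s=1.4, t2f=0.015, t2s=0.09, mwf=mwf, kfs=kfs)
        lhs = t.kfs * t.mwf
        rhs = t.ksf * (1.0 - t.mwf)
        # one rounding step in ksf = kfs*mwf/(1-mwf): equal to ~1 ulp
        assert abs(lhs - rhs) <= 2e-16 * max(lhs, 1.0)
        assert TissueParams(
            t1f=0.45, t1s=1.4, t2f=0.015, t2s=0.09, mwf=0.0, kfs=kfs
        ).ksf == 0.0

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"t1f": -0.1},
            {"t2f": 0.0},
            {"t2f": 0.5},  # exceeds t1f
            {"mwf": 1.0},
            {"mwf": -0.01},
            {"kfs": -1.0},
        ],
    )
    def test_invalid_parameters_rejected(self, kwargs):
        base = dict(t1f=0.45, t1s=1.4, t2f=0.015, t2s=0.09, mwf=0.15, kfs=8.0)
        base.update(kwargs)
        with pytest.raises(InvalidParameterError):
            TissueParams(**base)

    def test_array_round_trip(self, hb):
        assert TissueParams.from_array(hb.to_array()) == hb


class TestSpgrSinglePool:
    def test_zero_flip_angle_gives_zero_signal(self):
        sv = spgr_single_pool(1.0, 1.0, [0.0, 10.0], 6.5e-3)
        assert sv.values[0] == 0.0

    def test_matches_ernst_closed_form(self):
        fa = np.arange(2, 21, 2.0)
        sv = spgr_single_pool(1.0, 1.0, fa, 6.5e-3)
        expected = _oracles.ernst_spgr(1.0, 1.0, fa, 6.5e-3)
        np.testing.assert_allclose(sv.values, expected, rtol=1e-12)

    def test_signal_maximized_at_ernst_angle(self):
        t1, tr = 1.0, 6.5e-3
        grid = np.linspace(0.1, 30.0, 2000)
        sv = spgr_single_pool(t1, 1.0, grid, tr)
        ernst = math.degrees(math.acos(math.exp(-tr / t1)))
        assert abs(grid[np.argmax(sv.values)] - ernst) < 0.05

    def test_nonpositive_t1_or_tr_rejected(self):
        with pytest.raises(InvalidParameterError):
            spgr_single_pool(0.0, 1.0, [10.0], 6.5e-3)
        with pytest.raises(InvalidParameterError):
            spgr_single_pool(1.0, 1.0, [10.0], -1e-3)


class TestTwoPoolReductions:
    """Degenerate two-pool inputs must collapse to the single-pool forms."""

    def test_empty_fast_pool_spgr(self, s1):
        t = TissueParams(t1f=0.3, t1s=1.2, t2f=0.01, t2s=0.08, mwf=0.0, kfs=5.0)
        two = spgr_two_pool(t, s1.fa_spgr, s1.tr_spgr)
        one = spgr_single_pool(1.2, 1.0, s1.fa_spgr, s1.tr_spgr)
        np.testing.assert_allclose(two.values, one.values, rtol=1e-10)

    def test_indistinguishable_pools_spgr(self, s1):
        t = TissueParams(t1f=1.2, t1s=1.2, t2f=0.08, t2s=0.08, mwf=0.3, kfs=0.0)
        two = spgr_two_pool(t, s1.fa_spgr, s1.tr_spgr)
        one = spgr_single_pool(1.2, 1.0, s1.fa_spgr, s1.tr_spgr)
        np.testing.assert_allclose(two.values, one.values, rtol=1e-10)

    def test_empty_fast_pool_bssfp_matches_closed_form(self):
        t1, t2, tr = 1.0, 0.1, 6.5e-3
        t = TissueParams(t1f=0.3, t1s=t1, t2f=0.01, t2s=t2, mwf=0.0, kfs=0.0)
        fa = [2, 6, 14, 22, 30, 38, 46, 54, 62, 70]
        sv = bssfp_two_pool(t, fa, tr, math.pi)
        expected = _oracles.bssfp_single_pool_closed_form(t1, t2, 1.0, fa, tr)
        np.testing.assert_allclose(sv.values, expected, rtol=1e-10)

    def test_zero_flip_angle_bssfp(self, hb):
        sv = bssfp_two_pool(hb, [0.0], 6.5e-3, math.pi)
        assert sv.values[0] == pytest.approx(0.0, abs=1e-15)


class TestPropagationOracle:
    """Closed-form steady states vs 5000-TR discrete propagation."""

    @pytest.mark.parametrize("tissue_name", ["HB", "WML", "INT", "GML"])
    @pytest.mark.parametrize("scheme_name", ["S1", "S2", "S3"])
    def test_all_tissues_and_schemes(self, tissues, schemes, tissue_name, scheme_name):
        tissue = tissues[tissue_name]
        scheme = schemes[scheme_name]
        spgr = spgr_two_pool(tissue, scheme.fa_spgr, scheme.tr_spgr)
        ref = _oracles.propagate_spgr(tissue, scheme.fa_spgr, scheme.tr_spgr)
        np.testing.assert_allclose(spgr.values, ref, rtol=1e-8)
        for fa_list, phase in (
            (scheme.fa_bssfp180, math.pi),
            (scheme.fa_bssfp0, 0.0),
        ):
            if not fa_list:
                continue
            model = bssfp_two_pool(tissue, fa_list, scheme.tr_ssfp, phase)
            ref = _oracles.propagate_bssfp(tissue, fa_list, scheme.tr_ssfp, phase)
            np.testing.assert_allclose(model.values, ref, rtol=1e-8)


class TestSignalProperties:
    def test_continuity_under_tiny_perturbations(self, tissues, s1):
        """Perturbing any parameter by 1e-9 moves no signal by >1e-6 relative."""
        for tissue in tissues.values():
            base = forward_signals(tissue, s1).values
            for name in PARAM_NAMES:
                bumped = tissue.with_(**{name: getattr(tissue, name) + 1e-9})
                pert = forward_signals(bumped, s1).values
                assert np.max(np.abs(pert - base) / base) < 1e-6

    def test_passband_shift_symmetry(self, hb, s1):
        """bSSFP180 on-resonance equals bSSFP0 at delta_f = 1/(2 TR)."""
        tr = s1.tr_ssfp
        shifted = hb.with_(delta_f=1.0 / (2.0 * tr))
        s180 = bssfp_two_pool(hb, s1.fa_bssfp180, tr, math.pi)
        s0 = bssfp_two_pool(shifted, s1.fa_bssfp180, tr, 0.0)
        np.testing.assert_allclose(s180.values, s0.values, rtol=1e-10)


class TestForwardSignals:
    @pytest.mark.parametrize(
        "scheme_name,total,blocks",
        [("S1", 30, (10, 10, 10)), ("S2", 24, (8, 8, 8)), ("S3", 14, (6, 6, 2))],
    )
    def test_scheme_block_structure(self, schemes, hb, scheme_name, total, blocks):
        sv = forward_signals(hb, schemes[scheme_name])
        assert len(sv) == total
        for tag, n in zip(("SPGR", "bSSFP180", "bSSFP0"), blocks):
            assert int(sv.mask(tag).sum()) == n

    def test_empty_bssfp0_block(self, hb, s1):
        from despotsim.study_config import AcquisitionScheme

        scheme = AcquisitionScheme(
            tr_spgr=s1.tr_spgr, tr_ssfp=s1.tr_ssfp,
            fa_spgr=s1.fa_spgr, fa_bssfp180=s1.fa_bssfp180, fa_bssfp0=(),
        )
        sv = forward_signals(hb, scheme)
        assert len(sv) == 20
        assert set(sv.sequences) == {"SPGR", "bSSFP180"}


class TestNormalize:
    def test_group_means_are_one(self, hb, s1):
        sv = normalize(forward_signals(hb, s1))
        assert sv.normalized
        for tag in ("SPGR",):
            assert sv.values[sv.mask(tag)].mean() == pytest.approx(1.0, abs=1e-14)
        pooled = sv.values[sv.mask("bSSFP180", "bSSFP0")]
        assert pooled.mean() == pytest.approx(1.0, abs=1e-14)

    def test_per_sequence_grouping(self, hb, s1):
        sv = normalize(forward_signals(hb, s1), grouping="per_sequence")
        for tag in ("SPGR", "bSSFP180", "bSSFP0"):
            assert sv.values[sv.mask(tag)].mean() == pytest.approx(1.0, abs=1e-14)

    @settings(derandomize=True, max_examples=50)
    @given(
        values=st.lists(
            st.floats(min_value=1e-6, max_value=1e6), min_size=4, max_size=12
        )
    )
    def test_group_means_one_for_arbitrary_positive_vectors(self, values):
        half = len(values) // 2
        sv = SignalVector(
            values=values,
            sequences=("SPGR",) * half + ("bSSFP180",) * (len(values) - half),
            flip_angles_deg=np.arange(len(values), dtype=float) + 1,
        )
        out = normalize(sv)
        for tag in ("SPGR", "bSSFP180"):
            assert out.values[out.mask(tag)].mean() == pytest.approx(1.0, rel=1e-12)

    def test_constant_block_maps_to_ones(self):
        sv = SignalVector(
            values=[3.0, 3.0, 3.0, 5.0, 5.0],
            sequences=("SPGR",) * 3 + ("bSSFP180",) * 2,
            flip_angles_deg=[2, 4, 6, 10, 20],
        )
        out = normalize(sv)
        np.testing.assert_allclose(out.values, 1.0)

    def test_idempotence(self, hb, s1):
        once = normalize(forward_signals(hb, s1))
        twice = normalize(once)
        np.testing.assert_allclose(once.values, twice.values, rtol=1e-14)

    def test_zero_group_mean_rejected(self):
        sv = SignalVector(
            values=[0.0, 0.0, 1.0],
            sequences=("SPGR", "SPGR", "bSSFP180"),
            flip_angles_deg=[2, 4, 10],
        )
        with pytest.raises(DegenerateInputError):
            normalize(sv)

    def test_csv_round_trip(self, hb, s1, tmp_path):
        sv = forward_signals(hb, s1)
        path = tmp_path / "signals.csv"
        sv.to_csv(path)
        back = SignalVector.from_csv(path)
        np.testing.assert_allclose(back.values, sv.values)
        assert back.sequences == sv.sequences
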