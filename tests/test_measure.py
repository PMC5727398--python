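"""Measurement operators: PF counting, moire, layer lines, lattice typing."""

import math

import numpy as np
import pytest
from scipy import stats

from mtarch.grid import DensityGrid
from mtarch.lattice import LatticeSpec, skew_from_moire
from mtarch.measure import (
    ArchitectureCall,
    LowerBound,
    MeasurementError,
    call_lattice_type,
    classify_pf_number,
    compare_repeats,
    estimate_skew,
    measure_axial_repeat,
    measure_moire,
    summarize,
)
from mtarch.synth import build_lattice, decorate, render, transverse_sections


def _sections(spec, length=70.0, snr=math.inf, seed=None, decorated=False):
    lat = build_lattice(spec, length)
    if decorated:
        lat = decorate(lat)
    vol = render(lat, mode="volume", snr=snr, seed=seed)
    return transverse_sections(vol, 4.0, 4.0)


class TestClassifyPfNumber:
    @pytest.mark.parametrize("n_pf", [11, 12, 13, 14, 15])
    def test_recovers_pf_number_at_snr2(self, n_pf):
        secs = _sections(LatticeSpec(n_pf=n_pf, skew_deg=-0.4), snr=2, seed=n_pf)
        n, conf = classify_pf_number(secs)
        assert n == n_pf
        assert conf >= 1.5

    def test_featureless_noise_is_undetermined(self, rng):
        secs = [
            DensityGrid(rng.normal(size=(101, 101)).astype(np.float32),
                        0.35, "yx")
            for _ in range(10)
        ]
        n, conf = classify_pf_number(secs)
        assert n is None

    def test_requires_sections(self):
        with pytest.raises(ValueError):
            classify_pf_number([])


class TestMeasureMoire:
    def test_skew_1deg_period(self, projection_skew1):
        moire = measure_moire(projection_skew1)
        assert moire == pytest.approx(295.0, abs=5.0)

    def test_straight_pfs_give_lower_bound(self, straight_projection):
        result = measure_moire(straight_projection)
        assert isinstance(result, LowerBound)
        assert result.box_nm >= 400.0

    def test_gmpcpp_regime_short_moire(self):
        """The very short ~100 nm repeat regime is recovered."""
        theta = skew_from_moire(100.0, "left")
        proj = render(build_lattice(LatticeSpec(skew_deg=theta), 400.0))
        assert measure_moire(proj) == pytest.approx(100.0, rel=0.05)

    def test_empty_image_is_an_error(self):
        empty = DensityGrid(np.zeros((600, 80), dtype=np.float32), 0.35, "zy")
        with pytest.raises(MeasurementError):
            measure_moire(empty)

    def test_consistent_with_skew_estimate(self, projection_skew1,
                                           decorated_b_volume):
        """Inverting the measured moire gives the directly estimated skew."""
        moire = measure_moire(projection_skew1)
        assert skew_from_moire(moire, "right") == pytest.approx(1.0, abs=0.05)
        proj_04 = render(build_lattice(LatticeSpec(skew_deg=-0.4), 1800.0))
        moire_04 = measure_moire(proj_04)
        theta_proj = skew_from_moire(moire_04, "left")
        theta_vol = estimate_skew(decorated_b_volume)
        assert theta_proj == pytest.approx(theta_vol, abs=0.05)


class TestMeasureAxialRepeat:
    @pytest.mark.parametrize("dimer_nm", [8.326, 8.291, 8.144])
    def test_recovers_generated_spacing(self, dimer_nm):
        spec = LatticeSpec(monomer_rise=dimer_nm / 2,
                           lateral_rise=3 * dimer_nm / 2 / 13)
        proj = render(decorate(build_lattice(spec, 55 * dimer_nm)))
        measured = measure_axial_repeat(proj)
        assert abs(measured - dimer_nm) * 10 < 0.05  # Angstrom

    def test_uniform_image_is_an_error(self):
        flat = DensityGrid(np.ones((800, 60), dtype=np.float32), 0.35, "zy")
        with pytest.raises(MeasurementError):
            measure_axial_repeat(flat)

    def test_no_dimer_contrast_is_an_error(self):
        """Undecorated tubes with identical monomers have no 8 nm line."""
        proj = render(build_lattice(LatticeSpec(), 400.0))
        with pytest.raises(MeasurementError):
            measure_axial_repeat(proj)


class TestEstimateSkew:
    @pytest.mark.parametrize(
        "skew", [-0.4, 0.0, 0.888]
    )
    def test_recovers_generated_skew(self, skew):
        spec = LatticeSpec(n_pf=12 if skew > 0 else 13, skew_deg=skew)
        vol = render(build_lattice(spec, 70.0), mode="volume")
        assert estimate_skew(vol) == pytest.approx(skew, abs=0.05)

    def test_needs_enough_sections(self):
        vol = render(build_lattice(LatticeSpec(), 35.0), mode="volume")
        short = DensityGrid(vol.values[:80], vol.pixel_nm, "zyx")
        with pytest.raises(ValueError):
            estimate_skew(short)


class TestCallLatticeType:
    def test_single_seam_b_lattice(self, decorated_b_volume):
        assert call_lattice_type(decorated_b_volume) == "B"

    def test_all_a_lattice(self):
        lat = decorate(build_lattice(LatticeSpec.all_a(skew_deg=-0.4), 70.0))
        assert call_lattice_type(render(lat, mode="volume")) == "A"

    def test_multi_seam_is_mixed(self):
        spec = LatticeSpec(skew_deg=-0.4, seam_interfaces=(2, 6, 10))
        lat = decorate(build_lattice(spec, 70.0))
        assert call_lattice_type(render(lat, mode="volume")) == "mixed"

    def test_undecorated_is_undetermined(self):
        vol = render(build_lattice(LatticeSpec(skew_deg=-0.4), 70.0),
                     mode="volume")
        assert call_lattice_type(vol) == "undetermined"


class TestSummarize:
    def _calls(self, counts):
        calls = []
        for n_pf, count in counts.items():
            for _ in range(count):
                calls.append(("cond", ArchitectureCall(pf_number=n_pf)))
        return calls

    def test_table_mixture_percentages(self):
        summary = summarize(self._calls({12: 2, 13: 21, 14: 2}))
        table = summary.table.set_index("pf_number")
        assert table.loc[13, "percent"] == 84
        assert table.loc[12, "percent"] == 8
        assert table.loc[14, "percent"] == 8

    def test_single_call_is_100_percent(self):
        summary = summarize([("c", ArchitectureCall(pf_number=13))])
        assert summary.table["percent"].tolist() == [100]

    def test_empty_is_an_error(self):
        with pytest.raises(ValueError):
            summarize([])

    @pytest.mark.parametrize(
        "counts", [{13: 3}, {12: 1, 13: 1, 14: 1}, {11: 2, 13: 5, 15: 6},
                   {11: 1, 12: 1, 13: 1, 14: 1, 15: 3}]
    )
    def test_percentages_sum_to_100(self, counts):
        summary = summarize(self._calls(counts))
        assert abs(summary.table["percent"].sum() - 100) <= 1

    def test_moire_range_formats_lower_bounds(self):
        calls = [
            ("c", ArchitectureCall(pf_number=13, moire_nm=210.0)),
            ("c", ArchitectureCall(pf_number=13, moire_nm=LowerBound(1000.0))),
        ]
        assert summarize(calls).table["moire_range_nm"].iloc[0] == "210->1000"

    def test_repeat_stats_group_means(self):
        vals = [8.32, 8.33, 8.34, 8.35, 8.36, 8.37]
        calls = [("c", ArchitectureCall(pf_number=13, axial_repeat_nm=v))
                 for v in vals]
        stats_ = summarize(calls, n_groups=3).repeat_stats["c"]
        groups = [np.mean(vals[g::3]) for g in range(3)]
        assert stats_["mean_nm"] == pytest.approx(np.mean(groups))
        assert stats_["sd_nm"] == pytest.approx(np.std(groups, ddof=1))


class TestCompareRepeats:
    def test_matches_welch_reference_formula(self):
        """Independent oracle: Welch's statistic computed from the textbook
        formulas."""
        a = [83.25, 83.27, 83.26, 83.29]
        b = [83.29, 83.31, 83.28, 83.33, 83.30]
        res = compare_repeats(a, b)
        ma, mb = np.mean(a), np.mean(b)
        va, vb = np.var(a, ddof=1), np.var(b, ddof=1)
        se2 = va / len(a) + vb / len(b)
        t_ref = (ma - mb) / math.sqrt(se2)
        df_ref = se2**2 / (
            (va / len(a)) ** 2 / (len(a) - 1) + (vb / len(b)) ** 2 / (len(b) - 1)
        )
        p_ref = 2 * stats.t.sf(abs(t_ref), df_ref)
        assert res.t == pytest.approx(t_ref, rel=1e-12)
        assert res.df == pytest.approx(df_ref, rel=1e-12)
        assert res.p == pytest.approx(p_ref, rel=1e-12)

    def test_null_p_values_are_uniform(self, rng):
        """Resampling oracle: under exchangeability p is uniform."""
        ps = []
        for _ in range(400):
            x = rng.normal(83.0, 0.05, size=12)
            ps.append(compare_repeats(list(x[:6]), list(x[6:])).p)
        ps = np.asarray(ps)
        assert abs(np.mean(ps) - 0.5) < 0.05
        assert abs(np.mean(ps < 0.2) - 0.2) < 0.06

    def test_zero_variance_equal_means(self):
        res = compare_repeats([8.3, 8.3], [8.3, 8.3])
        assert res.p == 1.0 and res.t == 0.0 and res.degenerate

    def test_zero_variance_unequal_means(self):
        res = compare_repeats([8.3, 8.3], [8.2, 8.2])
        assert res.p == 0.0 and math.isinf(res.t) and res.degenerate

    def test_needs_two_values_per_group(self):
        with pytest.raises(ValueError):
            compare_repeats([8.3], [8.2, 8.25])
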