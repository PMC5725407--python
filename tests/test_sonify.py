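"""Regional averaging and the triple-tone frequency mapping."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from tritone.errors import (
    EmptyRegionError,
    FrequencyCollapseError,
    ParameterError,
    ReferenceError_,
)
from tritone.io_voxels import SliceGrid
from tritone.preprocess import Region
from tritone.sonify import (
    DETUNE_FACTORS,
    RegionStats,
    TTSParams,
    compute_region_stats,
    region_average,
    relative_deviation,
    severity_to_detune,
    sonification_report,
    tts_frequencies,
)


def stats(av_fl=100.0, av_pl=100.0, av_smc=100.0):
    return RegionStats(av_FL=av_fl, av_PL=av_pl, av_SMC=av_smc,
                       n_FL=10, n_PL=10, n_SMC=10)


class TestRegionAverage:
    def labelled_grid(self, values, mask=None):
        labels = np.zeros(values.shape, dtype=np.int8)
        labels[:2, :] = Region.FRONTAL
        grid = SliceGrid(values=values, mask=mask)
        return grid, labels

    def test_constant_region(self):
        values = np.full((4, 5), 100, dtype=int)
        grid, labels = self.labelled_grid(values)
        mean, count = region_average(grid, labels, Region.FRONTAL)
        assert (mean, count) == (100.0, 10)

    def test_two_value_region(self):
        values = np.zeros((4, 2), dtype=int)
        values[0, :] = 80
        values[1, :] = 120
        grid, labels = self.labelled_grid(values)
        mean, _ = region_average(grid, labels, Region.FRONTAL)
        assert mean == 100.0

    def test_masked_pixels_excluded(self):
        values = np.zeros((4, 2), dtype=int)
        values[:2, :] = [[10, 10], [500, 500]]
        mask = values >= 100
        grid, labels = self.labelled_grid(values, mask=mask)
        mean, count = region_average(grid, labels, Region.FRONTAL)
        assert (mean, count) == (500.0, 2)

    def test_brute_force_oracle(self, rng):
        values = rng.integers(0, 32768, size=(30, 40))
        labels = rng.integers(0, 4, size=(30, 40)).astype(np.int8)
        mask = rng.random((30, 40)) > 0.3
        grid = SliceGrid(values=values, mask=mask)
        for region in (Region.FRONTAL, Region.PARIETAL, Region.SENSORIMOTOR):
            total = n = 0
            for i in range(30):
                for j in range(40):
                    if labels[i, j] == region and mask[i, j]:
                        total += int(values[i, j])
                        n += 1
            mean, count = region_average(grid, labels, region)
            assert count == n
            assert mean == pytest.approx(total / n, rel=0, abs=0)

    def test_empty_region_error_names_region(self):
        values = np.zeros((4, 2), dtype=int)
        grid, labels = self.labelled_grid(values, mask=np.zeros((4, 2), bool))
        with pytest.raises(EmptyRegionError, match="FRONTAL"):
            region_average(grid, labels, Region.FRONTAL)


class TestRelativeDeviation:
    @pytest.mark.parametrize(
        "av, smc, expected",
        [(100, 100, 0.0), (75, 100, 0.25), (125, 100, 0.25)],
    )
    def test_values(self, av, smc, expected):
        assert relative_deviation(av, smc) == expected

    @pytest.mark.parametrize("smc", [0.0, -5.0])
    def test_nonpositive_reference(self, smc):
        with pytest.raises(ReferenceError_):
            relative_deviation(50.0, smc)


class TestSeverityTable:
    @pytest.mark.parametrize(
        "severity, df",
        [("normal", 0.05), ("mild", 0.10), ("moderate", 0.15), ("severe", 0.20)],
    )
    def test_detune_table(self, severity, df):
        assert severity_to_detune(severity) == df

    def test_unknown_severity(self):
        with pytest.raises(ParameterError, match="very severe"):
            severity_to_detune("very severe")


class TestTTSFrequencies:
    def test_zero_deviation_gives_three_440s(self):
        tones = tts_frequencies(stats(), TTSParams(severity="normal"))
        assert tones.frequencies == (440.0, 440.0, 440.0)
        assert tones.beat_rate_FL == tones.beat_rate_PL == 0.0

    def test_frontal_hand_evaluation(self):
        # DF 0.20, av_FL 75 vs SMC 100: delta 0.25, f_FL = 440 * 1.05
        tones = tts_frequencies(stats(av_fl=75), TTSParams(detune_factor=0.20))
        assert tones.delta_FL == 0.25
        assert tones.f_FL == pytest.approx(462.0)

    def test_parietal_negative_sign(self):
        # DF 0.10, av_PL 80 vs SMC 100: delta 0.20, f_PL = 440 * 0.98
        tones = tts_frequencies(stats(av_pl=80), TTSParams(detune_factor=0.10))
        assert tones.delta_PL == pytest.approx(0.20)
        assert tones.f_PL == pytest.approx(431.2)
        assert tones.f_PL < tones.f_SMC

    @pytest.mark.parametrize("df", sorted(DETUNE_FACTORS.values()))
    @pytest.mark.parametrize("delta", [0.0, 0.05, 0.25, 0.5])
    def test_equation_grid_full_precision(self, df, delta):
        s = stats(av_fl=100.0 * (1 + delta), av_pl=100.0 * (1 - delta))
        tones = tts_frequencies(s, TTSParams(detune_factor=df))
        d_fl = abs(s.av_FL - 100.0) / 100.0
        d_pl = abs(s.av_PL - 100.0) / 100.0
        assert tones.f_FL == 440.0 * (1.0 + df * d_fl)
        assert tones.f_PL == 440.0 * (1.0 - df * d_pl)

    def test_beat_rates_closed_form(self):
        tones = tts_frequencies(
            stats(av_fl=130, av_pl=70), TTSParams(detune_factor=0.15)
        )
        assert tones.beat_rate_FL == pytest.approx(440 * 0.15 * 0.30)
        assert tones.beat_rate_PL == pytest.approx(440 * 0.15 * 0.30)

    def test_monotone_in_deviation_and_detune(self):
        f_fl = lambda av, df: tts_frequencies(
            stats(av_fl=av), TTSParams(detune_factor=df)
        ).f_FL
        f_pl = lambda av, df: tts_frequencies(
            stats(av_pl=av), TTSParams(detune_factor=df)
        ).f_PL
        assert f_fl(110, 0.1) < f_fl(120, 0.1) < f_fl(120, 0.2)
        assert f_pl(90, 0.1) > f_pl(80, 0.1) > f_pl(80, 0.2)

    @given(
        scale=st.floats(1e-3, 1e3),
        av_fl=st.floats(50, 200),
        av_pl=st.floats(50, 200),
    )
    def test_scale_invariance(self, scale, av_fl, av_pl):
        """Multiplying all regional means by a constant leaves tones unchanged."""
        params = TTSParams(detune_factor=0.15)
        a = tts_frequencies(stats(av_fl, av_pl, 100.0), params)
        b = tts_frequencies(stats(av_fl * scale, av_pl * scale, 100.0 * scale), params)
        assert a.f_FL == pytest.approx(b.f_FL, rel=1e-12)
        assert a.f_PL == pytest.approx(b.f_PL, rel=1e-12)

    def test_equal_deviations_do_not_collapse(self):
        """The sign rule keeps frontal and parietal tones apart when their
        deviations match, preserving three distinct beating pairs."""
        tones = tts_frequencies(
            stats(av_fl=80, av_pl=80), TTSParams(detune_factor=0.2)
        )
        assert tones.delta_FL == tones.delta_PL
        assert tones.f_FL != tones.f_PL
        assert tones.f_PL < tones.f_SMC < tones.f_FL

    def test_parietal_positive_compatibility_flag(self):
        tones = tts_frequencies(
            stats(av_fl=80, av_pl=80),
            TTSParams(detune_factor=0.2, parietal_positive=True),
        )
        assert tones.f_PL == tones.f_FL  # collapse the flag re-enables

    def test_frequency_collapse_error(self):
        with pytest.raises(FrequencyCollapseError):
            tts_frequencies(stats(av_pl=1500), TTSParams(detune_factor=0.5))

    @pytest.mark.parametrize(
        "kwargs",
        [
            {},  # neither severity nor detune
            {"severity": "mild", "detune_factor": 0.1},  # both
            {"detune_factor": -0.1},
            {"severity": "nope"},
            {"severity": "mild", "f_default": 0.0},
        ],
    )
    def test_params_validation(self, kwargs):
        with pytest.raises(ParameterError):
            TTSParams(**kwargs)


class TestReport:
    def test_report_carries_all_audit_fields(self):
        params = TTSParams(severity="moderate")
        s = stats(av_fl=120, av_pl=90)
        tones = tts_frequencies(s, params)
        report = sonification_report(s, tones, params, mask_threshold=14745.15)
        assert report["detune_factor"] == 0.15
        assert report["f_SMC_hz"] == 440.0
        assert report["mask_threshold"] == 14745.15
        for key in ("av_FL", "av_PL", "av_SMC", "delta_FL", "delta_PL",
                    "f_FL_hz", "f_PL_hz", "n_SMC"):
            assert key in report


def test_compute_region_stats_matches_region_average(rng):
    values = rng.integers(0, 1000, size=(10, 10))
    labels = np.zeros((10, 10), dtype=np.int8)
    labels[:3] = Region.FRONTAL
    labels[3:6] = Region.PARIETAL
    labels[6:] = Region.SENSORIMOTOR
    grid = SliceGrid(values=values)
    s = compute_region_stats(grid, labels)
    assert s.av_FL == values[:3].mean()
    assert s.av_PL == values[3:6].mean()
    assert s.av_SMC == values[6:].mean()
    assert (s.n_FL, s.n_PL, s.n_SMC) == (30, 30, 40)
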