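"""Rhythmicity, phase arithmetic, surrogate correlation and modules."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from introflow import (
    classify_tf,
    cluster_modules,
    correlate_with_surrogate,
    cosinor_test,
    interpolate_linear,
    per_gene_performance,
    phase_difference,
    replicate_robustness,
    target_intron_length_association,
)


def cosine_series(times, phase, period=24.0, amplitude=1.0, mesor=10.0):
    return mesor + amplitude * np.cos(2 * np.pi * (times - phase) / period)


class TestCosinor:
    times = np.arange(0, 24, 2.0)

    def test_exact_phase_recovery_on_noiseless_cosine(self):
        res = cosinor_test(cosine_series(self.times, 6.0), self.times)
        assert res.phase == pytest.approx(6.0, abs=1e-6)
        assert res.amplitude == pytest.approx(1.0, abs=1e-9)
        assert res.p_value < 1e-10

    def test_constant_series_non_rhythmic(self):
        with pytest.warns(UserWarning, match="constant"):
            res = cosinor_test(np.full(12, 3.0), self.times)
        assert res.p_value == 1.0 and res.amplitude == 0.0

    def test_insufficient_points_or_span_rejected(self):
        with pytest.raises(ValueError):
            cosinor_test([1, 2, 3, 4], [0, 2, 4, 6])
        with pytest.raises(ValueError):
            cosinor_test(np.ones(6), np.linspace(0, 10, 6))  # span < 12 h

    @pytest.mark.parametrize("shift", [1.5, 4.0, 13.0])
    def test_phase_equivariance_under_time_shift(self, shift):
        base = cosinor_test(cosine_series(self.times, 3.0), self.times)
        shifted = cosinor_test(cosine_series(self.times, 3.0 + shift), self.times)
        expected = (base.phase + shift) % 24.0
        assert shifted.phase == pytest.approx(expected, abs=1e-6)

    def test_type_one_error_close_to_alpha(self):
        rng = np.random.default_rng(2024)
        rejections = sum(
            cosinor_test(rng.normal(size=12), self.times).p_value < 0.05
            for _ in range(400)
        )
        assert 0.02 <= rejections / 400 <= 0.08


class TestClassification:
    def make(self, p):
        from introflow import RhythmResult
        return RhythmResult(tf="X", p_value=p, amplitude=1.0, phase=0.0, period=24.0)

    @pytest.mark.parametrize(
        "p_intron,p_exon,expected",
        [
            (0.01, 0.01, "class1"),
            (0.01, 0.2, "class2"),
            (0.2, 0.01, "class3"),
            (0.2, 0.2, "none"),
            (0.05, 0.01, "class3"),  # threshold is strict
        ],
    )
    def test_classes(self, p_intron, p_exon, expected):
        assert classify_tf(self.make(p_intron), self.make(p_exon)) == expected


class TestPhaseDifference:
    def test_sign_convention_exon_lag_positive(self):
        assert phase_difference(8.0, 6.0) == pytest.approx(2.0)

    def test_wrap_across_midnight(self):
        assert phase_difference(1.0, 23.0) == pytest.approx(2.0)

    def test_equal_phases_zero_and_antisymmetry(self):
        assert phase_difference(5.0, 5.0) == 0.0
        assert phase_difference(3.0, 9.0) == -phase_difference(9.0, 3.0)

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(
        pe=st.floats(0, 23.5).map(lambda x: round(x * 2) / 2),
        pi=st.floats(0, 23.5).map(lambda x: round(x * 2) / 2),
    )
    def test_wrap_properties_on_half_hour_grid(self, pe, pi):
        d = phase_difference(pe, pi)
        assert -12.0 < d <= 12.0
        assert (pi + d) % 24.0 == pytest.approx(pe % 24.0)

    def test_out_of_range_phase_rejected(self):
        with pytest.raises(ValueError):
            phase_difference(24.0, 0.0)


class TestInterpolation:
    def test_midpoint_and_identity(self):
        times = np.array([0.0, 1.0, 2.0])
        values = np.array([0.0, 4.0, 8.0])
        assert interpolate_linear(values, times, [0.5]) == pytest.approx([2.0])
        assert np.allclose(interpolate_linear(values, times, times), values)

    def test_half_hour_grid_point_count(self):
        grid = np.arange(0, 7.5 + 1e-9, 0.5)
        assert len(grid) == 16
        out = interpolate_linear(np.linspace(0, 1, 9), np.linspace(0, 7.5, 9), grid)
        assert len(out) == 16

    def test_extrapolation_refused(self):
        with pytest.raises(ValueError):
            interpolate_linear([1.0, 2.0], [0.0, 1.0], [1.5])


class TestSurrogateCorrelation:
    times = np.arange(0, 8, 1.0)

    def test_self_and_negated(self):
        x = np.sin(self.times) + 2
        res = correlate_with_surrogate(x, self.times, x, self.times)
        assert res.r == pytest.approx(1.0)
        res = correlate_with_surrogate(x, self.times, -x, self.times)
        assert res.r == pytest.approx(-1.0)

    def test_planted_driver_recovered(self, small_fixture):
        from introflow import average_replicates, cpm, filter_regulon, tfa_mean
        fx = small_fixture
        intron = average_replicates(cpm(fx.counts, "intron"), fx.counts.sample_time)
        targets = filter_regulon(fx.regulons, "TF1")
        act = tfa_mean(intron, targets)
        times = intron.values.columns.to_numpy(dtype=float)
        res = correlate_with_surrogate(
            act.to_numpy(), times,
            fx.surrogate["TF1"].to_numpy(), fx.surrogate.index.to_numpy(dtype=float),
        )
        assert res.r > 0.9

    def test_too_few_shared_points(self):
        with pytest.raises(ValueError):
            correlate_with_surrogate([1, 2], [0, 1], [1, 2], [0, 1], grid=[0.0, 0.5])


class TestPerGenePerformance:
    def test_low_expression_genes_excluded_and_ratio_one(self):
        times = np.arange(6)
        sur = np.sin(times)
        genes = ["hi", "lo"]
        intron = pd.DataFrame([10 + 5 * sur, 0.05 + 0.01 * sur], index=genes)
        exon = pd.DataFrame([10 + 5 * sur, 0.05 + 0.01 * sur], index=genes)
        table, _ = per_gene_performance(intron, exon, sur)
        assert list(table.index) == ["hi"]
        assert table.loc["hi", "ratio"] == pytest.approx(1.0)

    def test_halflife_association_from_constructed_fixture(self):
        # long-lived genes: exon series lags/blurs, lowering exon correlation
        rng = np.random.default_rng(7)
        times = np.arange(0, 24, 2.0)
        sur = np.cos(2 * np.pi * times / 24)
        genes, intron_rows, exon_rows, hls = [], [], [], {}
        for i, hl in enumerate([20, 50, 100, 400, 800, 1600]):
            lag = 5.0 * hl / (hl + 1000.0)  # saturating lag (h), longer-lived genes lag more
            genes.append(f"g{i}")
            intron_rows.append(10 + 3 * np.cos(2 * np.pi * times / 24) + rng.normal(0, .05, 12))
            exon_rows.append(10 + 3 * np.cos(2 * np.pi * (times - lag) / 24) + rng.normal(0, .05, 12))
            hls[f"g{i}"] = hl
        table, summary = per_gene_performance(
            pd.DataFrame(intron_rows, index=genes),
            pd.DataFrame(exon_rows, index=genes),
            sur, half_lives=pd.Series(hls),
        )
        assert summary is not None and summary.r > 0.5

    def test_no_double_positive_warns(self):
        times = np.arange(5)
        sur = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        intron = pd.DataFrame([[5, 4, 3, 2, 1.0]], index=["g"])  # anti-correlated
        exon = pd.DataFrame([[5, 4, 3, 2, 1.0]], index=["g"])
        with pytest.warns(UserWarning, match="positive"):
            table, summary = per_gene_performance(intron, exon, sur)
        assert summary is None


class TestReplicateRobustness:
    times = np.arange(0, 24, 2.0)

    def test_noiseless_cosine_fully_robust(self):
        reps = pd.DataFrame([cosine_series(self.times, 4.0)] * 4)
        assert replicate_robustness(reps, self.times) == 1.0

    def test_leave_one_out_attempt_count(self):
        rng = np.random.default_rng(0)
        reps = pd.DataFrame(rng.normal(size=(4, 12)))
        frac = replicate_robustness(reps, self.times)
        assert frac in {0.0, 0.25, 0.5, 0.75, 1.0}  # 4 leave-one-out attempts

    def test_pure_noise_rarely_robust(self):
        rng = np.random.default_rng(123)
        fracs = [
            replicate_robustness(pd.DataFrame(rng.normal(size=(4, 12))), self.times)
            for _ in range(40)
        ]
        assert np.mean(fracs) < 0.2

    def test_all_subsets_mode_and_min_replicates(self):
        reps = pd.DataFrame([cosine_series(self.times, 4.0)] * 4)
        assert replicate_robustness(reps, self.times, subsets="all") == 1.0
        with pytest.raises(ValueError):
            replicate_robustness(reps.iloc[:2], self.times)


class TestModuleClustering:
    times = np.arange(0, 24, 2.0)

    def make_activity(self, seed=0):
        rng = np.random.default_rng(seed)
        rows = {}
        for i in range(3):
            rows[f"up{i}"] = cosine_series(self.times, 0.0) + rng.normal(0, 0.05, 12)
        for i in range(3):
            rows[f"down{i}"] = cosine_series(self.times, 12.0) + rng.normal(0, 0.05, 12)
        return pd.DataFrame(rows).T

    def test_recovers_planted_antiphase_groups(self):
        part = cluster_modules(self.make_activity())
        groups = {tuple(sorted(part.module(1))), tuple(sorted(part.module(2)))}
        assert groups == {("up0", "up1", "up2"), ("down0", "down1", "down2")}

    def test_duplicate_series_same_module(self):
        act = self.make_activity()
        act.loc["up_copy"] = act.loc["up0"]
        part = cluster_modules(act)
        assert part.labels["up_copy"] == part.labels["up0"]

    def test_invariance_to_order_and_affine_rescaling(self):
        act = self.make_activity(seed=5)
        base = cluster_modules(act).labels
        shuffled = cluster_modules(act.iloc[::-1]).labels
        assert all(
            (base[a] == base[b]) == (shuffled[a] == shuffled[b])
            for a in base.index for b in base.index
        )
        rescaled = act.mul(pd.Series(np.linspace(1, 5, 6), index=act.index), axis=0) + 7
        assert cluster_modules(rescaled).labels.equals(
            cluster_modules(act).labels
        )

    def test_constant_series_excluded_with_warning(self):
        act = self.make_activity()
        act.loc["flat"] = 1.0
        with pytest.warns(UserWarning, match="constant"):
            part = cluster_modules(act)
        assert "flat" not in part.labels.index

    def test_two_nonempty_modules(self):
        part = cluster_modules(self.make_activity(seed=9))
        assert len(part.module(1)) > 0 and len(part.module(2)) > 0


class TestIntronLengthAssociation:
    def test_identical_vectors(self):
        res = target_intron_length_association([1, 2, 3, 4.0], [1, 2, 3, 4.0])
        assert res.r == pytest.approx(1.0)

    def test_orthogonal_fixture_near_zero(self):
        rng = np.random.default_rng(11)
        x = rng.normal(size=200)
        y = rng.normal(size=200)
        x -= x.mean()
        y -= y.mean()
        y -= x * np.dot(x, y) / np.dot(x, x)  # orthogonalised after centring
        res = target_intron_length_association(x, y)
        assert abs(res.r) < 1e-10

    def test_permutation_distribution_symmetric(self):
        rng = np.random.default_rng(4)
        x = rng.normal(size=30)
        y = rng.normal(size=30)
        rs = [
            target_intron_length_association(x, rng.permutation(y)).r
            for _ in range(500)
        ]
        assert abs(np.mean(rs)) < 3 * np.std(rs) / np.sqrt(500)
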