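import numpy as np
import pytest

from awarescreen import (
    ClusterAssignment,
    ResponseMatrix,
    ScaleSpec,
    icc_from_components,
    icc_series,
    variance_components_oneway,
)


def _anova_oracle(values, groups):
    """Hand-rolled one-way ANOVA variance components, loop by loop."""
    values = list(map(float, values))
    n = len(values)
    levels = sorted(set(groups))
    means, sizes = {}, {}
    for g in levels:
        ys = [y for y, gg in zip(values, groups) if gg == g]
        sizes[g] = len(ys)
        means[g] = sum(ys) / len(ys)
    grand = sum(values) / n
    ssb = sum(sizes[g] * (means[g] - grand) ** 2 for g in levels)
    ssw = sum(
        (y - means[g]) ** 2 for y, g in zip(values, groups)
    )
    msb = ssb / (len(levels) - 1)
    msw = ssw / (n - len(levels))
    n0 = (n - sum(s * s for s in sizes.values()) / n) / (len(levels) - 1)
    return max(0.0, (msb - msw) / n0), msw


def _assignment(labels):
    labels = np.asarray(labels, dtype=np.int8)
    idx0 = int(np.argmax(labels == 0))
    idx1 = int(np.argmax(labels == 1))
    return ClusterAssignment(
        labels=labels,
        medoid_indices=(idx0, idx1),
        cluster_sizes=(int((labels == 0).sum()), int((labels == 1).sum())),
    )


class TestVarianceComponents:
    @pytest.mark.parametrize("estimator", ["reml", "anova"])
    def test_zero_within_group_variance(self, estimator):
        sb, sw, conv = variance_components_oneway(
            np.array([1.0, 1, 3, 3]), np.array([0, 0, 1, 1]), estimator
        )
        assert conv and sw == 0.0 and sb > 0.0
        assert icc_from_components(sb, sw) == 1.0

    @pytest.mark.parametrize("estimator", ["reml", "anova"])
    def test_equal_group_means_truncate_between_to_zero(self, estimator):
        sb, sw, conv = variance_components_oneway(
            np.array([0.0, 2, 0, 2]), np.array([0, 0, 1, 1]), estimator
        )
        assert conv and sb == 0.0 and sw > 0.0

    @pytest.mark.parametrize("estimator", ["reml", "anova"])
    def test_constant_values_do_not_converge(self, estimator):
        _, _, conv = variance_components_oneway(
            np.full(8, 2.0), np.repeat([0, 1], 4), estimator
        )
        assert not conv

    def test_matches_handrolled_anova_oracle(self, rng):
        """On a fixed balanced dataset with an interior between-estimate,
        REML coincides with the method-of-moments decomposition."""
        y = np.concatenate([rng.normal(0.0, 1.0, 10), rng.normal(2.0, 1.0, 10)])
        g = np.repeat([0, 1], 10)
        sb_oracle, sw_oracle = _anova_oracle(y, g)
        assert sb_oracle > 0  # interior
        for estimator in ("reml", "anova"):
            sb, sw, conv = variance_components_oneway(y, g, estimator)
            assert conv
            assert sb == pytest.approx(sb_oracle, rel=1e-6)
            assert sw == pytest.approx(sw_oracle, rel=1e-6)

    def test_unbalanced_anova_uses_group_size_correction(self, rng):
        y = np.concatenate([rng.normal(0.0, 1.0, 12), rng.normal(1.5, 1.0, 30)])
        g = np.concatenate([np.zeros(12, int), np.ones(30, int)])
        sb, sw, conv = variance_components_oneway(y, g, "anova")
        sb_oracle, sw_oracle = _anova_oracle(y, g)
        assert conv
        assert sb == pytest.approx(sb_oracle, rel=1e-12)
        assert sw == pytest.approx(sw_oracle, rel=1e-12)

    def test_reml_matches_mixedlm_on_unbalanced_data(self, rng):
        """Independent mixed-model fitter agrees on the same decomposition."""
        from statsmodels.regression.mixed_linear_model import MixedLM

        for shift in (0.8, 1.5, 2.2):  # clearly interior between-variance
            n1, n2 = rng.integers(25, 70, 2)
            y = np.concatenate(
                [rng.normal(0, 1, n1), rng.normal(shift, 1, n2)]
            )
            g = np.concatenate([np.zeros(n1, int), np.ones(n2, int)])
            sb, sw, conv = variance_components_oneway(y, g, "reml")
            assert conv
            fit = MixedLM(y, np.ones_like(y), groups=g).fit(reml=True)
            assert sw == pytest.approx(float(fit.scale), rel=1e-3)
            assert sb == pytest.approx(float(np.asarray(fit.cov_re)[0, 0]),
                                       rel=1e-3, abs=1e-6)

    @pytest.mark.parametrize("estimator", ["reml", "anova"])
    def test_shift_and_scale_invariance_of_icc(self, rng, estimator):
        y = np.concatenate([rng.normal(0, 1, 20), rng.normal(1, 1, 20)])
        g = np.repeat([0, 1], 20)
        sb, sw, _ = variance_components_oneway(y, g, estimator)
        base = icc_from_components(sb, sw)
        sb2, sw2, _ = variance_components_oneway(y + 100.0, g, estimator)
        assert icc_from_components(sb2, sw2) == pytest.approx(base, rel=1e-9)
        sb3, sw3, _ = variance_components_oneway(y * -2.5, g, estimator)
        assert icc_from_components(sb3, sw3) == pytest.approx(base, rel=1e-7)

    def test_balanced_reml_anova_equivalence_property(self, rng):
        worst = 0.0
        for _ in range(20):
            y = np.concatenate(
                [rng.normal(0, 1, 25) + rng.normal(0, 0.8),
                 rng.normal(0, 1, 25) + rng.normal(0, 0.8)]
            )
            g = np.repeat([0, 1], 25)
            sba, swa, _ = variance_components_oneway(y, g, "anova")
            if sba <= 1e-8:
                continue  # boundary case; equivalence holds only interior
            sbr, swr, _ = variance_components_oneway(y, g, "reml")
            worst = max(worst, abs(sbr - sba) / sba, abs(swr - swa) / swa)
        assert worst < 1e-6

    def test_large_sample_recovery_of_known_ratio(self, rng):
        """Data from the one-way model with known groups recovers the true
        variance ratio within Monte-Carlo error at n = 10^4."""
        n = 10_000
        rho = 0.4
        sigma_b, sigma_w = np.sqrt(rho), np.sqrt(1 - rho)
        g = rng.integers(0, 2, n)
        u = rng.normal(0, sigma_b, 2)
        y = u[g] + rng.normal(0, sigma_w, n)
        # with only 2 random levels the between-variance itself is noisy
        # (2 draws of u), so compare against the realized u variance
        realized_b = np.var(u, ddof=1)  # (u0 - u1)^2 / 2 for two draws
        sb, sw, conv = variance_components_oneway(y, g, "anova")
        assert conv
        assert sw == pytest.approx(1 - rho, rel=0.05)
        assert sb == pytest.approx(realized_b, rel=0.05)

    def test_preconditions(self):
        with pytest.raises(ValueError):
            variance_components_oneway(np.ones(3), np.array([0, 1, 1]))
        with pytest.raises(ValueError):
            variance_components_oneway(np.ones(6), np.zeros(6, int))


class TestIccFromComponents:
    @pytest.mark.parametrize(
        "sb,sw,expected", [(0.0, 1.0, 0.0), (1.0, 0.0, 1.0), (0.25, 0.75, 0.25)]
    )
    def test_direct_formula(self, sb, sw, expected):
        assert icc_from_components(sb, sw) == expected

    def test_zero_total_variance_undefined(self):
        with pytest.raises(ValueError):
            icc_from_components(0.0, 0.0)

    def test_negative_components_rejected(self):
        with pytest.raises(ValueError):
            icc_from_components(-0.1, 1.0)


class TestIccSeries:
    def _rm(self, values, spec):
        return ResponseMatrix(
            [f"s{i}" for i in range(len(values))], spec.labels, values
        )

    def test_all_items_converge(self, rng, small_scale):
        values = rng.normal(size=(40, 4)) + rng.integers(0, 2, 40)[:, None]
        labels = rng.integers(0, 2, 40)
        labels[:2] = [0, 1]
        series = icc_series(self._rm(values, small_scale), small_scale,
                            _assignment(labels))
        assert series.n_converged == 4 and series.screenable
        assert [e.position for e in series.estimates] == [2, 10, 25, 40]
        assert all(0.0 <= e.icc <= 1.0 for e in series.estimates)

    def test_constant_column_flagged_not_dropped(self, rng, small_scale):
        values = rng.normal(size=(40, 4))
        values[:, 2] = 1.5
        labels = np.repeat([0, 1], 20)
        series = icc_series(self._rm(values, small_scale), small_scale,
                            _assignment(labels))
        assert len(series.estimates) == 4
        assert not series.estimates[2].converged
        assert series.n_converged == 3 and series.screenable

    def test_label_swap_gives_identical_series(self, rng, small_scale):
        values = rng.normal(size=(40, 4))
        labels = np.repeat([0, 1], 20)
        rm = self._rm(values, small_scale)
        s1 = icc_series(rm, small_scale, _assignment(labels))
        s2 = icc_series(rm, small_scale, _assignment(1 - labels))
        for e1, e2 in zip(s1.estimates, s2.estimates):
            assert e1.icc == pytest.approx(e2.icc, rel=1e-9)
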