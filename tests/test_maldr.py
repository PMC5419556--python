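"""Region restriction, loess smoothing and the monotone-ratio filter."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from maldr_age.gapsites import GapSite
from maldr_age.maldr import (AGE_GROUP_ORDER, GeneDepth, MaldrResult,
                             SmoothedGroupCurves, group_mean_depth,
                             monotone_fraction, restrict_introns,
                             restrict_low_coverage, run_maldr)
from maldr_age.params import MaldrParameters
from maldr_age.smoothing import loess_smooth


def curves(y, m, o, gene="G"):
    y, m, o = np.atleast_1d(np.asarray(y, float)), \
        np.atleast_1d(np.asarray(m, float)), \
        np.atleast_1d(np.asarray(o, float))
    pos = np.arange(1, y.size + 1)
    return SmoothedGroupCurves(gene, AGE_GROUP_ORDER, pos,
                               np.stack([y, m, o]))


def oracle_fraction(y, m, o, ratio=1.2, eps=1e-9):
    """Brute-force position-wise double check of the monotone fraction."""
    n_inc = n_dec = 0
    for yi, mi, oi in zip(y, m, o):
        r1 = mi / (yi if yi > 0 else eps)
        r2 = oi / (mi if mi > 0 else eps)
        if r1 > ratio and r2 > ratio:
            n_inc += 1
        r1 = yi / (mi if mi > 0 else eps)
        r2 = mi / (oi if oi > 0 else eps)
        if r1 > ratio and r2 > ratio:
            n_dec += 1
    n = len(y)
    if n_inc > n_dec:
        return "increasing", n_inc / n
    if n_dec > n_inc:
        return "decreasing", n_dec / n
    return "none", n_inc / n


class TestIntronRestriction:
    def test_interval_arithmetic(self):
        region = restrict_introns(np.arange(1, 101), "G",
                                  [GapSite("c", 40, 61)])
        assert region.kept_positions.size == 80
        assert region.removed_intronic.tolist() == list(range(41, 61))

    def test_no_gap_sites_is_identity(self):
        pos = np.arange(5, 50)
        region = restrict_introns(pos, "G", [])
        np.testing.assert_array_equal(region.kept_positions, pos)

    def test_overlapping_gap_sites_union(self):
        region = restrict_introns(np.arange(1, 101), "G",
                                  [GapSite("c", 40, 61),
                                   GapSite("c", 50, 71)])
        removed = set(region.removed_intronic.tolist())
        assert removed == set(range(41, 61)) | set(range(51, 71))
        assert region.kept_positions.size + len(removed) == 100


class TestGroupMeans:
    def make_depth(self):
        pos = np.arange(1, 11)
        depth = np.array([[10] * 10, [20] * 10, [30] * 10,
                          [40] * 10, [50] * 10, [60] * 10])
        sids = [f"S{i}" for i in range(6)]
        table = pd.DataFrame({"age_group": ["Young", "Young", "Middle",
                                            "Middle", "Old", "Old"]},
                             index=sids)
        return GeneDepth("G", pos, depth, sids), table

    def test_arithmetic_mean_per_group(self):
        gd, table = self.make_depth()
        means = group_mean_depth(gd, table)
        assert means.loc["Young"].eq(15).all()
        assert means.loc["Middle"].eq(35).all()
        assert means.loc["Old"].eq(55).all()

    def test_single_sample_group_equals_its_depth(self):
        pos = np.arange(1, 6)
        gd = GeneDepth("G", pos, np.array([[1, 2, 3, 4, 5]]), ["S0"])
        table = pd.DataFrame({"age_group": ["Young"]}, index=["S0"])
        means = group_mean_depth(gd, table, group_order=("Young",))
        np.testing.assert_array_equal(means.loc["Young"], [1, 2, 3, 4, 5])

    def test_empty_group_raises(self):
        gd, table = self.make_depth()
        table["age_group"] = "Young"
        with pytest.raises(ValueError, match="no samples"):
            group_mean_depth(gd, table)


class TestLoess:
    def test_constant_input_reproduced(self):
        x = np.arange(50.)
        np.testing.assert_allclose(loess_smooth(x, np.full(50, 3.3)),
                                   np.full(50, 3.3), atol=1e-9)

    def test_linear_input_reproduced(self):
        x = np.sort(np.random.default_rng(0).uniform(0, 100, 80))
        y = 2.0 + 0.5 * x
        np.testing.assert_allclose(loess_smooth(x, y, span=0.3), y,
                                   atol=1e-9)

    def test_matches_brute_force_local_fit(self, rng):
        x = np.sort(rng.uniform(0, 50, 40))
        y = rng.uniform(0, 10, 40)
        span = 0.4
        w = int(np.ceil(span * 40))
        expected = []
        for xi in x:
            idx = np.argsort(np.abs(x - xi), kind="mergesort")[:w]
            d = np.abs(x[idx] - xi)
            u = d / d.max()
            wt = (1 - u**3) ** 3
            coef = np.polyfit(x[idx] - xi, y[idx], 1, w=np.sqrt(wt))
            expected.append(max(coef[1], 0.0))
        np.testing.assert_allclose(loess_smooth(x, y, span=span), expected,
                                   atol=1e-8)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_noisy_step_stays_within_input_range(self, seed):
        rng = np.random.default_rng(seed)
        x = np.arange(100.)
        y = np.where(x < 50, 0.0, 10.0) + rng.normal(0, 0.5, 100)
        s = loess_smooth(x, y, span=0.3)
        assert s.min() >= min(y.min(), 0.0) and s.max() <= y.max()

    def test_short_input_passes_through_with_warning(self):
        with pytest.warns(UserWarning, match="skipped"):
            out = loess_smooth(np.arange(4.), np.array([1., 5., 2., 4.]))
        np.testing.assert_array_equal(out, [1, 5, 2, 4])

    def test_output_clipped_at_zero(self):
        x = np.arange(20.)
        y = np.where(x < 10, 0.0, 50.0)
        assert loess_smooth(x, y, span=0.5).min() >= 0.0


class TestLowCoverageCut:
    def test_flat_gene_keeps_everything(self):
        c = curves([5] * 10, [5] * 10, [5] * 10)
        out, region = restrict_low_coverage(c)
        assert out.positions.size == 10
        assert region.removed_low_coverage.size == 0

    def test_positions_below_two_percent_removed(self):
        y = np.array([1000.0, 1000.0, 1.0, 1000.0])
        c = curves(y, y, y)
        out, region = restrict_low_coverage(c)
        assert region.removed_low_coverage.tolist() == [3]
        assert out.positions.tolist() == [1, 2, 4]

    def test_all_groups_rule_keeps_mixed_position(self):
        # one group at 1% of max, another at 50%: kept
        y = np.array([1000.0, 10.0])
        m = np.array([1000.0, 500.0])
        o = np.array([1000.0, 10.0])
        out, _ = restrict_low_coverage(curves(y, m, o))
        assert out.positions.tolist() == [1, 2]

    def test_everything_removed_marks_unevaluable(self):
        c = curves([0.0, 0.0], [0.0, 0.0], [0.0, 0.0])
        out, region = restrict_low_coverage(c)
        assert out.positions.size == 0


class TestMonotoneFraction:
    def test_ratio_thresholds_pass(self):
        res = monotone_fraction(curves([10] * 5, [13] * 5, [17] * 5))
        assert res.direction == "increasing"
        assert res.monotone_fraction == 1.0
        assert res.passes

    def test_ratio_exactly_at_threshold_fails(self):
        res = monotone_fraction(curves([10.0], [12.0], [20.0]))
        assert res.monotone_fraction == 0.0 and not res.passes

    def test_equal_curves_no_direction(self):
        res = monotone_fraction(curves([7] * 4, [7] * 4, [7] * 4))
        assert res.direction == "none"
        assert res.monotone_fraction == 0.0 and not res.passes

    def test_zero_denominator_guarded(self):
        res = monotone_fraction(curves([0.0], [5.0], [10.0]))
        assert res.direction == "increasing" and res.monotone_fraction == 1.0

    def test_needs_three_groups(self):
        c = SmoothedGroupCurves("G", ("Young", "Old"), np.arange(1, 4),
                                np.ones((2, 3)))
        with pytest.raises(ValueError, match="3 ordered groups"):
            monotone_fraction(c)

    @settings(derandomize=True, max_examples=200)
    @given(st.integers(0, 2**32 - 1), st.integers(1, 30))
    def test_agrees_with_bruteforce_oracle(self, seed, n):
        rng = np.random.default_rng(seed)
        y, m, o = rng.uniform(0, 20, (3, n)).round(1)
        res = monotone_fraction(curves(y, m, o))
        direction, frac = oracle_fraction(y, m, o)
        assert res.direction == direction
        assert res.monotone_fraction == pytest.approx(frac, abs=1e-12)

    @settings(derandomize=True, max_examples=50)
    @given(st.integers(0, 2**32 - 1),
           st.floats(0.01, 100.0, allow_nan=False))
    def test_scale_invariance(self, seed, scale):
        rng = np.random.default_rng(seed)
        y, m, o = rng.uniform(0.1, 20, (3, 20))
        r1 = monotone_fraction(curves(y, m, o))
        r2 = monotone_fraction(curves(y * scale, m * scale, o * scale))
        assert r1.direction == r2.direction
        assert r1.monotone_fraction == pytest.approx(r2.monotone_fraction)

    @settings(derandomize=True, max_examples=50)
    @given(st.integers(0, 2**32 - 1))
    def test_group_reversal_symmetry(self, seed):
        rng = np.random.default_rng(seed)
        y, m, o = rng.uniform(0.1, 20, (3, 25))
        r1 = monotone_fraction(curves(y, m, o))
        r2 = monotone_fraction(curves(o, m, y))
        flip = {"increasing": "decreasing", "decreasing": "increasing",
                "none": "none"}
        assert r2.direction == flip[r1.direction]
        assert r1.monotone_fraction == pytest.approx(r2.monotone_fraction)


@pytest.fixture(scope="module")
def dataset():
    from maldr_age import synthetic_data as sd
    genes = sd.generate_gene_models(
        sd.SyntheticGenomeSpec(n_genes=20), seed=5)
    samples = sd.simulate_cohort(sd.CohortSpec(seed=5))
    injected = [g.gene_id for g in genes[:5]]
    effects = [sd.EffectSpec(g, "monotone_up", ratio=1.5)
               for g in injected]
    depths = sd.simulate_depth_profiles(genes, samples, effects, seed=5,
                                        donor_sigma=0.05)
    ggs = {g.gene_id: g.annotated_gap_sites() for g in genes}
    return genes, samples, depths, ggs, injected


class TestFullMaldr:
    def test_low_noise_recovery(self, dataset):
        genes, samples, depths, ggs, injected = dataset
        res = run_maldr([g.gene_id for g in genes], depths, ggs, samples)
        assert res.loc[injected, "passes"].all()
        nulls = res.drop(index=injected)
        assert nulls["passes"].sum() <= 1

    def test_deterministic_rerun(self, dataset):
        genes, samples, depths, ggs, _ = dataset
        ids = [g.gene_id for g in genes]
        r1 = run_maldr(ids, depths, ggs, samples)
        r2 = run_maldr(ids, depths, ggs, samples)
        pd.testing.assert_frame_equal(r1, r2)

    def test_missing_profiles_skipped(self, dataset):
        genes, samples, depths, ggs, _ = dataset
        res = run_maldr(["NOT_A_GENE", genes[0].gene_id], depths, ggs,
                        samples)
        assert list(res.index) == [genes[0].gene_id]
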