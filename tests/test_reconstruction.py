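import numpy as np
import pandas as pd
import pytest

from behaveseq.reconstruction import (
    GapCorrelationCurve,
    artificial_pool,
    compare_alignments,
    compare_gap_groups,
    compare_to_reference,
    embed_samples,
    pairwise_gap_correlations,
    smooth_trajectory,
)
from behaveseq.synthetic_data import ExpressionSimConfig, gen_expression_cohort


def frame_from(values, samples=None):
    values = np.asarray(values, float)
    samples = samples or [f"s{i}" for i in range(values.shape[1])]
    return pd.DataFrame(values, index=[f"g{i}" for i in range(values.shape[0])], columns=samples)


def ages_for(df, ages):
    return pd.Series(np.asarray(ages, float), index=df.columns)


class TestPairwiseGapCorrelations:
    def test_duplicated_sample_r_one(self, rng):
        base = rng.uniform(1, 100, size=50)
        df = frame_from(np.column_stack([base, base, rng.uniform(1, 100, 50)]))
        curve = pairwise_gap_correlations(df, ages_for(df, [10.0, 10.0, 400.0]),
                                          gap_edges=[0, 5, 600])
        assert curve.mean_r[0] == pytest.approx(1.0)

    def test_pair_accounting_exact(self, default_rpm):
        rpm, samples, _ = default_rpm
        curve = pairwise_gap_correlations(rpm, samples.ages("l4"))
        n = rpm.n_samples
        assert curve.total_pairs == n * (n - 1) // 2

    def test_uncorrelated_profiles_near_zero(self, rng):
        n_genes = 4000
        df = frame_from(rng.uniform(0, 100, size=(n_genes, 3)))
        curve = pairwise_gap_correlations(df, ages_for(df, [0.0, 300.0, 600.0]),
                                          gap_edges=[0, 600], log_transform=False)
        assert np.all(np.abs(curve.pair_r) < 3 / np.sqrt(n_genes))

    def test_constant_sample_excluded_with_warning(self, rng):
        vals = rng.uniform(1, 100, size=(20, 4))
        vals[:, 2] = 5.0
        df = frame_from(vals)
        with pytest.warns(UserWarning, match="constant"):
            curve = pairwise_gap_correlations(df, ages_for(df, [0, 10, 20, 30.0]),
                                              gap_edges=[0, 600])
        assert curve.total_pairs == 3 * 2 // 2

    def test_noise_free_curve_decreasing(self, noisefree_grid_cohort):
        _, counts, samples, _ = noisefree_grid_cohort
        curve = pairwise_gap_correlations(counts, samples.ages("l4"))
        mr = curve.mean_r[~np.isnan(curve.mean_r)]
        assert np.all(np.diff(mr) <= 0)


class TestCompareGapGroups:
    def _curve(self, gaps, r):
        return GapCorrelationCurve(
            edges=np.array([0.0, 600.0]), mean_r=np.array([np.mean(r)]),
            sem_r=np.array([0.0]), n_pairs=np.array([len(r)]),
            pair_gaps=np.asarray(gaps, float), pair_r=np.asarray(r, float),
        )

    def test_identical_distributions(self):
        curve = self._curve([1, 2, 3, 10, 20, 30], [0.5, 0.6, 0.7, 0.5, 0.6, 0.7])
        with pytest.warns(UserWarning, match="underpowered"):
            stat, p = compare_gap_groups(curve)
        assert stat == 0.0 and p == 1.0

    def test_shifted_groups_significant(self, rng):
        close_r = rng.normal(0.8, 0.05, 150)
        far_r = rng.normal(0.6, 0.05, 150)
        curve = self._curve(
            np.concatenate([np.full(150, 2.0), np.full(150, 100.0)]),
            np.concatenate([close_r, far_r]),
        )
        _, p = compare_gap_groups(curve)
        assert p < 0.001

    def test_empty_group_raises(self):
        curve = self._curve([10.0, 20.0], [0.5, 0.6])
        with pytest.raises(ValueError):
            compare_gap_groups(curve)


class TestCompareAlignments:
    def test_zero_jitter_alignments_equal(self):
        cfg = ExpressionSimConfig(n_individuals=120, seed=4, prestage_jitter_sd=0.0)
        counts, samples, _ = gen_expression_cohort(cfg)
        cmp = compare_alignments(counts, samples.ages("l4"), samples.ages("hatch"))
        assert cmp.mean_r_l4 == pytest.approx(cmp.mean_r_hatch, abs=1e-12)

    def test_jitter_gives_l4_advantage(self, jittered_cohort):
        _, rpm, samples, _ = jittered_cohort
        cmp = compare_alignments(rpm, samples.ages("l4"), samples.ages("hatch"))
        assert cmp.mean_r_l4 > cmp.mean_r_hatch

    def test_advantage_grows_with_jitter(self):
        adv = {}
        for jit in (0.1, 0.2):
            cfg = ExpressionSimConfig(n_individuals=150, seed=6, prestage_jitter_sd=jit)
            counts, samples, _ = gen_expression_cohort(cfg)
            cmp = compare_alignments(counts, samples.ages("l4"), samples.ages("hatch"))
            adv[jit] = cmp.advantage
        assert adv[0.2] > adv[0.1] > 0


class TestSmoothTrajectory:
    def test_constant_gene_flat(self, rng):
        ages = rng.uniform(0, 600, 80)
        out = smooth_trajectory(np.full(80, 7.5), ages)
        filled = out.values[~np.isnan(out.values)]
        assert np.allclose(filled, 7.5)

    def test_linear_gene_slope_preserved(self):
        # mean of a linear function over a symmetric window is exact
        ages = np.linspace(0, 600, 1201)  # dense, symmetric around grid points
        b = 0.35
        out = smooth_trajectory(10 + b * ages, ages, window_h=1.0, step_h=0.5)
        interior = slice(3, -3)
        slopes = np.diff(out.values[interior]) / np.diff(out.times_min[interior])
        assert np.allclose(slopes, b, atol=1e-9)

    def test_linearity_of_smoothing(self, rng):
        ages = rng.uniform(0, 600, 100)
        x, y = rng.normal(size=100), rng.normal(size=100)
        sx = smooth_trajectory(x, ages).values
        sy = smooth_trajectory(y, ages).values
        sxy = smooth_trajectory(2.0 * x - 3.0 * y, ages).values
        mask = ~np.isnan(sxy)
        assert np.allclose(sxy[mask], 2.0 * sx[mask] - 3.0 * sy[mask], atol=1e-9)

    def test_oscillation_peaks_recovered(self):
        cfg = ExpressionSimConfig(n_individuals=193, seed=8, dispersion=0.02,
                                  sampling="grid")
        counts, samples, _ = gen_expression_cohort(cfg)
        ages = samples.ages("l4")
        gene = counts.values.loc["oscillation_005"]
        out = smooth_trajectory(gene.to_numpy(), ages.loc[gene.index].to_numpy())
        # truth: 0.55 + 0.45 sin(2 pi t / 240); peaks at 60 and 300 min
        vals = np.where(np.isnan(out.values), -np.inf, out.values)
        for true_peak in (60.0, 300.0):
            near = np.abs(out.times_min - true_peak) <= 60.0
            peak_t = out.times_min[near][np.argmax(vals[near])]
            assert abs(peak_t - true_peak) <= 15.0

    def test_empty_everywhere_raises(self):
        with pytest.raises(ValueError):
            smooth_trajectory(np.array([]), np.array([]))


class TestEmbedSamples:
    def test_seed_reproducible(self, default_rpm):
        rpm, samples, _ = default_rpm
        sub = rpm.values.iloc[:, :60]
        a = embed_samples(sub, seed=3)
        b = embed_samples(sub, seed=3)
        assert np.allclose(a[["dim1", "dim2"]], b[["dim1", "dim2"]])

    def test_trajectory_neighborhood_structure(self, default_rpm):
        rpm, samples, _ = default_rpm
        ages = samples.ages("l4")
        emb = embed_samples(rpm.values, ages, seed=0)
        a = ages.to_numpy()
        baseline = np.abs(a[:, None] - a[None, :]).sum() / (len(a) * (len(a) - 1))
        assert emb["knn_age_gap"].mean() < 0.5 * baseline

    def test_shuffled_profiles_destroy_structure(self, default_rpm, rng):
        rpm, samples, _ = default_rpm
        shuffled = rpm.values.copy()
        for c in shuffled.columns:
            shuffled[c] = rng.permutation(shuffled[c].to_numpy())
        ages = samples.ages("l4")
        emb = embed_samples(shuffled, ages, seed=0)
        a = ages.to_numpy()
        baseline = np.abs(a[:, None] - a[None, :]).sum() / (len(a) * (len(a) - 1))
        assert emb["knn_age_gap"].mean() > 0.6 * baseline

    def test_too_few_samples_raises(self):
        df = frame_from(np.random.default_rng(0).uniform(size=(10, 3)))
        with pytest.raises(ValueError):
            embed_samples(df)


class TestArtificialPool:
    def test_single_center_mean(self):
        df = frame_from([[1.0, 3.0], [10.0, 30.0]])
        with pytest.raises(ValueError):
            artificial_pool(df, ages_for(df, [60.0, 62.0]))

    def test_samples_at_one_center_pool_to_mean(self):
        df = frame_from([[1.0, 3.0, 100.0], [10.0, 30.0, 200.0]])
        pooled = artificial_pool(df, ages_for(df, [59.0, 61.0, 122.0]))
        assert pooled.values.loc["g0", 1.0] == pytest.approx(2.0)
        assert pooled.n_per_bin[0] == 2

    def test_uniform_ages_ten_bins(self, default_rpm):
        rpm, samples, _ = default_rpm
        # hatch ages span prestage..prestage+600 -> ~10 populated hourly bins
        pooled = artificial_pool(rpm, samples.ages("hatch"))
        assert 9 <= pooled.n_bins <= 11
        populated = pooled.n_per_bin[pooled.n_per_bin > 0]
        assert np.all(populated > 0)
        assert pooled.n_per_bin.mean() == pytest.approx(rpm.n_samples / pooled.n_bins, rel=0.35)

    def test_bin_membership_window(self, default_rpm):
        rpm, samples, _ = default_rpm
        pooled = artificial_pool(rpm, samples.ages("hatch"))
        a = samples.ages("hatch").to_numpy()
        for c, n in zip(pooled.bin_centers_h, pooled.n_per_bin):
            assert n == int((np.abs(a - c * 60.0) <= 30.0).sum())


class TestCompareToReference:
    def test_self_comparison_all_r_one(self, default_rpm):
        rpm, samples, _ = default_rpm
        pooled = artificial_pool(rpm, samples.ages("hatch"))
        res = compare_to_reference(pooled, pooled, hour_offset=0.0, seed=1)
        assert np.allclose(res.gene_r, 1.0)

    def test_matched_archetypes_beat_shuffle(self):
        cfg = ExpressionSimConfig(n_individuals=193, seed=12, param_diversity=True,
                                  n_genes_per_archetype=25)
        counts, samples, _ = gen_expression_cohort(cfg)
        pooled = artificial_pool(counts, samples.ages("hatch"))
        # independent cohort from the same generator acts as the reference
        cfg2 = ExpressionSimConfig(n_individuals=193, seed=12, param_diversity=True,
                                   n_genes_per_archetype=25)
        counts2, samples2, _ = gen_expression_cohort(cfg2, genotype="replicate")
        ref = artificial_pool(counts2, samples2.ages("hatch"))
        res = compare_to_reference(pooled, ref, hour_offset=0.0, seed=1)
        assert res.mean_r > res.mean_shuffled_r
        assert res.p_value < 0.001

    def test_offset_alignment(self, default_rpm):
        rpm, samples, _ = default_rpm
        pooled = artificial_pool(rpm, samples.ages("hatch"))
        shifted = pd.DataFrame(
            pooled.values.to_numpy(),
            index=pooled.values.index,
            columns=pooled.bin_centers_h - 2.0,
        )
        from behaveseq.reconstruction import PooledMatrix

        ref = PooledMatrix(shifted, pooled.bin_centers_h - 2.0, pooled.n_per_bin)
        res = compare_to_reference(pooled, ref, hour_offset=2.0, seed=0)
        assert np.allclose(res.gene_r, 1.0)

    def test_constant_gene_excluded_with_warning(self, default_rpm):
        rpm, samples, _ = default_rpm
        pooled = artificial_pool(rpm, samples.ages("hatch"))
        ref_vals = pooled.values.copy()
        ref_vals.iloc[0, :] = 5.0
        from behaveseq.reconstruction import PooledMatrix

        ref = PooledMatrix(ref_vals, pooled.bin_centers_h, pooled.n_per_bin)
        with pytest.warns(UserWarning, match="constant"):
            res = compare_to_reference(pooled, ref, seed=0)
        assert pooled.values.index[0] not in res.gene_r.index

    def test_no_shared_genes_raises(self, default_rpm):
        rpm, samples, _ = default_rpm
        pooled = artificial_pool(rpm, samples.ages("hatch"))
        from behaveseq.reconstruction import PooledMatrix

        other = PooledMatrix(
            pooled.values.rename(index=lambda g: "x_" + g),
            pooled.bin_centers_h,
            pooled.n_per_bin,
        )
        with pytest.raises(ValueError, match="shared genes"):
            compare_to_reference(pooled, other)
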