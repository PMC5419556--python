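"""The synthetic cohort generator: structure, effects, determinism."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from maldr_age import synthetic_data as sd


class TestGeneModels:
    def test_one_intron_per_exon_pair(self):
        genes = sd.generate_gene_models(
            sd.SyntheticGenomeSpec(n_genes=1, exons_per_gene=(2, 2)), seed=0)
        assert len(genes) == 1
        assert len(genes[0].annotated_gap_sites()) == 1

    def test_junction_count_formula(self):
        genes = sd.generate_gene_models(
            sd.SyntheticGenomeSpec(n_genes=10, exons_per_gene=(3, 3)), seed=0)
        sites = [s for g in genes for s in g.annotated_gap_sites()]
        assert len(genes) == 10 and len(sites) == 20

    def test_genes_do_not_overlap(self):
        genes = sd.generate_gene_models(
            sd.SyntheticGenomeSpec(n_genes=30), seed=3)
        spans = sorted(g.span for g in genes)
        assert all(b0 < a1 for (_, b0), (a1, _) in zip(spans, spans[1:]))

    def test_gtf_deterministic_and_round_trips(self, tmp_path):
        spec = sd.SyntheticGenomeSpec(n_genes=6)
        p1, p2 = tmp_path / "a.gtf", tmp_path / "b.gtf"
        g1 = sd.generate_gene_models(spec, seed=9)
        g2 = sd.generate_gene_models(spec, seed=9)
        sd.write_gtf(g1, p1)
        sd.write_gtf(g2, p2)
        assert p1.read_bytes() == p2.read_bytes()
        back = sd.read_gtf(p1)
        assert [(g.gene_id, g.chrom, g.strand, g.exons) for g in back] == \
            [(g.gene_id, g.chrom, g.strand, g.exons) for g in g1]

    def test_declared_chromosome_too_short_rejected(self):
        spec = sd.SyntheticGenomeSpec(n_genes=50, chrom_len=1000)
        with pytest.raises(ValueError, match="chrom_len"):
            sd.generate_gene_models(spec, seed=0)


class TestCohort:
    def test_default_cohort_structure(self, default_cohort):
        assert len(default_cohort) == 54
        assert default_cohort["age_group"].value_counts().eq(18).all()
        donors = default_cohort.drop_duplicates("donor")
        assert len(donors) == 27
        assert donors["gender"].value_counts().to_dict() == {
            "male": 14, "female": 13}

    def test_one_sample_per_donor_per_location(self, default_cohort):
        per = default_cohort.groupby(["donor", "location"]).size()
        assert (per == 1).all()

    def test_ages_within_group_ranges(self, default_cohort):
        ranges = {"Young": (18, 25), "Middle": (35, 49), "Old": (60, 67)}
        for grp, (lo, hi) in ranges.items():
            ages = default_cohort.loc[
                default_cohort["age_group"] == grp, "age"]
            assert ages.between(lo, hi).all()

    def test_single_donor_cohort(self):
        spec = sd.CohortSpec(
            n_donors=1, age_groups=[sd.AgeGroupSpec("Young", 18, 25, 1, 1)])
        assert len(sd.simulate_cohort(spec)) == 2

    def test_group_sizes_must_sum(self):
        with pytest.raises(ValueError, match="sum"):
            sd.CohortSpec(n_donors=20)


class TestEffects:
    def test_ratio_below_one_rejected(self):
        with pytest.raises(ValueError):
            sd.EffectSpec("G1", "monotone_up", ratio=0.5)

    def test_outlier_fields_only_for_outlier_kind(self):
        with pytest.raises(ValueError):
            sd.EffectSpec("G1", "null", outlier_fold=5.0)

    def test_unknown_gene_in_effects_rejected(self, small_genes,
                                              default_cohort):
        with pytest.raises(KeyError, match="unknown gene"):
            sd.simulate_counts(small_genes, default_cohort,
                               [sd.EffectSpec("NOPE", "monotone_up",
                                              ratio=1.5)], seed=0)


class TestCounts:
    def test_determinism(self, small_genes, default_cohort):
        c1 = sd.simulate_counts(small_genes, default_cohort, seed=4)
        c2 = sd.simulate_counts(small_genes, default_cohort, seed=4)
        pd.testing.assert_frame_equal(c1.counts, c2.counts)

    def test_poisson_limit_at_zero_dispersion(self, small_genes):
        spec = sd.CohortSpec(seed=2, lib_size=(250_000, 250_000))
        samples = sd.simulate_cohort(spec)
        counts = sd.simulate_counts(small_genes, samples, nb_dispersion=0.0,
                                    donor_sigma=0.0, seed=2)
        y = counts.counts.to_numpy(dtype=float)
        ratio = y.var(axis=1, ddof=1) / y.mean(axis=1)
        # variance/mean ~ 1 for Poisson at equal library sizes
        assert 0.7 < np.median(ratio) < 1.4

    def test_monotone_effect_old_young_ratio(self, default_cohort):
        genes = sd.generate_gene_models(
            sd.SyntheticGenomeSpec(n_genes=40, exons_per_gene=(2, 2)),
            seed=6)
        effects = [sd.EffectSpec(g.gene_id, "monotone_up", ratio=1.5)
                   for g in genes]
        counts = sd.simulate_counts(genes, default_cohort, effects, seed=6)
        young = default_cohort.index[default_cohort.age_group == "Young"]
        old = default_cohort.index[default_cohort.age_group == "Old"]
        y = counts.counts
        assert y[young].to_numpy().mean() >= 100
        obs = y[old].to_numpy().mean() / y[young].to_numpy().mean()
        assert obs == pytest.approx(1.5**2, rel=0.10)

    def test_library_size_conservation(self, small_genes):
        """Total gap-site counts scale linearly with library size."""
        libs = np.linspace(50_000, 500_000, 10)
        totals = []
        for lib in libs:
            spec = sd.CohortSpec(seed=3, lib_size=(int(lib), int(lib)))
            samples = sd.simulate_cohort(spec)
            counts = sd.simulate_counts(small_genes, samples, seed=3,
                                        donor_sigma=0.0)
            totals.append(counts.counts.to_numpy().sum() / len(samples))
        r = stats.linregress(libs, totals).rvalue
        assert r**2 > 0.99

    def test_null_groups_equal_means(self):
        """With no effects, age-group count means differ only by noise."""
        genes = sd.generate_gene_models(
            sd.SyntheticGenomeSpec(n_genes=1000, exons_per_gene=(2, 2)),
            seed=8)
        samples = sd.simulate_cohort(sd.CohortSpec(seed=8))
        counts = sd.simulate_counts(genes, samples, seed=8)
        y = counts.counts.to_numpy(dtype=float)
        grp = samples["age_group"].to_numpy()
        rejected = 0
        for row in y:
            groups = [row[grp == g] for g in ("Young", "Middle", "Old")]
            if stats.f_oneway(*groups).pvalue < 0.001:
                rejected += 1
        assert rejected / len(y) <= 0.01


class TestDepthProfiles:
    def test_zero_expression_gene_all_zero(self, small_genes,
                                           default_cohort):
        gid = small_genes[0].gene_id
        depths = sd.simulate_depth_profiles(
            small_genes, default_cohort, seed=1, gene_weights={gid: 0.0})
        assert depths[gid].depth.sum() == 0

    def test_outlier_donors_elevated_tenfold(self, default_cohort):
        genes = sd.generate_gene_models(
            sd.SyntheticGenomeSpec(n_genes=5), seed=4)
        donors = list(default_cohort["donor"].unique()[:3])
        eff = [sd.EffectSpec(genes[0].gene_id, "outlier_donors",
                             outlier_donor_ids=tuple(donors),
                             outlier_fold=10.0)]
        depths = sd.simulate_depth_profiles(genes, default_cohort, eff,
                                            seed=4, donor_sigma=0.0)
        gd = depths[genes[0].gene_id]
        exonic = np.zeros(gd.positions.size, bool)
        for a, b in genes[0].exons:
            exonic |= (gd.positions >= a) & (gd.positions <= b)
        flagged = default_cohort["donor"].isin(donors).to_numpy()
        mean_flagged = gd.depth[flagged][:, exonic].mean()
        med_other = np.median(gd.depth[~flagged][:, exonic].mean(axis=1))
        assert mean_flagged / med_other == pytest.approx(10.0, rel=0.15)

    def test_intronic_leakage_small(self, default_cohort):
        genes = sd.generate_gene_models(
            sd.SyntheticGenomeSpec(n_genes=3), seed=4)
        depths = sd.simulate_depth_profiles(genes, default_cohort, seed=4)
        g, gd = genes[0], depths[genes[0].gene_id]
        exonic = np.zeros(gd.positions.size, bool)
        for a, b in g.exons:
            exonic |= (gd.positions >= a) & (gd.positions <= b)
        assert gd.depth[:, ~exonic].mean() < 0.05 * gd.depth[:, exonic].mean()

    def test_monotone_effect_orders_group_means(self):
        """Low-noise monotone genes order Young<Middle<Old at every exonic
        base after smoothing in nearly all replicates."""
        from maldr_age.maldr import group_mean_depth, smooth_group_curves
        genes = sd.generate_gene_models(
            sd.SyntheticGenomeSpec(n_genes=40), seed=11)
        samples = sd.simulate_cohort(sd.CohortSpec(seed=11))
        effects = [sd.EffectSpec(g.gene_id, "monotone_up", ratio=1.3)
                   for g in genes]
        depths = sd.simulate_depth_profiles(genes, samples, effects,
                                            seed=11, donor_sigma=0.05)
        ordered = 0
        for g in genes:
            gd = depths[g.gene_id]
            exonic = np.zeros(gd.positions.size, bool)
            for a, b in g.exons:
                exonic |= (gd.positions >= a) & (gd.positions <= b)
            sub = sd.GeneDepth(g.gene_id, gd.positions[exonic],
                               gd.depth[:, exonic], gd.sample_ids)
            means = group_mean_depth(sub, samples)
            sm = smooth_group_curves(means, g.gene_id)
            y, m, o = sm.curves
            if np.all(y < m) and np.all(m < o):
                ordered += 1
        assert ordered / len(genes) >= 0.95

    def test_depth_consistent_with_gapsite_counts(self, small_genes,
                                                  default_cohort):
        """Counts and depth generated from one seed share the same latent
        expression: per-junction counts and mean exonic depth agree in
        scale (ratio read_len/(read_len-1)) and covary across samples."""
        read_len = 101
        counts = sd.simulate_counts(small_genes, default_cohort, seed=12)
        depths = sd.simulate_depth_profiles(small_genes, default_cohort,
                                            seed=12)
        gene_counts = counts.counts.groupby(counts.feature_genes).sum()
        for g in small_genes[:6]:
            gd = depths[g.gene_id]
            exonic = np.zeros(gd.positions.size, bool)
            for a, b in g.exons:
                exonic |= (gd.positions >= a) & (gd.positions <= b)
            mean_depth = gd.depth[:, exonic].mean(axis=1)
            per_site = gene_counts.loc[g.gene_id].to_numpy() \
                / len(g.introns())
            # totals over 54 samples: scale agreement within sampling error
            scale = mean_depth.sum() / per_site.sum()
            assert scale == pytest.approx(read_len / (read_len - 1),
                                          rel=0.15)
            # shared latent expression: strong per-sample covariation
            assert np.corrcoef(per_site, mean_depth)[0, 1] > 0.6


class TestFastqEmitter:
    def test_gc_content_controlled(self):
        reads = sd.simulate_fastq_reads(200, read_len=80, gc=0.8, seed=0)
        gc = sum(r.count("G") + r.count("C") for r in reads) / (200 * 80)
        assert gc == pytest.approx(0.8, abs=0.02)

    def test_fastq_round_trip(self, tmp_path):
        from maldr_age.qc import read_fastq
        reads = sd.simulate_fastq_reads(10, read_len=30, seed=1)
        for name in ("r.fastq", "r.fastq.gz"):
            p = tmp_path / name
            sd.write_fastq(reads, p)
            assert read_fastq(p) == reads
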