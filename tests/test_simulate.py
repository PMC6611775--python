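"""Synthetic-data generators: reproducibility, composition, and planted truth."""

import numpy as np
import pandas as pd
import pytest

from uromics import (
    SimulationConfig,
    gen_caller_tables,
    gen_expression_cohort,
    gen_ihc_table,
    gen_msi_sites,
    gen_mutations,
    gen_reference,
    compute_hscore,
)
from uromics.simulate import IMMUNE_GENES, CallerProfile, GenerationError
from uromics.signatures import CATEGORIES_96


class TestConfigValidation:
    def test_rejects_bad_parameters(self):
        with pytest.raises(ValueError):
            SimulationConfig(contig_length=2)
        with pytest.raises(ValueError):
            SimulationConfig(gc_fraction=1.5)
        with pytest.raises(ValueError):
            SimulationConfig(signature_mix={"a": 0.5, "b": 0.6})
        with pytest.raises(ValueError):
            SimulationConfig(signature_mix={"a": -0.5, "b": 1.5})
        with pytest.raises(ValueError):
            SimulationConfig(msi_unstable_fraction=1.2)
        with pytest.raises(ValueError):
            CallerProfile(sensitivity=1.2, fp_per_mb=0)


class TestGenReference:
    def test_gc_content_within_band(self):
        cfg = SimulationConfig(seed=1, contig_length=10_000, gc_fraction=0.5)
        _, seq = gen_reference(cfg)
        gc = (seq.count("G") + seq.count("C")) / len(seq)
        assert 0.47 <= gc <= 0.53

    def test_deterministic(self):
        cfg = SimulationConfig(seed=1, contig_length=5_000)
        assert gen_reference(cfg) == gen_reference(cfg)

    def test_zero_gc_is_at_only(self):
        cfg = SimulationConfig(seed=2, contig_length=100, gc_fraction=0.0)
        _, seq = gen_reference(cfg)
        assert set(seq) <= {"A", "T"}


class TestGenMutations:
    def test_point_mass_category(self, reference_catalog):
        point = pd.DataFrame(0.0, index=list(CATEGORIES_96), columns=["P"])
        point.loc["A[C>T]G", "P"] = 1.0
        cfg = SimulationConfig(seed=3, contig_length=20_000,
                               n_mutations_per_sample=30, signature_mix={"P": 1.0})
        ref = gen_reference(cfg)
        vbs, expo = gen_mutations(cfg, ref, point)
        seq = ref[1]
        for rec in vbs["S001"]:
            tri = seq[rec.pos - 2 : rec.pos + 1]
            assert (tri, rec.alt_allele) in {("ACG", "T"), ("CGT", "A")}
        assert expo.loc["S001", "P"] == 30

    def test_zero_mutations(self, reference_catalog):
        cfg = SimulationConfig(seed=4, contig_length=5_000, n_mutations_per_sample=0)
        ref = gen_reference(cfg)
        vbs, expo = gen_mutations(cfg, ref, reference_catalog)
        assert vbs["S001"] == [] and expo.to_numpy().sum() == 0

    def test_positions_distinct_within_sample(self, reference_catalog):
        cfg = SimulationConfig(seed=5, contig_length=50_000, n_mutations_per_sample=400)
        ref = gen_reference(cfg)
        vbs, _ = gen_mutations(cfg, ref, reference_catalog)
        positions = [r.pos for r in vbs["S001"]]
        assert len(positions) == len(set(positions))

    def test_category_frequencies_within_multinomial_bounds(self, reference_catalog):
        """Realized 96-category counts near the mixture across 500 draws."""
        cfg = SimulationConfig(
            seed=6, contig_length=60_000, n_mutations_per_sample=500,
            signature_mix={"APOBEC_CT": 0.7, "CPG_CT": 0.3},
        )
        ref = gen_reference(cfg)
        vbs, _ = gen_mutations(cfg, ref, reference_catalog)
        from uromics import build_catalog

        cat = build_catalog(vbs, {ref[0]: ref[1]})
        mix = (0.7 * reference_catalog["APOBEC_CT"] + 0.3 * reference_catalog["CPG_CT"])
        n = 500
        counts = cat.counts.loc["S001"]
        # 3-sigma bounds per category where the normal approximation holds
        # (expected >= 5); the sparse floor categories are tested in aggregate
        heavy = [c for c in CATEGORIES_96 if n * mix[c] >= 5]
        assert heavy, "mixture should concentrate mass on some categories"
        for c in heavy:
            exp = n * mix[c]
            sigma = np.sqrt(n * mix[c] * (1 - mix[c]))
            assert abs(counts[c] - exp) <= 3 * sigma
        floor = [c for c in CATEGORIES_96 if c not in heavy]
        p_floor = float(mix[floor].sum())
        exp_floor = n * p_floor
        sigma_floor = np.sqrt(n * p_floor * (1 - p_floor))
        assert abs(counts[floor].sum() - exp_floor) <= 3 * sigma_floor

    def test_insufficient_sites_raise(self):
        point = pd.DataFrame(0.0, index=list(CATEGORIES_96), columns=["P"])
        point.loc["A[C>T]G", "P"] = 1.0
        cfg = SimulationConfig(seed=7, contig_length=50, gc_fraction=0.0,
                               n_mutations_per_sample=5, signature_mix={"P": 1.0})
        ref = gen_reference(cfg)  # A/T only: no ACG context exists
        with pytest.raises(GenerationError, match=r"A\[C>T\]G"):
            gen_mutations(cfg, ref, point)


class TestGenCallerTables:
    def _setup(self, seed, n_mut, **kwargs):
        cfg = SimulationConfig(seed=seed, contig_length=100_000,
                               n_mutations_per_sample=n_mut, **kwargs)
        ref = gen_reference(cfg)
        from uromics import synthetic_reference_catalog

        vbs, _ = gen_mutations(cfg, ref, synthetic_reference_catalog())
        return cfg, ref, vbs["S001"]

    def test_perfect_callers_reproduce_truth(self):
        profiles = {c: CallerProfile(1.0, 0.0) for c in
                    ("mutect2", "strelka", "varscan", "somaticsniper")}
        cfg, ref, truth_vars = self._setup(8, 100, caller_profiles=profiles)
        tables, truth = gen_caller_tables(truth_vars, cfg, ref)
        for table in tables.values():
            assert {r.key for r in table} == truth

    def test_dead_callers_produce_nothing(self):
        profiles = {c: CallerProfile(0.0, 0.0) for c in ("mutect2", "strelka")}
        cfg, ref, truth_vars = self._setup(9, 50, caller_profiles=profiles)
        tables, _ = gen_caller_tables(truth_vars, cfg, ref)
        assert all(t == [] for t in tables.values())

    def test_sensitivity_within_binomial_bounds(self):
        profiles = {"mutect2": CallerProfile(0.9, 0.0)}
        cfg, ref, truth_vars = self._setup(10, 1000, caller_profiles=profiles)
        tables, truth = gen_caller_tables(truth_vars, cfg, ref)
        tp = len({r.key for r in tables["mutect2"]} & truth)
        sigma = np.sqrt(1000 * 0.9 * 0.1)
        assert abs(tp - 900) <= 3 * sigma

    def test_read_counts_respect_depth_model(self):
        cfg, ref, truth_vars = self._setup(11, 200)
        tables, _ = gen_caller_tables(truth_vars, cfg, ref)
        depths = [r.tumor_depth for t in tables.values() for r in t]
        assert abs(np.mean(depths) - cfg.mean_tumor_depth) < 5
        assert all(r.tumor_alt <= r.tumor_depth for t in tables.values() for r in t)


class TestGenExpressionCohort:
    def test_truth_marginals_match_planted_design(self):
        """28 depleted / 4 inflamed in UTUC; 71 / 57 in UCB — exactly."""
        cfg = SimulationConfig(seed=12)
        _, truth = gen_expression_cohort(cfg)
        counts = truth.groupby(["cohort", "immune_state"]).size()
        assert counts[("UTUC", "depleted")] == 28
        assert counts[("UTUC", "inflamed")] == 4
        assert counts[("UCB", "depleted")] == 71
        assert counts[("UCB", "inflamed")] == 57

    def test_noiseless_same_subtype_columns_identical(self):
        cfg = SimulationConfig(
            seed=13, expr_sigma=0.0, batch_sigma=0.0, immune_hot_shift=0.0,
            immune_activity_sd=0.0,
            n_samples_per_group={"A": 6, "B": 6},
            immune_split={"A": (6, 0), "B": (6, 0)},
            n_genes=200,
        )
        matrix, truth = gen_expression_cohort(cfg)
        for subtype, group in truth.groupby("subtype"):
            cols = matrix.values[list(group.index)]
            assert (cols.nunique(axis=1) == 1).all()

    def test_zero_hot_shift_null_immune_contrast(self):
        cfg = SimulationConfig(
            seed=14, immune_hot_shift=0.0, n_genes=400,
            n_samples_per_group={"A": 40, "B": 40},
            immune_split={"A": (20, 20), "B": (20, 20)},
        )
        matrix, truth = gen_expression_cohort(cfg)
        immune = [g for g in IMMUNE_GENES if g in matrix.genes]
        hot = truth.index[truth["immune_state"] == "inflamed"]
        cold = truth.index[truth["immune_state"] == "depleted"]
        log = np.log2(matrix.values + 1)
        diff = log[list(hot)].loc[immune].mean().mean() - log[list(cold)].loc[immune].mean().mean()
        assert abs(diff) < 0.2

    def test_values_nonnegative_and_deterministic(self):
        cfg = SimulationConfig(seed=15, n_genes=100,
                               n_samples_per_group={"A": 3, "B": 3},
                               immune_split={"A": (3, 0), "B": (3, 0)})
        m1, t1 = gen_expression_cohort(cfg)
        m2, t2 = gen_expression_cohort(cfg)
        pd.testing.assert_frame_equal(m1.values, m2.values)
        pd.testing.assert_frame_equal(t1, t2)
        assert (m1.values.to_numpy() >= 0).all()

    def test_too_few_groups_rejected(self):
        with pytest.raises(ValueError):
            gen_expression_cohort(SimulationConfig(seed=0, n_samples_per_group={"A": 4}))


class TestGenMsiSites:
    def test_extreme_fractions(self):
        cfg0 = SimulationConfig(seed=16, msi_unstable_fraction=0.0, msi_n_sites=50)
        _, truth0 = gen_msi_sites(cfg0)
        assert not any(truth0.values())
        cfg1 = SimulationConfig(seed=17, msi_unstable_fraction=1.0, msi_n_sites=50)
        _, truth1 = gen_msi_sites(cfg1)
        assert all(truth1.values())

    def test_unstable_count_within_binomial_bounds(self):
        cfg = SimulationConfig(seed=18, msi_unstable_fraction=0.035, msi_n_sites=200)
        _, truth = gen_msi_sites(cfg)
        n = sum(truth.values())
        sigma = np.sqrt(200 * 0.035 * 0.965)
        assert abs(n - 7) <= 3 * sigma

    def test_deterministic(self):
        cfg = SimulationConfig(seed=19, msi_n_sites=20)
        s1, t1 = gen_msi_sites(cfg)
        s2, t2 = gen_msi_sites(cfg)
        assert t1 == t2
        assert all(a.tumor_hist == b.tumor_hist for a, b in zip(s1, s2))


class TestGenIhcTable:
    def test_degenerate_all_maximal(self):
        cfg = SimulationConfig(seed=20)
        table = gen_ihc_table(cfg, alphas={"X": (1e-9, 1e-9, 1e-9, 1.0)},
                              n_per_group={"X": 3})
        for _, row in table.iterrows():
            assert row["pct_3"] == pytest.approx(100, abs=1e-6)

    def test_rows_sum_to_100_and_reproducible(self):
        cfg = SimulationConfig(seed=21)
        t1 = gen_ihc_table(cfg)
        t2 = gen_ihc_table(cfg)
        pd.testing.assert_frame_equal(t1, t2)
        sums = t1[["pct_0", "pct_1", "pct_2", "pct_3"]].sum(axis=1)
        assert np.allclose(sums, 100.0, atol=1e-9)

    def test_group_intensity_ordering_via_hscores(self):
        """Low- vs high-intensity groups produce ordered mean H-scores."""
        cfg = SimulationConfig(seed=22)
        table = gen_ihc_table(cfg)
        scores = {}
        for group, rows in table.groupby("group"):
            scores[group] = np.mean([
                compute_hscore((r.pct_0, r.pct_1, r.pct_2, r.pct_3)).h_score
                for r in rows.itertuples()
            ])
        assert scores["UCB"] > scores["UTUC"]
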