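"""Immune contexture: variable-gene selection, anchored classifier discovery,
consensus clustering, and association tests."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from uromics import (
    compare_gene_by_label,
    consensus_cluster_samples,
    discover_classifier,
    fisher_association,
    fisher_exact_2x2,
    select_variable_genes,
)

from conftest import make_matrix


class TestSelectVariableGenes:
    def test_hand_worked_mad_ranking(self):
        vals = [
            [1, 1, 1, 1, 1],      # MAD 0
            [0, 10, 20, 30, 40],  # MAD 10
            [0, 1, 2, 3, 4],      # MAD 1
            [0, 5, 10, 15, 20],   # MAD 5
            [7, 7, 7, 7, 100],    # MAD 0
        ]
        m = make_matrix(vals, unit="normalized-log")
        assert select_variable_genes(m, 3) == ["g1", "g3", "g2"]

    def test_constant_gene_excluded_while_room(self):
        vals = np.vstack([np.zeros(6), np.arange(6), np.arange(6) * 2])
        m = make_matrix(vals, unit="normalized-log")
        assert "g0" not in select_variable_genes(m, 2)

    def test_sample_order_invariance_and_bounds(self):
        rng = np.random.default_rng(0)
        vals = rng.normal(size=(10, 8))
        m = make_matrix(vals, unit="normalized-log")
        sel = select_variable_genes(m, 5)
        perm = list(rng.permutation(m.samples))
        m2 = make_matrix(m.values[perm].to_numpy(), genes=m.genes, samples=perm,
                         unit="normalized-log")
        assert select_variable_genes(m2, 5) == sel
        with pytest.raises(ValueError):
            select_variable_genes(m, 11)


def _planted_immune_matrix(seed, n_immune=150, n_background=4850, n_samples=60, r=0.75):
    """Anchored co-regulated immune block against independent background."""
    rng = np.random.default_rng(seed)
    factor = rng.normal(0, 1, n_samples)
    immune = np.sqrt(r) * factor + np.sqrt(1 - r) * rng.normal(0, 1, (n_immune, n_samples))
    background = rng.normal(0, 1, (n_background, n_samples))
    genes = ["CD8A"] + [f"IMM{i}" for i in range(1, n_immune)] + [
        f"BG{i}" for i in range(n_background)
    ]
    vals = np.vstack([immune, background])
    return make_matrix(vals, genes=genes, unit="normalized-log"), set(genes[:n_immune])


class TestDiscoverClassifier:
    def test_planted_cluster_recovery(self):
        """>= 90% of planted immune genes, <= 1% background, across 5 seeds."""
        for seed in range(5):
            m, immune = _planted_immune_matrix(seed)
            found = set(discover_classifier(m, "CD8A", n_variable=5000, k=20))
            recovered = len(found & immune) / len(immune)
            background = len(found - immune) / max(len(found), 1)
            assert recovered >= 0.9, f"seed {seed}: {recovered}"
            assert background <= 0.01, f"seed {seed}: {background}"

    def test_k_one_returns_all_genes(self):
        m, _ = _planted_immune_matrix(0, n_immune=10, n_background=20, n_samples=12)
        assert set(discover_classifier(m, "CD8A", n_variable=30, k=1)) == set(m.genes)

    def test_deterministic(self):
        m, _ = _planted_immune_matrix(1, n_immune=20, n_background=80, n_samples=20)
        a = discover_classifier(m, "CD8A", n_variable=100, k=5)
        b = discover_classifier(m, "CD8A", n_variable=100, k=5)
        assert a == b
        assert a[0] == "CD8A"

    def test_anchor_absent_raises(self):
        m, _ = _planted_immune_matrix(2, n_immune=10, n_background=30, n_samples=12)
        with pytest.raises(ValueError, match="NOPE"):
            discover_classifier(m, "NOPE", n_variable=40, k=5)


def _two_state_cohort(seed, n_depleted=40, n_inflamed=30, shift=2.5, n_classifier=30,
                      n_other=100):
    rng = np.random.default_rng(seed)
    n = n_depleted + n_inflamed
    states = ["depleted"] * n_depleted + ["inflamed"] * n_inflamed
    classifier = rng.normal(0, 1, (n_classifier, n))
    classifier[:, n_depleted:] += shift
    other = rng.normal(0, 1, (n_other, n))
    genes = [f"CL{i}" for i in range(n_classifier)] + [f"O{i}" for i in range(n_other)]
    m = make_matrix(np.vstack([classifier, other]), genes=genes, unit="normalized-log")
    truth = dict(zip(m.samples, states))
    return m, genes[:n_classifier], truth


class TestConsensusClustering:
    def test_planted_two_state_recovery(self):
        """Adjusted Rand >= 0.8 across 5 seeds at a 2.5-SD shift."""
        from sklearn.metrics import adjusted_rand_score

        for seed in range(5):
            m, classifier, truth = _two_state_cohort(seed)
            labeling = consensus_cluster_samples(m, classifier, seed=seed)
            y_true = [truth[s] for s in m.samples]
            y_pred = [labeling.labels[s] for s in m.samples]
            ari = adjusted_rand_score(y_true, y_pred)
            assert ari >= 0.8, f"seed {seed}: ARI {ari}"
            # inflamed state has higher classifier-gene expression by definition
            inflamed = [s for s in m.samples if labeling.labels[s] == "inflamed"]
            depleted = [s for s in m.samples if labeling.labels[s] == "depleted"]
            assert (
                m.values.loc[classifier, inflamed].mean().mean()
                > m.values.loc[classifier, depleted].mean().mean()
            )

    def test_consensus_matrix_properties(self):
        m, classifier, _ = _two_state_cohort(7, n_depleted=10, n_inflamed=10)
        labeling = consensus_cluster_samples(m, classifier, n_runs=40, seed=0)
        C = labeling.consensus_matrix.to_numpy()
        assert np.allclose(C, C.T)
        assert np.allclose(np.diag(C), 1.0)
        assert C.min() >= 0 and C.max() <= 1

    def test_duplicated_samples_always_coassigned(self):
        m, classifier, _ = _two_state_cohort(3, n_depleted=8, n_inflamed=8)
        vals = m.values.copy()
        vals["dup_0"] = vals[m.samples[0]]
        m2 = make_matrix(vals.to_numpy(), genes=m.genes, samples=list(vals.columns),
                         unit="normalized-log")
        labeling = consensus_cluster_samples(m2, classifier, n_runs=60, seed=1)
        c = labeling.consensus_matrix.loc[m.samples[0], "dup_0"]
        assert c == pytest.approx(1.0)

    def test_null_cohort_gives_weak_consensus(self):
        from sklearn.metrics import adjusted_rand_score

        m, classifier, truth = _two_state_cohort(11, shift=0.0)
        labeling = consensus_cluster_samples(m, classifier, seed=2)
        ari = adjusted_rand_score(
            [truth[s] for s in m.samples], [labeling.labels[s] for s in m.samples]
        )
        assert abs(ari) < 0.2
        off_diag = labeling.consensus_matrix.to_numpy()[
            ~np.eye(len(m.samples), dtype=bool)
        ]
        assert 0.05 < off_diag.mean() < 0.95  # far from all-0/all-1 certainty

    def test_k_other_than_two_unsupported(self):
        m, classifier, _ = _two_state_cohort(5, n_depleted=5, n_inflamed=5)
        with pytest.raises(ValueError):
            consensus_cluster_samples(m, classifier, k=3)


class TestFullContexturePipeline:
    def test_depleted_fractions_within_one_sample_of_truth(self):
        """Discovery -> consensus -> labels on generated cohorts with the
        planted 28/4 vs 71/57 design and a clean >= 2-SD shift reproduces
        the per-cohort depleted counts within one sample, across 5 seeds."""
        from uromics import (
            ExpressionMatrix,
            SimulationConfig,
            gen_expression_cohort,
            log_transform,
            quantile_normalize,
        )

        for seed in range(5):
            cfg = SimulationConfig(seed=seed, immune_hot_shift=2.5,
                                   immune_activity_sd=0.2)
            matrix, truth = gen_expression_cohort(cfg)
            parts = []
            for group in cfg.n_samples_per_group:
                cols = [s for s in matrix.samples if matrix.cohort[s] == group]
                parts.append(ExpressionMatrix(
                    values=matrix.values[cols], unit="FPKM",
                    cohort={s: group for s in cols}))
            normalized = log_transform(quantile_normalize(parts))
            classifier = discover_classifier(normalized, "CD8A",
                                             n_variable=2000, k=20)
            labeling = consensus_cluster_samples(normalized, classifier, seed=seed)
            for group, expected in (("UTUC", 28), ("UCB", 71)):
                depleted = sum(
                    1 for s in normalized.samples
                    if normalized.cohort[s] == group
                    and labeling.labels[s] == "depleted"
                )
                assert abs(depleted - expected) <= 1, f"seed {seed}, {group}"


class TestFisherExact:
    def test_printed_contexture_table(self):
        _, p = fisher_exact_2x2([[28, 4], [71, 57]])
        assert p == pytest.approx(0.0009, abs=5e-5)  # one significant figure

    def test_symmetric_unit_table(self):
        _, p = fisher_exact_2x2([[1, 1], [1, 1]])
        assert p == pytest.approx(1.0)

    def test_matches_scipy_on_random_tables(self):
        rng = np.random.default_rng(0)
        for _ in range(200):
            a, b, c, d = rng.integers(0, 30, 4)
            if (a + b == 0) or (c + d == 0) or (a + c == 0) or (b + d == 0):
                continue
            _, p = fisher_exact_2x2([[a, b], [c, d]])
            p_scipy = stats.fisher_exact([[a, b], [c, d]]).pvalue
            assert p == pytest.approx(p_scipy, abs=1e-12)

    def test_odds_ratio_with_continuity_correction(self):
        odds, _ = fisher_exact_2x2([[10, 0], [5, 5]])
        assert odds == pytest.approx((10.5 * 5.5) / (0.5 * 5.5))

    def test_degenerate_margins_rejected(self):
        with pytest.raises(ValueError):
            fisher_exact_2x2([[0, 0], [3, 4]])

    def test_association_from_label_mappings(self):
        labels = {f"u{i}": ("depleted" if i < 28 else "inflamed") for i in range(32)}
        labels |= {f"b{i}": ("depleted" if i < 71 else "inflamed") for i in range(128)}
        group = {s: ("UTUC" if s.startswith("u") else "UCB") for s in labels}
        res = fisher_association(labels, group)
        assert res.p_value == pytest.approx(0.0009022376517190155, abs=1e-12)
        flat = sorted(x for row in res.table for x in row)
        assert flat == [4, 28, 57, 71]


class TestCompareGeneByLabel:
    def _matrix_and_labels(self, seed, n1=10, n2=10, shift=0.0):
        rng = np.random.default_rng(seed)
        vals = rng.normal(0, 1, (1, n1 + n2))
        vals[0, n1:] += shift
        m = make_matrix(vals, genes=["FGFR3"], unit="normalized-log")
        labels = {s: ("depleted" if i < n1 else "inflamed")
                  for i, s in enumerate(m.samples)}
        return m, labels

    def test_complete_separation_exact_p(self):
        m, labels = self._matrix_and_labels(0, shift=100.0)
        table = compare_gene_by_label(m, "FGFR3", labels)
        p = table["mannwhitney_p"].iloc[0]
        assert p == pytest.approx(2 / math.comb(20, 10), rel=1e-9)

    def test_label_swap_symmetry(self):
        m, labels = self._matrix_and_labels(1, shift=1.0)
        p1 = compare_gene_by_label(m, "FGFR3", labels)["mannwhitney_p"].iloc[0]
        swapped = {s: ("inflamed" if l == "depleted" else "depleted")
                   for s, l in labels.items()}
        p2 = compare_gene_by_label(m, "FGFR3", swapped)["mannwhitney_p"].iloc[0]
        assert p1 == pytest.approx(p2, rel=1e-12)

    def test_null_rejection_rate(self):
        """Across 100 null draws the rejection rate stays near alpha."""
        rejections = 0
        n_trials = 100
        for seed in range(n_trials):
            m, labels = self._matrix_and_labels(seed, n1=15, n2=15)
            p = compare_gene_by_label(m, "FGFR3", labels)["mannwhitney_p"].iloc[0]
            rejections += p <= 0.05
        sigma = np.sqrt(0.05 * 0.95 / n_trials)
        assert rejections / n_trials <= 0.05 + 3 * sigma

    def test_missing_gene_rejected(self):
        m, labels = self._matrix_and_labels(2)
        with pytest.raises(ValueError):
            compare_gene_by_label(m, "ABSENT", labels)
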