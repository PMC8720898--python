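"""DE/DZI likelihood-ratio tests, BH adjustment, gene classification."""

import numpy as np
import pandas as pd
import pytest

from zinbcap.distributions import zinb_sample
from zinbcap.estimation import make_design
from zinbcap.inference import (
    adjust_pvalues,
    classify_genes,
    classify_label,
    de_dzi_tests,
    lrt_test,
)


class TestLRT:
    def test_duplicated_groups_carry_no_signal(self):
        # the same cells labeled as two groups: contrast is uninformative
        y_half = zinb_sample(200, 0.3, 5.0, 2.0, seed=1)
        y = np.concatenate([y_half, y_half])
        groups = np.repeat([0, 1], 200)
        res = lrt_test(y, make_design(groups), "DE")
        assert res.stat == pytest.approx(0.0, abs=1e-4)
        assert res.p_value > 0.99

    def test_strong_de_signal_detected(self):
        rng = np.random.default_rng(2)
        groups = np.repeat([0, 1], 300)
        mu = np.where(groups == 0, 3.0, 9.0)
        y = zinb_sample(600, 0.2, mu, 2.0, seed=3)
        res = lrt_test(y, make_design(groups), "DE")
        assert res.p_value < 1e-6
        assert res.df == 1
        # lfc on natural-log scale ~ log(3); log2 conversion consistent
        assert res.lfc == pytest.approx(np.log(3.0), abs=0.35)
        assert res.lfc_log2 == pytest.approx(res.lfc / np.log(2.0))

    def test_dzi_signal_detected(self):
        from scipy.special import expit, logit

        groups = np.repeat([0, 1], 400)
        pi = np.where(groups == 0, expit(logit(0.15)), expit(logit(0.15) + 2.0))
        rng = np.random.default_rng(4)
        nb = rng.negative_binomial(2.0, 2.0 / (2.0 + 6.0), size=800)
        y = np.where(rng.random(800) < pi, 0, nb)
        res = lrt_test(y, make_design(groups), "DZI")
        assert res.p_value < 1e-4
        assert res.lfc > 0.5  # positive logit shift recovered

    def test_statistic_invariant_to_reference_relabeling(self):
        groups = np.repeat([0, 1], 250)
        mu = np.where(groups == 0, 2.0, 5.0)
        y = zinb_sample(500, 0.25, mu, 1.5, seed=6)
        a = lrt_test(y, make_design(groups), "DE")
        b = lrt_test(y, make_design(1 - groups), "DE")
        assert a.stat == pytest.approx(b.stat, abs=1e-4)

    def test_single_group_rejected(self):
        y = zinb_sample(50, 0.2, 3.0, 1.0, seed=7)
        with pytest.raises(ValueError, match="group"):
            lrt_test(y, make_design(np.zeros(50, dtype=int)), "DE")

    def test_statistic_nonnegative(self):
        rng = np.random.default_rng(8)
        groups = np.repeat([0, 1], 150)
        for seed in range(6):
            y = zinb_sample(300, 0.4, 1.5, 1.0, seed=seed)
            for target in ("DE", "DZI"):
                res = lrt_test(y, make_design(groups), target)
                assert res.stat >= 0.0
                assert 0.0 <= res.p_value <= 1.0


class TestBH:
    def test_hand_computed_adjustment(self):
        adj, fdr = adjust_pvalues([0.01, 0.02, 0.03])
        np.testing.assert_allclose(adj, [0.03, 0.03, 0.03])
        np.testing.assert_allclose(fdr, adj)

    def test_all_ones(self):
        adj, _ = adjust_pvalues([1.0, 1.0, 1.0])
        np.testing.assert_allclose(adj, 1.0)

    def test_single_p_identity(self):
        adj, _ = adjust_pvalues([0.2])
        assert adj[0] == pytest.approx(0.2)

    def test_empty_input(self):
        adj, fdr = adjust_pvalues([])
        assert adj.size == 0 and fdr.size == 0

    def test_adjusted_at_least_raw_and_order_preserved(self, rng):
        p = rng.uniform(size=100)
        adj, _ = adjust_pvalues(p)
        assert np.all(adj >= p - 1e-15)
        order = np.argsort(p)
        assert np.all(np.diff(adj[order]) >= -1e-15)

    def test_fdr_controlled_on_mixture(self):
        # 10% true effects with tiny p-values; BH keeps FDP near alpha
        rng = np.random.default_rng(10)
        reps, fdps = 200, []
        for _ in range(reps):
            p_null = rng.uniform(size=900)
            p_alt = rng.uniform(0, 1e-5, size=100)
            p = np.concatenate([p_null, p_alt])
            truth = np.arange(1000) >= 900
            adj, _ = adjust_pvalues(p)
            sig = adj <= 0.05
            if sig.sum():
                fdps.append(np.sum(sig & ~truth) / sig.sum())
        assert np.mean(fdps) <= 0.05 + 2 * np.std(fdps) / np.sqrt(len(fdps))

    def test_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            adjust_pvalues([0.5, 1.2])


class TestClassification:
    @pytest.mark.parametrize("de,dzi,label", [
        (True, True, "DEZI"),
        (True, False, "DE_only"),
        (False, True, "DZI_only"),
        (False, False, "non_influential"),
    ])
    def test_label_map(self, de, dzi, label):
        assert classify_label(de, dzi) == label

    def test_classify_from_frames(self):
        de = pd.DataFrame({"gene_id": ["a", "b", "c", "d"],
                           "p_adjusted": [0.01, 0.01, 0.5, 0.9]})
        dzi = pd.DataFrame({"gene_id": ["a", "b", "c", "d"],
                            "p_adjusted": [0.02, 0.8, 0.03, 0.7]})
        classes = classify_genes(de, dzi, alpha=0.05)
        labels = {c.gene_id: c.label for c in classes}
        assert labels == {"a": "DEZI", "b": "DE_only", "c": "DZI_only",
                          "d": "non_influential"}

    def test_mismatched_gene_sets_rejected(self):
        de = pd.DataFrame({"gene_id": ["a", "b"], "p_adjusted": [0.1, 0.2]})
        dzi = pd.DataFrame({"gene_id": ["a", "c"], "p_adjusted": [0.1, 0.2]})
        with pytest.raises(ValueError, match="different gene sets"):
            classify_genes(de, dzi)

    def test_classes_partition_genes_end_to_end(self, small_dataset):
        design = make_design(small_dataset.cell_meta.group.to_numpy())
        frame = de_dzi_tests(
            small_dataset.observed, design,
            capture=small_dataset.cell_meta.p.to_numpy(),
        )
        per_gene = frame[frame.target == "DE"]
        counts = per_gene.gene_class.value_counts()
        assert counts.sum() == len(per_gene)
        assert set(counts.index) <= {"DEZI", "DE_only", "DZI_only", "non_influential"}
        # labels agree with the two significance flags
        dzi_sig = frame[frame.target == "DZI"].set_index("gene_id").significant
        for _, row in per_gene.iterrows():
            assert row.gene_class == classify_label(
                bool(row.significant), bool(dzi_sig[row.gene_id])
            )
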