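import numpy as np
import pytest

from mrxome.regulon import (
    Regulon,
    RegulonError,
    default_bins,
    infer_regulons,
    mutual_information,
    regulon_activity,
    regulon_phenotype_test,
)
from mrxome.summary_io import ExpressionStudy
from mrxome.synthetic import ExprSimConfig, TfSpec, gene_names, simulate_expression


def _study(values, labels=None):
    g, n = values.shape
    genes = [f"G{i:03d}" for i in range(g)]
    samples = [f"S{j:03d}" for j in range(n)]
    if labels is None:
        labels = ["active"] * (n // 2) + ["inactive"] * (n - n // 2)
    return ExpressionStudy(genes, samples, values, dict(zip(samples, labels)))


class TestMutualInformation:
    def test_perfect_dependence_is_log_bins(self):
        x = np.arange(64.0)
        assert mutual_information(x, x, bins=4) == pytest.approx(np.log(4))
        assert mutual_information(x, x) == pytest.approx(np.log(default_bins(64)))

    def test_symmetry(self, rng):
        x, y = rng.normal(size=50), rng.normal(size=50)
        assert mutual_information(x, y) == mutual_information(y, x)

    def test_nonnegative(self, rng):
        for _ in range(20):
            x, y = rng.normal(size=30), rng.normal(size=30)
            assert mutual_information(x, y) >= 0.0

    def test_length_mismatch_errors(self, rng):
        with pytest.raises(RegulonError):
            mutual_information(rng.normal(size=10), rng.normal(size=11))

    def test_too_short_errors(self, rng):
        with pytest.raises(RegulonError):
            mutual_information(rng.normal(size=5), rng.normal(size=5))

    def test_independence_calibration(self):
        # permutation p of MI between independent vectors exceeds 0.05 ~95% of the time
        keep = 0
        n_rep, n_perm = 60, 200
        for s in range(n_rep):
            r = np.random.default_rng(s)
            x, y = r.normal(size=200), r.normal(size=200)
            obs = mutual_information(x, y)
            null = np.array([
                mutual_information(x, r.permutation(y)) for _ in range(n_perm)
            ])
            p = (1 + np.sum(null >= obs)) / (n_perm + 1)
            keep += p > 0.05
        assert keep / n_rep >= 0.85

    def test_bivariate_normal_closed_form(self):
        rho = 0.8
        target = -0.5 * np.log(1 - rho ** 2)
        ests = []
        for s in range(5):
            r = np.random.default_rng(s)
            x = r.normal(size=2000)
            y = rho * x + np.sqrt(1 - rho ** 2) * r.normal(size=2000)
            ests.append(mutual_information(x, y))
        assert abs(np.mean(ests) - target) / target < 0.25


class TestInferRegulons:
    def test_planted_recovery(self):
        genes = gene_names(60)
        prec, rec = [], []
        for s in range(10):
            cfg = ExprSimConfig(
                n_genes=60, n_active=20, n_inactive=20,
                tf_specs=(TfSpec(genes[0], tuple(genes[1:11]), 1.5),), seed=s,
            )
            study, truth = simulate_expression(cfg)
            regs = infer_regulons(study, [genes[0]], n_perm=500, n_boot=50, seed=s)
            got, tru = set(regs[0].targets), set(truth.tf_targets[genes[0]])
            prec.append(len(got & tru) / max(len(got), 1))
            rec.append(len(got & tru) / len(tru))
        assert np.mean(prec) >= 0.9
        assert np.mean(rec) >= 0.8

    def test_null_tf_empty_regulon(self):
        genes = gene_names(50)
        sizes = []
        for s in range(5):
            cfg = ExprSimConfig(
                n_genes=50, n_active=20, n_inactive=20,
                tf_specs=(TfSpec(genes[0], tuple(genes[1:11]), 0.0),), seed=200 + s,
            )
            study, _ = simulate_expression(cfg)
            regs = infer_regulons(study, [genes[0]], n_perm=500, n_boot=50, seed=s)
            sizes.append(len(regs[0].targets))
        assert np.mean(sizes) < 0.01 * 50

    def test_dpi_removes_indirect_edge(self):
        removed = 0
        for s in range(10):
            r = np.random.default_rng(s)
            n = 100
            tf = r.normal(size=n)
            y = tf + 0.7 * r.normal(size=n)
            z = y + 0.7 * r.normal(size=n)
            vals = np.vstack([tf, y, z, r.normal(size=(5, n))])
            study = _study(vals)
            regs = infer_regulons(
                study, ["G000", "G001"], n_perm=500, n_boot=50, seed=s
            )
            by_tf = {reg.tf_id: reg for reg in regs}
            removed += "G002" not in by_tf["G000"].targets
        assert removed >= 9

    def test_dpi_tol_infinite_removes_nothing(self):
        r = np.random.default_rng(0)
        n = 100
        tf = r.normal(size=n)
        y = tf + 0.7 * r.normal(size=n)
        z = y + 0.7 * r.normal(size=n)
        vals = np.vstack([tf, y, z, r.normal(size=(5, n))])
        study = _study(vals)
        kwargs = dict(n_perm=300, n_boot=30, seed=0)
        pruned = infer_regulons(study, ["G000", "G001"], dpi_tol=0.0, **kwargs)
        unpruned = infer_regulons(study, ["G000", "G001"], dpi_tol=np.inf, **kwargs)
        n_pruned = sum(len(r.targets) for r in pruned)
        n_unpruned = sum(len(r.targets) for r in unpruned)
        assert n_pruned <= n_unpruned

    def test_gene_order_invariance(self):
        genes = gene_names(30)
        cfg = ExprSimConfig(
            n_genes=30, n_active=10, n_inactive=10,
            tf_specs=(TfSpec(genes[0], tuple(genes[1:6]), 2.0),), seed=4,
        )
        study, _ = simulate_expression(cfg)
        perm = np.random.default_rng(1).permutation(30)
        shuffled = ExpressionStudy(
            [study.gene_ids[i] for i in perm], list(study.sample_ids),
            study.values[perm], dict(study.phenotype),
        )
        a = infer_regulons(study, [genes[0]], n_perm=300, n_boot=30, seed=9)
        b = infer_regulons(shuffled, [genes[0]], n_perm=300, n_boot=30, seed=9)
        assert a[0].targets == b[0].targets

    def test_signs_follow_direction(self):
        r = np.random.default_rng(3)
        n = 60
        tf = r.normal(size=n)
        up = tf * 2 + 0.3 * r.normal(size=n)
        down = -tf * 2 + 0.3 * r.normal(size=n)
        vals = np.vstack([tf, up, down, r.normal(size=(4, n))])
        study = _study(vals)
        regs = infer_regulons(study, ["G000"], n_perm=300, n_boot=30, seed=2)
        targets = regs[0].targets
        assert targets["G001"][1] == 1
        assert targets["G002"][1] == -1

    def test_few_samples_errors(self, rng):
        study = _study(rng.normal(size=(10, 6)))
        with pytest.raises(RegulonError):
            infer_regulons(study, ["G000"], seed=1)

    def test_unknown_tf_errors(self, rng):
        study = _study(rng.normal(size=(10, 20)))
        with pytest.raises(RegulonError, match="ZZZ"):
            infer_regulons(study, ["ZZZ"], seed=1)


class TestRegulonActivity:
    def test_positive_targets_at_top_maximal(self, rng):
        vals = rng.normal(size=(10, 3))
        vals[:3, 0] += 100.0  # targets at the very top of sample 0
        study = _study(vals, labels=["active", "active", "inactive"])
        reg = Regulon("TF", {"G000": (1.0, 1), "G001": (1.0, 1), "G002": (1.0, 1)})
        act = regulon_activity(study, [reg])
        assert act.values[0, 0] == act.values[0].max()

    def test_sign_negation_negates_activity(self, rng):
        vals = rng.normal(size=(12, 5))
        study = _study(vals, labels=["active"] * 5)
        reg = Regulon("TF", {"G001": (1.0, 1), "G002": (1.0, -1), "G003": (1.0, 1)})
        neg = Regulon("TF", {g: (mi, -s) for g, (mi, s) in reg.targets.items()})
        a = regulon_activity(study, [reg]).values
        b = regulon_activity(study, [neg]).values
        np.testing.assert_allclose(a, -b, atol=1e-12)

    def test_group_separation_of_planted_tf(self):
        # activity of a TF whose effect differs by group separates the groups
        from scipy.stats import mannwhitneyu

        seps = 0
        for s in range(10):
            r = np.random.default_rng(s)
            n_a, n_b = 10, 10
            tf = np.concatenate([r.normal(1.5, 1, n_a), r.normal(-1.5, 1, n_b)])
            targets = tf * 1.5 + r.normal(0, 1, (8, n_a + n_b))
            vals = np.vstack([tf, targets, r.normal(size=(20, n_a + n_b))])
            study = _study(vals)
            reg = Regulon(
                "G000", {f"G{i:03d}": (1.0, 1) for i in range(1, 9)}
            )
            act = regulon_activity(study, [reg]).values[0]
            p = mannwhitneyu(act[:n_a], act[n_a:]).pvalue
            seps += p < 0.05
        assert seps >= 8

    def test_unusable_regulon_skipped_with_warning(self, rng, caplog):
        study = _study(rng.normal(size=(5, 4)))
        bad = Regulon("TF_BAD", {"NOT_PRESENT": (1.0, 1)})
        ok = Regulon("TF_OK", {"G001": (1.0, 1)})
        with caplog.at_level("WARNING"):
            act = regulon_activity(study, [bad, ok])
        assert act.tf_ids == ["TF_OK"]
        assert any("TF_BAD" in m for m in caplog.messages)


class TestPhenotypeTest:
    def _planted_study(self, seed):
        r = np.random.default_rng(seed)
        n_a = n_b = 10
        labels = ["active"] * n_a + ["inactive"] * n_b
        group = np.array([1.0] * n_a + [-1.0] * n_b)
        up = group[None, :] * 1.0 + r.normal(0, 1, (6, n_a + n_b))
        down = -group[None, :] * 1.0 + r.normal(0, 1, (6, n_a + n_b))
        rest = r.normal(size=(30, n_a + n_b))
        study = _study(np.vstack([up, down, rest]), labels=labels)
        reg = Regulon("TF", {
            **{f"G{i:03d}": (1.0, 1) for i in range(6)},
            **{f"G{i:03d}": (1.0, -1) for i in range(6, 12)},
        })
        return study, reg

    def test_two_tailed_power_and_direction(self):
        hits = 0
        for s in range(10):
            study, reg = self._planted_study(s)
            res = regulon_phenotype_test(
                study, [reg], tails="two", n_perm=200, seed=s
            )[0]
            hits += res.pval < 0.05 and res.direction == "positive"
        assert hits >= 9

    def test_one_tailed_runs(self):
        study, reg = self._planted_study(0)
        res = regulon_phenotype_test(study, [reg], tails="one", n_perm=200, seed=1)[0]
        assert res.direction is None and 0 < res.pval <= 1

    def test_null_calibration(self):
        pvals = []
        for s in range(40):
            r = np.random.default_rng(1000 + s)
            study = _study(r.normal(size=(30, 20)))
            reg = Regulon("TF", {f"G{i:03d}": (1.0, 1) for i in range(5)})
            res = regulon_phenotype_test(
                study, [reg], tails="two", n_perm=100, seed=s
            )[0]
            pvals.append(res.pval)
        assert 0.2 < np.mean(pvals) < 0.8  # roughly uniform null

    def test_unknown_tails_errors(self, rng):
        study = _study(rng.normal(size=(6, 10)))
        reg = Regulon("TF", {"G001": (1.0, 1)})
        with pytest.raises(RegulonError):
            regulon_phenotype_test(study, [reg], tails="three", seed=1)

    def test_disjoint_regulon_errors(self, rng):
        study = _study(rng.normal(size=(6, 10)))
        reg = Regulon("TF", {"ABSENT": (1.0, 1)})
        with pytest.raises(RegulonError, match="TF"):
            regulon_phenotype_test(study, [reg], tails="one", seed=1)
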