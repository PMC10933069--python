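import numpy as np
import pandas as pd
import pytest

from mrxome.cell_scores import (
    CellScoreError,
    CellScoreMatrix,
    correlate_genes_cells,
    lasso_select,
    score_cell_types,
    spillover_correct,
    univariate_screen,
)
from mrxome.enrichment import ssgsea_score
from mrxome.summary_io import (
    ExpressionStudy,
    GeneSetCollection,
    SignatureCollection,
)
from mrxome.synthetic import CellSpec, ExprSimConfig, gene_names, simulate_expression


def _study(rng, n_genes=30, n_per=10):
    genes = [f"G{i:03d}" for i in range(n_genes)]
    samples = [f"S{j:03d}" for j in range(2 * n_per)]
    labels = ["active"] * n_per + ["inactive"] * n_per
    return ExpressionStudy(
        genes, samples, rng.normal(size=(n_genes, 2 * n_per)),
        dict(zip(samples, labels)),
    )


def _scores(values, labels=None, cell_types=None):
    n_cells, n_samples = values.shape
    cts = cell_types or [f"cell{i}" for i in range(n_cells)]
    return CellScoreMatrix(cts, [f"S{j:03d}" for j in range(n_samples)], values)


def _pheno(n_per):
    return {
        f"S{j:03d}": ("active" if j < n_per else "inactive") for j in range(2 * n_per)
    }


class TestScoreCellTypes:
    def test_single_signature_equals_ssgsea(self, rng):
        study = _study(rng)
        sig = SignatureCollection({"s1": ["G001", "G002"]}, {"s1": "cellA"})
        cell = score_cell_types(study, sig)
        direct = ssgsea_score(study, GeneSetCollection({"s1": ["G001", "G002"]}))
        np.testing.assert_allclose(cell.values[0], direct.values[0], atol=1e-12)

    def test_duplicate_signature_same_as_one(self, rng):
        study = _study(rng)
        one = score_cell_types(
            study, SignatureCollection({"a": ["G001", "G005"]}, {"a": "c"})
        )
        two = score_cell_types(
            study,
            SignatureCollection(
                {"a": ["G001", "G005"], "b": ["G001", "G005"]}, {"a": "c", "b": "c"}
            ),
        )
        np.testing.assert_allclose(one.values, two.values, atol=1e-12)

    def test_planted_cell_higher_in_active(self):
        genes = gene_names(60)
        spec = CellSpec("cellA", tuple(genes[10:20]), (("active", 1.5),))
        cfg = ExprSimConfig(
            n_genes=60, n_active=15, n_inactive=15, cell_specs=(spec,), seed=4
        )
        study, _ = simulate_expression(cfg)
        sig = SignatureCollection(
            {"sA": list(spec.signature_genes)}, {"sA": "cellA"}
        )
        scores = score_cell_types(study, sig)
        active = [j for j, s in enumerate(scores.sample_ids)
                  if study.phenotype[s] == "active"]
        inactive = [j for j, s in enumerate(scores.sample_ids)
                    if study.phenotype[s] == "inactive"]
        assert scores.values[0, active].mean() > scores.values[0, inactive].mean()

    def test_unusable_cell_type_dropped(self, rng):
        study = _study(rng)
        sig = SignatureCollection(
            {"ok": ["G001"], "gone": ["ZZZ"]}, {"ok": "cellA", "gone": "cellB"}
        )
        scores = score_cell_types(study, sig)
        assert scores.cell_types == ["cellA"]


class TestSpillover:
    def test_identity_clips_negatives(self, rng):
        raw = _scores(np.array([[1.0, -0.5], [0.3, 0.2]]))
        sp = pd.DataFrame(np.eye(2), index=raw.cell_types, columns=raw.cell_types)
        out = spillover_correct(raw, sp)
        np.testing.assert_allclose(out.values, [[1.0, 0.0], [0.3, 0.2]])
        assert out.provenance == "spillover_corrected"

    def test_constructed_inverse_problem(self, rng):
        k, n = 5, 8
        truth = rng.uniform(0.5, 2.0, (k, n))
        sp_vals = np.eye(k) + rng.uniform(0, 0.2, (k, k))
        cts = [f"cell{i}" for i in range(k)]
        sp = pd.DataFrame(sp_vals, index=cts, columns=cts)
        raw = _scores(sp_vals @ truth, cell_types=cts)
        out = spillover_correct(raw, sp)
        np.testing.assert_allclose(out.values, truth, atol=1e-6)

    def test_projection_property(self, rng):
        raw = _scores(rng.normal(size=(3, 6)))
        sp = pd.DataFrame(np.eye(3), index=raw.cell_types, columns=raw.cell_types)
        once = spillover_correct(raw, sp)
        twice = spillover_correct(once, sp)
        np.testing.assert_allclose(once.values, twice.values, atol=1e-12)

    def test_missing_cell_type_errors(self, rng):
        raw = _scores(rng.uniform(size=(2, 4)))
        sp = pd.DataFrame(np.eye(1), index=["cell0"], columns=["cell0"])
        with pytest.raises(CellScoreError, match="cell1"):
            spillover_correct(raw, sp)

    def test_singular_matrix_errors(self, rng):
        raw = _scores(rng.uniform(size=(2, 4)))
        sp = pd.DataFrame(np.ones((2, 2)), index=raw.cell_types, columns=raw.cell_types)
        with pytest.raises(CellScoreError, match="singular"):
            spillover_correct(raw, sp)


class TestUnivariateScreen:
    def test_null_size(self):
        flags = 0
        n_rep = 100
        for s in range(n_rep):
            r = np.random.default_rng(s)
            scores = _scores(r.normal(size=(1, 40)))
            out = univariate_screen(scores, _pheno(20))
            flags += out[0][1] < 0.05
        assert 0.01 <= flags / n_rep <= 0.10

    def test_separation_falls_back(self):
        r = np.random.default_rng(0)
        y = np.array([1.0] * 10 + [0.0] * 10)
        scores = _scores((y + 1e-4 * r.normal(size=20))[None, :])
        out = univariate_screen(scores, _pheno(10))
        assert out[0][1] < 0.05

    def test_single_cell_type(self, rng):
        scores = _scores(rng.normal(size=(1, 20)))
        out = univariate_screen(scores, _pheno(10))
        assert len(out) == 1

    def test_small_groups_error(self, rng):
        scores = _scores(rng.normal(size=(1, 4)))
        with pytest.raises(CellScoreError):
            univariate_screen(scores, _pheno(2))


class TestLassoSelect:
    def _make(self, seed, n_per=30, n_noise=9):
        r = np.random.default_rng(seed)
        y = np.array([1.0] * n_per + [0.0] * n_per)
        strong = y * 2.0 + r.normal(0, 1, 2 * n_per)
        noise = r.normal(size=(n_noise, 2 * n_per))
        values = np.vstack([strong[None, :], noise])
        cts = ["strong"] + [f"noise{i}" for i in range(n_noise)]
        return _scores(values, cell_types=cts), _pheno(n_per)

    def test_selection_benchmark(self):
        hits, false_counts = 0, []
        for s in range(15):
            scores, pheno = self._make(s)
            screened = [(c, 0.01) for c in scores.cell_types]  # bypass screen
            sel = lasso_select(scores, pheno, screened=screened, seed=s)
            names = [c for c, _ in sel.selected]
            hits += "strong" in names
            false_counts.append(len([c for c in names if c != "strong"]))
        assert hits >= 14
        assert np.median(false_counts) <= 1

    def test_path_monotone_active_sets(self):
        scores, pheno = self._make(3)
        screened = [(c, 0.01) for c in scores.cell_types]
        sel = lasso_select(scores, pheno, screened=screened, seed=3)
        counts = sel.path_active_counts  # lambdas descend -> counts nondecreasing
        assert all(a <= b for a, b in zip(counts, counts[1:]))

    def test_seed_determinism(self):
        scores, pheno = self._make(5)
        screened = [(c, 0.01) for c in scores.cell_types]
        a = lasso_select(scores, pheno, screened=screened, seed=11)
        b = lasso_select(scores, pheno, screened=screened, seed=11)
        assert a.selected == b.selected and a.lambda_chosen == b.lambda_chosen

    def test_too_few_screened_errors(self, rng):
        scores = _scores(rng.normal(size=(3, 20)))
        with pytest.raises(CellScoreError):
            lasso_select(scores, _pheno(10), screened=[("cell0", 0.01),
                                                       ("cell1", 0.9),
                                                       ("cell2", 0.9)])

    def test_selected_subset_of_screened(self):
        scores, pheno = self._make(7)
        screened = [(c, 0.01 if i < 5 else 0.9) for i, c in enumerate(scores.cell_types)]
        sel = lasso_select(scores, pheno, screened=screened, seed=7)
        kept = {c for c, p in screened if p < 0.05}
        assert {c for c, _ in sel.selected} <= kept


class TestCorrelateGenesCells:
    def test_gene_equal_to_score(self, rng):
        study = _study(rng, n_genes=5, n_per=10)
        scores = _scores(study.values[:1].copy(), cell_types=["cellA"])
        r, p, counts = correlate_genes_cells(study, scores, gene_ids=["G000"])
        assert r.loc["G000", "cellA"] == pytest.approx(1.0)
        assert p.loc["G000", "cellA"] < 1e-10
        assert counts["G000"] == 1

    def test_independent_rate(self):
        sig = 0
        total = 0
        for s in range(30):
            r = np.random.default_rng(s)
            study = _study(r, n_genes=10, n_per=15)
            scores = _scores(r.normal(size=(4, 30)))
            _, p, _ = correlate_genes_cells(study, scores)
            sig += (p.to_numpy() < 0.05).sum()
            total += p.size
        assert 0.02 <= sig / total <= 0.08

    def test_zero_variance_reported_missing(self, rng):
        study = _study(rng, n_genes=3, n_per=5)
        study.values[0] = 1.0
        scores = _scores(rng.normal(size=(2, 10)))
        r, p, _ = correlate_genes_cells(study, scores)
        assert np.isnan(r.loc["G000"]).all()

    def test_two_samples_error(self, rng):
        study = ExpressionStudy(
            ["G1"], ["S000", "S001"], rng.normal(size=(1, 2)),
            {"S000": "active", "S001": "inactive"},
        )
        scores = _scores(rng.normal(size=(1, 2)))
        with pytest.raises(CellScoreError):
            correlate_genes_cells(study, scores)

    def test_full_layer_recovery(self):
        # planted abundant cell type survives score -> correct -> screen -> select
        genes = gene_names(80)
        hits = 0
        for s in range(10):
            spec = CellSpec("target", tuple(genes[0:10]), (("active", 1.0),))
            cfg = ExprSimConfig(
                n_genes=80, n_active=30, n_inactive=30, cell_specs=(spec,), seed=s
            )
            study, _ = simulate_expression(cfg)
            sigs = {"t1": genes[0:5], "t2": genes[5:10]}
            cell_of = {"t1": "target", "t2": "target"}
            for i in range(5):
                sigs[f"n{i}"] = genes[20 + 6 * i: 26 + 6 * i]
                cell_of[f"n{i}"] = f"noise{i}"
            raw = score_cell_types(study, SignatureCollection(sigs, cell_of))
            k = len(raw.cell_types)
            sp = pd.DataFrame(np.eye(k), index=raw.cell_types, columns=raw.cell_types)
            corrected = spillover_correct(raw, sp)
            screened = univariate_screen(corrected, study.phenotype)
            screened_sig = [c for c, p in screened if p < 0.05]
            if len(screened_sig) < 2:
                hits += "target" in screened_sig
                continue
            sel = lasso_select(corrected, study.phenotype, screened=screened, seed=s)
            hits += "target" in [c for c, _ in sel.selected]
        assert hits >= 8
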