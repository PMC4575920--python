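"""Signature scoring, labels, and the seeded ensemble's fast properties."""

import numpy as np
import pandas as pd
import pytest

from sigforest.signature import (
    EnsembleConfig,
    SignatureForestSelector,
    build_class_labels,
    extract_predictive_set,
    max_score,
    rf_score,
    run_signature_discovery,
    score_candidates,
)
from sigforest.counts import compute_fold_changes, encode_fold_changes, estimate_size_factors
from sigforest.simulate import SimulationConfig, generate_paired_counts


class TestScore:
    def test_printed_extremes(self):
        assert rf_score(100.0, 500, 2) == 25000.0
        assert max_score(500) == 25000.0

    def test_direct_arithmetic(self):
        assert rf_score(80.0, 250, 4) == 5000.0
        assert rf_score(0.0, 499, 2) == 0.0

    def test_validation(self):
        with pytest.raises(ValueError, match="sensitivity"):
            rf_score(101.0, 1, 2)
        with pytest.raises(ValueError, match="ni"):
            rf_score(50.0, 0, 2)
        with pytest.raises(ValueError, match="at least 2"):
            rf_score(50.0, 1, 1)

    def test_identity_bound_and_monotonicity_on_random_triples(self, rng):
        n_seeds = 500
        for _ in range(1000):
            s = float(rng.uniform(0, 100))
            ni = int(rng.integers(1, n_seeds + 1))
            ng = int(rng.integers(2, 12))
            r = rf_score(s, ni, ng)
            assert r * ng == pytest.approx(s * ni, abs=1e-9)
            assert r <= max_score(n_seeds) + 1e-9
            assert rf_score(min(s + 1, 100.0), ni, ng) >= r
            assert rf_score(s, min(ni + 1, n_seeds), ng) >= r
            assert rf_score(s, ni, ng + 1) <= r


class TestScoreCandidates:
    def test_aggregation_and_ranking(self):
        ex = [(("b", "a"), 100.0), (("a", "b"), 90.0), (("c", "d", "e"), 100.0)]
        cands = score_candidates(ex, n_seeds_total=10)
        assert cands[0].genes == ("a", "b")
        assert cands[0].ni == 2
        assert cands[0].sensitivity == 95.0
        assert cands[0].score == 95.0 * 2 / 2
        assert cands[1].genes == ("c", "d", "e")
        assert sum(c.ni for c in cands) == 3

    def test_tie_break_smaller_set_then_lexicographic(self):
        ex = [(("a", "b"), 50.0), (("c", "d", "e"), 75.0), (("a", "c"), 50.0)]
        cands = score_candidates(ex, 3)
        # scores: ab=25, cde=25, ac=25 -> size then gene order
        assert [c.genes for c in cands] == [("a", "b"), ("a", "c"), ("c", "d", "e")]

    def test_more_extractions_than_seeds_rejected(self):
        with pytest.raises(ValueError, match="seeds"):
            score_candidates([(("a", "b"), 1.0)] * 3, 2)


class TestLabels:
    @staticmethod
    def sheet(classes):
        rows = []
        for i, c in enumerate(classes):
            pair = f"P{i:02d}"
            for cond in ("tumor", "normal"):
                rows.append({"sample_id": f"{pair}{cond[0]}", "pair_id": pair,
                             "condition": cond, "class": c})
        return pd.DataFrame(rows).set_index("sample_id")

    def test_eleven_vs_twentynine(self):
        labels = build_class_labels(self.sheet(["A"] * 11 + ["B"] * 29))
        assert int(labels.sum()) == 11
        assert len(labels) == 40

    def test_swapped_scheme_complements(self):
        sheet = self.sheet(["A", "B", "B"])
        a = build_class_labels(sheet, positive_classes=("A",))
        b = build_class_labels(sheet, positive_classes=("B",))
        assert (a + b == 1).all()

    def test_single_class_degenerate(self):
        with pytest.raises(ValueError, match="one class"):
            build_class_labels(self.sheet(["A", "A"]))


def _toy_dataset(seed=1, n_genes=12, n_a=6, n_b=10):
    cfg = SimulationConfig(n_genes=n_genes, n_pairs_classA=n_a, n_pairs_classB=n_b,
                           signature_genes=("G00003", "G00008"), seed=seed)
    cm = generate_paired_counts(cfg)
    sf = estimate_size_factors(cm)
    enc = encode_fold_changes(compute_fold_changes(cm, sf))
    labels = build_class_labels(cm.samples)
    return enc, labels


class TestEnsemble:
    def test_config_validation(self):
        with pytest.raises(ValueError, match="duplicate"):
            EnsembleConfig(seeds=(1, 1, 2))
        with pytest.raises(ValueError, match="non-empty"):
            EnsembleConfig(seeds=())
        with pytest.raises(ValueError, match="at least 2"):
            EnsembleConfig(max_set_size=1)

    def test_extraction_deterministic(self):
        enc, labels = _toy_dataset()
        cfg = EnsembleConfig(seeds=(42,), max_set_size=3,
                             trees_per_forest=30, eval_trees=30)
        a = extract_predictive_set(enc, labels, 42, cfg)
        b = extract_predictive_set(enc, labels, 42, cfg)
        assert a == b
        genes, s = a
        assert 2 <= len(genes) <= 3
        assert 0.0 <= s <= 100.0

    def test_single_seed_run_has_ni_one(self):
        enc, labels = _toy_dataset()
        cfg = EnsembleConfig(seeds=(42,), max_set_size=3,
                             trees_per_forest=30, eval_trees=30)
        sel = run_signature_discovery(enc, labels, cfg)
        best = sel.best_candidate_
        assert best.ni == 1
        assert best.score == pytest.approx(best.sensitivity / best.ng)
        assert sel.manifest_["seeds"] == [42]

    def test_ni_sums_to_seed_count_and_run_is_reproducible(self):
        enc, labels = _toy_dataset(seed=2)
        cfg = EnsembleConfig(seeds=tuple(range(1, 13)), max_set_size=3,
                             trees_per_forest=30, eval_trees=30)
        sel1 = run_signature_discovery(enc, labels, cfg)
        sel2 = run_signature_discovery(enc, labels, cfg)
        assert sum(c.ni for c in sel1.candidates_) == 12
        assert sel1.manifest_ == sel2.manifest_
        for c in sel1.candidates_:
            assert c.score * c.ng == pytest.approx(c.sensitivity * c.ni)
            assert c.score <= max_score(12)

    def test_perfect_separator_is_extracted(self, rng):
        """A gene whose symbol perfectly splits the classes joins the
        predictive set in nearly every seed."""
        n_a, n_b, n_genes = 8, 12, 10
        X = rng.choice(["D", "U"], size=(n_a + n_b, n_genes)).astype("<U1")
        X[:n_a, 0] = "U"
        X[n_a:, 0] = "D"
        y = np.array([1] * n_a + [0] * n_b)
        sel = SignatureForestSelector(seeds=tuple(range(1, 41)), max_set_size=3,
                                      trees_per_forest=40, eval_trees=60).fit(X, y)
        hit = sum(c.ni for c in sel.candidates_ if "f0" in c.genes)
        assert hit >= 38  # >= 95% of seeds
        assert "f0" in sel.best_candidate_.genes
        assert sel.get_support().sum() == sel.best_candidate_.ng

    def test_symbol_outside_alphabet_rejected(self):
        X = np.array([["D", "U"], ["U", "Z"], ["D", "D"], ["U", "D"]])
        with pytest.raises(ValueError, match="D/U/X"):
            SignatureForestSelector(seeds=(1,)).fit(X, [0, 1, 0, 1])

    def test_fewer_than_two_candidate_genes_rejected(self):
        X = np.array([["D"], ["U"], ["D"], ["U"]])
        with pytest.raises(ValueError, match="at least 2"):
            SignatureForestSelector(seeds=(1,)).fit(X, [0, 1, 0, 1])

    def test_restricting_candidate_genes(self):
        enc, labels = _toy_dataset(seed=3)
        cfg = EnsembleConfig(seeds=(1, 2), max_set_size=2,
                             trees_per_forest=20, eval_trees=20)
        keep = list(enc.index[:6])
        sel = run_signature_discovery(enc, labels, cfg, candidate_genes=keep)
        assert set(sel.best_candidate_.genes) <= set(keep)
        with pytest.raises(ValueError, match="absent"):
            run_signature_discovery(enc, labels, cfg, candidate_genes=["nope", "nah"])
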