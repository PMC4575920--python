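"""Seeded random-forest ensemble discovery of minimal gene signatures.

Classifier features are the D/U/X-encoded tumor/normal fold changes of
candidate genes; observations are tumor/normal pairs; the label
separates larynx/hypopharynx-type pairs (positive) from oral-cavity-type
pairs (negative).  One forest is grown per seed; each seed contributes a
small "predictive set" of genes together with its sensitivity S (percent
of positive pairs recovered).  Identical sets are aggregated across
seeds and ranked by the signature score

    R = S * ni / ng

with ni the number of seeds extracting that exact set and ng the set
size.  With 500 seeds, S capped at 100 and sets of at least two genes,
the score ceiling is 100 * 500 / 2 = 25000.

Each seed perturbs the data (a stratified subsample of the training
pairs) and the forests (bootstrap and feature subsampling), trains a
ranking forest on all candidate genes, ranks genes by impurity
importance (summed over a gene's three symbol indicators), and then
backward-eliminates from the top-``max_set_size`` prefix: a gene is
dropped while its removal does not worsen the pair (out-of-bag balanced
accuracy, sensitivity), stopping at two genes.  Recurrence across seeds
is therefore stability under data perturbation: a chance-correlated set
rarely survives resampling, a real signature does.  Pairs a forest was
trained on are always judged out-of-bag so a memorized forest cannot
trivially report 100; a flag restores literal resubstitution.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator
from sklearn.ensemble import RandomForestClassifier
from sklearn.utils.validation import check_is_fitted

__all__ = [
    "EnsembleConfig",
    "SignatureCandidate",
    "rf_score",
    "max_score",
    "build_class_labels",
    "extract_predictive_set",
    "score_candidates",
    "run_signature_discovery",
    "SignatureForestSelector",
]

_SYMBOLS = ("D", "U", "X")


def rf_score(sensitivity: float, ni: int, ng: int) -> float:
    """Signature score R = S * ni / ng.

    ``sensitivity`` is on the 0-100 percent scale, ``ni`` counts the
    seeds in which the set recurred and ``ng`` is the set size (minimum
    2), so larger, rarely-recurring or poorly-detecting sets score low.
    """
    if not 0.0 <= sensitivity <= 100.0:
        raise ValueError("sensitivity must lie in [0, 100]")
    if ni <= 0:
        raise ValueError("ni must be a positive count")
    if ng < 2:
        raise ValueError("a signature has at least 2 genes")
    return sensitivity * ni / ng


def max_score(n_seeds: int) -> float:
    """Score ceiling: S=100 repeated in every seed at the minimum set
    size of 2, i.e. 100 * n_seeds / 2 (25000 for 500 seeds)."""
    if n_seeds <= 0:
        raise ValueError("n_seeds must be positive")
    return 100.0 * n_seeds / 2.0


@dataclass
class EnsembleConfig:
    """Configuration of the seeded ensemble.

    ``seeds`` defaults to 1..500.  ``training_classes`` /
    ``prediction_classes`` restrict which pair classes are used to grow
    the forests and to measure sensitivity; ``None`` uses all pairs for
    both, in which case sensitivity is out-of-bag unless
    ``resubstitution`` is set.
    """

    seeds: Sequence[int] = field(default_factory=lambda: tuple(range(1, 501)))
    max_set_size: int = 10
    trees_per_forest: int = 500
    eval_trees: int = 200
    subsample_fraction: float = 0.8
    training_classes: frozenset | None = None
    prediction_classes: frozenset | None = None
    resubstitution: bool = False
    # unweighted trees resolve uninformative regions to the majority
    # (negative) class; weighting them "balanced" lets a degenerate
    # mostly-positive classifier report high sensitivity on no signal
    class_weight: str | None = None

    def __post_init__(self) -> None:
        seeds = tuple(int(s) for s in self.seeds)
        if not seeds:
            raise ValueError("seeds must be non-empty")
        if len(set(seeds)) != len(seeds):
            raise ValueError("seeds must be duplicate-free")
        self.seeds = seeds
        if self.max_set_size < 2:
            raise ValueError("max_set_size must be at least 2")
        if self.trees_per_forest <= 0 or self.eval_trees <= 0:
            raise ValueError("forest sizes must be positive")
        if not 0.0 < self.subsample_fraction <= 1.0:
            raise ValueError("subsample_fraction must lie in (0, 1]")


@dataclass(frozen=True)
class SignatureCandidate:
    """A candidate gene signature with its aggregate score."""

    genes: tuple[str, ...]
    ni: int
    sensitivity: float  # percent, mean over the ni seeds
    score: float

    @property
    def ng(self) -> int:
        return len(self.genes)


def build_class_labels(samples: pd.DataFrame,
                       positive_classes: Iterable[str] = ("A",)) -> pd.Series:
    """Binary per-pair labels from the sample sheet's class column.

    Positive (1) = larynx/hypopharynx-type, negative (0) =
    oral-cavity-type.  Every pair must carry a known class and both
    classes must occur.
    """
    positive = set(positive_classes)
    per_pair = samples.groupby("pair_id", sort=False)["class"].agg(
        lambda s: s.dropna().unique()
    )
    labels = {}
    for pair, classes in per_pair.items():
        if len(classes) != 1:
            raise ValueError(f"pair {pair!r} has no unambiguous class: {list(classes)}")
        labels[pair] = int(classes[0] in positive)
    out = pd.Series(labels, name="label")
    if out.nunique() < 2:
        raise ValueError("all pairs fall in one class; classification is degenerate")
    return out


def _one_hot(X: np.ndarray) -> np.ndarray:
    """Indicator expansion of a pairs x genes symbol matrix; the three
    symbols are unordered categories, giving 3 columns per gene."""
    blocks = [(X == s) for s in _SYMBOLS]
    out = np.empty((X.shape[0], 3 * X.shape[1]), dtype=np.float64)
    for j, b in enumerate(blocks):
        out[:, j::3] = b
    return out


class SignatureForestSelector(BaseEstimator):
    """Scikit-learn style selector running the full seeded ensemble.

    ``fit`` expects ``X`` as a pairs x genes matrix over {D, U, X}
    (DataFrame or array) and ``y`` as binary pair labels (1 =
    positive class).  Fitted attributes:

    candidates_ : list[SignatureCandidate], ranked by score
    best_candidate_ : SignatureCandidate
    manifest_ : dict with config and per-seed outcomes
    """

    def __init__(self, seeds=tuple(range(1, 501)), max_set_size=10,
                 trees_per_forest=500, eval_trees=200, subsample_fraction=0.8,
                 resubstitution=False, class_weight=None,
                 train_mask=None, predict_mask=None):
        self.seeds = seeds
        self.max_set_size = max_set_size
        self.trees_per_forest = trees_per_forest
        self.eval_trees = eval_trees
        self.subsample_fraction = subsample_fraction
        self.resubstitution = resubstitution
        self.class_weight = class_weight
        self.train_mask = train_mask
        self.predict_mask = predict_mask

    # -- internals ---------------------------------------------------
    def _forest(self, seed: int) -> RandomForestClassifier:
        """Ranking forest: default feature subsampling keeps per-seed
        diversity in the importance ranking."""
        return RandomForestClassifier(
            n_estimators=self.trees_per_forest,
            random_state=seed,
            oob_score=True,
            class_weight=self.class_weight,
            n_jobs=None,
        )

    def _eval_forest(self, seed: int) -> RandomForestClassifier:
        """Evaluation forest, refit on the candidate subset alone with
        the ensemble seed: bagging over all features of the small
        subset, so out-of-bag recall reflects the subset rather than
        feature subsampling."""
        return RandomForestClassifier(
            n_estimators=self.eval_trees,
            random_state=seed,
            oob_score=True,
            class_weight=self.class_weight,
            max_features=None,
            n_jobs=None,
        )

    def _recalls(self, rf: RandomForestClassifier, Xoh, cols, y,
                 train_mask, pred_mask) -> tuple[float, float]:
        """(sensitivity, specificity) in percent on the prediction pairs.

        Prediction pairs the forest was trained on are judged
        out-of-bag (a memorized forest cannot trivially report 100),
        held-out pairs by direct prediction; ``resubstitution`` judges
        everything by direct prediction.
        """
        pred_rows = np.flatnonzero(pred_mask)
        y_pred = y[pred_rows]
        pos = y_pred == 1
        if not pos.any():
            raise ValueError("no positive-class pairs in the prediction set")
        pred = rf.predict(Xoh[np.ix_(pred_rows, cols)])
        seen = np.ones(len(pred_rows), dtype=bool)
        common = train_mask & pred_mask
        if not self.resubstitution and common.any():
            proba = rf.oob_decision_function_
            oob_ok = ~np.isnan(proba).any(axis=1)
            oob_cls = np.zeros(len(proba), dtype=int)
            oob_cls[oob_ok] = rf.classes_[np.argmax(proba[oob_ok], axis=1)]
            common_rows = np.flatnonzero(common)
            t_pos = np.searchsorted(np.flatnonzero(train_mask), common_rows)
            p_pos = np.searchsorted(pred_rows, common_rows)
            pred[p_pos] = oob_cls[t_pos]
            seen[p_pos[~oob_ok[t_pos]]] = False
        use_pos = pos & seen
        sens = 100.0 * float(np.mean(pred[use_pos] == 1)) if use_pos.any() else 0.0
        use_neg = ~pos & seen
        spec = 100.0 * float(np.mean(pred[use_neg] == 0)) if use_neg.any() else 0.0
        return sens, spec

    def _eval_subset(self, gene_idx: tuple[int, ...], seed: int, Xoh, y,
                     train_mask, pred_mask, cache: dict):
        """(sensitivity, specificity) of a forest refit on the subset
        alone with the ensemble seed; cached per (seed, subset)."""
        key = (seed, gene_idx)
        if key in cache:
            return cache[key]
        cols = np.sort(np.concatenate([3 * np.asarray(gene_idx) + j for j in range(3)]))
        rf = self._eval_forest(seed).fit(Xoh[train_mask][:, cols], y[train_mask])
        out = self._recalls(rf, Xoh, cols, y, train_mask, pred_mask)
        cache[key] = out
        return out

    def _subsample(self, y, train_idx, rng):
        """Per-seed stratified subsample of the training pairs: the
        stability-selection perturbation that makes recurrence (ni)
        informative — signal survives every subsample, chance
        correlations do not."""
        frac = self.subsample_fraction
        if frac >= 1.0:
            return train_idx
        keep = np.zeros_like(train_idx)
        for cls in np.unique(y[train_idx]):
            rows = np.flatnonzero(train_idx & (y == cls))
            k = min(len(rows), max(2, int(round(frac * len(rows)))))
            keep[rng.choice(rows, size=k, replace=False)] = True
        return keep

    def _extract_one(self, Xoh, y, genes, seed, train_idx, pred_idx, cache):
        rng = np.random.default_rng(seed)
        train_sub = self._subsample(y, train_idx, rng)
        rf = self._forest(seed).fit(Xoh[train_sub], y[train_sub])
        imp = rf.feature_importances_.reshape(-1, 3).sum(axis=1)
        # ties in importance (typically exact zeros) break per-seed at
        # random, so uninformative features cannot recur by name order
        order = np.lexsort((rng.random(len(genes)), -imp))
        k_max = min(self.max_set_size, len(genes))
        # backward elimination from the top-importance prefix: drop any
        # gene whose removal does not worsen the objective; stops at 2
        working = [int(i) for i in order[:k_max]]
        key = self._key(tuple(sorted(working)), seed, Xoh, y, train_sub,
                        pred_idx, cache)
        while len(working) > 2:
            best_drop, best_key = None, None
            for g in working:  # ranking order; later candidates win ties
                reduced = tuple(sorted(i for i in working if i != g))
                k_g = self._key(reduced, seed, Xoh, y, train_sub, pred_idx,
                                cache)
                if best_key is None or k_g >= best_key:
                    best_drop, best_key = g, k_g
            if best_key >= key:
                working.remove(best_drop)
                key = best_key
            else:
                break
        selected = tuple(sorted(str(g) for g in np.asarray(genes)[working]))
        return selected, key[-1]

    def _key(self, gene_idx, seed, Xoh, y, train_mask, pred_mask, cache):
        """Elimination objective: out-of-bag balanced accuracy, with
        sensitivity as the tie-break.  Sensitivity alone is maximized
        by the degenerate always-positive classifier and specificity
        alone by the always-negative one; their mean scores both at 50
        and rewards genuine discrimination.  The last element is the
        set's reported S."""
        sens, spec = self._eval_subset(gene_idx, seed, Xoh, y, train_mask,
                                       pred_mask, cache)
        return (sens + spec, sens, sens)

    # -- estimator API -----------------------------------------------
    def fit(self, X, y):
        if isinstance(X, pd.DataFrame):
            genes = [str(c) for c in X.columns]
            Xs = X.to_numpy(dtype="<U1")
        else:
            Xs = np.asarray(X, dtype="<U1")
            genes = [f"f{j}" for j in range(Xs.shape[1])]
        if Xs.shape[1] < 2:
            raise ValueError("need at least 2 candidate genes")
        bad = ~np.isin(Xs, _SYMBOLS)
        if bad.any():
            raise ValueError(f"symbols outside D/U/X found: {np.unique(Xs[bad])!r}")
        y = np.asarray(y, dtype=int)
        if y.shape[0] != Xs.shape[0]:
            raise ValueError("X and y disagree on the number of pairs")
        cfg_err = set(np.unique(y)) - {0, 1}
        if cfg_err:
            raise ValueError(f"labels must be binary 0/1, got extra {cfg_err}")
        seeds = tuple(int(s) for s in self.seeds)
        if not seeds or len(set(seeds)) != len(seeds):
            raise ValueError("seeds must be non-empty and duplicate-free")

        train_idx = (np.asarray(self.train_mask, dtype=bool)
                     if self.train_mask is not None else np.ones(len(y), dtype=bool))
        pred_idx = (np.asarray(self.predict_mask, dtype=bool)
                    if self.predict_mask is not None else np.ones(len(y), dtype=bool))
        if len(np.unique(y[train_idx])) < 2:
            raise ValueError("training pairs must contain both classes")

        Xoh = _one_hot(Xs)
        extractions = []
        cache: dict = {}
        for seed in seeds:
            selected, s = self._extract_one(Xoh, y, genes, seed, train_idx,
                                            pred_idx, cache)
            extractions.append((selected, s))
        self.extractions_ = extractions
        self.candidates_ = score_candidates(extractions, len(seeds))
        self.best_candidate_ = self.candidates_[0]
        self.feature_names_in_ = np.asarray(genes, dtype=object)
        self.n_features_in_ = len(genes)
        self.manifest_ = {
            "seeds": list(seeds),
            "config": {
                "max_set_size": int(self.max_set_size),
                "trees_per_forest": int(self.trees_per_forest),
                "eval_trees": int(self.eval_trees),
                "subsample_fraction": float(self.subsample_fraction),
                "resubstitution": bool(self.resubstitution),
                "class_weight": self.class_weight,
            },
            "n_pairs": int(len(y)),
            "n_candidate_genes": int(len(genes)),
            "per_seed": [
                {"seed": s, "genes": list(g), "sensitivity": sens}
                for s, (g, sens) in zip(seeds, extractions)
            ],
        }
        return self

    def get_support(self, indices: bool = False):
        check_is_fitted(self, "best_candidate_")
        mask = np.isin(self.feature_names_in_, self.best_candidate_.genes)
        return np.flatnonzero(mask) if indices else mask


def extract_predictive_set(
    encoded: pd.DataFrame, labels: pd.Series, seed: int, cfg: EnsembleConfig,
    classes: pd.Series | None = None,
) -> tuple[tuple[str, ...], float]:
    """Single-seed predictive set and its sensitivity (percent).

    ``encoded`` is genes x pairs over {D, U, X}; ``labels`` binary per
    pair.  Deterministic given identical inputs and seed.
    """
    sel = _selector_from_config(cfg, labels, classes, seeds=(seed,))
    sel.fit(encoded.T.loc[labels.index], labels.to_numpy())
    return sel.extractions_[0]


def score_candidates(
    extractions: Sequence[tuple[Sequence[str], float]], n_seeds_total: int
) -> list[SignatureCandidate]:
    """Aggregate per-seed extractions into ranked signature candidates.

    Identical sets (exact identity) are merged: ni is the recurrence
    count, S the mean of their per-seed sensitivities, R = S * ni / ng.
    Sorted by R descending, ties to smaller sets then lexicographic.
    """
    groups: dict[tuple[str, ...], list[float]] = {}
    for genes, s in extractions:
        key = tuple(sorted(genes))
        if not 0.0 <= s <= 100.0:
            raise ValueError(f"sensitivity {s} outside [0, 100]")
        groups.setdefault(key, []).append(float(s))
    if sum(len(v) for v in groups.values()) > n_seeds_total:
        raise ValueError("more extractions than seeds: inconsistent ensemble")
    candidates = []
    for genes, sens in groups.items():
        ni = len(sens)
        s_mean = float(np.mean(sens))
        candidates.append(
            SignatureCandidate(genes=genes, ni=ni, sensitivity=s_mean,
                               score=rf_score(s_mean, ni, len(genes)))
        )
    candidates.sort(key=lambda c: (-c.score, c.ng, c.genes))
    return candidates


def _selector_from_config(cfg: EnsembleConfig, labels: pd.Series,
                          classes: pd.Series | None,
                          seeds=None) -> SignatureForestSelector:
    train_mask = pred_mask = None
    if cfg.training_classes is not None or cfg.prediction_classes is not None:
        if classes is None:
            raise ValueError("per-pair classes required to restrict training/prediction")
        classes = classes.loc[labels.index]
        if cfg.training_classes is not None:
            train_mask = classes.isin(cfg.training_classes).to_numpy()
        if cfg.prediction_classes is not None:
            pred_mask = classes.isin(cfg.prediction_classes).to_numpy()
    return SignatureForestSelector(
        seeds=tuple(seeds if seeds is not None else cfg.seeds),
        max_set_size=cfg.max_set_size,
        trees_per_forest=cfg.trees_per_forest,
        eval_trees=cfg.eval_trees,
        subsample_fraction=cfg.subsample_fraction,
        resubstitution=cfg.resubstitution,
        class_weight=cfg.class_weight,
        train_mask=train_mask,
        predict_mask=pred_mask,
    )


def run_signature_discovery(
    encoded: pd.DataFrame,
    labels: pd.Series,
    cfg: EnsembleConfig | None = None,
    candidate_genes: Sequence[str] | None = None,
    classes: pd.Series | None = None,
):
    """Full ensemble run: one extraction per seed, aggregated scores.

    ``encoded`` is genes x pairs over {D, U, X}; ``labels`` binary per
    pair (index = pair IDs, 1 = positive class).  Returns the fitted
    :class:`SignatureForestSelector`, whose ``candidates_`` list is
    ranked and whose ``manifest_`` records seeds, config and per-seed
    outcomes.
    """
    cfg = cfg or EnsembleConfig()
    if candidate_genes is not None:
        missing = set(candidate_genes) - set(encoded.index)
        if missing:
            raise ValueError(f"candidate genes absent from encoded matrix: {sorted(missing)}")
        encoded = encoded.loc[list(candidate_genes)]
    sel = _selector_from_config(cfg, labels, classes)
    sel.fit(encoded.T.loc[labels.index], labels.to_numpy())
    return sel
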