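"""Count-matrix container, I/O, normalization, fold changes and D/U/X encoding.

The count matrix is genes x samples with a sample sheet carrying pair
identity, tumor/normal condition and a class label.  Normalization is
the median-of-ratios size-factor estimator; per-pair tumor/normal fold
changes of normalized counts are discretized to the three-letter
alphabet D (down, FC<1), U (up, FC>1), X (no change).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_array, check_is_fitted

__all__ = [
    "CountMatrix",
    "read_count_matrix",
    "filter_expressed_genes",
    "MedianOfRatiosNormalizer",
    "estimate_size_factors",
    "compute_fold_changes",
    "FoldChangeDiscretizer",
    "encode_fold_changes",
]

_CONDITIONS = ("tumor", "normal")


@dataclass
class CountMatrix:
    """Raw integer read counts (genes x samples) with sample metadata.

    ``samples`` is indexed by sample ID with columns ``pair_id``,
    ``condition`` (tumor/normal) and ``class``; ``truth`` optionally
    records planted effects for simulated data.
    """

    counts: pd.DataFrame
    samples: pd.DataFrame
    truth: dict | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        if self.counts.index.duplicated().any():
            dup = self.counts.index[self.counts.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicated gene IDs: {dup}")
        if self.counts.columns.duplicated().any():
            dup = self.counts.columns[self.counts.columns.duplicated()].unique().tolist()
            raise ValueError(f"duplicated sample IDs: {dup}")
        if self.samples.index.duplicated().any():
            dup = self.samples.index[self.samples.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicated sample IDs in sample sheet: {dup}")
        missing = set(self.samples.index) - set(self.counts.columns)
        if missing:
            raise ValueError(f"samples in sheet but not in count matrix: {sorted(missing)}")
        extra = set(self.counts.columns) - set(self.samples.index)
        if extra:
            raise ValueError(f"samples in count matrix but not in sheet: {sorted(extra)}")
        bad = self.samples.loc[~self.samples["condition"].isin(_CONDITIONS)]
        if len(bad):
            raise ValueError(f"condition must be tumor/normal; offending samples: {bad.index.tolist()}")
        vals = self.counts.to_numpy()
        if not np.issubdtype(vals.dtype, np.number):
            raise ValueError("non-numeric counts")
        if (vals < 0).any():
            g, s = np.argwhere(vals < 0)[0]
            raise ValueError(
                f"negative count at gene {self.counts.index[g]!r}, sample {self.counts.columns[s]!r}"
            )
        if not np.allclose(vals, np.round(vals)):
            g, s = np.argwhere(~np.isclose(vals, np.round(vals)))[0]
            raise ValueError(
                f"non-integer count at gene {self.counts.index[g]!r}, sample {self.counts.columns[s]!r}"
            )
        # align sheet order to matrix columns
        self.samples = self.samples.loc[self.counts.columns]

    @property
    def genes(self) -> list[str]:
        return self.counts.index.tolist()

    @property
    def sample_ids(self) -> list[str]:
        return self.counts.columns.tolist()

    @property
    def pair_ids(self) -> list[str]:
        seen: dict[str, None] = {}
        for p in self.samples["pair_id"]:
            seen.setdefault(p, None)
        return list(seen)

    def pair_columns(self) -> pd.DataFrame:
        """One row per pair with its tumor and normal sample IDs.

        Raises if any pair is incomplete or duplicated.
        """
        rows = []
        for pair, grp in self.samples.groupby("pair_id", sort=False):
            conds = grp["condition"].tolist()
            if sorted(conds) != ["normal", "tumor"]:
                raise ValueError(
                    f"pair {pair!r} must have exactly one tumor and one normal sample, got {conds}"
                )
            rows.append(
                {
                    "pair_id": pair,
                    "tumor": grp.index[grp["condition"] == "tumor"][0],
                    "normal": grp.index[grp["condition"] == "normal"][0],
                    "class": grp["class"].iloc[0] if "class" in grp else None,
                }
            )
        return pd.DataFrame(rows).set_index("pair_id")

    def subset_genes(self, genes) -> "CountMatrix":
        return CountMatrix(self.counts.loc[list(genes)], self.samples, self.truth)


def read_count_matrix(path, sample_sheet_path) -> CountMatrix:
    """Read a count TSV (first column gene ID) and a sample-sheet CSV."""
    counts = pd.read_csv(path, sep="\t", index_col=0)
    sheet = pd.read_csv(sample_sheet_path, index_col="sample_id")
    return CountMatrix(counts=counts, samples=sheet)


def filter_expressed_genes(m: CountMatrix) -> CountMatrix:
    """Keep genes with a non-zero read count in at least one sample."""
    keep = (m.counts > 0).any(axis=1)
    return CountMatrix(m.counts.loc[keep], m.samples, m.truth)


class MedianOfRatiosNormalizer(TransformerMixin, BaseEstimator):
    """Median-of-ratios depth normalization (samples x genes orientation).

    For each sample the size factor is the median, over genes with a
    strictly positive count in every sample, of that sample's count
    divided by the gene's geometric mean across samples.  ``transform``
    divides each sample's counts by its factor.
    """

    def fit(self, X, y=None):
        X = check_array(X, dtype="numeric", ensure_min_samples=2)
        if (X < 0).any():
            raise ValueError("counts must be non-negative")
        usable = (X > 0).all(axis=0)
        if not usable.any():
            raise ValueError(
                "no gene has non-zero counts in every sample; size factors are "
                "undefined — filter samples or add a pseudocount upstream"
            )
        Xu = X[:, usable]
        geomean = np.exp(np.log(Xu).mean(axis=0))
        self.size_factors_ = np.median(Xu / geomean, axis=1)
        self.n_features_in_ = X.shape[1]
        self.n_usable_genes_ = int(usable.sum())
        return self

    def transform(self, X):
        check_is_fitted(self, "size_factors_")
        X = check_array(X, dtype="numeric")
        if X.shape[0] != self.size_factors_.shape[0]:
            raise ValueError("transform expects the same samples used in fit")
        return X / self.size_factors_[:, None]


def estimate_size_factors(m: CountMatrix) -> pd.Series:
    """Per-sample median-of-ratios size factors for a CountMatrix."""
    norm = MedianOfRatiosNormalizer().fit(m.counts.to_numpy(dtype=float).T)
    return pd.Series(norm.size_factors_, index=m.sample_ids, name="size_factor")


def normalized_counts(m: CountMatrix, sf: pd.Series) -> pd.DataFrame:
    """Counts divided by their sample's size factor."""
    sf = sf.loc[m.sample_ids]
    if (sf <= 0).any():
        raise ValueError("size factors must be strictly positive")
    return m.counts / sf


def compute_fold_changes(
    m: CountMatrix, sf: pd.Series, pseudocount: float = 0.5
) -> pd.DataFrame:
    """Per-pair tumor/normal fold changes of normalized counts.

    FC(g, p) = (normalized tumor + pseudocount) / (normalized normal +
    pseudocount); the pseudocount keeps FC finite at zero-count normals
    and cancels when both members are zero.
    """
    if pseudocount <= 0:
        raise ValueError("pseudocount must be positive")
    pairs = m.pair_columns()
    norm = normalized_counts(m, sf)
    tumor = norm[pairs["tumor"].to_numpy()].to_numpy()
    normal = norm[pairs["normal"].to_numpy()].to_numpy()
    fc = (tumor + pseudocount) / (normal + pseudocount)
    out = pd.DataFrame(fc, index=m.genes, columns=pairs.index)
    out.attrs["pseudocount"] = float(pseudocount)
    return out


class FoldChangeDiscretizer(TransformerMixin, BaseEstimator):
    """Discretize fold changes to the D/U/X alphabet.

    FC < 1 - tol maps to D (down-regulated), FC > 1 + tol to U
    (up-regulated), and the remaining band to X (no change).  The
    default ``tol=0`` is the literal rule; a positive tolerance widens
    the X band, which is otherwise measure-zero on normalized data.
    """

    def __init__(self, tol: float = 0.0):
        self.tol = tol

    def fit(self, X, y=None):
        if self.tol < 0:
            raise ValueError("tol must be non-negative")
        self.n_features_in_ = np.asarray(X).shape[1] if np.ndim(X) == 2 else None
        return self

    def transform(self, X):
        if self.tol < 0:
            raise ValueError("tol must be non-negative")
        X = np.asarray(X, dtype=float)
        out = np.full(X.shape, "X", dtype="<U1")
        out[X < 1.0 - self.tol] = "D"
        out[X > 1.0 + self.tol] = "U"
        return out


def encode_fold_changes(fc: pd.DataFrame, tol: float = 0.0) -> pd.DataFrame:
    """D/U/X encoding of a genes x pairs fold-change matrix."""
    enc = FoldChangeDiscretizer(tol=tol).fit(fc.to_numpy()).transform(fc.to_numpy())
    return pd.DataFrame(enc, index=fc.index, columns=fc.columns)
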