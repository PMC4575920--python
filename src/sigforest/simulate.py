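"""Synthetic paired tumor/normal count data and Ct-value fixtures.

Everything downstream of sequencing is testable against data generated
here: negative-binomial count matrices with planted differential
expression, a planted class-discriminative tumor signature, and qPCR /
qMSP cycle-threshold tables that invert exactly under the delta-delta-Ct
operations when generated noiselessly.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .counts import CountMatrix

__all__ = [
    "SimulationConfig",
    "generate_paired_counts",
    "generate_ct_table",
    "write_count_matrix",
]

# Baseline expression spans low- and high-count regimes so that the
# median-of-ratios estimator is exercised both where it is well behaved
# and where it degrades.
_BASELINE_MEAN_RANGE = (5.0, 5000.0)
# Planted signature genes are drawn from the well-expressed range:
# usable expression markers are by construction detectably expressed.
_SIGNATURE_MEAN_RANGE = (200.0, 2000.0)


@dataclass
class SimulationConfig:
    """Conditions for one simulated paired discovery/validation cohort.

    Parameters
    ----------
    n_genes : int
        Number of genes in the simulated universe (IDs ``G00001`` ...).
    n_pairs_classA : int
        Tumor/normal pairs of the positive class (larynx/hypopharynx-like).
    n_pairs_classB : int
        Pairs of the negative class (oral-cavity-like).
    de_fraction : float
        Fraction of genes differentially expressed tumor-vs-normal in
        every pair regardless of class.
    de_log2fc_mean : float
        Signed log2 effect applied to the tumor mean of each planted DE
        gene (positive = up in tumor).
    signature_genes : sequence of str
        Gene IDs shifted in class-A tumors only; the planted
        discriminative signature to be recovered downstream.
    signature_log2fc : float
        log2 shift applied to signature genes where they are expressed.
        The default models an on/off marker (8-fold), the behavior of
        e.g. cancer-testis antigens.
    signature_pattern : str
        ``"mosaic"`` (default): marker expression is mutually exclusive
        across class-A tumors — the tumors partition round-robin over
        the signature genes and each tumor strongly expresses only its
        assigned marker, the behavior of mosaic markers such as
        cancer-testis antigens.  No proper subset of the signature then
        covers every positive pair, so the full set is genuinely
        minimal.  ``"uniform"``: every signature gene is shifted in
        every class-A tumor (fully redundant genes).  In both patterns
        signature genes are shifted only in class-A tumors.
    nb_dispersion : float
        Negative-binomial dispersion alpha, variance = mu + alpha*mu^2.
    size_factor_range : (float, float)
        Per-sample depth factors are drawn log-uniformly from this range.
    seed : int
        Root seed; each stage draws from its own child stream.
    """

    n_genes: int
    n_pairs_classA: int
    n_pairs_classB: int = 0
    de_fraction: float = 0.0
    de_log2fc_mean: float = 2.0
    signature_genes: Sequence[str] = field(default_factory=tuple)
    signature_log2fc: float = 3.0
    signature_pattern: str = "mosaic"
    nb_dispersion: float = 0.1
    size_factor_range: tuple[float, float] = (0.5, 2.0)
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_genes", "n_pairs_classA", "n_pairs_classB"):
            v = getattr(self, name)
            if not isinstance(v, (int, np.integer)) or isinstance(v, bool):
                raise ValueError(f"{name} must be an integer, got {v!r}")
        if self.n_genes <= 0:
            raise ValueError("n_genes must be positive")
        if self.n_pairs_classA <= 0:
            raise ValueError("n_pairs_classA must be positive")
        if self.n_pairs_classB < 0:
            raise ValueError("n_pairs_classB must be non-negative")
        if not 0.0 <= self.de_fraction <= 1.0:
            raise ValueError("de_fraction must lie in [0, 1]")
        if self.nb_dispersion < 0:
            raise ValueError("nb_dispersion must be non-negative")
        lo, hi = self.size_factor_range
        if not (0 < lo <= hi):
            raise ValueError("size_factor_range must be a positive interval")
        universe = set(self.gene_ids)
        unknown = [g for g in self.signature_genes if g not in universe]
        if unknown:
            raise ValueError(f"signature genes outside the gene universe: {unknown}")
        if len(set(self.signature_genes)) != len(self.signature_genes):
            raise ValueError("duplicate signature gene IDs")
        if self.signature_pattern not in ("mosaic", "uniform"):
            raise ValueError(f"unknown signature_pattern {self.signature_pattern!r}")

    @property
    def gene_ids(self) -> list[str]:
        return [f"G{i + 1:05d}" for i in range(self.n_genes)]


def _sample_sheet(config: SimulationConfig) -> pd.DataFrame:
    rows = []
    for cls, n in (("A", config.n_pairs_classA), ("B", config.n_pairs_classB)):
        for i in range(n):
            pair = f"{cls}{i + 1:02d}"
            for cond in ("tumor", "normal"):
                rows.append(
                    {
                        "sample_id": f"{pair}{cond[0].upper()}",
                        "pair_id": pair,
                        "condition": cond,
                        "class": cls,
                    }
                )
    return pd.DataFrame(rows).set_index("sample_id")


def generate_paired_counts(config: SimulationConfig) -> CountMatrix:
    """Simulate a genes x samples count matrix of matched pairs.

    Counts are negative binomial with gene baseline means log-uniform
    over ``[5, 5000]``, per-sample depth factors log-uniform over
    ``config.size_factor_range``, planted tumor/normal effects of
    ``de_log2fc_mean`` on a random ``de_fraction`` of non-signature
    genes, and the signature shift applied in class-A tumors only.
    Truth labels (which genes carry which planted effect) are attached
    as ``CountMatrix.truth``.
    """
    genes = config.gene_ids
    sheet = _sample_sheet(config)
    ss = np.random.SeedSequence(config.seed)
    rng_base, rng_de, rng_sf, rng_counts = (
        np.random.default_rng(s) for s in ss.spawn(4)
    )

    lo, hi = _BASELINE_MEAN_RANGE
    baseline = np.exp(rng_base.uniform(np.log(lo), np.log(hi), size=config.n_genes))
    sig_idx = np.array(
        [genes.index(g) for g in config.signature_genes], dtype=int
    )
    if sig_idx.size:
        slo, shi = _SIGNATURE_MEAN_RANGE
        baseline[sig_idx] = np.exp(
            rng_base.uniform(np.log(slo), np.log(shi), size=sig_idx.size)
        )

    n_de = int(round(config.de_fraction * config.n_genes))
    eligible = np.setdiff1d(np.arange(config.n_genes), sig_idx)
    if n_de > eligible.size:
        raise ValueError("de_fraction leaves no room for the signature genes")
    de_idx = np.sort(rng_de.choice(eligible, size=n_de, replace=False))

    slo, shi = config.size_factor_range
    sf = np.exp(rng_sf.uniform(np.log(slo), np.log(shi), size=len(sheet)))

    is_tumor = (sheet["condition"] == "tumor").to_numpy()
    is_classA = (sheet["class"] == "A").to_numpy()
    log2_effect = np.zeros((config.n_genes, len(sheet)))
    log2_effect[np.ix_(de_idx, is_tumor)] = config.de_log2fc_mean
    signature_assignment: dict[str, list[str]] = {}
    if sig_idx.size:
        a_tumor_cols = np.flatnonzero(is_tumor & is_classA)
        if config.signature_pattern == "uniform":
            log2_effect[np.ix_(sig_idx, a_tumor_cols)] = config.signature_log2fc
            signature_assignment = {
                genes[i]: [sheet.index[c] for c in a_tumor_cols] for i in sig_idx
            }
        else:  # mosaic: the positive-class tumors partition round-robin
            rng_sig = np.random.default_rng(ss.spawn(1)[0])
            order = rng_sig.permutation(a_tumor_cols)
            signature_assignment = {genes[i]: [] for i in sig_idx}
            for t, col in enumerate(order):
                gi_ = sig_idx[t % sig_idx.size]
                log2_effect[gi_, col] = config.signature_log2fc
                signature_assignment[genes[gi_]].append(str(sheet.index[col]))
            signature_assignment = {g: sorted(v) for g, v in signature_assignment.items()}

    mu = baseline[:, None] * 2.0 ** log2_effect * sf[None, :]
    alpha = config.nb_dispersion
    if alpha > 0:
        counts = rng_counts.negative_binomial(1.0 / alpha, 1.0 / (1.0 + alpha * mu))
    else:
        counts = rng_counts.poisson(mu)

    truth = {
        "de_genes": {genes[i]: float(config.de_log2fc_mean) for i in de_idx},
        "signature_genes": list(config.signature_genes),
        "signature_log2fc": float(config.signature_log2fc),
        "signature_pattern": config.signature_pattern,
        "signature_assignment": signature_assignment,
        "size_factors": {s: float(f) for s, f in zip(sheet.index, sf)},
        "seed": int(config.seed),
    }
    cm = CountMatrix(
        counts=pd.DataFrame(counts, index=genes, columns=sheet.index),
        samples=sheet,
        truth=truth,
    )
    return cm


def write_count_matrix(cm: CountMatrix, counts_path, sheet_path, truth_path=None) -> None:
    """Write a count matrix as TSV, its sample sheet as CSV and, when a
    path is given, the truth labels as a JSON sidecar."""
    out = cm.counts.copy()
    out.index.name = "gene"
    out.to_csv(counts_path, sep="\t")
    cm.samples.to_csv(sheet_path)
    if truth_path is not None:
        with open(truth_path, "w") as fh:
            json.dump(cm.truth or {}, fh, indent=2)


# Reference (beta-actin) cycle thresholds used when planting Ct values.
_CT_REFERENCE = 18.0
_CT_TARGET_BASE = 25.0
_QMSP_TOTAL_QUANTITY = 0.5  # target quantity relative to beta-actin


def generate_ct_table(
    n_samples: int,
    true_log2fc: Mapping[str, float] | None = None,
    true_meth_fraction: Sequence[float] | None = None,
    noise_sd: float = 0.0,
    seed: int = 0,
    meth_gene: str = "MTGT",
) -> pd.DataFrame:
    """Build a Ct table whose ideal delta-delta-Ct inversion is known.

    For each of ``n_samples`` pairs, qPCR rows (primer ``NA``) are
    planted per gene in ``true_log2fc`` so that the tumor-vs-normal
    beta-actin-normalized log2 fold change equals the requested value,
    and qMSP rows (primers ``M``/``U`` on the tumor sample) are planted
    so that the normalized percent methylation equals
    ``100 * true_meth_fraction``. Gaussian noise of ``noise_sd`` cycles
    is added to every Ct when requested.
    """
    if n_samples <= 0:
        raise ValueError("n_samples must be positive")
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    if true_meth_fraction is not None:
        if len(true_meth_fraction) != n_samples:
            raise ValueError("one methylation fraction per sample required")
        for f in true_meth_fraction:
            if not 0.0 < f < 1.0:
                raise ValueError(
                    f"methylation fraction {f} not in (0, 1): Ct would be infinite"
                )
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    rows: list[dict] = []
    for i in range(n_samples):
        sid = f"V{i + 1:02d}"
        if true_log2fc:
            for cond in ("tumor", "normal"):
                rows.append(
                    {"sample_id": sid, "condition": cond, "assay": "ACTB",
                     "primer": "NA", "ct": _CT_REFERENCE}
                )
            for j, (gene, lfc) in enumerate(sorted(true_log2fc.items())):
                base = _CT_TARGET_BASE + j  # distinct baseline per gene
                rows.append(
                    {"sample_id": sid, "condition": "normal", "assay": gene,
                     "primer": "NA", "ct": base}
                )
                rows.append(
                    {"sample_id": sid, "condition": "tumor", "assay": gene,
                     "primer": "NA", "ct": base - lfc}
                )
        if true_meth_fraction is not None:
            f = float(true_meth_fraction[i])
            for primer in ("M", "U"):
                rows.append(
                    {"sample_id": sid, "condition": "tumor", "assay": "ACTB",
                     "primer": primer, "ct": _CT_REFERENCE}
                )
            qm = f * _QMSP_TOTAL_QUANTITY
            qu = (1.0 - f) * _QMSP_TOTAL_QUANTITY
            rows.append(
                {"sample_id": sid, "condition": "tumor", "assay": meth_gene,
                 "primer": "M", "ct": _CT_REFERENCE - np.log2(qm)}
            )
            rows.append(
                {"sample_id": sid, "condition": "tumor", "assay": meth_gene,
                 "primer": "U", "ct": _CT_REFERENCE - np.log2(qu)}
            )
    table = pd.DataFrame(rows, columns=["sample_id", "condition", "assay", "primer", "ct"])
    if noise_sd > 0:
        table["ct"] = table["ct"] + rng.normal(0.0, noise_sd, size=len(table))
    return table
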