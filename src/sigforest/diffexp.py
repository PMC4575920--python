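"""Negative-binomial differential expression over three interpretations.

The three contrasts mirror a paired tumor/normal discovery design:

* ``TN_P``  — matched tumors vs their matched normals (pairs only),
* ``TN_UP`` — all tumors vs all normals, matched or not,
* ``T_P``   — one contrast per individual tumor/normal pair.

Each gene is tested with a conditional NB test: given the total of the
two group sums of normalized counts, the group-A sum follows a
beta-binomial under the null of equal expression, with shape parameters
set by moment-matching the NB model (per-gene dispersion estimated by
method of moments, pooled within groups, floored at 1e-8).  The
two-sided p-value is the summed probability of all outcomes no more
likely than the observed one.  Benjamini-Hochberg adjustment is applied
within each interpretation and the significant-gene selection is the
union over interpretations at the padj threshold.
"""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import gammaln, logsumexp
from statsmodels.stats.multitest import multipletests

from .counts import CountMatrix, normalized_counts

__all__ = [
    "nb_test_two_groups",
    "pooled_dispersion",
    "run_interpretations",
    "select_significant_genes",
]

_MIN_DISPERSION = 1e-8
# Cap on the NB size parameter: above this the NB is numerically
# indistinguishable from Poisson while gammaln differences lose precision.
_MAX_SIZE = 1e8


def _nb_logpmf(a: np.ndarray, m: float, r: float, logfact: np.ndarray) -> np.ndarray:
    """log NB pmf over the count vector ``a`` (mean m, size r)."""
    return (
        gammaln(a + r) - gammaln(r) - logfact[a]
        + r * np.log(r / (r + m)) + a * np.log(m / (m + r))
    )


def _conditional_pvalue(k_a: int, total: int, m_a: float, r_a: float,
                        m_b: float, r_b: float, logfact: np.ndarray) -> float:
    """Two-sided conditional NB tail given the total of both group sums.

    The group-A sum is NB(mean m_a, size r_a) and likewise for B; the
    conditional law of the A sum given the total is the product of the
    two pmfs renormalized over all splits.  The p-value is the summed
    probability of every split no more likely than the observed one.
    ``logfact[a]`` must hold log(a!) for a = 0..total.
    """
    if total == 0:
        return 1.0
    a = np.arange(total + 1)
    left = _nb_logpmf(a, m_a, r_a, logfact)
    if r_a == r_b and m_a == m_b:
        right = left[::-1]
    else:
        right = _nb_logpmf(a, m_b, r_b, logfact)[::-1]
    lp = left + right
    if not np.isfinite(lp).all():  # degenerate parameters: refuse to reject
        return 1.0
    lp -= logsumexp(lp)
    obs = lp[k_a]
    return min(float(np.exp(lp[lp <= obs + 1e-9]).sum()), 1.0)


def _dispersion_trend(alpha_raw: np.ndarray, q: np.ndarray) -> np.ndarray:
    """Fit alpha(q) = a0 + a1/q through the raw per-gene estimates.

    A gamma GLM with identity link on the positive raw estimates, the
    parametric mean-dispersion trend; falls back to the median raw
    estimate when too few genes are usable or the fit fails.
    """
    ok = (alpha_raw > 0) & (q > 0) & np.isfinite(alpha_raw)
    fallback = float(np.median(alpha_raw[ok])) if ok.any() else _MIN_DISPERSION
    out = np.full_like(q, max(fallback, _MIN_DISPERSION), dtype=float)
    if ok.sum() >= 50:
        import warnings

        import statsmodels.api as sm

        design = sm.add_constant(1.0 / q[ok])
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                fit = sm.GLM(alpha_raw[ok], design,
                             family=sm.families.Gamma(sm.families.links.Identity())).fit()
            coef = fit.params
            pred = coef[0] + coef[1] / np.where(q > 0, q, np.inf)
            if np.isfinite(pred[q > 0]).all():
                out = np.maximum(pred, _MIN_DISPERSION)
        except Exception:
            pass  # keep the constant fallback
    return out


def pooled_dispersion(m: CountMatrix, sf: pd.Series,
                      group_a: Sequence[str], group_b: Sequence[str],
                      mode: str = "trend") -> pd.Series:
    """Per-gene NB dispersion from normalized counts.

    The raw per-gene estimate is method of moments,
    alpha = (s2 - q*xi) / q^2, with s2 the within-group pooled sample
    variance, q the grand mean of normalized counts and xi the mean
    reciprocal size factor (the shot-noise scale of normalized counts).
    ``mode="trend"`` (default) replaces the noisy gene-wise values with
    a mean-dispersion trend fitted across genes, which keeps the test
    calibrated at moderate replication; ``mode="gene"`` floors the raw
    values at 1e-8 and uses them directly.
    """
    if mode not in ("trend", "gene"):
        raise ValueError(f"unknown dispersion mode {mode!r}")
    group_a, group_b = list(group_a), list(group_b)
    z = normalized_counts(m, sf)
    za, zb = z[group_a].to_numpy(), z[group_b].to_numpy()
    n_a, n_b = za.shape[1], zb.shape[1]
    q = np.concatenate([za, zb], axis=1).mean(axis=1)
    dof = max(n_a - 1, 0) + max(n_b - 1, 0)
    if dof == 0:
        raise ValueError("dispersion estimation needs replication in at least one group")
    ss = np.zeros_like(q)
    if n_a > 1:
        ss += za.var(axis=1, ddof=1) * (n_a - 1)
    if n_b > 1:
        ss += zb.var(axis=1, ddof=1) * (n_b - 1)
    s2 = ss / dof
    inv_sf = (1.0 / sf.loc[group_a + group_b]).mean()
    with np.errstate(divide="ignore", invalid="ignore"):
        alpha_raw = (s2 - q * inv_sf) / q**2
    alpha_raw = np.where(q > 0, alpha_raw, _MIN_DISPERSION)
    if mode == "trend":
        alpha = _dispersion_trend(alpha_raw, q)
    else:
        alpha = np.maximum(alpha_raw, _MIN_DISPERSION)
    return pd.Series(alpha, index=m.genes, name="dispersion")


def _nb_size(q: float, alpha: float, inv_sf_sum: float, n: int) -> float:
    """NB size parameter for a sum of n normalized counts with grand
    mean q, matching mean and variance (shot noise + overdispersion)."""
    mean = n * q
    var = q * inv_sf_sum + n * alpha * q**2
    excess = max(var - mean, mean / _MAX_SIZE)
    return min(mean**2 / excess, _MAX_SIZE)


def nb_test_two_groups(
    m: CountMatrix,
    sf: pd.Series,
    group_a: Sequence[str],
    group_b: Sequence[str],
    dispersion: pd.Series | None = None,
    pseudocount: float = 0.5,
) -> pd.DataFrame:
    """Test each gene for a difference between two sample groups.

    Returns a DataFrame indexed by gene with ``log2FC`` (positive =
    higher in ``group_a``) and ``pvalue`` columns.  ``dispersion``
    overrides the per-gene estimate; it is required when neither group
    has replication (the single-pair contrasts).
    """
    group_a, group_b = list(group_a), list(group_b)
    if not group_a or not group_b:
        raise ValueError("both groups must be non-empty")
    overlap = set(group_a) & set(group_b)
    if overlap:
        raise ValueError(f"groups overlap: {sorted(overlap)}")
    if dispersion is None:
        dispersion = pooled_dispersion(m, sf, group_a, group_b)
    alpha = dispersion.loc[m.genes].to_numpy(dtype=float)

    z = normalized_counts(m, sf)
    za, zb = z[group_a].to_numpy(), z[group_b].to_numpy()
    n_a, n_b = za.shape[1], zb.shape[1]
    sum_a, sum_b = za.sum(axis=1), zb.sum(axis=1)
    q = (sum_a + sum_b) / (n_a + n_b)
    inv_a = float((1.0 / sf.loc[group_a]).sum())
    inv_b = float((1.0 / sf.loc[group_b]).sum())

    k_a = np.rint(sum_a).astype(np.int64)
    k_b = np.rint(sum_b).astype(np.int64)
    totals = k_a + k_b
    logfact = gammaln(np.arange(1, int(totals.max()) + 2, dtype=float))

    pvals = np.ones(len(totals))
    for i in range(len(totals)):
        if totals[i] == 0 or q[i] <= 0:
            continue
        r_a = _nb_size(q[i], alpha[i], inv_a, n_a)
        r_b = _nb_size(q[i], alpha[i], inv_b, n_b)
        pvals[i] = _conditional_pvalue(int(k_a[i]), int(totals[i]),
                                       n_a * q[i], r_a, n_b * q[i], r_b, logfact)

    log2fc = np.log2((sum_a / n_a + pseudocount) / (sum_b / n_b + pseudocount))
    return pd.DataFrame({"log2FC": log2fc, "pvalue": pvals}, index=m.genes)


def _with_padj(res: pd.DataFrame) -> pd.DataFrame:
    res = res.copy()
    res["padj"] = multipletests(res["pvalue"].to_numpy(), method="fdr_bh")[1]
    return res


def run_interpretations(
    m: CountMatrix,
    sf: pd.Series,
    interpretations: Sequence[str] = ("TN_P", "TN_UP", "T_P"),
    pseudocount: float = 0.5,
) -> dict[str, pd.DataFrame]:
    """Run the requested differential-expression interpretations.

    Returns a mapping from interpretation label to a per-gene result
    table (``log2FC``, ``pvalue``, ``padj``).  Pair-wise results are
    keyed ``T_P:<pair_id>`` and use the per-gene dispersion pooled
    across all samples, since a single pair carries no replication.
    """
    tumors = m.samples.index[m.samples["condition"] == "tumor"].tolist()
    normals = m.samples.index[m.samples["condition"] == "normal"].tolist()
    paired = m.samples.groupby("pair_id")["condition"].nunique() == 2
    matched_pairs = paired.index[paired].tolist()

    out: dict[str, pd.DataFrame] = {}
    if "TN_P" in interpretations:
        if not matched_pairs:
            raise ValueError("TN_P requested but no matched tumor/normal pairs present")
        in_pair = m.samples["pair_id"].isin(matched_pairs)
        ta = m.samples.index[(m.samples["condition"] == "tumor") & in_pair].tolist()
        na = m.samples.index[(m.samples["condition"] == "normal") & in_pair].tolist()
        out["TN_P"] = _with_padj(nb_test_two_groups(m, sf, ta, na, pseudocount=pseudocount))
    if "TN_UP" in interpretations:
        out["TN_UP"] = _with_padj(nb_test_two_groups(m, sf, tumors, normals, pseudocount=pseudocount))
    if "T_P" in interpretations:
        if not matched_pairs:
            raise ValueError("T_P requested but no matched tumor/normal pairs present")
        disp = pooled_dispersion(m, sf, tumors, normals)
        pairs = m.pair_columns()
        for pair in matched_pairs:
            res = nb_test_two_groups(
                m, sf,
                [pairs.loc[pair, "tumor"]], [pairs.loc[pair, "normal"]],
                dispersion=disp, pseudocount=pseudocount,
            )
            out[f"T_P:{pair}"] = _with_padj(res)
    return out


def select_significant_genes(
    results: Mapping[str, pd.DataFrame], threshold: float = 0.05
) -> list[str]:
    """Union of genes with padj <= threshold in any interpretation.

    Ordered by the minimum padj across interpretations, ties broken by
    gene ID.
    """
    if not 0.0 <= threshold < 1.0:
        raise ValueError("threshold must lie in [0, 1)")
    best: dict[str, float] = {}
    for res in results.values():
        hits = res.loc[res["padj"] <= threshold, "padj"]
        for gene, padj in hits.items():
            if gene not in best or padj < best[gene]:
                best[gene] = float(padj)
    return sorted(best, key=lambda g: (best[g], g))
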