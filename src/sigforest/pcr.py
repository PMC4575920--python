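"""Delta-delta-Ct quantification for qPCR and qMSP validation assays.

Both statistics are normalized against the beta-actin housekeeping
assay (``ACTB``) and assume 100% amplification efficiency (one cycle =
factor 2).  Technical replicates are collapsed by mean Ct before any
difference is taken.

qPCR:  log2FC = -[(Ct_gene,T - Ct_ACTB,T) - (Ct_gene,N - Ct_ACTB,N)],
the 2^-ddCt quantity on the log2 scale; negative = down in tumor.

qMSP:  percent methylation = 100 * Qm / (Qm + Qu) with
Qm = 2^-(Ct_M,target - Ct_M,ACTB) and Qu the unmethylated analogue.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = [
    "read_ct_table",
    "qpcr_log2fc",
    "qpcr_table",
    "qmsp_percent_methylation",
    "qmsp_table",
]

REFERENCE_ASSAY = "ACTB"

_COLUMNS = ("sample_id", "condition", "assay", "primer", "ct")


def read_ct_table(path) -> pd.DataFrame:
    """Read a Ct CSV with columns sample_id, condition, assay, primer, ct."""
    table = pd.read_csv(path, keep_default_na=False, na_values=[""])
    missing = set(_COLUMNS) - set(table.columns)
    if missing:
        raise ValueError(f"Ct table lacks columns: {sorted(missing)}")
    table["ct"] = pd.to_numeric(table["ct"])
    if not np.isfinite(table["ct"]).all():
        raise ValueError("non-finite Ct values present")
    return table


def _mean_ct(ct: pd.DataFrame, sample: str, condition: str | None,
             assay: str, primer: str) -> float:
    m = (ct["sample_id"] == sample) & (ct["assay"] == assay) & (ct["primer"] == primer)
    if condition is not None:
        m &= ct["condition"] == condition
    sub = ct.loc[m, "ct"]
    if sub.empty:
        raise ValueError(
            f"missing Ct for sample={sample!r} condition={condition!r} "
            f"assay={assay!r} primer={primer!r}"
        )
    return float(sub.mean())  # technical replicates collapse by mean


def qpcr_log2fc(ct: pd.DataFrame, gene: str, pair: str) -> float:
    """Beta-actin-normalized tumor-vs-normal log2 fold change for one pair."""
    d_tumor = (_mean_ct(ct, pair, "tumor", gene, "NA")
               - _mean_ct(ct, pair, "tumor", REFERENCE_ASSAY, "NA"))
    d_normal = (_mean_ct(ct, pair, "normal", gene, "NA")
                - _mean_ct(ct, pair, "normal", REFERENCE_ASSAY, "NA"))
    return -(d_tumor - d_normal)


def qpcr_table(ct: pd.DataFrame) -> pd.DataFrame:
    """Gene x pair grid of qPCR log2 fold changes for all assayed genes."""
    genes = sorted(set(ct.loc[ct["primer"] == "NA", "assay"]) - {REFERENCE_ASSAY})
    pairs = list(dict.fromkeys(ct.loc[ct["primer"] == "NA", "sample_id"]))
    data = {p: [qpcr_log2fc(ct, g, p) for g in genes] for p in pairs}
    return pd.DataFrame(data, index=genes)


def qmsp_percent_methylation(ct: pd.DataFrame, sample: str,
                             gene: str | None = None) -> float:
    """Percent promoter methylation for one sample, in [0, 100]."""
    if gene is None:
        targets = set(ct.loc[(ct["sample_id"] == sample)
                             & ct["primer"].isin(["M", "U"]), "assay"])
        targets -= {REFERENCE_ASSAY}
        if len(targets) != 1:
            raise ValueError(
                f"sample {sample!r} has {len(targets)} qMSP target assays; pass gene="
            )
        gene = targets.pop()
    q = {}
    for primer in ("M", "U"):
        d = (_mean_ct(ct, sample, None, gene, primer)
             - _mean_ct(ct, sample, None, REFERENCE_ASSAY, primer))
        q[primer] = 2.0 ** (-d)
    denom = q["M"] + q["U"]
    if denom == 0 or not np.isfinite(denom):
        raise ValueError(f"degenerate methylated/unmethylated quantities for {sample!r}")
    return 100.0 * q["M"] / denom


def qmsp_table(ct: pd.DataFrame) -> pd.Series:
    """Percent methylation for every sample carrying qMSP rows."""
    samples = list(dict.fromkeys(ct.loc[ct["primer"].isin(["M", "U"]), "sample_id"]))
    return pd.Series({s: qmsp_percent_methylation(ct, s) for s in samples},
                     name="percent_methylation")
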