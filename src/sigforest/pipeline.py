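"""End-to-end orchestration: normalize -> DE -> encode -> signature.

A :class:`PipelineConfig` (optionally loaded from YAML) names the
inputs, thresholds and ensemble settings; :func:`run_pipeline` writes
every intermediate artifact plus a JSON manifest with input checksums
so a run can be reproduced byte-for-byte.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .counts import (
    read_count_matrix,
    filter_expressed_genes,
    estimate_size_factors,
    compute_fold_changes,
    encode_fold_changes,
)
from .diffexp import run_interpretations, select_significant_genes
from .pcr import read_ct_table, qpcr_table, qmsp_table
from .signature import EnsembleConfig, build_class_labels, run_signature_discovery

__all__ = ["PipelineConfig", "run_pipeline"]


@dataclass
class PipelineConfig:
    counts: str
    sample_sheet: str
    outdir: str
    qpcr_ct: str | None = None
    qmsp_ct: str | None = None
    padj_threshold: float = 0.05
    fc_tolerance: float = 0.0
    pseudocount: float = 0.5
    positive_classes: tuple[str, ...] = ("A",)
    ensemble: EnsembleConfig = field(default_factory=EnsembleConfig)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "ensemble" in raw:
            ens = raw["ensemble"]
            if isinstance(ens.get("seeds"), dict):
                ens["seeds"] = tuple(range(ens["seeds"]["start"], ens["seeds"]["stop"] + 1))
            raw["ensemble"] = EnsembleConfig(**ens)
        if "positive_classes" in raw:
            raw["positive_classes"] = tuple(raw["positive_classes"])
        return cls(**raw)


def _sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def _write_tsv(df, path, index_name="gene"):
    out = df.copy()
    out.index.name = index_name
    out.to_csv(path, sep="\t")


def run_pipeline(config: PipelineConfig) -> dict:
    """Run the full chain and return the artifact manifest.

    Writes size factors, per-interpretation DE tables, the
    genes-of-interest list, fold-change and encoded matrices, the
    ranked signature candidates and (when Ct tables are configured) the
    qPCR/qMSP summaries.  Raises on the first stage error.
    """
    for name in ("counts", "sample_sheet"):
        p = getattr(config, name)
        if not Path(p).exists():
            raise FileNotFoundError(f"{name} input does not exist: {p}")
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    artifacts: dict[str, str] = {}

    cm = read_count_matrix(config.counts, config.sample_sheet)
    cm = filter_expressed_genes(cm)
    sf = estimate_size_factors(cm)
    _write_tsv(sf.to_frame(), outdir / "size_factors.tsv", index_name="sample_id")
    artifacts["size_factors"] = "size_factors.tsv"

    results = run_interpretations(cm, sf, pseudocount=config.pseudocount)
    for label, res in results.items():
        fname = f"de_{label.replace(':', '_')}.tsv"
        _write_tsv(res, outdir / fname)
        artifacts[f"de:{label}"] = fname
    goi = select_significant_genes(results, threshold=config.padj_threshold)
    pd.Series(goi, name="gene").to_csv(outdir / "genes_of_interest.tsv",
                                       sep="\t", index=False)
    artifacts["genes_of_interest"] = "genes_of_interest.tsv"

    fc = compute_fold_changes(cm, sf, pseudocount=config.pseudocount)
    _write_tsv(fc, outdir / "fold_changes.tsv")
    artifacts["fold_changes"] = "fold_changes.tsv"
    encoded = encode_fold_changes(fc, tol=config.fc_tolerance)
    _write_tsv(encoded, outdir / "encoded.tsv")
    artifacts["encoded"] = "encoded.tsv"

    # candidate genes: the significant set when non-trivial, else all
    candidates_in = goi if len(goi) >= 2 else cm.genes
    labels = build_class_labels(cm.samples, config.positive_classes)
    classes = cm.samples.groupby("pair_id", sort=False)["class"].first()
    sel = run_signature_discovery(encoded, labels, config.ensemble,
                                  candidate_genes=candidates_in, classes=classes)
    cand = pd.DataFrame(
        [{"genes": ";".join(c.genes), "ng": c.ng, "ni": c.ni,
          "S": c.sensitivity, "R": c.score} for c in sel.candidates_]
    )
    cand.to_csv(outdir / "candidates.tsv", sep="\t", index=False)
    artifacts["candidates"] = "candidates.tsv"
    with open(outdir / "signature_manifest.json", "w") as fh:
        json.dump(sel.manifest_, fh, indent=2)
    artifacts["signature_manifest"] = "signature_manifest.json"

    if config.qpcr_ct:
        _write_tsv(qpcr_table(read_ct_table(config.qpcr_ct)),
                   outdir / "qpcr_log2fc.tsv")
        artifacts["qpcr_log2fc"] = "qpcr_log2fc.tsv"
    if config.qmsp_ct:
        _write_tsv(qmsp_table(read_ct_table(config.qmsp_ct)).to_frame(),
                   outdir / "qmsp_percent_methylation.tsv", index_name="sample_id")
        artifacts["qmsp_percent_methylation"] = "qmsp_percent_methylation.tsv"

    manifest = {
        "version": __version__,
        "numpy": np.__version__,
        "inputs": {
            "counts": {"path": str(config.counts), "sha256": _sha256(config.counts)},
            "sample_sheet": {"path": str(config.sample_sheet),
                             "sha256": _sha256(config.sample_sheet)},
        },
        "config": {
            **{k: v for k, v in asdict(config).items() if k != "ensemble"},
            "ensemble": {**asdict(config.ensemble),
                         "seeds": list(config.ensemble.seeds),
                         "training_classes": sorted(config.ensemble.training_classes)
                         if config.ensemble.training_classes else None,
                         "prediction_classes": sorted(config.ensemble.prediction_classes)
                         if config.ensemble.prediction_classes else None},
        },
        "artifacts": artifacts,
    }
    manifest["artifacts_sha256"] = {
        name: _sha256(outdir / fname) for name, fname in artifacts.items()
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
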