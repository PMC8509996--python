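"""Readers and writers for the plain-text formats the tool exchanges.

Intervals travel as BED6 (chrom, start, end, name, score, strand; 0-based
half-open). Binding sites are BED6 plus read_support, sample_support,
region_type and concurred columns, with ``name = <rbp>|<mirna>``. Expression
matrices are TSV with row ids in the first column and sample ids in the
header, with a companion sample sheet (sample, batch, condition[, tissue]).
Networks are JSON. Boosted models persist as XGBoost's native JSON plus a
small metadata JSON.
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd

from .bayesnet import SEMFit
from .expr import ExpressionMatrix
from .predict import BoostingConfig, BoostingModel
from .sites import BindingSite, ClipSample, GenomicInterval

__all__ = [
    "read_bed",
    "write_bed",
    "read_loci_bed",
    "read_clip_dir",
    "write_sites_tsv",
    "read_sites_tsv",
    "read_expression_tsv",
    "write_expression_tsv",
    "read_sample_sheet",
    "read_ppi_tsv",
    "write_ppi_tsv",
    "semfit_to_json",
    "write_network_json",
    "read_network_json",
    "save_models",
    "load_models",
]

_BED_COLS = ["chrom", "start", "end", "name", "score", "strand"]


def read_bed(path) -> list:
    """BED6 (or BED3) -> list of (name, GenomicInterval)."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#", dtype=str)
    out = []
    for _, row in df.iterrows():
        chrom, start, end = row[0], int(row[1]), int(row[2])
        name = row[3] if df.shape[1] > 3 and pd.notna(row[3]) else "."
        strand = row[5] if df.shape[1] > 5 and pd.notna(row[5]) else "."
        out.append((name, GenomicInterval(chrom, start, end, strand)))
    return out


def write_bed(path, intervals, names=None, scores=None) -> None:
    rows = []
    for k, iv in enumerate(intervals):
        rows.append(
            [
                iv.chrom,
                iv.start,
                iv.end,
                names[k] if names else ".",
                scores[k] if scores else 0,
                iv.strand,
            ]
        )
    pd.DataFrame(rows, columns=_BED_COLS).to_csv(
        path, sep="\t", header=False, index=False
    )


def read_loci_bed(path) -> list:
    """Pre-miRNA BED6 (name = miRNA id) -> (mirna_id, interval) entries."""
    return [(name, iv) for name, iv in read_bed(path)]


def read_clip_dir(directory, condition: str = "cond0") -> list:
    """Directory of ``<rbp>__<sample>.bed`` read files -> ClipSamples."""
    samples = []
    for path in sorted(Path(directory).glob("*.bed")):
        stem = path.stem
        if "__" not in stem:
            raise ValueError(
                f"{path.name}: expected '<rbp>__<sample>.bed' naming"
            )
        rbp_id, sample_id = stem.split("__", 1)
        reads = [iv for _, iv in read_bed(path)]
        samples.append(ClipSample(rbp_id, sample_id, condition, reads))
    return samples


def write_sites_tsv(path, sites) -> None:
    rows = []
    for s in sites:
        rows.append(
            [
                s.interval.chrom,
                s.interval.start,
                s.interval.end,
                f"{s.rbp_id}|{s.mirna_id}",
                s.read_support,
                s.interval.strand,
                s.read_support,
                s.sample_support,
                s.region_type,
                int(s.concurred),
            ]
        )
    cols = _BED_COLS + ["read_support", "sample_support", "region_type", "concurred"]
    pd.DataFrame(rows, columns=cols).to_csv(path, sep="\t", index=False)


def read_sites_tsv(path) -> list:
    df = pd.read_csv(path, sep="\t")
    out = []
    for _, r in df.iterrows():
        rbp, mirna = str(r["name"]).split("|", 1)
        out.append(
            BindingSite(
                rbp_id=rbp,
                mirna_id=mirna,
                region_type=str(r["region_type"]),
                interval=GenomicInterval(
                    str(r["chrom"]), int(r["start"]), int(r["end"]), str(r["strand"])
                ),
                read_support=int(r["read_support"]),
                sample_support=int(r["sample_support"]),
                concurred=bool(int(r["concurred"])),
            )
        )
    return out


def read_sample_sheet(path) -> pd.DataFrame:
    sheet = pd.read_csv(path, sep="\t", dtype=str)
    if "sample" not in sheet.columns:
        raise ValueError("sample sheet needs a 'sample' column")
    return sheet


def read_expression_tsv(path, sample_sheet=None) -> ExpressionMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    batch, condition = {}, {}
    if sample_sheet is not None:
        sheet = (
            sample_sheet
            if isinstance(sample_sheet, pd.DataFrame)
            else read_sample_sheet(sample_sheet)
        )
        for _, row in sheet.iterrows():
            s = row["sample"]
            if "batch" in sheet.columns:
                batch[s] = row["batch"]
            if "condition" in sheet.columns:
                condition[s] = row["condition"]
    return ExpressionMatrix(df, batch=batch, condition=condition)


def write_expression_tsv(path, m: ExpressionMatrix) -> None:
    m.values.to_csv(path, sep="\t")


def read_ppi_tsv(path) -> list:
    df = pd.read_csv(path, sep="\t", header=None, comment="#", dtype=str)
    return [(a, b) for a, b in zip(df[0], df[1])]


def write_ppi_tsv(path, edges) -> None:
    pd.DataFrame(edges).to_csv(path, sep="\t", header=False, index=False)


def semfit_to_json(fit: SEMFit) -> dict:
    import numpy as np

    edges = []
    for i, j in zip(*np.nonzero(fit.B)):
        w = float(fit.B[i, j])
        edges.append(
            {
                "source": fit.nodes[i],
                "target": fit.nodes[j],
                "weight": w,
                "se": float(fit.se[i, j]),
                "pvalue": float(fit.pvalue[i, j]),
                "precision": float(fit.precision[i, j]),
                "sign": "positive" if w > 0 else "negative",
            }
        )
    return {
        "nodes": list(fit.nodes),
        "edges": edges,
        "metadata": {
            "mirna": fit.mirna_id,
            "step": fit.step,
            "condition": fit.condition,
            "lambda": fit.lambda_used,
        },
    }


def write_network_json(path, fits) -> None:
    payload = [semfit_to_json(f) for f in fits]
    Path(path).write_text(json.dumps(payload, indent=1))


def read_network_json(path) -> list:
    return json.loads(Path(path).read_text())


def save_models(directory, models: dict) -> None:
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    for mirna, model in models.items():
        booster = (
            model.booster.get_booster()
            if hasattr(model.booster, "get_booster")
            else model.booster
        )
        booster.save_model(d / f"{mirna}.model.json")
        meta = {
            "mirna_id": model.mirna_id,
            "feature_ids": list(model.feature_ids),
            "config": {
                "n_trees": model.config.n_trees,
                "max_depth": model.config.max_depth,
                "learning_rate": model.config.learning_rate,
                "gamma": model.config.gamma,
                "lambda_reg": model.config.lambda_reg,
                "seed": model.config.seed,
            },
        }
        (d / f"{mirna}.meta.json").write_text(json.dumps(meta, indent=1))


def load_models(directory) -> dict:
    import xgboost

    models = {}
    for meta_path in sorted(Path(directory).glob("*.meta.json")):
        meta = json.loads(meta_path.read_text())
        cfg = BoostingConfig(**meta["config"])
        booster = xgboost.Booster()
        booster.load_model(str(meta_path.with_name(f"{meta['mirna_id']}.model.json")))
        models[meta["mirna_id"]] = BoostingModel(
            meta["mirna_id"], meta["feature_ids"], cfg, booster
        )
    return models
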