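"""Readers and writers for the pipeline's CSV/TSV/JSON dialects.

Inputs are UTF-8 CSV with a decimal point; outputs are TSV (human) plus
JSON (machine). Every output embeds the configuration hash and seed in
a comment header so re-runs with the same configuration are
byte-identical; conversions are printed to one decimal place while
internals keep full precision.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Any, Iterable

import pandas as pd

from .conversion_stats import ConversionResult, GroupComparison, PeakTable
from .fa_model import FattyAcidError, format_fa, parse_fa
from .qpcr_quant import QpcrMeasurement

__all__ = [
    "PeakTableFormatError",
    "read_peak_table",
    "write_peak_table",
    "read_qpcr_measurements",
    "read_dilution_series",
    "config_hash",
    "write_conversions",
    "write_group_comparison",
    "write_tissue_summary",
]

PEAK_COLUMNS = ["sample_id", "treatment", "fatty_acid", "area"]


class PeakTableFormatError(ValueError):
    """A peak-table CSV violates the expected dialect; cites the row."""


def read_peak_table(path: str | Path) -> list[PeakTable]:
    """Read a peak-table CSV (sample_id, treatment, fatty_acid, area).

    Fatty-acid names are validated on read; errors cite the offending
    1-based data row. Duplicate (sample, fatty acid) pairs and negative
    areas are rejected.
    """
    df = pd.read_csv(path, dtype={"sample_id": str, "treatment": str, "fatty_acid": str})
    missing = [c for c in PEAK_COLUMNS if c not in df.columns]
    if missing:
        raise PeakTableFormatError(f"{path}: missing required column(s) {missing}")
    samples: dict[str, dict] = {}
    seen: set[tuple[str, str]] = set()
    for idx, row in enumerate(df.itertuples(index=False), start=1):
        try:
            fa = parse_fa(row.fatty_acid)
        except FattyAcidError as exc:
            raise PeakTableFormatError(f"{path}, row {idx}: {exc}") from exc
        area = float(row.area)
        if area < 0:
            raise PeakTableFormatError(
                f"{path}, row {idx}: negative area {area} for {row.fatty_acid}"
            )
        key = (row.sample_id, format_fa(fa))
        if key in seen:
            raise PeakTableFormatError(
                f"{path}, row {idx}: duplicate entry for sample {row.sample_id!r}, "
                f"fatty acid {format_fa(fa)}"
            )
        seen.add(key)
        entry = samples.setdefault(
            row.sample_id, {"treatment": row.treatment, "areas": {}}
        )
        if entry["treatment"] != row.treatment:
            raise PeakTableFormatError(
                f"{path}, row {idx}: sample {row.sample_id!r} appears under two "
                f"treatments ({entry['treatment']!r}, {row.treatment!r})"
            )
        entry["areas"][fa] = area
    return [
        PeakTable(sample_id=sid, treatment=v["treatment"], areas=v["areas"])
        for sid, v in samples.items()
    ]


def write_peak_table(tables: Iterable[PeakTable], path: str | Path) -> None:
    """Write peak tables in the same CSV dialect :func:`read_peak_table` reads."""
    rows = [
        {
            "sample_id": t.sample_id,
            "treatment": t.treatment,
            "fatty_acid": format_fa(fa),
            "area": area,
        }
        for t in tables
        for fa, area in sorted(t.areas.items())
    ]
    pd.DataFrame(rows, columns=PEAK_COLUMNS).to_csv(path, index=False)


def read_qpcr_measurements(path: str | Path) -> list[QpcrMeasurement]:
    """Read a qPCR CSV (tissue, sex, fish_id, gene, cq_rep1, cq_rep2, …)."""
    df = pd.read_csv(path, dtype={"tissue": str, "sex": str, "fish_id": str, "gene": str})
    required = ["tissue", "sex", "fish_id", "gene"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required column(s) {missing}")
    rep_cols = sorted(c for c in df.columns if c.startswith("cq_rep"))
    if not rep_cols:
        raise ValueError(f"{path}: no cq_rep* columns found")
    out = []
    for row in df.itertuples(index=False):
        cqs = tuple(float(getattr(row, c)) for c in rep_cols if pd.notna(getattr(row, c)))
        out.append(
            QpcrMeasurement(
                tissue=row.tissue, sex=row.sex, fish_id=row.fish_id,
                gene=row.gene, cq_values=cqs,
            )
        )
    return out


def read_dilution_series(path: str | Path) -> dict[str, list[tuple[float, float]]]:
    """Read a dilution-series CSV (gene, copies, cq) into per-gene points."""
    df = pd.read_csv(path, dtype={"gene": str})
    missing = [c for c in ("gene", "copies", "cq") if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required column(s) {missing}")
    points: dict[str, list[tuple[float, float]]] = {}
    for row in df.itertuples(index=False):
        points.setdefault(row.gene, []).append((float(row.copies), float(row.cq)))
    return points


def config_hash(config: dict[str, Any]) -> str:
    """Stable short hash of a JSON-serializable configuration mapping."""
    blob = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


def _header_lines(config: dict[str, Any]) -> str:
    seed = config.get("seed", "none")
    return f"# config_hash={config_hash(config)}\n# seed={seed}\n"


def write_conversions(
    results_by_enzyme: dict[str, list[ConversionResult]],
    path_tsv: str | Path,
    config: dict[str, Any],
) -> None:
    """Write a conversion table (one % column per enzyme) as TSV + JSON.

    Conversions are printed to one decimal place; a step with no
    detectable substrate or products prints ``N.D.``.
    """
    enzymes = list(results_by_enzyme)
    first = results_by_enzyme[enzymes[0]]
    for name, res in results_by_enzyme.items():
        if [(r.step_substrate, r.step_product) for r in res] != [
            (r.step_substrate, r.step_product) for r in first
        ]:
            raise ValueError(f"enzyme {name!r}: conversion steps differ across enzymes")

    def fmt(r: ConversionResult) -> str:
        return "N.D." if r.not_detected else f"{r.conversion:.1f}"

    rows = []
    for i, r in enumerate(first):
        row = {
            "substrate": format_fa(r.step_substrate),
            "product": format_fa(r.step_product),
        }
        for name in enzymes:
            row[f"pct_conversion_{name}"] = fmt(results_by_enzyme[name][i])
        row["elongation"] = f"C{r.step_substrate.carbons} → {r.step_product.carbons}"
        rows.append(row)
    path_tsv = Path(path_tsv)
    with open(path_tsv, "w", encoding="utf-8") as fh:
        fh.write(_header_lines(config))
        pd.DataFrame(rows).to_csv(fh, sep="\t", index=False)
    payload = {
        "config_hash": config_hash(config),
        "seed": config.get("seed"),
        "steps": [
            {
                "substrate": format_fa(r.step_substrate),
                "product": format_fa(r.step_product),
                "conversions_pct": {
                    name: (None if results_by_enzyme[name][i].not_detected
                           else results_by_enzyme[name][i].conversion)
                    for name in enzymes
                },
            }
            for i, r in enumerate(first)
        ],
    }
    path_tsv.with_suffix(".json").write_text(json.dumps(payload, indent=2))


def write_group_comparison(
    comparison: GroupComparison, path_tsv: str | Path, config: dict[str, Any]
) -> None:
    """Write a mean ± SE + letters table per fatty acid (TSV + JSON)."""
    df = comparison.to_frame()
    df["mean"] = df["mean"].map(lambda v: f"{v:.2f}")
    df["se"] = df["se"].map(lambda v: f"{v:.2f}")
    df["anova_p"] = df["anova_p"].map(lambda v: f"{v:.4g}")
    path_tsv = Path(path_tsv)
    with open(path_tsv, "w", encoding="utf-8") as fh:
        fh.write(_header_lines(config))
        df.to_csv(fh, sep="\t", index=False)
    payload = {
        "config_hash": config_hash(config),
        "seed": config.get("seed"),
        "alpha": comparison.alpha,
        "fatty_acids": {
            format_fa(fa): {
                "means": vc.means,
                "sems": vc.sems,
                "n": vc.ns,
                "anova_p": vc.anova_p,
                "tukey_p": {" vs ".join(k): v for k, v in vc.tukey_p.items()},
                "letters": vc.letters,
            }
            for fa, vc in comparison.variables.items()
        },
    }
    path_tsv.with_suffix(".json").write_text(json.dumps(payload, indent=2))


def write_tissue_summary(
    summary: pd.DataFrame, path_tsv: str | Path, config: dict[str, Any]
) -> None:
    """Write the per-tissue normalized-expression summary (TSV + JSON)."""
    df = summary.copy()
    df["mean_ratio"] = df["mean_ratio"].map(lambda v: f"{v:.6g}")
    df["se"] = df["se"].map(lambda v: f"{v:.6g}")
    df["anova_p"] = df["anova_p"].map(lambda v: f"{v:.4g}")
    path_tsv = Path(path_tsv)
    with open(path_tsv, "w", encoding="utf-8") as fh:
        fh.write(_header_lines(config))
        df.to_csv(fh, sep="\t", index=False)
    payload = {
        "config_hash": config_hash(config),
        "seed": config.get("seed"),
        "tissues": summary.to_dict(orient="records"),
    }
    path_tsv.with_suffix(".json").write_text(json.dumps(payload, indent=2))
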