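"""Report rendering and the end-to-end analysis pipeline.

Rounding is presentation-only: every index is carried at full precision
through the computation and quantized half-even only when a table is
rendered (3 decimals for the unitless indices, 2 for FL percentages,
matching the conventions of published ethnobotanical index tables).
"""

from __future__ import annotations

import csv
import dataclasses
import hashlib
import io
import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

from ethnosurvey import __version__
from ethnosurvey.consensus_fidelity import consensus_table, fidelity_table
from ethnosurvey.ethno_indices import species_index_table
from ethnosurvey.survey_data import (
    StudyDesign,
    UseReportTable,
    load_use_reports,
    load_use_reports_xlsx,
    validate,
)

__all__ = ["PipelineConfig", "render_value", "render_table", "run_pipeline"]

logger = logging.getLogger(__name__)

#: Per-column display decimals for the three report tables.
ROUNDING = {"ci": 3, "rfc": 3, "ri": 3, "cve": 3, "iar": 3, "fl": 2}


def render_value(value: object, decimals: int | None = None) -> str:
    """Render one cell; floats are quantized half-even to ``decimals``.

    Uses decimal arithmetic on the shortest repr of the float, so decimal
    ties round to even (1.7345 -> "1.734") instead of inheriting binary
    representation error.  NaN renders as an empty field (undefined
    marker, e.g. IAR of a category with fewer than two reports).
    """
    if isinstance(value, float):
        if math.isnan(value):
            return ""
        if decimals is not None:
            from decimal import ROUND_HALF_EVEN, Decimal

            q = Decimal(1).scaleb(-decimals)
            return str(Decimal(repr(value)).quantize(q, rounding=ROUND_HALF_EVEN))
        return repr(value)
    return str(value)


def render_table(
    rows: pd.DataFrame,
    format: str = "csv",
    rounding: Mapping[str, int] | None = None,
) -> str:
    """Render a report table as CSV (RFC-4180) or a markdown pipe table.

    ``rounding`` maps column name to display decimals; unlisted columns
    render verbatim.  An empty frame yields header-only output.
    """
    if format not in ("csv", "markdown"):
        raise ValueError(f"unknown format: {format!r} (expected csv or markdown)")
    rounding = dict(ROUNDING if rounding is None else rounding)
    header = list(rows.columns)
    body = [
        [render_value(row[c], rounding.get(c)) for c in header]
        for _, row in rows.iterrows()
    ]
    if format == "csv":
        buf = io.StringIO()
        writer = csv.writer(buf, lineterminator="\n")
        writer.writerow(header)
        writer.writerows(body)
        return buf.getvalue()
    widths = [
        max(len(str(h)), *(len(r[i]) for r in body)) if body else len(str(h))
        for i, h in enumerate(header)
    ]
    lines = [
        "| " + " | ".join(str(h).ljust(w) for h, w in zip(header, widths)) + " |",
        "|" + "|".join("-" * (w + 2) for w in widths) + "|",
    ]
    lines += [
        "| " + " | ".join(c.ljust(w) for c, w in zip(r, widths)) + " |" for r in body
    ]
    return "\n".join(lines) + "\n"


@dataclass
class PipelineConfig:
    """Everything needed to run (and re-run) one analysis."""

    input: str
    out_dir: str = "ethnosurvey-out"
    xlsx: bool = False
    column_map: dict[str, str] = field(default_factory=dict)
    delimiter: str = ","
    n_informants: int | None = None
    categories: tuple[str, ...] | None = None
    normalize: bool = True
    formats: tuple[str, ...] = ("csv",)
    index_decimals: int = 3
    fl_decimals: int = 2

    def __post_init__(self) -> None:
        if self.index_decimals < 0 or self.fl_decimals < 0:
            raise ValueError("rounding decimals must be >= 0")
        for f in self.formats:
            if f not in ("csv", "markdown"):
                raise ValueError(f"unknown output format: {f!r}")


def _design_from_config(config: PipelineConfig) -> StudyDesign | None:
    if config.n_informants is None and config.categories is None:
        return None
    if config.n_informants is None or config.categories is None:
        raise ValueError(
            "an explicit study design needs both n_informants and categories"
        )
    return StudyDesign(config.n_informants, tuple(config.categories))


def _load(config: PipelineConfig) -> UseReportTable:
    design = _design_from_config(config)
    if config.xlsx:
        return load_use_reports_xlsx(
            config.input, config.column_map or None, design, normalize=config.normalize
        )
    return load_use_reports(
        config.input,
        config.column_map or None,
        design,
        delimiter=config.delimiter,
        normalize=config.normalize,
    )


def run_pipeline(config: PipelineConfig) -> dict[str, Path]:
    """Load, analyze and write the three report tables plus a manifest.

    Writes ``species_indices``, ``consensus`` and ``fidelity`` tables in
    each requested format and ``manifest.json`` recording the input
    checksum, the full configuration, and record/species/category counts.
    Outputs are deterministic for a fixed input and configuration.
    Returns the written paths keyed by report name.
    """
    table = _load(config)
    for finding in validate(table):
        logger.info("validation: %s", finding.message)

    rounding = dict(ROUNDING)
    for col in ("ci", "rfc", "ri", "cve", "iar"):
        rounding[col] = config.index_decimals
    rounding["fl"] = config.fl_decimals

    reports = {
        "species_indices": species_index_table(table),
        "consensus": consensus_table(table),
        "fidelity": fidelity_table(table),
    }
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    ext = {"csv": "csv", "markdown": "md"}
    written: dict[str, Path] = {}
    for name, frame in reports.items():
        for fmt in config.formats:
            path = out_dir / f"{name}.{ext[fmt]}"
            path.write_text(render_table(frame, fmt, rounding), encoding="utf-8")
            written[f"{name}.{fmt}"] = path
            logger.info("wrote %s (%d rows)", path, len(frame))

    digest = hashlib.sha256(Path(config.input).read_bytes()).hexdigest()
    manifest = {
        "tool": {"name": "ethnosurvey", "version": __version__},
        "input_sha256": digest,
        "config": dataclasses.asdict(config),
        "counts": {
            "records": table.n_records,
            "species": len(table.species),
            "informants_observed": len(table.informants),
            "informants_designed": table.design.n_informants,
            "categories": table.design.n_categories,
        },
    }
    manifest_path = out_dir / "manifest.json"
    manifest_path.write_text(
        json.dumps(manifest, indent=2, sort_keys=True, default=list) + "\n",
        encoding="utf-8",
    )
    written["manifest"] = manifest_path
    return written
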