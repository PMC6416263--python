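"""Deterministic serialization of experiment reports."""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd

from . import __version__
from .analysis import ExperimentReport

__all__ = ["write_report"]

_TABLES = {
    "features_long.csv": "features",
    "correlations.csv": "correlations",
    "percent_changes.csv": "percent_changes",
    "volume_sensitivity.csv": "volume_sensitivity",
    "m4_outliers.csv": "m4_outliers",
}


def _write_csv(df: pd.DataFrame, path: Path) -> None:
    # full double precision, fixed column order, no index: byte-identical
    # output for identical reports
    df.to_csv(path, index=False, float_format="%.17g", lineterminator="\n")


def write_report(report: ExperimentReport, out_dir) -> list[Path]:
    """Write all report tables plus a manifest; returns the files written.

    Cells recorded as failed are serialized as explicit NA with the failure
    reason preserved in the ``failure`` column if present.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written = []
    for fname, attr in _TABLES.items():
        df = getattr(report, attr)
        if df is None or (hasattr(df, "empty") and df.empty and attr == "m4_outliers"):
            continue
        _write_csv(df, out / fname)
        written.append(out / fname)
    manifest = {
        "software": "spiculo",
        "version": __version__,
        "provenance": report.provenance,
        "tables": [p.name for p in written],
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    written.append(out / "manifest.json")

    lines = ["# Phantom robustness report", ""]
    if not report.correlations.empty:
        sub = report.correlations
        lines.append("## Spearman correlation with spiculatedness degree d")
        lines.append("")
        lines.append(sub.to_string(index=False, float_format=lambda v: f"{v:.4f}"))
        lines.append("")
    if not report.volume_sensitivity.empty:
        lines.append("## Volume sensitivity vs spiculatedness span")
        lines.append("")
        lines.append(
            report.volume_sensitivity.to_string(
                index=False, float_format=lambda v: f"{v:.4f}"
            )
        )
        lines.append("")
    (out / "summary.md").write_text("\n".join(lines) + "\n")
    written.append(out / "summary.md")
    return written
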