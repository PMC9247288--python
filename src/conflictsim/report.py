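"""Tabular serialization of model outputs.

Probabilities are kept on the [0, 1] scale internally and serialized as
percentages (0-100) in conflict-table reports.  ``csv`` and ``json`` output
keep full floating precision; ``pretty`` rounds to the reporting precision
(ages and offspring counts to 1 decimal, percentages to 1 decimal) so visual
diffs against the published table line up.
"""

from __future__ import annotations

import dataclasses
import io
from pathlib import Path

import pandas as pd

from .optimize import OptimumResult, SweepCurve

FORMATS = ("csv", "json", "pretty")

#: Exact column order of the conflict-table CSV contract.
TABLE_COLUMNS = (
    "scenario",
    "maternal_opt_age", "paternal_opt_age", "delta_age",
    "maternal_lrf", "paternal_lrf", "delta_lrf",
    "maternal_mortality_pct", "paternal_mortality_pct", "delta_mortality_pct",
    "maternal_stunting_pct", "paternal_stunting_pct", "delta_stunting_pct",
)

_PCT_MAP = {
    "maternal_mortality_pct": "mortality_at_maternal_opt",
    "paternal_mortality_pct": "mortality_at_paternal_opt",
    "delta_mortality_pct": "delta_mortality",
    "maternal_stunting_pct": "stunting_at_maternal_opt",
    "paternal_stunting_pct": "stunting_at_paternal_opt",
    "delta_stunting_pct": "delta_stunting",
}


@dataclasses.dataclass(frozen=True)
class ReportConfig:
    """Output format and rounding for the reporting layer."""

    fmt: str = "pretty"
    decimals: int = 1         # ages and offspring counts (pretty mode only)
    pct_decimals: int = 1     # percentages (pretty mode only)
    out: str | Path | None = None  # None -> standard output

    def __post_init__(self) -> None:
        if self.fmt not in FORMATS:
            raise ValueError(f"format must be one of {FORMATS}, got {self.fmt!r}")
        if self.decimals < 0 or self.pct_decimals < 0:
            raise ValueError("decimal places must be >= 0")


def table_frame(rows: list[OptimumResult]) -> pd.DataFrame:
    """Conflict-table DataFrame with the canonical columns, full precision."""
    records = []
    for r in rows:
        d = dataclasses.asdict(r)
        rec = {c: d[c] for c in TABLE_COLUMNS if c in d}
        for col, src in _PCT_MAP.items():
            rec[col] = d[src] * 100.0
        records.append(rec)
    return pd.DataFrame(records, columns=list(TABLE_COLUMNS))


def sweep_frame(curve: SweepCurve) -> pd.DataFrame:
    """Sweep DataFrame: one row per grid age, every outcome field, [0,1] scale."""
    return curve.to_frame()


def read_sweep_csv(path: str | Path) -> pd.DataFrame:
    """Read back a sweep CSV written by :func:`render` (lossless round trip)."""
    return pd.read_csv(path)


#: Columns on the [0,1] probability scale; pretty mode keeps 3 decimals so a
#: rate like 0.340 is not flattened to 0.3.
_PROB_COLUMNS = frozenset({
    "lbw_risk", "postnatal_factor", "child_mortality_rate", "stunting_rate",
    "paternity_uncertainty", "maternal_mortality_risk",
})


def _pretty(df: pd.DataFrame, cfg: ReportConfig) -> str:
    shown = df.copy()
    for col in shown.columns:
        if shown[col].dtype.kind != "f":
            continue
        if col.endswith("_pct"):
            nd = cfg.pct_decimals
        elif col in _PROB_COLUMNS:
            nd = cfg.pct_decimals + 2
        else:
            nd = cfg.decimals
        shown[col] = shown[col].round(nd)
    return shown.to_string(index=False)


def render(df: pd.DataFrame, cfg: ReportConfig) -> str:
    """Render a DataFrame per the report config, returning the text."""
    if cfg.fmt == "csv":
        buf = io.StringIO()
        df.to_csv(buf, index=False)
        return buf.getvalue()
    if cfg.fmt == "json":
        return df.to_json(orient="records", indent=2, double_precision=15)
    return _pretty(df, cfg) + "\n"


def write_report(df: pd.DataFrame, cfg: ReportConfig) -> str:
    """Render and either write to ``cfg.out`` or return for printing."""
    text = render(df, cfg)
    if cfg.out is not None:
        Path(cfg.out).write_text(text, encoding="utf-8")
    return text
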