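"""Concordance integration of the exposure and cohort panels.

OncomiRs are miRNAs up-regulated under chronic areca nut exposure in at
least one cell line AND overexpressed in tumors; TSmiRs are the mirrored
down/under set.  Signature members additionally exceed an absolute
fold-regulation of 2 on both axes (the tumor/normal fold-regulation and
the averaged exposure fold-regulation).

The published signature lists are reproduced by a *strict* inequality
(> 2) on the printed values: with >=, one additional OncomiR sitting
exactly at tumor/normal fold-regulation 2.00 would join, contradicting
the published count of ten.  The non-strict variant is retained behind a
flag, with the boundary case documented.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .foldreg import average_fold_regulation, render_report_value, to_ratio

SIGNATURE_THRESHOLD = 2.0


@dataclass(frozen=True)
class IntegratedRecord:
    """One concordant miRNA with both axes' fold regulations (signed)."""

    mirna: str
    cls: str  # "OncomiR" | "TSmiR"
    tn_fr: float
    p_value: float
    per_line_fc: dict  # cell line -> signed fold-regulation
    avg_fc: float
    signature: bool = False


def signed_magnitude(value: float, dialect: str = "signed") -> float:
    """Fold magnitude of a panel value: max(r, 1/r) of its linear ratio."""
    r = to_ratio(value, dialect)
    return r if r >= 1 else 1.0 / r


def _fc_columns(df: pd.DataFrame) -> list[str]:
    return [c for c in df.columns if c.endswith("_fc") and c != "avg_fc"]


def compute_panel_averages(df: pd.DataFrame) -> pd.DataFrame:
    """Add ratio-scale averages and magnitudes to a panel-format frame.

    The frame follows the published layout (mirna, tn_fr, p, one ``*_fc``
    column per cell line, avg_fc) plus a ``dialect`` column naming how the
    fold values are printed.  ``avg_fc_computed`` is recomputed from the
    per-line values; any pre-printed ``avg_fc`` is left untouched for
    reference and report round-trips.
    """
    df = df.copy()
    dialect = df["dialect"].iloc[0] if "dialect" in df else "signed"
    fc_cols = _fc_columns(df)
    if not fc_cols:
        raise ValueError("panel frame has no per-line *_fc columns")
    df["avg_fc_computed"] = [
        average_fold_regulation(
            [row[c] for c in fc_cols], out_dialect="signed", in_dialect=dialect
        ).value
        for _, row in df.iterrows()
    ]
    df["tn_magnitude"] = [signed_magnitude(v, dialect) for v in df["tn_fr"]]
    df["avg_magnitude"] = [abs(v) for v in df["avg_fc_computed"]]
    return df


def integrate_panel_tables(
    oncomir_table: pd.DataFrame, tsmir_table: pd.DataFrame
) -> pd.DataFrame:
    """Stack the two published-format panel tables into one frame with
    recomputed averages and an OncomiR/TSmiR class column."""
    frames = []
    for cls, df in (("OncomiR", oncomir_table), ("TSmiR", tsmir_table)):
        df = compute_panel_averages(df)
        df["cls"] = cls
        frames.append(df)
    out = pd.concat(frames, ignore_index=True)
    if out["mirna"].duplicated().any():
        dups = out.loc[out["mirna"].duplicated(), "mirna"].tolist()
        raise ValueError(f"miRNA(s) present in both panels: {dups}")
    return out


def intersect_panels(
    ane_up: set[str],
    ane_down: set[str],
    cohort_over: set[str],
    cohort_under: set[str],
    ane_table: pd.DataFrame | None = None,
    cohort_table: pd.DataFrame | None = None,
) -> tuple[list[IntegratedRecord], list[IntegratedRecord]]:
    """Intersect the exposure and cohort panels into OncomiR/TSmiR sets.

    "Up in the exposure panel" means up in at least one cell line (the
    union regions R1+R2+R3), not the common-to-both set.  When the
    per-panel tables are supplied (``ane_table`` with ``fc_<line>`` ratio
    columns indexed by miRNA; ``cohort_table`` with signed ``tn_fr`` and
    ``p``), records carry both axes' values and each class is sorted by
    decreasing average exposure fold magnitude (published-table order).
    """
    if ane_up & ane_down or cohort_over & cohort_under:
        raise ValueError("up/down (over/under) input sets must be disjoint")
    oncomirs = sorted(ane_up & cohort_over)
    tsmirs = sorted(ane_down & cohort_under)

    def _records(names: list[str], cls: str) -> list[IntegratedRecord]:
        records = []
        for name in names:
            per_line: dict = {}
            avg = tn = p = float("nan")
            if ane_table is not None and name in ane_table.index:
                fc_cols = [c for c in ane_table.columns if c.startswith("fc_")]
                ratios = [float(ane_table.loc[name, c]) for c in fc_cols]
                per_line = {
                    c.removeprefix("fc_"): (r if r >= 1 else -1.0 / r)
                    for c, r in zip(fc_cols, ratios)
                }
                avg = average_fold_regulation(ratios, "signed", in_dialect="ratio").value
            if cohort_table is not None and name in cohort_table.index:
                tn = float(cohort_table.loc[name, "tn_fr"])
                p = float(cohort_table.loc[name, "p"])
            records.append(IntegratedRecord(name, cls, tn, p, per_line, avg))
        records.sort(key=lambda rec: -abs(rec.avg_fc))
        return records

    return _records(oncomirs, "OncomiR"), _records(tsmirs, "TSmiR")


def select_signatures(
    records: pd.DataFrame | list[IntegratedRecord],
    threshold: float = SIGNATURE_THRESHOLD,
    strict: bool = True,
) -> list[str]:
    """Two-axis signature selection.

    Keeps miRNAs whose tumor/normal fold magnitude AND averaged exposure
    fold magnitude both exceed ``threshold`` (strictly by default; at or
    above with ``strict=False``).
    """
    if isinstance(records, pd.DataFrame):
        df = records if "avg_magnitude" in records else compute_panel_averages(records)
        triples = list(zip(df["mirna"], df["tn_magnitude"], df["avg_magnitude"]))
    else:
        triples = [(r.mirna, abs(r.tn_fr), abs(r.avg_fc)) for r in records]
    if strict:
        return [n for n, a, b in triples if a > threshold and b > threshold]
    return [n for n, a, b in triples if a >= threshold and b >= threshold]


def render_panel_table(panel: pd.DataFrame, decimals: int = 2) -> pd.DataFrame:
    """Render a panel-format frame in the published layout.

    Fold columns are half-up rounded strings at ``decimals``; the p column
    is passed through verbatim; rows are stable-sorted by decreasing
    average fold magnitude, so a parsed published table renders back
    byte-identically.
    """
    df = panel.copy()
    dialect = df["dialect"].iloc[0] if "dialect" in df else "signed"
    sort_key = [
        signed_magnitude(v, dialect) if dialect == "ratio" else abs(v)
        for v in df["avg_fc"]
    ]
    df = df.iloc[pd.Series(sort_key).sort_values(ascending=False, kind="stable").index]
    out = pd.DataFrame({"mirna": df["mirna"].to_numpy(), "tn_fr": "", "p": df["p"].to_numpy()})
    out["tn_fr"] = [render_report_value(v, decimals) for v in df["tn_fr"]]
    for c in _fc_columns(panel):
        out[c] = [render_report_value(v, decimals) for v in df[c]]
    out["avg_fc"] = [render_report_value(v, decimals) for v in df["avg_fc"]]
    return out.reset_index(drop=True)


def records_to_panel_frame(records: list[IntegratedRecord]) -> pd.DataFrame:
    """Panel-format frame (signed dialect) from integrated records."""
    rows = []
    for rec in records:
        row = {"mirna": rec.mirna, "tn_fr": rec.tn_fr, "p": rec.p_value}
        for line, fc in rec.per_line_fc.items():
            row[f"{line}_fc"] = fc
        row["avg_fc"] = rec.avg_fc
        rows.append(row)
    df = pd.DataFrame(rows)
    df["dialect"] = "signed"
    return df
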