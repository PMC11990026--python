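"""Report rendering: color-coded concordance tables and quality summaries.

The merged concordance table can be exported as TSV, XLSX (with the
category cell filled in its color) or a static HTML page.  Quality
metrics (QUAL, DP and the bcftools bias statistics) are summarized per
platform as mean, sample standard deviation (n−1 denominator) and Tukey
boxplot statistics (quartiles plus 1.5×IQR whiskers).
"""

from __future__ import annotations

import html
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .concordance import (
    CATEGORY_COLORS,
    ConcordanceCategory,
    ConcordanceRecord,
    ConcordanceSummary,
    records_to_frame,
    summarize,
)
from .io_vcf import EXTRA_METRIC_NAMES, Platform, SampleVariantCall

#: Category → cell-fill hex (RGB, no '#'), overridable via config.
DEFAULT_HEX_COLORS = {
    ConcordanceCategory.AGREE: "C6EFCE",
    ConcordanceCategory.DISCREPANT: "FFC7CE",
    ConcordanceCategory.ILLUMINA_ONLY: "FFEB9C",
    ConcordanceCategory.ONT_ONLY: "FFD8A8",
}

QUALITY_METRICS = ("QUAL", "DP") + EXTRA_METRIC_NAMES


@dataclass(frozen=True)
class QualityMetricsSummary:
    metric: str
    platform: Platform
    n: int
    mean: float
    sd: float
    quartiles: tuple[float, float, float]  # q1, median, q3
    whiskers: tuple[float, float]  # Tukey low/high
    n_missing: int = 0  # calls lacking this metric


def _metric_value(call: SampleVariantCall, metric: str) -> Optional[float]:
    if metric == "QUAL":
        return call.qual
    if metric == "DP":
        return float(call.depth) if call.depth is not None else None
    return call.extra_metrics.get(metric)


def summarize_quality_metrics(
    calls: Sequence[SampleVariantCall],
    metrics: Sequence[str] = QUALITY_METRICS,
) -> list[QualityMetricsSummary]:
    """Per-metric, per-platform distribution summaries.

    Calls lacking a metric are skipped (count disclosed in
    ``n_missing``); a metric absent from every call yields a warning and
    no summary row.
    """
    out = []
    platforms = sorted({c.platform for c in calls}, key=lambda p: p.value)
    for metric in metrics:
        metric_seen = False
        for platform in platforms:
            sub = [c for c in calls if c.platform is platform]
            values = np.array(
                [v for c in sub if (v := _metric_value(c, metric)) is not None
                 and not np.isnan(v)]
            )
            if values.size == 0:
                continue
            metric_seen = True
            q1, med, q3 = np.percentile(values, [25, 50, 75])
            iqr = q3 - q1
            in_fence = values[
                (values >= q1 - 1.5 * iqr) & (values <= q3 + 1.5 * iqr)
            ]
            out.append(
                QualityMetricsSummary(
                    metric=metric,
                    platform=platform,
                    n=int(values.size),
                    mean=float(values.mean()),
                    sd=float(values.std(ddof=1)) if values.size > 1 else 0.0,
                    quartiles=(float(q1), float(med), float(q3)),
                    whiskers=(float(in_fence.min()), float(in_fence.max())),
                    n_missing=len(sub) - int(values.size),
                )
            )
        if calls and not metric_seen:
            warnings.warn(f"metric {metric} absent from all calls", stacklevel=2)
    return out


def quality_summary_frame(summaries: Sequence[QualityMetricsSummary]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "metric": s.metric,
                "platform": s.platform.value,
                "n": s.n,
                "mean": s.mean,
                "sd": s.sd,
                "q1": s.quartiles[0],
                "median": s.quartiles[1],
                "q3": s.quartiles[2],
                "whisker_low": s.whiskers[0],
                "whisker_high": s.whiskers[1],
                "n_missing": s.n_missing,
            }
            for s in summaries
        ]
    )


def _summary_frame(summaries: Sequence[ConcordanceSummary]) -> pd.DataFrame:
    rows = []
    for s in summaries:
        row = {"scope": s.scope, "key": "all" if s.key is None else str(s.key)}
        for cat in ConcordanceCategory:
            row[f"n_{cat.value.lower()}"] = s.counts[cat]
            row[f"f_{cat.value.lower()}"] = s.frequencies[cat]
        rows.append(row)
    return pd.DataFrame(rows)


def render_concordance_report(
    records: Sequence[ConcordanceRecord],
    path: str | Path,
    fmt: str = "tsv",
    summaries: Optional[Sequence[ConcordanceSummary]] = None,
    hex_colors: Optional[dict[ConcordanceCategory, str]] = None,
) -> Path:
    """Write the merged, color-coded concordance table.

    One row per (sample, site) with category, color and both platforms'
    GT/QUAL/DP.  For xlsx and html the category cell is filled with the
    category color; per-position and per-sample frequency sheets (or
    sections) are appended.  ``summaries`` defaults to the per-position
    and per-sample aggregations of ``records``.
    """
    path = Path(path)
    hex_colors = hex_colors or DEFAULT_HEX_COLORS
    frame = records_to_frame(records)
    if summaries is None:
        summaries = summarize(records, "per_position") + summarize(
            records, "per_sample"
        )
    if fmt == "tsv":
        frame.to_csv(path, sep="\t", index=False, na_rep=".")
        if summaries:
            _summary_frame(summaries).to_csv(
                path.with_suffix(".summary.tsv"), sep="\t", index=False
            )
    elif fmt == "xlsx":
        _render_xlsx(frame, summaries, path, hex_colors)
    elif fmt == "html":
        _render_html(frame, summaries, path, hex_colors)
    else:
        raise ValueError(f"unknown report format {fmt!r}")
    return path


def _render_xlsx(frame, summaries, path, hex_colors) -> None:
    from openpyxl import Workbook
    from openpyxl.styles import PatternFill

    wb = Workbook()
    ws = wb.active
    ws.title = "concordance"
    ws.append(list(frame.columns))
    fills = {
        cat.value: PatternFill(start_color=hx, end_color=hx, fill_type="solid")
        for cat, hx in hex_colors.items()
    }
    cat_col = list(frame.columns).index("category") + 1
    for _, row in frame.iterrows():
        ws.append(["." if pd.isna(v) else v for v in row.tolist()])
        ws.cell(row=ws.max_row, column=cat_col).fill = fills[row["category"]]
    if summaries:
        ws2 = wb.create_sheet("frequencies")
        sf = _summary_frame(summaries)
        ws2.append(list(sf.columns))
        for _, row in sf.iterrows():
            ws2.append(row.tolist())
    wb.save(path)


def _render_html(frame, summaries, path, hex_colors) -> None:
    css_colors = {cat.value: f"#{hx}" for cat, hx in hex_colors.items()}

    def table(df: pd.DataFrame, color_by_category: bool) -> str:
        head = "".join(f"<th>{html.escape(str(c))}</th>" for c in df.columns)
        body = []
        for _, row in df.iterrows():
            cells = []
            for col, v in row.items():
                text = "." if pd.isna(v) else html.escape(str(v))
                style = ""
                if color_by_category and col == "category":
                    style = f' style="background-color:{css_colors[row["category"]]}"'
                cells.append(f"<td{style}>{text}</td>")
            body.append("<tr>" + "".join(cells) + "</tr>")
        return (
            f"<table><thead><tr>{head}</tr></thead>"
            f"<tbody>{''.join(body)}</tbody></table>"
        )

    parts = [
        "<!DOCTYPE html><html><head><meta charset='utf-8'>",
        "<title>Concordance report</title>",
        "<style>table{border-collapse:collapse}td,th{border:1px solid #999;"
        "padding:2px 6px;font:12px monospace}</style></head><body>",
        "<h1>Cross-platform concordance</h1>",
        table(frame, True),
    ]
    if summaries:
        parts += ["<h2>Category frequencies</h2>", table(_summary_frame(summaries), False)]
    parts.append("</body></html>")
    Path(path).write_text("\n".join(parts))
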