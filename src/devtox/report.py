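"""Text/TSV and HTML report writers for per-compound predictions."""

from __future__ import annotations

import html
from dataclasses import dataclass

from devtox.applicability_domain import ADReport


@dataclass
class CompoundReport:
    """One output row: prediction, confidence, remarks and neighbours."""

    id: str
    smiles: str
    predicted_class: str
    confidence: float | None  # AFP degree or RF vote fraction
    remarks: str = "none"
    ad: ADReport | None = None
    error: str = ""  # non-empty for rows that failed to parse


_TSV_COLUMNS = [
    "id",
    "smiles",
    "predicted_class",
    "confidence",
    "remarks",
    "error",
]


def _neighbor_cells(report: CompoundReport, k: int = 6) -> list[str]:
    cells = []
    neighbors = report.ad.neighbors.neighbors if report.ad else []
    for i in range(k):
        if i < len(neighbors):
            nb = neighbors[i]
            cells.append(
                f"{nb.id}|s={nb.breakdown.s:.3f}"
                f"|exp={nb.experimental_class or '?'}"
                f"|pred={nb.predicted_class or '?'}"
            )
        else:
            cells.append("")
    return cells


def write_tsv(reports: list[CompoundReport], path) -> None:
    header = _TSV_COLUMNS + [f"neighbor{i+1}" for i in range(6)]
    with open(path, "w") as fh:
        fh.write("\t".join(header) + "\n")
        for r in reports:
            conf = "" if r.confidence is None else f"{r.confidence:.4f}"
            row = [r.id, r.smiles, r.predicted_class, conf, r.remarks, r.error]
            row += _neighbor_cells(r)
            fh.write("\t".join(row) + "\n")


def write_html(reports: list[CompoundReport], path, title: str = "Predictions") -> None:
    rows = []
    for r in reports:
        conf = "" if r.confidence is None else f"{r.confidence:.4f}"
        neighbors = "<br>".join(c for c in _neighbor_cells(r) if c) or "&mdash;"
        rows.append(
            "<tr>"
            f"<td>{html.escape(r.id)}</td>"
            f"<td><code>{html.escape(r.smiles)}</code></td>"
            f"<td>{html.escape(r.predicted_class)}</td>"
            f"<td>{conf}</td>"
            f"<td>{html.escape(r.remarks)}</td>"
            f"<td>{neighbors}</td>"
            "</tr>"
        )
    doc = (
        "<!DOCTYPE html>\n<html><head><meta charset='utf-8'>"
        f"<title>{html.escape(title)}</title>"
        "<style>body{font-family:sans-serif}table{border-collapse:collapse}"
        "td,th{border:1px solid #999;padding:4px 8px;vertical-align:top}"
        "th{background:#eee}</style></head><body>"
        f"<h1>{html.escape(title)}</h1>"
        "<table><tr><th>id</th><th>SMILES</th><th>predicted</th>"
        "<th>confidence</th><th>remarks</th><th>six nearest neighbours</th></tr>"
        + "".join(rows)
        + "</table></body></html>\n"
    )
    with open(path, "w") as fh:
        fh.write(doc)
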