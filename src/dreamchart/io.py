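"""Reading dream reports and external-variable tables.

Reports can come as plain-text files (one report each), a directory of
such files, or a CSV / JSON-lines table with ``id`` and ``text`` columns.
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd

from .scoring import DreamReport

__all__ = ["read_reports", "read_externals"]


def _reports_from_frame(frame: pd.DataFrame, source: str) -> list[DreamReport]:
    cols = {c.lower(): c for c in frame.columns}
    if "id" not in cols or "text" not in cols:
        raise ValueError(f"{source}: expected columns 'id' and 'text', got {list(frame.columns)}")
    return [
        DreamReport(report_id=str(row[cols["id"]]), text=str(row[cols["text"]]))
        for _, row in frame.iterrows()
    ]


def read_reports(path: str | Path) -> list[DreamReport]:
    """Load dream reports from a file or directory.

    * ``.txt`` file — one report; the stem becomes the report_id
    * directory — every ``*.txt`` inside, sorted by name
    * ``.csv`` — columns ``id,text``
    * ``.jsonl`` — one JSON object per line with keys ``id`` and ``text``
    """
    path = Path(path)
    if path.is_dir():
        files = sorted(path.glob("*.txt"))
        if not files:
            raise FileNotFoundError(f"no .txt reports in {path}")
        return [DreamReport(report_id=f.stem, text=f.read_text(encoding="utf-8")) for f in files]
    if not path.exists():
        raise FileNotFoundError(path)
    suffix = path.suffix.lower()
    if suffix == ".txt":
        return [DreamReport(report_id=path.stem, text=path.read_text(encoding="utf-8"))]
    if suffix == ".csv":
        return _reports_from_frame(pd.read_csv(path), str(path))
    if suffix in (".jsonl", ".ndjson"):
        rows = [
            json.loads(line)
            for line in path.read_text(encoding="utf-8").splitlines()
            if line.strip()
        ]
        return _reports_from_frame(pd.DataFrame(rows), str(path))
    raise ValueError(f"unsupported report format: {path.suffix!r}")


def read_externals(path: str | Path) -> pd.DataFrame:
    """Load an external-variables CSV: one row per report_id, numeric columns."""
    frame = pd.read_csv(path)
    cols = {c.lower(): c for c in frame.columns}
    if "report_id" not in cols:
        raise ValueError(f"{path}: externals table needs a 'report_id' column")
    frame = frame.rename(columns={cols["report_id"]: "report_id"})
    frame["report_id"] = frame["report_id"].astype(str)
    return frame
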