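"""Tab-separated table formats.

Two count-table dialects are supported:

* ``plain`` — first column ``sample_id``, remaining columns OTU counts;
* ``shared`` — the mothur shared dialect: ``label``, ``Group``, ``numOtus``
  followed by the OTU columns.

Files may begin with ``#key=value`` comment lines; writers emit a header
recording the stage name, seed and parameters so every output is
self-describing.  Readers validate integer cells, ragged rows and duplicate
sample ids, reporting line numbers.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ParseError

__all__ = [
    "read_count_table",
    "write_count_table",
    "read_table",
    "write_table",
    "read_header_meta",
]


def _header_lines(meta: dict | None) -> list[str]:
    if not meta:
        return []
    return [f"#{k}={json.dumps(v) if not isinstance(v, str) else v}" for k, v in meta.items()]


def read_header_meta(path) -> dict:
    meta = {}
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            if "=" in line:
                k, v = line[1:].rstrip("\n").split("=", 1)
                meta[k] = v
    return meta


def write_count_table(table: pd.DataFrame, path, dialect: str = "plain",
                      meta: dict | None = None) -> None:
    path = Path(path)
    lines = _header_lines(meta)
    if dialect == "plain":
        lines.append("\t".join(["sample_id"] + [str(c) for c in table.columns]))
        for sid, row in table.iterrows():
            lines.append("\t".join([str(sid)] + [str(int(v)) for v in row]))
    elif dialect == "shared":
        lines.append("\t".join(["label", "Group", "numOtus"] + [str(c) for c in table.columns]))
        for sid, row in table.iterrows():
            lines.append(
                "\t".join(["0.97", str(sid), str(table.shape[1])]
                          + [str(int(v)) for v in row])
            )
    else:
        raise ParseError(f"unknown dialect {dialect!r}")
    path.write_text("\n".join(lines) + "\n")


def read_count_table(path, dialect: str | None = None) -> pd.DataFrame:
    """Read either count-table dialect (auto-detected from the header)."""
    path = Path(path)
    raw = [
        (i + 1, line.rstrip("\n"))
        for i, line in enumerate(path.read_text().splitlines())
        if line.strip()
    ]
    body = [(ln, line) for ln, line in raw if not line.startswith("#")]
    if not body:
        raise ParseError(f"{path}: no header row found")
    header_ln, header = body[0]
    fields = header.split("\t")
    if dialect is None:
        dialect = "shared" if fields[:3] == ["label", "Group", "numOtus"] else "plain"
    if dialect == "shared":
        otus = fields[3:]
        id_pos, first_count = 1, 3
    else:
        otus = fields[1:]
        id_pos, first_count = 0, 1

    ids, rows = [], []
    seen = {}
    for ln, line in body[1:]:
        cells = line.split("\t")
        if len(cells) != len(fields):
            raise ParseError(f"{path}:{ln}: ragged row ({len(cells)} fields, expected {len(fields)})")
        sid = cells[id_pos]
        if sid in seen:
            raise ParseError(f"{path}:{ln}: duplicate sample id {sid!r} (first at line {seen[sid]})")
        seen[sid] = ln
        try:
            counts = [int(c) for c in cells[first_count:]]
        except ValueError as exc:
            raise ParseError(f"{path}:{ln}: non-integer cell ({exc})") from exc
        ids.append(sid)
        rows.append(counts)
    table = pd.DataFrame(rows, index=pd.Index(ids, name="sample_id"), columns=otus)
    return table.astype(np.int64)


def write_table(frame: pd.DataFrame, path, meta: dict | None = None,
                index: bool = True, float_format: str = "%.10g") -> None:
    """Write any DataFrame as tab-separated text with a comment header."""
    path = Path(path)
    with open(path, "w") as fh:
        for line in _header_lines(meta):
            fh.write(line + "\n")
        frame.to_csv(fh, sep="\t", index=index, float_format=float_format)


def read_table(path, index_col=0) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#", index_col=index_col)
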