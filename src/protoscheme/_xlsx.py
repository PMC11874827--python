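"""Byte-deterministic xlsx writing.

openpyxl stamps wall-clock times into both the workbook properties and
the zip entries, so two writes of identical content differ. Scheme
outputs and generated fixtures must be reproducible byte-for-byte, so
workbook timestamps are pinned and the archive is repacked with constant
entry metadata and sorted names.
"""

from __future__ import annotations

import datetime
import io
import re
import zipfile
from pathlib import Path

import openpyxl

_EPOCH = datetime.datetime(2000, 1, 1)
_MODIFIED_RE = re.compile(
    rb"(<dcterms:modified[^>]*>)[^<]*(</dcterms:modified>)"
)


def write_workbook(wb: "openpyxl.Workbook", path: Path) -> None:
    wb.properties.created = _EPOCH
    wb.properties.modified = _EPOCH
    buf = io.BytesIO()
    wb.save(buf)
    src = zipfile.ZipFile(io.BytesIO(buf.getvalue()))
    out = io.BytesIO()
    with zipfile.ZipFile(out, "w", zipfile.ZIP_DEFLATED) as dst:
        for name in sorted(src.namelist()):
            data = src.read(name)
            if name == "docProps/core.xml":
                # openpyxl resets `modified` at save time; pin it again
                data = _MODIFIED_RE.sub(rb"\g<1>2000-01-01T00:00:00Z\g<2>", data)
            info = zipfile.ZipInfo(name, date_time=(1980, 1, 1, 0, 0, 0))
            info.compress_type = zipfile.ZIP_DEFLATED
            dst.writestr(info, data)
    Path(path).write_bytes(out.getvalue())


def write_rows(rows: list[list], path: Path) -> None:
    """Write a header+data row list as a deterministic xlsx file."""
    wb = openpyxl.Workbook()
    ws = wb.active
    for row in rows:
        ws.append(row)
    write_workbook(wb, path)
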