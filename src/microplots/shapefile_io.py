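"""Minimal ESRI shapefile I/O for polygon layers.

Implements exactly the subset of the shapefile format this package needs:
2-D polygon geometry (shape type 5) in ``.shp``/``.shx``, attribute records
in dBASE III ``.dbf`` (numeric and character fields), and a ``.prj`` sidecar
carrying an opaque CRS tag verbatim.  Outer rings are written clockwise as
the format requires.  No installed library provides shapefile access, hence
this hand-rolled reader/writer; it round-trips its own output and reads any
single-ring polygon layer with a flat attribute table.
"""

from __future__ import annotations

import struct
from pathlib import Path

import numpy as np

__all__ = ["write_polygons", "read_polygons"]

_SHAPE_POLYGON = 5


def _ring_signed_area(ring: np.ndarray) -> float:
    x, y = ring[:, 0], ring[:, 1]
    return 0.5 * float(np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y))


def _close_clockwise(points) -> np.ndarray:
    ring = np.asarray(points, dtype=float)
    if not np.allclose(ring[0], ring[-1]):
        ring = np.vstack([ring, ring[0]])
    # shapefile convention: outer ring vertices in clockwise order
    if _ring_signed_area(ring) > 0:
        ring = ring[::-1]
    return ring


def _field_descriptors(records: list[dict]) -> list[tuple[str, str, int, int]]:
    descs = []
    for name in records[0]:
        values = [r[name] for r in records]
        if all(isinstance(v, (int, np.integer)) and not isinstance(v, bool) for v in values):
            descs.append((name, "N", 10, 0))
        elif all(isinstance(v, (int, float, np.floating, np.integer)) for v in values):
            descs.append((name, "N", 19, 8))
        else:
            width = max(1, min(254, max(len(str(v)) for v in values)))
            descs.append((name, "C", width, 0))
    return descs


def _write_dbf(path: Path, records: list[dict]) -> None:
    descs = _field_descriptors(records)
    record_size = 1 + sum(w for _, _, w, _ in descs)
    header_size = 32 + 32 * len(descs) + 1
    buf = bytearray()
    buf += struct.pack("<B3BLHH20x", 0x03, 95, 7, 26, len(records), header_size, record_size)
    for name, ftype, width, dec in descs:
        buf += struct.pack("<11sc4xBB14x", name.encode("ascii")[:10], ftype.encode(), width, dec)
    buf += b"\x0d"
    for rec in records:
        buf += b" "
        for name, ftype, width, dec in descs:
            v = rec[name]
            if ftype == "N":
                text = f"{v:.{dec}f}" if dec else f"{int(v):d}"
                buf += text.rjust(width).encode("ascii")[:width]
            else:
                buf += str(v).ljust(width).encode("ascii", "replace")[:width]
    buf += b"\x1a"
    path.write_bytes(bytes(buf))


def _read_dbf(path: Path) -> list[dict]:
    raw = path.read_bytes()
    n_records, header_size, record_size = struct.unpack_from("<LHH", raw, 4)
    descs = []
    pos = 32
    while raw[pos] != 0x0D:
        name = raw[pos:pos + 11].split(b"\x00")[0].decode("ascii")
        ftype = chr(raw[pos + 11])
        width, dec = raw[pos + 16], raw[pos + 17]
        descs.append((name, ftype, width, dec))
        pos += 32
    records = []
    pos = header_size
    for _ in range(n_records):
        rec, offset = {}, pos + 1  # skip deletion flag
        for name, ftype, width, dec in descs:
            text = raw[offset:offset + width].decode("ascii", "replace").strip()
            offset += width
            if ftype == "N" and text:
                rec[name] = float(text) if dec or "." in text else int(text)
            else:
                rec[name] = text
        records.append(rec)
        pos += record_size
    return records


def write_polygons(base_path, polygons, records=None, crs_tag=None) -> Path:
    """Write single-ring polygons plus attributes as ``base.shp/.shx/.dbf``.

    ``polygons`` is a sequence of point sequences (one exterior ring each);
    ``records`` a parallel list of flat attribute dicts (defaults to an
    ``id`` counter).  Returns the ``.shp`` path.
    """
    base = Path(base_path).with_suffix("")
    rings = [_close_clockwise(p) for p in polygons]
    if not rings:
        raise ValueError("cannot write an empty polygon layer")
    if records is None:
        records = [{"id": i} for i in range(len(rings))]
    if len(records) != len(rings):
        raise ValueError("records and polygons differ in length")

    all_pts = np.vstack(rings)
    bbox = (*all_pts.min(axis=0), *all_pts.max(axis=0))  # xmin ymin xmax ymax

    shp_records, shx_records = [], []
    offset_words = 50  # main header = 100 bytes
    for i, ring in enumerate(rings):
        content = struct.pack("<i4dii", _SHAPE_POLYGON,
                              ring[:, 0].min(), ring[:, 1].min(),
                              ring[:, 0].max(), ring[:, 1].max(), 1, len(ring))
        content += struct.pack("<i", 0)
        content += ring.astype("<f8").tobytes()
        length_words = len(content) // 2
        shp_records.append(struct.pack(">ii", i + 1, length_words) + content)
        shx_records.append(struct.pack(">ii", offset_words, length_words))
        offset_words += 4 + length_words

    def main_header(total_words: int) -> bytes:
        return struct.pack(">i5ii", 9994, 0, 0, 0, 0, 0, total_words) + \
            struct.pack("<ii4d4d", 1000, _SHAPE_POLYGON, *bbox, 0, 0, 0, 0)

    shp_body = b"".join(shp_records)
    base.with_suffix(".shp").write_bytes(main_header(50 + len(shp_body) // 2) + shp_body)
    shx_body = b"".join(shx_records)
    base.with_suffix(".shx").write_bytes(main_header(50 + len(shx_body) // 2) + shx_body)
    _write_dbf(base.with_suffix(".dbf"), records)
    if crs_tag:
        base.with_suffix(".prj").write_text(str(crs_tag))
    return base.with_suffix(".shp")


def read_polygons(path):
    """Read a polygon shapefile; returns ``(rings, records, crs_tag)``.

    ``rings`` are ``(N, 2)`` float arrays (exterior ring, closed); multi-ring
    shapes yield their first ring only.  ``crs_tag`` is the verbatim ``.prj``
    content or ``None``.
    """
    base = Path(path).with_suffix("")
    raw = base.with_suffix(".shp").read_bytes()
    if struct.unpack_from(">i", raw, 0)[0] != 9994:
        raise ValueError(f"{path}: not a shapefile")
    shape_type = struct.unpack_from("<i", raw, 32)[0]
    if shape_type != _SHAPE_POLYGON:
        raise ValueError(f"{path}: unsupported shape type {shape_type}")

    rings = []
    pos = 100
    while pos < len(raw):
        _, length_words = struct.unpack_from(">ii", raw, pos)
        pos += 8
        stype = struct.unpack_from("<i", raw, pos)[0]
        if stype != _SHAPE_POLYGON:
            raise ValueError(f"record at byte {pos}: unsupported shape type {stype}")
        n_parts, n_points = struct.unpack_from("<ii", raw, pos + 36)
        parts = np.frombuffer(raw, "<i4", n_parts, pos + 44)
        pts = np.frombuffer(raw, "<f8", 2 * n_points, pos + 44 + 4 * n_parts)
        pts = pts.reshape(-1, 2)
        end = parts[1] if n_parts > 1 else n_points
        rings.append(np.array(pts[parts[0]:end]))
        pos += 2 * length_words

    dbf = base.with_suffix(".dbf")
    records = _read_dbf(dbf) if dbf.exists() else [{} for _ in rings]
    prj = base.with_suffix(".prj")
    crs_tag = prj.read_text().strip() if prj.exists() else None
    return rings, records, crs_tag
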