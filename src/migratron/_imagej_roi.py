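"""Minimal codec for ImageJ ``.roi`` polyline files.

Only the subset needed here is supported: polyline (and polygon/freeline)
vertex chains with integer pixel coordinates, plus ``.zip`` archives of such
files as written by the ImageJ ROI manager. Coordinates are stored in the
file as shorts relative to the bounding box, big-endian, starting at byte 64.
"""
from __future__ import annotations

import struct
import zipfile
from pathlib import Path

_MAGIC = b"Iout"
_VERSION = 227

# ImageJ roi type bytes
TYPE_POLYGON = 0
TYPE_LINE = 3
TYPE_FREELINE = 4
TYPE_POLYLINE = 5
_VERTEX_TYPES = {TYPE_POLYGON, TYPE_FREELINE, TYPE_POLYLINE}


def decode_roi(data: bytes, default_name: str = "roi") -> tuple[str, list[tuple[float, float]]]:
    """Decode one .roi blob into ``(name, [(x_px, y_px), ...])``."""
    if len(data) < 64 or data[:4] != _MAGIC:
        raise ValueError("not an ImageJ ROI file (bad magic)")
    roi_type = data[6]
    top, left, bottom, right = struct.unpack(">4h", data[8:16])
    (n,) = struct.unpack(">h", data[16:18])
    if roi_type == TYPE_LINE:
        x1, y1, x2, y2 = struct.unpack(">4f", data[18:34])
        return _read_name(data, default_name), [(x1, y1), (x2, y2)]
    if roi_type not in _VERTEX_TYPES:
        raise ValueError(f"unsupported ImageJ ROI type {roi_type}; expected a polyline")
    if n < 2:
        raise ValueError("ImageJ ROI has fewer than 2 vertices")
    off = 64
    xs = struct.unpack(f">{n}h", data[off : off + 2 * n])
    ys = struct.unpack(f">{n}h", data[off + 2 * n : off + 4 * n])
    pts = [(float(x + left), float(y + top)) for x, y in zip(xs, ys)]
    return _read_name(data, default_name), pts


def _read_name(data: bytes, default: str) -> str:
    # header2 offset lives at bytes 56..60; name offset/length at header2+16/+20
    try:
        (h2,) = struct.unpack(">i", data[56:60])
        if h2 <= 0 or h2 + 24 > len(data):
            return default
        name_off, name_len = struct.unpack(">2i", data[h2 + 16 : h2 + 24])
        if name_off <= 0 or name_len <= 0:
            return default
        raw = data[name_off : name_off + 2 * name_len]
        return raw.decode("utf-16-be")
    except (struct.error, UnicodeDecodeError):
        return default


def encode_polyline(points_px: list[tuple[float, float]]) -> bytes:
    """Encode integer pixel vertices as an ImageJ polyline ROI blob."""
    if len(points_px) < 2:
        raise ValueError("polyline needs at least 2 vertices")
    xs = [int(round(x)) for x, _ in points_px]
    ys = [int(round(y)) for _, y in points_px]
    left, top = min(xs), min(ys)
    right, bottom = max(xs), max(ys)
    n = len(xs)
    header = bytearray(64)
    header[:4] = _MAGIC
    struct.pack_into(">h", header, 4, _VERSION)
    header[6] = TYPE_POLYLINE
    struct.pack_into(">4h", header, 8, top, left, bottom, right)
    struct.pack_into(">h", header, 16, n)
    body = struct.pack(f">{n}h", *[x - left for x in xs]) + struct.pack(
        f">{n}h", *[y - top for y in ys]
    )
    return bytes(header) + body


def read_roi_file(path: str | Path) -> list[tuple[str, list[tuple[float, float]]]]:
    """Read a ``.roi`` file or a ``.zip`` of them; returns [(name, points_px)]."""
    path = Path(path)
    if zipfile.is_zipfile(path):
        out = []
        with zipfile.ZipFile(path) as zf:
            for entry in zf.namelist():
                stem = Path(entry).stem
                name, pts = decode_roi(zf.read(entry), default_name=stem)
                out.append((stem if name == "roi" else name, pts))
        return out
    data = path.read_bytes()
    name, pts = decode_roi(data, default_name=path.stem)
    return [(name, pts)]


def write_roi_file(path: str | Path, points_px: list[tuple[float, float]]) -> None:
    Path(path).write_bytes(encode_polyline(points_px))


def write_roi_zip(path: str | Path, rois: dict[str, list[tuple[float, float]]]) -> None:
    with zipfile.ZipFile(path, "w") as zf:
        for name, pts in rois.items():
            zf.writestr(f"{name}.roi", encode_polyline(pts))
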