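"""Image and table I/O: 16-bit single-channel TIFF in/out, ground-truth CSVs.

Timepoints are parsed from a ``t<minutes>min`` token in the filename (e.g.
``field0_t45min.tif``) or from a JSON sidecar (``<stem>.json`` with a
``timepoint_min`` key). Intensities round-trip bit-exactly.
"""

from __future__ import annotations

import json
import re
from pathlib import Path

import numpy as np
import tifffile


class ImageFormatError(ValueError):
    """Unsupported image layout (e.g. RGB / multi-channel input)."""


_TIME_RE = re.compile(r"t(\d+(?:\.\d+)?)min")


def _parse_timepoint(path: Path) -> float | None:
    sidecar = path.with_suffix(".json")
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())
        if "timepoint_min" in meta:
            return float(meta["timepoint_min"])
    m = _TIME_RE.search(path.stem)
    return float(m.group(1)) if m else None


def read_images(paths) -> list[dict]:
    """Read single-channel grayscale TIFFs.

    Returns one dict per file: ``image`` (2-D array, dtype preserved),
    ``path``, ``timepoint_min`` (or None) and ``saturation_level`` (255
    for 8-bit input, 65535 for 16-bit).
    """
    out = []
    for p in map(Path, paths):
        if not p.exists():
            raise FileNotFoundError(f"image not found: {p}")
        img = tifffile.imread(p)
        if img.ndim != 2:
            raise ImageFormatError(
                f"{p}: expected a single-channel grayscale image, got shape "
                f"{img.shape}; split channels / convert RGB to gray first")
        if img.dtype == np.uint8:
            sat = 255.0
        elif img.dtype == np.uint16:
            sat = 65535.0
        else:
            sat = float(img.max()) if img.size else 0.0
        out.append({"image": img, "path": str(p),
                    "timepoint_min": _parse_timepoint(p),
                    "saturation_level": sat})
    return out


def write_field(outdir, images, timepoints, ground_truth=None,
                field_id: str = "field0") -> list[Path]:
    """Write one image per timepoint plus ground-truth CSVs and the
    parameter snapshot (JSON, including the seed)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written = []
    for img, t in zip(images, timepoints):
        p = outdir / f"{field_id}_t{t:g}min.tif"
        tifffile.imwrite(p, img)
        written.append(p)
    if ground_truth is not None:
        ground_truth.cells.to_csv(outdir / f"{field_id}_cells.csv", index=False)
        ground_truth.foci.to_csv(outdir / f"{field_id}_foci.csv", index=False)
        snap = {"seed": ground_truth.seed, "params": ground_truth.params}
        (outdir / f"{field_id}_params.json").write_text(
            json.dumps(snap, indent=2, default=str))
    return written
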