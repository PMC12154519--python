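"""Lossless image I/O: grayscale TIFF + CSV twins + JSON metadata sidecar.

Each energy window of a :class:`DetectedImage` is written as

* ``<prefix>_w<k>.tif``  -- little-endian grayscale TIFF, uint16 when the
  counts fit, automatically promoted to uint32 otherwise (promotion logged
  in the sidecar);
* ``<prefix>_w<k>.csv``  -- integer count matrix, decoding identically;
* ``<prefix>_w<k>_weights.csv`` / ``..._weights_sq.csv`` -- weighted grids,
  written only when they differ from the counts (cone-sampled runs);

plus a single ``<prefix>_meta.json`` carrying windows, seed, protocol summary
and tallies.  ``read_image(write_image(img)) == img``.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import tifffile

from .emission import EnergyWindow
from .transport import DetectedImage

__all__ = ["write_image", "read_image"]


def write_image(image: DetectedImage, prefix: str | Path) -> list[Path]:
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    windows_meta = []
    for k, window in enumerate(image.windows):
        counts = image.counts[window]
        if counts.max(initial=0) <= np.iinfo(np.uint16).max:
            enc = counts.astype(np.uint16)
            dtype = "uint16"
        else:
            enc = counts.astype(np.uint32)
            dtype = "uint32"
        tif = prefix.parent / f"{prefix.name}_w{k}.tif"
        tifffile.imwrite(tif, enc, byteorder="<")
        csv = tif.with_suffix(".csv")
        np.savetxt(csv, counts, fmt="%d", delimiter=",")
        written += [tif, csv]
        wmeta = {"index": k, "intervals": list(window.intervals), "dtype": dtype,
                 "label": window.label(), "weighted": False}
        if not np.array_equal(image.weights[window], counts):
            wcsv = prefix.parent / f"{prefix.name}_w{k}_weights.csv"
            np.savetxt(wcsv, image.weights[window], delimiter=",")
            sqcsv = prefix.parent / f"{prefix.name}_w{k}_weights_sq.csv"
            np.savetxt(sqcsv, image.weights_sq[window], delimiter=",")
            written += [wcsv, sqcsv]
            wmeta["weighted"] = True
        windows_meta.append(wmeta)
    meta_path = prefix.parent / f"{prefix.name}_meta.json"
    meta_path.write_text(
        json.dumps({"windows": windows_meta, "meta": _jsonable(image.meta)}, indent=2)
        + "\n"
    )
    written.append(meta_path)
    return written


def read_image(prefix: str | Path) -> DetectedImage:
    prefix = Path(prefix)
    meta_path = prefix.parent / f"{prefix.name}_meta.json"
    if not meta_path.exists():
        raise FileNotFoundError(f"no image metadata at {meta_path}")
    payload = json.loads(meta_path.read_text())
    counts, weights, weights_sq = {}, {}, {}
    for wmeta in payload["windows"]:
        window = EnergyWindow(tuple(tuple(iv) for iv in wmeta["intervals"]))
        k = wmeta["index"]
        tif = prefix.parent / f"{prefix.name}_w{k}.tif"
        grid = tifffile.imread(tif).astype(np.int64)
        csv_grid = np.loadtxt(tif.with_suffix(".csv"), delimiter=",", ndmin=2)
        if not np.array_equal(grid, csv_grid.astype(np.int64)):
            raise ValueError(f"TIFF and CSV twins disagree for {tif}")
        counts[window] = grid
        if wmeta.get("weighted"):
            weights[window] = np.loadtxt(
                prefix.parent / f"{prefix.name}_w{k}_weights.csv", delimiter=",", ndmin=2
            )
            weights_sq[window] = np.loadtxt(
                prefix.parent / f"{prefix.name}_w{k}_weights_sq.csv", delimiter=",", ndmin=2
            )
        else:
            weights[window] = grid.astype(float)
            weights_sq[window] = grid.astype(float)
    return DetectedImage(counts, weights, weights_sq, payload["meta"])


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    return obj
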