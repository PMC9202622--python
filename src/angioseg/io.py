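"""Image and table I/O.

Grayscale rasters travel as PGM (both the plain ``P2`` and binary ``P5``
variants, the format the reference angiogram ground truth uses) or PNG.
Per-branch geometry and feature tables are headered CSV; labels and run
metadata are JSON sidecars.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
from PIL import Image

__all__ = [
    "read_image",
    "write_image",
    "read_pgm",
    "write_pgm",
    "write_json",
    "read_json",
]


def read_pgm(path: str | Path) -> np.ndarray:
    """Read a PGM file (P2 plain or P5 binary) as a 2-D uint8/uint16 array."""
    path = Path(path)
    with open(path, "rb") as fh:
        magic = fh.read(2)
    if magic == b"P2":
        return _read_plain_pgm(path)
    # Pillow handles P5
    return np.asarray(Image.open(path))


def _read_plain_pgm(path: Path) -> np.ndarray:
    tokens: list[str] = []
    with open(path, "r") as fh:
        for line in fh:
            line = line.split("#", 1)[0]
            tokens.extend(line.split())
    if tokens[0] != "P2":
        raise ValueError(f"not a plain PGM file: {path}")
    w, h, maxval = int(tokens[1]), int(tokens[2]), int(tokens[3])
    data = np.array(tokens[4 : 4 + w * h], dtype=np.uint16 if maxval > 255 else np.uint8)
    return data.reshape(h, w)


def write_pgm(path: str | Path, image: np.ndarray, plain: bool = False) -> None:
    """Write a 2-D array as PGM (maxval 255); ``plain`` selects ASCII P2."""
    arr = np.asarray(image)
    if arr.ndim != 2:
        raise ValueError("PGM output requires a 2-D grayscale array")
    arr = np.clip(np.rint(arr), 0, 255).astype(np.uint8)
    if plain:
        h, w = arr.shape
        with open(path, "w") as fh:
            fh.write(f"P2\n{w} {h}\n255\n")
            for row in arr:
                fh.write(" ".join(str(v) for v in row) + "\n")
    else:
        Image.fromarray(arr).save(path)


def read_image(path: str | Path) -> np.ndarray:
    """Read a grayscale image (PGM or PNG) as float64 in [0, 255]."""
    path = Path(path)
    if path.suffix.lower() == ".pgm":
        arr = read_pgm(path)
    else:
        arr = np.asarray(Image.open(path).convert("L"))
    return arr.astype(np.float64)


def write_image(path: str | Path, image: np.ndarray) -> None:
    """Write a grayscale image; format chosen by extension (.pgm or .png)."""
    path = Path(path)
    if path.suffix.lower() == ".pgm":
        write_pgm(path, image)
    else:
        arr = np.clip(np.rint(np.asarray(image)), 0, 255).astype(np.uint8)
        Image.fromarray(arr).save(path)


def write_json(path: str | Path, obj) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True, default=_json_default)
        fh.write("\n")


def read_json(path: str | Path):
    with open(path) as fh:
        return json.load(fh)


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(f"not JSON serializable: {type(o)}")
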