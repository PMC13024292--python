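"""Reading and writing mask stacks, trace tables and metadata sidecars.

Canonical on-disk format for label stacks is a multi-page TIFF with 16-bit
unsigned integer labels plus a YAML metadata sidecar (``<stem>.meta.yaml``).
A directory of lexicographically ordered PNG files is accepted as an input
dialect.
"""

from __future__ import annotations

import os
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd
import tifffile
import yaml
from PIL import Image

from .datamodel import (
    DEFAULT_LABEL_MAP,
    LabelMaskSequence,
    RecordingMeta,
    RotationTrace,
    SegmentTrace,
    check_same_frame_count,
)
from .errors import FormatError, InsufficientDataError

__all__ = [
    "read_mask_sequence",
    "write_mask_sequence",
    "write_trace_table",
    "read_trace_table",
    "sidecar_path",
]

PathLike = Union[str, os.PathLike]


def sidecar_path(path: PathLike) -> Path:
    p = Path(path)
    if p.is_dir():
        return p / "meta.yaml"
    return p.with_suffix("").with_suffix(".meta.yaml") if p.suffix else p.parent / (
        p.name + ".meta.yaml"
    )


def _read_sidecar(path: PathLike) -> tuple[Optional[RecordingMeta], Optional[dict]]:
    sp = sidecar_path(path)
    if not sp.exists():
        return None, None
    with open(sp) as fh:
        d = yaml.safe_load(fh) or {}
    meta = RecordingMeta.from_dict(d.get("meta", {}))
    lm = d.get("label_map")
    label_map = {int(k): str(v) for k, v in lm.items()} if lm else None
    return meta, label_map


def _frames_from_tiff(path: Path) -> list[np.ndarray]:
    arr = tifffile.imread(path)
    if arr.ndim == 2:
        arr = arr[None]
    if arr.ndim != 3:
        raise FormatError(f"expected a 2D frame stack in {path}, got shape {arr.shape}")
    return [np.asarray(f) for f in arr]


def _frames_from_png_dir(path: Path) -> list[np.ndarray]:
    files = sorted(p for p in path.iterdir() if p.suffix.lower() == ".png")
    if not files:
        raise FormatError(f"no PNG files found in directory {path}")
    return [np.asarray(Image.open(p)) for p in files]


def read_mask_sequence(
    path: PathLike,
    label_map: Optional[dict[int, str]] = None,
    meta: Optional[RecordingMeta] = None,
) -> LabelMaskSequence:
    """Load a label-mask stack from a multi-page TIFF or a PNG directory.

    Frame order is page order (TIFF) or lexicographic file order (PNG
    directory).  Pixel values must be integers; a YAML sidecar, when present,
    supplies metadata and the label map.  Explicit ``label_map``/``meta``
    arguments override the sidecar.
    """
    p = Path(path)
    side_meta, side_map = _read_sidecar(p)
    if p.is_dir():
        frames = _frames_from_png_dir(p)
    elif p.exists():
        frames = _frames_from_tiff(p)
    else:
        raise FileNotFoundError(str(p))
    for i, f in enumerate(frames):
        if not np.issubdtype(f.dtype, np.integer):
            raise FormatError(f"frame {i} has non-integer pixel data ({f.dtype})")
    if len(frames) < 2:
        raise InsufficientDataError(f"{p} holds {len(frames)} frame(s); >= 2 required")
    lm = label_map or side_map
    if lm is None:
        present = set()
        for f in frames:
            present.update(int(v) for v in np.unique(f) if v != 0)
        lm = {l: DEFAULT_LABEL_MAP.get(l, f"label{l}") for l in present} or dict(
            DEFAULT_LABEL_MAP
        )
    m = meta or side_meta or RecordingMeta(recording_id=p.stem)
    return LabelMaskSequence(meta=m, frames=frames, label_map=lm)


def write_mask_sequence(seq: LabelMaskSequence, path: PathLike) -> None:
    """Write a sequence as 16-bit multi-page TIFF plus a YAML sidecar.

    The encoding is lossless: ``read_mask_sequence`` inverts it bit-exactly.
    """
    p = Path(path)
    stack = seq.to_array()
    if stack.min() < 0 or stack.max() > np.iinfo(np.uint16).max:
        raise FormatError("labels out of uint16 range")
    tifffile.imwrite(p, stack.astype(np.uint16))
    side = {
        "meta": seq.meta.to_dict(),
        "label_map": {int(k): str(v) for k, v in seq.label_map.items()},
    }
    with open(sidecar_path(p), "w") as fh:
        yaml.safe_dump(side, fh, sort_keys=True)


def _trace_frame(traces: Sequence[Union[RotationTrace, SegmentTrace]]) -> pd.DataFrame:
    rows = []
    for tr in traces:
        if isinstance(tr, RotationTrace):
            for t in range(tr.n_frames):
                rows.append(
                    {
                        "frame": t,
                        "name": tr.vertebra,
                        "kind": "vertebra",
                        "theta_deg": tr.theta_deg[t],
                        "dtheta_deg": tr.dtheta_deg[t],
                        "fit_overlap": tr.fit_overlap[t],
                    }
                )
        elif isinstance(tr, SegmentTrace):
            for t in range(tr.n_frames):
                rows.append(
                    {
                        "frame": t,
                        "name": tr.name,
                        "kind": "segment",
                        "dtheta_rel_deg": tr.dtheta_rel_deg[t],
                        "dtheta_rel_smoothed_deg": tr.dtheta_rel_smoothed_deg[t],
                        "srom_deg": tr.srom_deg,
                    }
                )
        else:
            raise TypeError(f"unsupported trace type {type(tr)!r}")
    cols = ["frame", "name", "kind"]
    if rows:
        extra = [c for c in rows[0] if c not in cols]
    else:
        extra = ["theta_deg", "dtheta_deg", "fit_overlap"]
    return pd.DataFrame(rows, columns=cols + extra)


def write_trace_table(
    traces: Sequence[Union[RotationTrace, SegmentTrace]], path: PathLike
) -> None:
    """Write traces as a long-format TSV (one row per frame per trace).

    Missing values are encoded as empty cells, never as zeros.  An empty trace
    list yields a header-only file.
    """
    check_same_frame_count(traces)
    df = _trace_frame(traces)
    df.to_csv(path, sep="\t", index=False, na_rep="")


def read_trace_table(path: PathLike) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
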