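"""Section-stack I/O, size conforming and orthogonal reslicing.

Coordinate convention (used everywhere in the package): 0-based,
x = column, y = row, pixel centers at integer coordinates.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import tifffile
from PIL import Image

from .errors import DecodeError, DomainError, NoSectionsError, WriteError

__all__ = [
    "SectionStack",
    "read_stack",
    "write_stack",
    "conform_stack",
    "reslice_side_view",
    "natural_key",
]

_RASTER_SUFFIXES = {".tif", ".tiff", ".png"}


@dataclass
class SectionStack:
    """Ordered serial sections, all uint8, index 0..N-1 in cutting order."""

    sections: list[np.ndarray]
    labels: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.labels:
            self.labels = [str(i) for i in range(len(self.sections))]

    def __len__(self) -> int:
        return len(self.sections)

    def __getitem__(self, i: int) -> np.ndarray:
        return self.sections[i]

    @property
    def mode(self) -> str:
        return "rgb" if self.sections[0].ndim == 3 else "gray"

    @property
    def shape(self) -> tuple[int, int]:
        return self.sections[0].shape[:2]

    def copy(self) -> "SectionStack":
        return SectionStack([s.copy() for s in self.sections], list(self.labels))


def natural_key(name: str):
    """Sort key placing 's2' before 's10'."""
    return [
        int(tok) if tok.isdigit() else tok.lower()
        for tok in re.split(r"(\d+)", name)
    ]


def _to_uint8(pages: list[np.ndarray]) -> list[np.ndarray]:
    """Rescale >8-bit input to 8-bit with a single per-stack min-max window."""
    if all(p.dtype == np.uint8 for p in pages):
        return pages
    lo = min(float(p.min()) for p in pages)
    hi = max(float(p.max()) for p in pages)
    scale = 255.0 / (hi - lo) if hi > lo else 0.0
    return [
        np.clip(np.rint((p.astype(np.float64) - lo) * scale), 0, 255).astype(np.uint8)
        for p in pages
    ]


def _normalize_page(page: np.ndarray, source: str) -> np.ndarray:
    if page.ndim == 3 and page.shape[2] == 4:  # drop alpha
        page = page[:, :, :3]
    if page.ndim == 3 and page.shape[2] == 1:
        page = page[:, :, 0]
    if page.ndim not in (2, 3) or (page.ndim == 3 and page.shape[2] != 3):
        raise DecodeError(f"decode failure: unsupported page shape in {source}")
    return page


def read_stack(path: str | Path) -> SectionStack:
    """Read a multi-page TIFF or a directory of numbered TIFF/PNG sections.

    Directory entries are ordered by natural numeric sort.  16-bit input is
    rescaled to 8-bit by per-stack min-max; mixed gray/RGB input is promoted
    to RGB.
    """
    path = Path(path)
    pages: list[np.ndarray] = []
    labels: list[str] = []
    if path.is_dir():
        files = sorted(
            (f for f in path.iterdir() if f.suffix.lower() in _RASTER_SUFFIXES),
            key=lambda f: natural_key(f.name),
        )
        if not files:
            raise NoSectionsError(f"no sections found in directory {path}")
        for f in files:
            try:
                if f.suffix.lower() in (".tif", ".tiff"):
                    arr = tifffile.imread(f)
                else:
                    arr = np.asarray(Image.open(f))
            except NoSectionsError:
                raise
            except Exception as exc:  # noqa: BLE001 — surface the filename
                raise DecodeError(f"decode failure: {f}: {exc}") from exc
            pages.append(_normalize_page(arr, str(f)))
            labels.append(f.stem)
    else:
        if not path.exists():
            raise NoSectionsError(f"no sections: {path} does not exist")
        try:
            with tifffile.TiffFile(path) as tif:
                raw = [p.asarray() for p in tif.pages]
        except Exception as exc:  # noqa: BLE001
            raise DecodeError(f"decode failure: {path}: {exc}") from exc
        if not raw:
            raise NoSectionsError(f"no sections: {path} has zero pages")
        pages = [_normalize_page(p, str(path)) for p in raw]
        labels = [str(i) for i in range(len(pages))]
    pages = _to_uint8(pages)
    if any(p.ndim == 3 for p in pages) and any(p.ndim == 2 for p in pages):
        pages = [
            p if p.ndim == 3 else np.repeat(p[:, :, None], 3, axis=2) for p in pages
        ]
    return SectionStack(pages, labels)


def write_stack(stack: SectionStack, path: str | Path) -> None:
    """Write the stack as a lossless multi-page TIFF, one page per section."""
    path = Path(path)
    try:
        with tifffile.TiffWriter(path) as tif:
            for sec in stack.sections:
                photometric = "rgb" if sec.ndim == 3 else "minisblack"
                tif.write(sec, photometric=photometric, compression=None)
    except OSError as exc:
        raise WriteError(f"write failure: {path}: {exc}") from exc


def conform_stack(stack: SectionStack) -> SectionStack:
    """Zero-pad every section symmetrically to the stack's maximum H and W.

    Black padding keeps added pixels out of foreground masks; no original
    pixel value is altered.
    """
    hmax = max(s.shape[0] for s in stack.sections)
    wmax = max(s.shape[1] for s in stack.sections)
    out = []
    for sec in stack.sections:
        dh = hmax - sec.shape[0]
        dw = wmax - sec.shape[1]
        pad = [(dh // 2, dh - dh // 2), (dw // 2, dw - dw // 2)]
        if sec.ndim == 3:
            pad.append((0, 0))
        out.append(np.pad(sec, pad, mode="constant", constant_values=0))
    return SectionStack(out, list(stack.labels))


def reslice_side_view(stack: SectionStack, axis: str, position: int) -> np.ndarray:
    """Orthogonal reslice for continuity inspection.

    axis='y': row `position` of every section stacked into an N x W image
    (XZ cut); axis='x': column `position` into N x H (YZ cut).
    """
    h, w = stack.shape
    if axis == "y":
        if not 0 <= position < h:
            raise DomainError(f"index error: row {position} outside [0, {h})")
        rows = [sec[position] for sec in stack.sections]
    elif axis == "x":
        if not 0 <= position < w:
            raise DomainError(f"index error: column {position} outside [0, {w})")
        rows = [sec[:, position] for sec in stack.sections]
    else:
        raise ValueError(f"axis must be 'x' or 'y', got {axis!r}")
    return np.stack(rows, axis=0)
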