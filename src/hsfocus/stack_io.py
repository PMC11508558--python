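"""Through-focus stack containers and disk I/O.

A *through-focus stack* is an ordered series of 2D frames of one field of
view, captured at strictly increasing focal (z) positions.  Frames are either
conventional video images (spatial × spatial) or instantaneous pushbroom
hyperspectral frames (one spatial axis, one spectral axis).  By convention
the spatial axis of a hyperspectral frame runs along a row (the second
array axis); rows index wavelength.

Supported on-disk layouts
-------------------------
* ENVI BIL raw + text header pair (``stack.raw`` + ``stack.hdr``), one ENVI
  *line* per frame (so ``lines`` = number of frames, ``bands`` = frame rows,
  ``samples`` = frame columns);
* multi-page TIFF, one page per frame;
* a directory of single-frame TIFFs listed in a manifest.

Each stack may carry a JSON manifest (``<stem>.json`` or ``manifest.json``)
recording the focal positions in micrometres, the axis semantics, the bit
depth and an optional dark-frame file.  Without a manifest, unit-spaced
positions are assumed.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import tifffile

from .errors import (
    FrameShapeError,
    MissingHeaderError,
    NonMonotonicZError,
    ROIError,
    StackLoadError,
)

log = logging.getLogger(__name__)

AXES_TAGS = ("spatial_spatial", "spatial_spectral")

# ENVI "data type" codes <-> numpy dtypes (the subset this package writes/reads)
_ENVI_DTYPES = {1: "u1", 2: "i2", 3: "i4", 4: "f4", 5: "f8", 12: "u2", 13: "u4"}
_ENVI_CODES = {np.dtype(v): k for k, v in _ENVI_DTYPES.items()}


@dataclass(frozen=True)
class ImageFrame:
    """One 2D intensity frame (detector counts).

    Parameters
    ----------
    pixels : ndarray, shape (H, W)
        Non-negative intensities, bounded by the detector dynamic range.
    bit_depth : int
        Detector bit depth (12, 14 or 16 on typical scientific cameras).
    axes : {"spatial_spatial", "spatial_spectral"}
        Axis semantics; in a pushbroom frame the spatial axis runs along a
        row and the rows index wavelength.
    """

    pixels: np.ndarray
    bit_depth: int = 12
    axes: str = "spatial_spatial"

    def __post_init__(self):
        px = np.asarray(self.pixels)
        if px.ndim != 2:
            raise ValueError(f"frame must be 2D, got shape {px.shape}")
        if px.shape[0] < 3 or px.shape[1] < 3:
            raise ValueError(f"frame must be at least 3x3, got {px.shape}")
        if self.axes not in AXES_TAGS:
            raise ValueError(f"axes must be one of {AXES_TAGS}, got {self.axes!r}")
        if px.min() < 0:
            raise ValueError("negative intensities are not valid detector counts")
        if px.max() > 2**self.bit_depth - 1:
            raise ValueError(
                f"intensities exceed {self.bit_depth}-bit range "
                f"(max {px.max()} > {2**self.bit_depth - 1})"
            )
        object.__setattr__(self, "pixels", px)

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]


@dataclass(frozen=True)
class ROISpec:
    """A rectangular region of interest, fully inside the frame."""

    row_offset: int
    col_offset: int
    rows: int
    cols: int

    def __post_init__(self):
        if self.rows < 3 or self.cols < 3:
            raise ROIError("ROI must be at least 3x3")
        if self.row_offset < 0 or self.col_offset < 0:
            raise ROIError("ROI offsets must be non-negative")

    def validate_for(self, shape: tuple[int, int]) -> None:
        h, w = shape
        if self.row_offset + self.rows > h or self.col_offset + self.cols > w:
            raise ROIError(f"ROI {self} exceeds frame shape {shape}")

    def slices(self) -> tuple[slice, slice]:
        return (
            slice(self.row_offset, self.row_offset + self.rows),
            slice(self.col_offset, self.col_offset + self.cols),
        )


@dataclass
class FocusStack:
    """Ordered frames of one field of view tagged with focal positions (μm)."""

    frames: list[ImageFrame]
    z_um: np.ndarray
    dark_frame: ImageFrame | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.z_um = np.asarray(self.z_um, dtype=float)
        if len(self.frames) == 0:
            raise ValueError("a stack needs at least one frame")
        if self.z_um.shape != (len(self.frames),):
            raise ValueError("z_um must have one entry per frame")
        if np.any(np.diff(self.z_um) <= 0):
            raise NonMonotonicZError("focal positions must be strictly increasing")
        ref = self.frames[0]
        for fr in self.frames:
            if fr.pixels.shape != ref.pixels.shape:
                raise FrameShapeError("all frames must share one shape")
            if fr.axes != ref.axes or fr.bit_depth != ref.bit_depth:
                raise ValueError("all frames must share axes tag and bit depth")
        if self.dark_frame is not None and self.dark_frame.pixels.shape != ref.pixels.shape:
            raise ValueError("dark frame shape must match the stack frames")

    def __len__(self) -> int:
        return len(self.frames)

    def __getitem__(self, s: int) -> ImageFrame:
        return self.frames[s]

    @property
    def frame_shape(self) -> tuple[int, int]:
        return self.frames[0].pixels.shape

    @property
    def axes(self) -> str:
        return self.frames[0].axes

    @property
    def bit_depth(self) -> int:
        return self.frames[0].bit_depth

    def pixel_cube(self) -> np.ndarray:
        """All frames as one (n_frames, H, W) array."""
        return np.stack([fr.pixels for fr in self.frames])


def subtract_dark(stack: FocusStack) -> FocusStack:
    """Subtract the paired dark frame from every frame, clamping at zero.

    Detector counts are non-negative, so differences below zero are clamped.
    Without a dark frame this is a logged no-op (the stack is returned as is).
    """
    if stack.dark_frame is None:
        log.warning("subtract_dark: stack has no dark frame; returning stack unchanged")
        return stack
    dark = stack.dark_frame.pixels.astype(np.float64)
    frames = [
        replace(fr, pixels=np.maximum(fr.pixels.astype(np.float64) - dark, 0.0))
        for fr in stack.frames
    ]
    meta = dict(stack.meta, dark_subtracted=True)
    return FocusStack(frames=frames, z_um=stack.z_um, dark_frame=None, meta=meta)


def crop_roi(stack: FocusStack, roi: ROISpec) -> FocusStack:
    """Crop every frame (and the dark frame) to the same region of interest."""
    roi.validate_for(stack.frame_shape)
    rs, cs = roi.slices()
    frames = [replace(fr, pixels=fr.pixels[rs, cs]) for fr in stack.frames]
    dark = stack.dark_frame
    if dark is not None:
        dark = replace(dark, pixels=dark.pixels[rs, cs])
    meta = dict(stack.meta, roi=(roi.row_offset, roi.col_offset, roi.rows, roi.cols))
    return FocusStack(frames=frames, z_um=stack.z_um, dark_frame=dark, meta=meta)


# ---------------------------------------------------------------------------
# readers / writers


def _manifest_path(path: Path) -> Path:
    if path.is_dir():
        return path / "manifest.json"
    return path.with_suffix(".json")


def _write_manifest(path: Path, stack: FocusStack, dark_name: str | None) -> None:
    manifest = {
        "z_um": [float(z) for z in stack.z_um],
        "axes": stack.axes,
        "bit_depth": stack.bit_depth,
    }
    if dark_name is not None:
        manifest["dark"] = dark_name
    if "files" in stack.meta:
        manifest["files"] = stack.meta["files"]
    _manifest_path(path).write_text(json.dumps(manifest, indent=1))


def _read_manifest(path: Path) -> dict | None:
    mp = _manifest_path(path)
    if not mp.exists():
        return None
    return json.loads(mp.read_text())


def _write_envi(path: Path, cube: np.ndarray) -> None:
    dtype = np.dtype("u2") if np.issubdtype(cube.dtype, np.integer) else np.dtype("f8")
    data = np.ascontiguousarray(cube.astype(dtype))
    n, h, w = data.shape
    hdr = "\n".join(
        [
            "ENVI",
            f"samples = {w}",
            f"lines = {n}",
            f"bands = {h}",
            "header offset = 0",
            "file type = ENVI Standard",
            f"data type = {_ENVI_CODES[dtype]}",
            "interleave = bil",
            "byte order = 0",
            "",
        ]
    )
    path.with_suffix(".hdr").write_text(hdr)
    # BIL with one frame per line: memory order (lines, bands, samples)
    data.tofile(path)


def _parse_envi_header(hdr_path: Path) -> dict:
    fields: dict[str, str] = {}
    for line in hdr_path.read_text().splitlines():
        if "=" in line:
            key, _, val = line.partition("=")
            fields[key.strip().lower()] = val.strip()
    return fields


def _read_envi(path: Path) -> np.ndarray:
    hdr_path = path.with_suffix(".hdr")
    if not hdr_path.exists():
        raise MissingHeaderError(f"missing ENVI header {hdr_path}")
    hdr = _parse_envi_header(hdr_path)
    try:
        n = int(hdr["lines"])
        h = int(hdr["bands"])
        w = int(hdr["samples"])
        code = int(hdr["data type"])
    except KeyError as exc:
        raise MissingHeaderError(f"ENVI header {hdr_path} lacks field {exc}") from exc
    interleave = hdr.get("interleave", "bil").lower()
    if interleave != "bil":
        raise StackLoadError(f"unsupported ENVI interleave {interleave!r}")
    dtype = np.dtype(_ENVI_DTYPES[code])
    data = np.fromfile(path, dtype=dtype)
    if data.size != n * h * w:
        raise FrameShapeError(
            f"ENVI raw size {data.size} does not match header {n}x{h}x{w}"
        )
    return data.reshape(n, h, w)


def write_stack(stack: FocusStack, path: str | Path, format: str | None = None) -> Path:
    """Write a stack as ENVI BIL (``.raw``), multi-page TIFF or frame directory.

    The format is inferred from the path suffix unless given explicitly.
    A JSON manifest with focal positions and axis metadata is written next to
    the data; an optional dark frame is stored as a single-page TIFF.
    """
    path = Path(path)
    fmt = format or _infer_format(path)
    cube = stack.pixel_cube()
    dark_name = None
    if stack.dark_frame is not None:
        dark_file = (path if path.is_dir() or fmt == "dir" else path.parent) / (
            (path.stem if fmt != "dir" else "stack") + "_dark.tif"
        )
    if fmt == "envi":
        _write_envi(path, cube)
    elif fmt == "tiff":
        tifffile.imwrite(path, cube, photometric='minisblack')
    elif fmt == "dir":
        path.mkdir(parents=True, exist_ok=True)
        files = []
        for s, fr in enumerate(stack.frames):
            name = f"frame_{s:04d}.tif"
            tifffile.imwrite(path / name, fr.pixels, photometric='minisblack')
            files.append(name)
        stack.meta = dict(stack.meta, files=files)
    else:
        raise ValueError(f"unknown stack format {fmt!r}")
    if stack.dark_frame is not None:
        dark_file.parent.mkdir(parents=True, exist_ok=True)
        tifffile.imwrite(dark_file, stack.dark_frame.pixels, photometric='minisblack')
        dark_name = dark_file.name
    _write_manifest(path, stack, dark_name)
    return path


def _infer_format(path: Path) -> str:
    suffix = path.suffix.lower()
    if suffix in (".raw", ".bil", ".img"):
        return "envi"
    if suffix in (".tif", ".tiff"):
        return "tiff"
    if suffix == "" or path.is_dir():
        return "dir"
    raise StackLoadError(f"cannot infer stack format from {path}")


def read_stack(path: str | Path, format_hint: str | None = None) -> FocusStack:
    """Read a stack written by :func:`write_stack` (or compatible layouts).

    Frames are returned ordered by ascending focal position; for the
    directory layout the manifest defines the order regardless of filename
    sort order.
    """
    path = Path(path)
    fmt = format_hint or _infer_format(path)
    manifest = _read_manifest(path)

    if fmt == "envi":
        cube = _read_envi(path)
    elif fmt == "tiff":
        cube = tifffile.imread(path)
        if cube.ndim == 2:
            cube = cube[None]
    elif fmt == "dir":
        if manifest is None or "files" not in manifest:
            raise MissingHeaderError(f"directory stack {path} needs a manifest with 'files'")
        planes = [tifffile.imread(path / name) for name in manifest["files"]]
        shapes = {p.shape for p in planes}
        if len(shapes) > 1:
            raise FrameShapeError(f"inconsistent frame shapes in {path}: {shapes}")
        cube = np.stack(planes)
    else:
        raise ValueError(f"unknown stack format {fmt!r}")

    n = cube.shape[0]
    if manifest is None:
        log.warning("no manifest for %s; assuming unit-spaced focal positions", path)
        manifest = {}
    z = np.asarray(manifest.get("z_um", np.arange(n, dtype=float)), dtype=float)
    if z.shape != (n,):
        raise StackLoadError(f"manifest lists {z.size} positions for {n} frames")
    if np.any(np.diff(z) <= 0):
        # a shuffled directory listing is fine as long as z sorts it out
        order = np.argsort(z)
        z_sorted = z[order]
        if np.any(np.diff(z_sorted) <= 0):
            raise NonMonotonicZError("focal positions contain duplicates")
        cube, z = cube[order], z_sorted
    axes = manifest.get("axes", "spatial_spatial")
    bit_depth = manifest.get("bit_depth", _infer_bit_depth(cube))
    dark = None
    if manifest.get("dark"):
        base = path if path.is_dir() else path.parent
        dark = ImageFrame(tifffile.imread(base / manifest["dark"]), bit_depth=bit_depth, axes=axes)
    frames = [ImageFrame(plane, bit_depth=bit_depth, axes=axes) for plane in cube]
    return FocusStack(frames=frames, z_um=z, dark_frame=dark, meta={"source": str(path)})


def _infer_bit_depth(cube: np.ndarray) -> int:
    if np.issubdtype(cube.dtype, np.integer):
        peak = int(cube.max(initial=0))
        for bits in (8, 12, 14, 16):
            if peak <= 2**bits - 1:
                return bits
    return 16
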