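"""Reading and writing plantar pressure grids, footprint images and cohort manifests.

The supported mat layout is a 48x48 array of pressure sensors (2304 cells)
covering a 400 mm x 400 mm detection area; one standing frame per file, stored
as a plain delimited numeric matrix (row-major, no header).  The device also
exports an interpolated 918x918 color image of the pressure distribution; we
emulate that export with :func:`grid_to_image`.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml
from PIL import Image

GRID_SHAPE = (48, 48)
#: mm per sensor cell (400 mm detection area / 48 sensor rows)
DEFAULT_SENSOR_PITCH = 400.0 / 48.0
#: side length, in pixels, of the device's interpolated color export
DEVICE_IMAGE_SIZE = 918

BACKGROUND_RGB = (255, 255, 255)


class GridFormatError(ValueError):
    """Raised when a pressure-grid file has the wrong shape or bad cells."""


@dataclass
class PressureGrid:
    """One static standing frame from the pressure mat.

    Parameters
    ----------
    values
        48x48 array of pressures in kPa, non-negative and finite.
    sensor_pitch
        Physical cell size in mm (default 400/48).
    frame_id
        Free-text identifier, typically ``<subject>_<side>``.
    """

    values: np.ndarray
    sensor_pitch: float = DEFAULT_SENSOR_PITCH
    frame_id: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != GRID_SHAPE:
            raise GridFormatError(
                f"pressure grid must be {GRID_SHAPE[0]}x{GRID_SHAPE[1]}, "
                f"got {self.values.shape[0] if self.values.ndim > 0 else 0}x"
                f"{self.values.shape[1] if self.values.ndim > 1 else 0}"
            )
        if not np.all(np.isfinite(self.values)):
            r, c = np.argwhere(~np.isfinite(self.values))[0]
            raise GridFormatError(f"non-finite pressure at cell ({r}, {c})")
        if np.any(self.values < 0):
            r, c = np.argwhere(self.values < 0)[0]
            raise GridFormatError(
                f"negative pressure {self.values[r, c]} at cell ({r}, {c})"
            )

    @property
    def n_cells(self) -> int:
        return self.values.size

    def contact_mask(self, threshold: float = 0.0) -> np.ndarray:
        """Boolean mask of cells with pressure strictly above ``threshold`` kPa."""
        return self.values > threshold


@dataclass
class FootprintImage:
    """Color footprint raster (H x W x 3, uint8 0-255)."""

    pixels: np.ndarray
    side: str = "both"  # left | right | both

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 3 or self.pixels.shape[2] != 3:
            raise ValueError(f"expected HxWx3 raster, got shape {self.pixels.shape}")
        if self.side not in ("left", "right", "both"):
            raise ValueError(f"side must be left/right/both, got {self.side!r}")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape[:2]


@dataclass
class CohortManifest:
    """Binds subject ids to their left/right grid files."""

    entries: list[tuple[str, Path, Path]] = field(default_factory=list)
    provenance: str = ""

    def __post_init__(self) -> None:
        ids = [e[0] for e in self.entries]
        if len(ids) != len(set(ids)):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate subject ids in manifest: {dupes}")

    def __len__(self) -> int:
        return len(self.entries)


def read_pressure_grid(path: str | Path, dialect: str = "csv") -> PressureGrid:
    """Read one delimited-text pressure frame.

    ``dialect`` selects the cell delimiter: ``csv`` (comma) or ``tsv`` (tab).
    The file must contain a full 48x48 numeric matrix; shape or value problems
    raise :class:`GridFormatError` naming the offending dimension or cell.
    """
    path = Path(path)
    delim = {"csv": ",", "tsv": "\t"}.get(dialect)
    if delim is None:
        raise ValueError(f"unknown dialect {dialect!r}; use 'csv' or 'tsv'")
    rows: list[list[str]] = []
    with open(path, newline="") as fh:
        for row in csv.reader(fh, delimiter=delim):
            if row and any(cell.strip() for cell in row):
                rows.append([cell.strip() for cell in row])
    n_rows = len(rows)
    n_cols = len(rows[0]) if rows else 0
    if n_rows != GRID_SHAPE[0] or any(len(r) != GRID_SHAPE[1] for r in rows):
        bad_cols = {len(r) for r in rows} or {0}
        raise GridFormatError(
            f"{path.name}: expected 48x48 matrix, observed {n_rows} rows x "
            f"{sorted(bad_cols)} columns"
        )
    values = np.empty(GRID_SHAPE, dtype=float)
    for i, row in enumerate(rows):
        for j, cell in enumerate(row):
            try:
                values[i, j] = float(cell)
            except ValueError as exc:
                raise GridFormatError(
                    f"{path.name}: non-numeric cell {cell!r} at ({i}, {j})"
                ) from exc
    if np.any(values < 0):
        r, c = np.argwhere(values < 0)[0]
        raise GridFormatError(
            f"{path.name}: negative pressure {values[r, c]} at cell ({r}, {c})"
        )
    return PressureGrid(values=values, frame_id=path.stem)


def write_pressure_grid(grid: PressureGrid, path: str | Path, dialect: str = "csv") -> Path:
    """Write a frame as delimited text at full (repr) precision.

    A csv round trip through :func:`read_pressure_grid` is bit-exact.
    """
    path = Path(path)
    delim = {"csv": ",", "tsv": "\t"}[dialect]
    with open(path, "w", newline="") as fh:
        for row in grid.values:
            fh.write(delim.join(repr(float(v)) for v in row))
            fh.write("\n")
    return path


# ---------------------------------------------------------------------------
# Pressure colormap (device-style export)
# ---------------------------------------------------------------------------

# Piecewise-linear blue -> cyan -> green -> yellow -> red map over normalized
# pressure, with pure white reserved for zero-pressure background.  Hues run
# 240 deg (blue) down to 0 deg (red), so on the half-degree HSV scale the foot
# occupies H 0-120 and the high-pressure end occupies H 0-40.
_STOPS = np.array(
    [
        [0.0, 0, 0, 255],      # blue
        [0.25, 0, 255, 255],   # cyan
        [0.5, 0, 255, 0],      # green
        [0.75, 255, 255, 0],   # yellow
        [1.0, 255, 0, 0],      # red
    ]
)


def pressure_colormap(normalized: np.ndarray) -> np.ndarray:
    """Map pressures normalized to [0, 1] onto RGB; monotone in hue rank."""
    x = np.clip(np.asarray(normalized, dtype=float), 0.0, 1.0)
    rgb = np.empty(x.shape + (3,), dtype=float)
    for ch in range(3):
        rgb[..., ch] = np.interp(x, _STOPS[:, 0], _STOPS[:, ch + 1])
    return rgb.astype(np.uint8)


def grid_to_image(
    grid: PressureGrid,
    out_size: int = DEVICE_IMAGE_SIZE,
    interpolation: str = "nearest",
    vmax: float | None = None,
) -> FootprintImage:
    """Render a pressure frame as a device-style color footprint image.

    Zero-pressure cells map to the white background; positive pressures map
    monotonically blue (low) through green to red (high).  Upsampling is
    nearest-neighbor by default so sensor-cell boundaries are preserved;
    ``interpolation='bilinear'`` smooths them.

    ``vmax`` fixes the pressure mapped to full red; by default the frame
    maximum is used (the device's per-frame autoscaling).
    """
    if out_size < GRID_SHAPE[0]:
        raise ValueError(f"out_size must be >= 48, got {out_size}")
    values = grid.values
    top = float(values.max()) if vmax is None else float(vmax)
    if top <= 0:
        pixels = np.full((out_size, out_size, 3), 255, dtype=np.uint8)
        return FootprintImage(pixels=pixels, side="both")
    normalized = values / top
    rgb = pressure_colormap(normalized).astype(float)
    background = values <= 0
    rgb[background] = BACKGROUND_RGB

    if interpolation == "nearest":
        # integer-block upsample then pad to out_size with background
        scale = out_size // GRID_SHAPE[0]
        if scale * GRID_SHAPE[0] == out_size:
            up = np.repeat(np.repeat(rgb, scale, axis=0), scale, axis=1)
        else:
            ridx = (np.arange(out_size) * GRID_SHAPE[0] // out_size).clip(0, 47)
            up = rgb[np.ix_(ridx, ridx)]
    elif interpolation == "bilinear":
        from skimage.transform import resize

        up = resize(rgb, (out_size, out_size), order=1, preserve_range=True,
                    anti_aliasing=False)
    else:
        raise ValueError(f"unknown interpolation {interpolation!r}")
    return FootprintImage(pixels=np.clip(up, 0, 255).astype(np.uint8), side="both")


def write_image(image: FootprintImage, path: str | Path) -> Path:
    path = Path(path)
    Image.fromarray(image.pixels, mode="RGB").save(path)
    return path


def read_image(path: str | Path, side: str = "both") -> FootprintImage:
    arr = np.asarray(Image.open(path).convert("RGB"))
    return FootprintImage(pixels=arr, side=side)


# ---------------------------------------------------------------------------
# Manifests and cohort loading
# ---------------------------------------------------------------------------

def write_manifest(manifest: CohortManifest, path: str | Path) -> Path:
    """Persist a manifest as YAML with paths relative to the manifest file."""
    path = Path(path)
    base = path.parent.resolve()

    def _rel(p: Path) -> str:
        p = Path(p).resolve()
        try:
            return str(p.relative_to(base))
        except ValueError:
            return str(p)

    doc = {
        "provenance": manifest.provenance,
        "subjects": [
            {"id": sid, "left": _rel(lp), "right": _rel(rp)}
            for sid, lp, rp in manifest.entries
        ],
    }
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)
    return path


def read_manifest(path: str | Path) -> CohortManifest:
    path = Path(path)
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    base = path.parent
    entries = [
        (str(s["id"]), base / s["left"], base / s["right"])
        for s in doc.get("subjects", [])
    ]
    return CohortManifest(entries=entries, provenance=doc.get("provenance", ""))


def load_cohort(
    manifest: CohortManifest, dialect: str = "csv"
) -> list[tuple[str, PressureGrid, PressureGrid]]:
    """Load (subject_id, left grid, right grid) triples, order preserved."""
    out = []
    for sid, left_path, right_path in manifest.entries:
        for side, p in (("left", left_path), ("right", right_path)):
            if not Path(p).exists():
                raise FileNotFoundError(
                    f"subject {sid!r}: missing {side} grid file {p}"
                )
        out.append(
            (sid, read_pressure_grid(left_path, dialect), read_pressure_grid(right_path, dialect))
        )
    return out


def combine_frame(left: PressureGrid, right: PressureGrid) -> PressureGrid:
    """Merge two single-foot frames (each foot in its own half) into one frame."""
    return PressureGrid(
        values=left.values + right.values,
        sensor_pitch=left.sensor_pitch,
        frame_id=f"{left.frame_id}+{right.frame_id}",
    )
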