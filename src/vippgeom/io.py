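"""File plumbing: MRC density maps, TIFF+sidecar height rasters, config.

Units policy: lattice and reciprocal quantities are Å, AFM-scale
quantities nm; CSV/JSON field names carry unit suffixes (_A, _nm,
_invA, _deg) to keep the mixed-unit domain explicit.

The MRC reader/writer is a deliberately small MRC2014 subset (modes
0/1/2, default axis order) sufficient for the synthetic maps used here;
voxel sizes are taken from the header cell dimensions and may be
anisotropic.
"""

from __future__ import annotations

import configparser
import json
import struct
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import tifffile

from . import presets
from .afm_synth import AFMImage
from .errors import FormatError, InvalidArgumentError

_MRC_HEADER_BYTES = 1024
_MRC_MODES = {0: np.int8, 1: np.int16, 2: np.float32}


def write_mrc(path, data: np.ndarray, voxel_A: float | tuple[float, float, float]) -> None:
    """Write a 3D float32 raster (indexed [z, y, x]) as MRC2014 mode 2."""
    data = np.asarray(data, dtype=np.float32)
    if data.ndim != 3:
        raise InvalidArgumentError("data must be a 3D raster")
    if isinstance(voxel_A, (tuple, list, np.ndarray)):
        vx, vy, vz = (float(v) for v in voxel_A)
    else:
        vx = vy = vz = float(voxel_A)
    nz, ny, nx = data.shape
    header = bytearray(_MRC_HEADER_BYTES)
    struct.pack_into("<3i", header, 0, nx, ny, nz)          # NX NY NZ
    struct.pack_into("<i", header, 12, 2)                   # MODE
    struct.pack_into("<3i", header, 28, nx, ny, nz)         # MX MY MZ
    struct.pack_into("<3f", header, 40, nx * vx, ny * vy, nz * vz)  # CELLA
    struct.pack_into("<3f", header, 52, 90.0, 90.0, 90.0)   # CELLB
    struct.pack_into("<3i", header, 64, 1, 2, 3)            # MAPC MAPR MAPS
    struct.pack_into("<3f", header, 76, float(data.min()), float(data.max()),
                     float(data.mean()))
    struct.pack_into("<i", header, 88, 1)                   # ISPG
    header[208:212] = b"MAP "
    header[212:216] = bytes([0x44, 0x44, 0x00, 0x00])       # little-endian stamp
    struct.pack_into("<f", header, 216, float(data.std()))
    with open(path, "wb") as fh:
        fh.write(bytes(header))
        fh.write(data.tobytes())


def read_density_map(path) -> tuple[np.ndarray, tuple[float, float, float]]:
    """Read an MRC/CCP4 map (modes 0/1/2).

    Returns ``(data, (vx, vy, vz))`` with the raster indexed [z, y, x]
    (axis order normalised from the header MAPC/MAPR/MAPS fields) and
    per-axis voxel sizes in Å.
    """
    raw = Path(path).read_bytes()
    if len(raw) < _MRC_HEADER_BYTES:
        raise FormatError(f"{path}: file shorter than the 1024-byte MRC header")
    if raw[208:212] not in (b"MAP ", b"MAP\x00"):
        raise FormatError(f"{path}: bad MAP magic field {raw[208:212]!r}")
    nx, ny, nz = struct.unpack_from("<3i", raw, 0)
    (mode,) = struct.unpack_from("<i", raw, 12)
    mx, my, mz = struct.unpack_from("<3i", raw, 28)
    ca, cb, cc = struct.unpack_from("<3f", raw, 40)
    mapc, mapr, maps_ = struct.unpack_from("<3i", raw, 64)
    (nsymbt,) = struct.unpack_from("<i", raw, 92)
    if mode not in _MRC_MODES:
        raise FormatError(f"{path}: unsupported MODE field {mode}")
    if min(nx, ny, nz) <= 0:
        raise FormatError(f"{path}: non-positive dimension field NX/NY/NZ=({nx},{ny},{nz})")
    if min(mx, my, mz) <= 0:
        raise FormatError(f"{path}: non-positive sampling field MX/MY/MZ=({mx},{my},{mz})")
    dtype = np.dtype(_MRC_MODES[mode]).newbyteorder("<")
    offset = _MRC_HEADER_BYTES + nsymbt
    need = offset + nx * ny * nz * dtype.itemsize
    if len(raw) < need:
        raise FormatError(f"{path}: truncated data block ({len(raw)} < {need} bytes)")
    data = np.frombuffer(raw, dtype=dtype, count=nx * ny * nz, offset=offset)
    # file order: column axis (fastest) = MAPC, then MAPR, then MAPS
    arr = data.reshape(nz, ny, nx)  # slowest..fastest as stored
    axis_of = {mapc: 2, mapr: 1, maps_: 0}  # crystal axis -> array axis
    if sorted((mapc, mapr, maps_)) != [1, 2, 3]:
        raise FormatError(f"{path}: bad axis fields MAPC/MAPR/MAPS=({mapc},{mapr},{maps_})")
    # normalise so that axis order is (z, y, x) = crystal (3, 2, 1)
    arr = np.moveaxis(arr, (axis_of[3], axis_of[2], axis_of[1]), (0, 1, 2))
    voxel = (ca / mx, cb / my, cc / mz)
    return np.ascontiguousarray(arr, dtype=np.float32), voxel


# --------------------------------------------------------------------------
# AFM rasters: 32-bit float TIFF + JSON sidecar
# --------------------------------------------------------------------------


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".json")


def write_afm_image(image: AFMImage, path) -> None:
    """Write heights (nm) as 32-bit float TIFF with a JSON metadata sidecar."""
    path = Path(path)
    tifffile.imwrite(path, image.heights.astype(np.float32))
    meta = {"pixel_nm": image.pixel_nm, **image.metadata}
    _sidecar_path(path).write_text(json.dumps(meta, indent=1, sort_keys=True))


def read_afm_image(path) -> AFMImage:
    """Read a TIFF+sidecar raster written by :func:`write_afm_image`."""
    path = Path(path)
    sidecar = _sidecar_path(path)
    if not sidecar.exists():
        raise FormatError(f"missing sidecar {sidecar} for {path}")
    meta = json.loads(sidecar.read_text())
    if "pixel_nm" not in meta:
        raise FormatError(f"{sidecar}: missing required field pixel_nm")
    heights = tifffile.imread(path)
    if heights.dtype.kind != "f":
        raise FormatError(f"{path}: expected a float TIFF, got dtype {heights.dtype}")
    pixel = float(meta.pop("pixel_nm"))
    return AFMImage(heights=np.asarray(heights, dtype=np.float32), pixel_nm=pixel,
                    metadata=meta)


# --------------------------------------------------------------------------
# configuration
# --------------------------------------------------------------------------


@dataclass
class ToolkitConfig:
    """Toolkit-wide defaults, overridable per CLI flag or config file."""

    k_max: int = 25
    radius_policy: str = "mid_wall"
    s0_A: float = presets.RIDGE_SPACING_RELAXED_A
    s_min_A: float = presets.RIDGE_SPACING_MIN_A
    s_max_A: float = presets.RIDGE_SPACING_MAX_A
    width_A: float = presets.FILAMENT_WIDTH_A
    seed: int = 0
    out_dir: str = "."
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if self.k_max < 2:
            raise InvalidArgumentError("k_max must be >= 2")
        if self.radius_policy not in ("mid_wall", "outer", "lumen"):
            raise InvalidArgumentError(f"unknown radius_policy {self.radius_policy!r}")
        if not (0 < self.s_min_A < self.s0_A < self.s_max_A):
            raise InvalidArgumentError("need 0 < s_min_A < s0_A < s_max_A")

    @classmethod
    def from_file(cls, path) -> "ToolkitConfig":
        """Load from a flat INI-style key=value file ([toolkit] section)."""
        parser = configparser.ConfigParser()
        parser.optionxform = str  # preserve case: unit suffixes matter
        parser.read_string(Path(path).read_text())
        known = {f: t for f, t in cls.__annotations__.items()}
        kwargs = {}
        for section in parser.sections():
            for key, value in parser.items(section):
                if key not in known:
                    raise InvalidArgumentError(f"unknown config key {key!r}")
                target = cls.__dataclass_fields__[key].type
                if target in ("int",):
                    kwargs[key] = int(value)
                elif target in ("float",):
                    kwargs[key] = float(value)
                else:
                    kwargs[key] = value
        return cls(**kwargs)

    def to_dict(self) -> dict:
        return asdict(self)
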