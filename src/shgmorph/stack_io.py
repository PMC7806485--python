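"""Reading and writing multiphoton stacks and absorbance spectra.

The in-memory containers defined here — :class:`MultiphotonStack` for
3-channel volumetric image data and :class:`Spectrum` for absorbance
spectra — are the interchange types used by every analysis module.

Channel convention
------------------
Stacks carry exactly three channels in the canonical order
``(AF, bSHG, fSHG)``:

* ``AF`` — two-photon autofluorescence (detected around 525 nm),
* ``bSHG`` — backward-scattered second harmonic generation (405 nm),
  dominated by fibrous collagen,
* ``fSHG`` — forward-scattered SHG, dominated by myofibrillar myosin-II.

Files on disk may store channels in any order; :func:`read_stack`
normalises them into the canonical order via an explicit ``channel_map``.
Downstream code indexes channels by name, never by position.

On disk, stacks are OME-TIFF (axes ``CZYX``) with physical voxel sizes in
the OME metadata; intensities are stored as unsigned 16-bit and analysed
in floating point. Spectra are two-column CSV (``wavelength_nm``,
``absorbance``).
"""

from __future__ import annotations

import logging
import xml.etree.ElementTree as ET
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import tifffile

logger = logging.getLogger(__name__)

#: Canonical channel order used throughout the package.
CHANNELS = ("AF", "bSHG", "fSHG")


@dataclass
class MultiphotonStack:
    """A 3-channel multiphoton volume with physical voxel sizes.

    Parameters
    ----------
    data
        Intensity array of shape ``(3, nz, ny, nx)``; nonnegative.
    voxel_size
        ``(dx, dy, dz)`` in µm. Slice ``k`` sits at depth ``k * dz`` µm,
        with ``k = 0`` at the objective-facing entry surface.
    channel_names
        Channel identity per axis-0 index; canonical ``(AF, bSHG, fSHG)``.
    metadata
        Free-form acquisition metadata (excitation wavelength, emission
        bands, simulation provenance, ...).
    """

    data: np.ndarray
    voxel_size: tuple[float, float, float]
    channel_names: tuple[str, ...] = CHANNELS
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 4 or self.data.shape[0] != 3:
            raise ValueError(
                f"stack data must have shape (3, nz, ny, nx); got {self.data.shape}"
            )
        self.voxel_size = tuple(float(v) for v in self.voxel_size)
        if len(self.voxel_size) != 3 or any(v <= 0 for v in self.voxel_size):
            raise ValueError(f"voxel_size must be 3 strictly positive µm values; got {self.voxel_size}")
        self.channel_names = tuple(self.channel_names)
        if len(self.channel_names) != 3:
            raise ValueError("exactly 3 channel names required")
        if self.data.size == 0:
            raise ValueError("empty volume")
        if np.nanmin(self.data) < 0:
            raise ValueError("stack intensities must be nonnegative")

    @property
    def dx(self) -> float:
        return self.voxel_size[0]

    @property
    def dy(self) -> float:
        return self.voxel_size[1]

    @property
    def dz(self) -> float:
        return self.voxel_size[2]

    @property
    def spatial_shape(self) -> tuple[int, int, int]:
        """``(nz, ny, nx)`` of one channel."""
        return self.data.shape[1:]

    @property
    def n_slices(self) -> int:
        return self.data.shape[1]

    @property
    def depths_um(self) -> np.ndarray:
        """Depth of each slice in µm (``k * dz``)."""
        return np.arange(self.n_slices) * self.dz

    def channel(self, name: str) -> np.ndarray:
        """Return one channel volume ``(nz, ny, nx)`` by name."""
        try:
            idx = self.channel_names.index(name)
        except ValueError:
            raise KeyError(f"unknown channel {name!r}; have {self.channel_names}") from None
        return self.data[idx]

    def with_data(self, data: np.ndarray) -> "MultiphotonStack":
        """Copy of the stack with replaced intensity data."""
        return MultiphotonStack(data, self.voxel_size, self.channel_names, dict(self.metadata))


@dataclass
class Spectrum:
    """An absorbance spectrum: wavelength grid (nm) and OD values."""

    wavelength_nm: np.ndarray
    absorbance: np.ndarray
    label: str = ""

    def __post_init__(self) -> None:
        self.wavelength_nm = np.asarray(self.wavelength_nm, dtype=float)
        self.absorbance = np.asarray(self.absorbance, dtype=float)
        wl, ab = self.wavelength_nm, self.absorbance
        if wl.ndim != 1 or wl.shape != ab.shape or wl.size < 2:
            raise ValueError("wavelength and absorbance must be equal-length 1D arrays (n >= 2)")
        steps = np.diff(wl)
        if np.any(steps <= 0):
            raise ValueError("wavelengths must be strictly increasing")
        if not np.allclose(steps, steps[0], rtol=1e-6, atol=1e-9):
            raise ValueError("wavelength step size must be uniform")
        if wl[0] < 200 or wl[-1] > 800:
            raise ValueError("wavelengths must lie within [200, 800] nm")
        if not np.all(np.isfinite(ab)):
            raise ValueError("absorbance values must be finite")

    @property
    def step_nm(self) -> float:
        return float(self.wavelength_nm[1] - self.wavelength_nm[0])

    def __len__(self) -> int:
        return int(self.wavelength_nm.size)


# ---------------------------------------------------------------------------
# Stack I/O
# ---------------------------------------------------------------------------

def _normalise_channel_map(channel_map) -> tuple[int, int, int]:
    """File channel index for each canonical channel (AF, bSHG, fSHG)."""
    if channel_map is None:
        return (0, 1, 2)
    if isinstance(channel_map, Mapping):
        missing = [c for c in CHANNELS if c not in channel_map]
        if missing:
            raise ValueError(f"channel_map missing entries for {missing}")
        return tuple(int(channel_map[c]) for c in CHANNELS)
    if isinstance(channel_map, Sequence):
        if len(channel_map) != 3:
            raise ValueError("channel_map sequence must have 3 indices (AF, bSHG, fSHG)")
        return tuple(int(i) for i in channel_map)
    raise TypeError("channel_map must be a mapping, a 3-sequence, or None")


def _voxel_size_from_ome(ome_xml: str) -> tuple[float, float, float] | None:
    try:
        root = ET.fromstring(ome_xml)
    except ET.ParseError:
        return None
    for elem in root.iter():
        if elem.tag.endswith("Pixels"):
            try:
                return (
                    float(elem.attrib["PhysicalSizeX"]),
                    float(elem.attrib["PhysicalSizeY"]),
                    float(elem.attrib["PhysicalSizeZ"]),
                )
            except KeyError:
                return None
    return None


def write_stack(stack: MultiphotonStack, path) -> Path:
    """Write a stack as OME-TIFF (CZYX, uint16) with voxel sizes embedded.

    Intensities are rounded to the nearest integer; values beyond the
    16-bit range are clamped with a logged warning.
    """
    path = Path(path)
    data = np.rint(np.asarray(stack.data, dtype=np.float64))
    n_over = int(np.count_nonzero(data > 65535))
    if n_over:
        logger.warning("write_stack: %d voxels exceed 16-bit range and were clamped to 65535", n_over)
    data = np.clip(data, 0, 65535).astype(np.uint16)
    dx, dy, dz = stack.voxel_size
    axes = "CZYX"
    if data.shape[1] == 1:  # tifffile squeezes a singleton Z
        data = data[:, 0]
        axes = "CYX"
    tifffile.imwrite(
        path,
        data,
        ome=True,
        photometric="minisblack",  # never mistake 3 channels for RGB samples
        metadata={
            "axes": axes,
            "PhysicalSizeX": dx,
            "PhysicalSizeXUnit": "µm",
            "PhysicalSizeY": dy,
            "PhysicalSizeYUnit": "µm",
            "PhysicalSizeZ": dz,
            "PhysicalSizeZUnit": "µm",
            "Channel": {"Name": list(stack.channel_names)},
        },
    )
    return path


def read_stack(path, channel_map=None, voxel_size=None) -> MultiphotonStack:
    """Read a multi-channel TIFF into a canonical-order stack.

    Parameters
    ----------
    path
        TIFF/OME-TIFF file with at least 3 channels (axes CZYX or ZCYX;
        a single-slice CYX file is promoted to nz = 1).
    channel_map
        Assignment of the canonical channels to file channel indices:
        either a mapping ``{"AF": i, "bSHG": j, "fSHG": k}`` or a
        3-sequence ``(i, j, k)`` in canonical order. Default ``(0, 1, 2)``.
    voxel_size
        Explicit ``(dx, dy, dz)`` µm override. Required when the file
        carries no physical voxel size metadata — the reader never invents
        voxel sizes.
    """
    path = Path(path)
    with tifffile.TiffFile(path) as tif:
        series = tif.series[0]
        axes = series.axes.upper()
        arr = series.asarray()
        ome_xml = tif.ome_metadata

    # normalise axes to CZYX
    if axes in ("CZYX", "ZCYX"):
        if axes == "ZCYX":
            arr = np.moveaxis(arr, 1, 0)
    elif axes == "CYX":
        arr = arr[:, None, :, :]
    elif axes == "ZYX" or axes == "QYX" or axes == "SYX" or axes == "IYX":
        # treat leading non-channel axis as channels only if nothing better
        arr = arr[:, None, :, :]
    else:
        raise ValueError(f"unsupported TIFF axes {axes!r}; expected CZYX-like layout")
    if arr.shape[0] < 3:
        raise ValueError(f"stack must have >= 3 channels; file has {arr.shape[0]} ({axes})")

    if voxel_size is None:
        voxel_size = _voxel_size_from_ome(ome_xml) if ome_xml else None
        if voxel_size is None:
            raise ValueError(
                "voxel size missing: file metadata has no PhysicalSizeX/Y/Z and no "
                "explicit voxel_size override was given"
            )
    order = _normalise_channel_map(channel_map)
    data = np.stack([arr[i] for i in order]).astype(np.float64)
    return MultiphotonStack(data, voxel_size, CHANNELS, {"source": str(path)})


# ---------------------------------------------------------------------------
# Spectrum I/O
# ---------------------------------------------------------------------------

def read_spectrum_csv(path, label: str | None = None) -> Spectrum:
    """Read a two-column CSV (``wavelength_nm``, ``absorbance``) spectrum.

    Validation (monotone wavelengths, uniform step, finite OD) happens in
    the :class:`Spectrum` constructor; a shuffled or malformed file raises.
    """
    path = Path(path)
    df = pd.read_csv(path)
    if df.shape[1] < 2:
        raise ValueError(f"{path}: expected two columns (wavelength_nm, absorbance)")
    if {"wavelength_nm", "absorbance"} <= set(df.columns):
        wl, ab = df["wavelength_nm"], df["absorbance"]
    else:
        wl, ab = df.iloc[:, 0], df.iloc[:, 1]
    return Spectrum(wl.to_numpy(float), ab.to_numpy(float), label if label is not None else path.stem)


def write_spectrum_csv(spectrum: Spectrum, path) -> Path:
    path = Path(path)
    pd.DataFrame(
        {"wavelength_nm": spectrum.wavelength_nm, "absorbance": spectrum.absorbance}
    ).to_csv(path, index=False)
    return path
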