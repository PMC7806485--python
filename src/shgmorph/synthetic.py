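"""Synthetic 3-channel muscle volumes with ground truth.

The simulator emulates the image content of label-free multiphoton stacks
of whole skeletal muscle so that every analysis stage in this package can
be exercised against a known truth:

* **Geometry** — parallel quasi-cylindrical myofibers running in-plane at
  a configurable angle, hexagonally packed with seeded jitter and
  separated by extracellular gaps; a thin collagen sheath wraps each
  fiber.
* **Channels** — fSHG is a raised sinusoid along the fiber axis (the
  sarcomere striation, period = sarcomere length); bSHG is concentrated
  in the collagen sheath at fiber boundaries; AF is uniform-with-texture
  across the tissue.
* **Necrosis** — an ellipsoidal (or explicit) sub-volume in which
  myofibrillar structure is lost: the fSHG banding is destroyed and its
  level drops to a small residual, while AF and bSHG are essentially
  retained. This mirrors the hallmark of myotoxin-induced necrosis, where
  fibers void of fSHG signal border fibers with intact striation.
* **Depth attenuation & noise** — each slice is scaled by
  ``exp(-depth / d)`` per channel (``d = inf`` models an optically
  cleared sample), followed by Poisson photon noise plus Gaussian read
  noise.

Everything is seeded: identical config + seed gives bit-identical output.
Each stochastic ingredient (geometry, AF texture, per-channel noise)
draws from its own stream keyed by (seed, purpose), so a pair of
simulations that differ only in the necrosis specification share the
identical AF and bSHG channels — a matched sham control by construction.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import ndimage
from scipy.spatial import cKDTree

from .stack_io import CHANNELS, MultiphotonStack, write_stack

__all__ = [
    "NoiseModel",
    "SimulationConfig",
    "GroundTruth",
    "generate_fiber_geometry",
    "render_channels",
    "apply_attenuation_and_noise",
    "simulate",
    "preset_config",
    "sham_twin",
    "PRESETS",
]

# stream keys for per-purpose RNGs; channel streams are keyed by canonical
# channel index so a channel's noise is invariant to other channels' params
_STREAM_GEOMETRY = 1
_STREAM_TEXTURE = 2
_STREAM_NOISE_BASE = 10


@dataclass
class NoiseModel:
    """Photon-counting detector noise: Poisson + Gaussian read noise.

    ``poisson`` toggles shot noise on the photon counts; ``read_noise_sd``
    and ``offset`` parameterise the additive Gaussian detector term (both
    in count units). All-off gives a noiseless identity.
    """

    poisson: bool = True
    read_noise_sd: float = 1.0
    offset: float = 0.0

    def validate(self) -> None:
        if self.read_noise_sd < 0:
            raise ValueError("read_noise_sd must be >= 0")
        if self.offset < 0:
            raise ValueError("detector offset must be >= 0")

    @property
    def enabled(self) -> bool:
        return self.poisson or self.read_noise_sd > 0 or self.offset != 0


def _per_channel(value, what: str) -> dict[str, float]:
    """Normalise a scalar or per-channel mapping into {channel: float}."""
    if isinstance(value, dict):
        missing = [c for c in CHANNELS if c not in value]
        if missing:
            raise ValueError(f"{what} missing channels {missing}")
        return {c: float(value[c]) for c in CHANNELS}
    return {c: float(value) for c in CHANNELS}


@dataclass
class SimulationConfig:
    """Full parameterisation of one synthetic acquisition.

    Lengths are µm, angles degrees, intensities photons. The voxel grid is
    ``volume_shape = (nx, ny, nz)`` with voxel size ``(dx, dy, dz)``;
    slice ``k`` sits at depth ``k * dz``, ``k = 0`` at the entry surface.
    """

    volume_shape: tuple[int, int, int] = (256, 256, 100)
    voxel_size: tuple[float, float, float] = (0.7, 0.7, 4.0)
    fiber_diameter_mean: float = 24.0
    fiber_diameter_sd: float = 3.0
    fiber_axis_angle: float = 0.0
    packing_angle_deg: float = 19.0  # hex-lattice row angle in the (cross-axis, depth) plane
    fiber_waviness_um: float = 5.0  # lateral undulation amplitude of fiber boundaries
    fiber_waviness_period_um: float = 60.0  # undulation period along the fiber axis
    sarcomere_length: float = 2.2
    sarcomere_contrast: float = 0.35
    sarcomere_length_jitter: float = 0.01  # per-fiber fractional sd
    collagen_sheath_thickness: float = 1.5
    psf_sigma_um: float = 0.5  # lateral optical resolution; 0 disables blur
    myofibril_edge_taper_um: float = 0.0  # fSHG ramp-up width at the fiber boundary
    channel_gains: dict = field(default_factory=lambda: {"AF": 80.0, "bSHG": 60.0, "fSHG": 120.0})
    af_collagen_factor: float = 0.5  # sheath AF level relative to myofiber cytoplasm
    necrosis_mask_spec: object = None  # dict(center_um, radii_um[, target_fraction]) | ndarray | None
    necrosis_ablation: dict = field(default_factory=lambda: {"AF": 1.0, "bSHG": 1.0, "fSHG": 0.02})
    attenuation_depth_constant: object = math.inf  # scalar µm or {channel: µm}; inf = cleared
    noise: NoiseModel = field(default_factory=NoiseModel)
    seed: int = 0
    metadata: dict = field(default_factory=lambda: {
        "excitation_nm": 810.0,
        "emission_bands_nm": {"AF": (525.0, 50.0), "bSHG": (405.0, 20.0), "fSHG": (405.0, 20.0)},
    })

    def __post_init__(self) -> None:
        self.volume_shape = tuple(int(n) for n in self.volume_shape)
        self.voxel_size = tuple(float(v) for v in self.voxel_size)
        if any(n <= 0 for n in self.volume_shape):
            raise ValueError("volume_shape entries must be positive")
        if any(v <= 0 for v in self.voxel_size):
            raise ValueError("voxel sizes must be strictly positive")
        for name in ("fiber_diameter_mean", "collagen_sheath_thickness"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
        if self.fiber_diameter_sd < 0:
            raise ValueError("fiber_diameter_sd must be >= 0")
        if not (1.0 < self.sarcomere_length < 5.0):
            raise ValueError("sarcomere_length must lie within (1.0, 5.0) µm")
        if not (0.0 <= self.sarcomere_contrast <= 1.0):
            raise ValueError("sarcomere_contrast must lie in [0, 1]")
        if self.sarcomere_length_jitter < 0:
            raise ValueError("sarcomere_length_jitter must be >= 0")
        if self.psf_sigma_um < 0:
            raise ValueError("psf_sigma_um must be >= 0")
        if self.myofibril_edge_taper_um < 0:
            raise ValueError("myofibril_edge_taper_um must be >= 0")
        self.channel_gains = _per_channel(self.channel_gains, "channel_gains")
        self.necrosis_ablation = _per_channel(self.necrosis_ablation, "necrosis_ablation")
        if any(not 0.0 <= a <= 1.0 for a in self.necrosis_ablation.values()):
            raise ValueError("necrosis_ablation factors must lie in [0, 1]")
        if not 0.0 <= self.af_collagen_factor <= 1.0:
            raise ValueError("af_collagen_factor must lie in [0, 1]")
        self.attenuation_depth_constant = _per_channel(
            self.attenuation_depth_constant, "attenuation_depth_constant"
        )
        if any(d <= 0 for d in self.attenuation_depth_constant.values()):
            raise ValueError("attenuation depth constants must be > 0 (inf allowed)")
        if isinstance(self.noise, dict):
            self.noise = NoiseModel(**self.noise)
        self.noise.validate()
        n_vox = int(np.prod(self.volume_shape))
        if n_vox > 5e7:
            raise ValueError(f"volume of {n_vox} voxels exceeds the desk-scale bound (5e7)")

    @property
    def n_voxels(self) -> int:
        return int(np.prod(self.volume_shape))

    def replace(self, **changes) -> "SimulationConfig":
        return dataclasses.replace(self, **changes)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["noise"] = dataclasses.asdict(self.noise)
        if isinstance(d["necrosis_mask_spec"], np.ndarray):
            d["necrosis_mask_spec"] = "<explicit mask array>"
        # inf is not portable JSON; encode as string
        d["attenuation_depth_constant"] = {
            c: ("inf" if math.isinf(v) else v) for c, v in d["attenuation_depth_constant"].items()
        }
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        d = dict(d)
        if "attenuation_depth_constant" in d and isinstance(d["attenuation_depth_constant"], dict):
            d["attenuation_depth_constant"] = {
                c: (math.inf if v in ("inf", "Infinity") else float(v))
                for c, v in d["attenuation_depth_constant"].items()
            }
        if isinstance(d.get("noise"), dict):
            d["noise"] = NoiseModel(**d["noise"])
        for key in ("volume_shape", "voxel_size"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)


@dataclass
class GroundTruth:
    """Simulator-side truth for recovery tests.

    ``fiber_label_map`` is an integer volume (0 = extracellular) on the
    same ``(nz, ny, nx)`` grid as the emitted stack; ``tissue_mask``
    includes fibers plus collagen sheaths; ``necrosis_mask`` is a subset
    of the tissue.
    """

    fiber_label_map: np.ndarray
    necrosis_mask: np.ndarray
    tissue_mask: np.ndarray
    sarcomere_length_true: float
    attenuation_depth_constant_true: dict

    def __post_init__(self) -> None:
        if not (self.fiber_label_map.shape == self.necrosis_mask.shape == self.tissue_mask.shape):
            raise ValueError("truth volumes must share one shape")
        if np.any(self.necrosis_mask & ~self.tissue_mask):
            raise ValueError("necrosis_mask must be a subset of tissue_mask")
        if np.any((self.fiber_label_map > 0) & ~self.tissue_mask):
            raise ValueError("fiber voxels must lie inside tissue_mask")

    @property
    def necrotic_fraction(self) -> float:
        """Necrotic share of tissue voxels (0 if there is no tissue)."""
        n_tissue = int(np.count_nonzero(self.tissue_mask))
        if n_tissue == 0:
            return 0.0
        return float(np.count_nonzero(self.necrosis_mask) / n_tissue)

    @property
    def tissue_fraction(self) -> float:
        return float(np.count_nonzero(self.tissue_mask) / self.tissue_mask.size)


# ---------------------------------------------------------------------------
# Geometry
# ---------------------------------------------------------------------------

def _inplane_coords(config: SimulationConfig):
    """Along-axis (a) and cross-axis (v) coordinate images, µm."""
    nx, ny, _ = config.volume_shape
    dx, dy, _ = config.voxel_size
    x = np.arange(nx) * dx
    y = np.arange(ny) * dy
    X, Y = np.meshgrid(x, y)  # (ny, nx)
    theta = math.radians(config.fiber_axis_angle)
    a = X * math.cos(theta) + Y * math.sin(theta)
    v = -X * math.sin(theta) + Y * math.cos(theta)
    return a.astype(np.float64), v.astype(np.float64)


def generate_fiber_geometry(config: SimulationConfig) -> GroundTruth:
    """Lay out jittered hexagonally packed fibers and realise the necrosis mask.

    Fibers are cylinders whose axes run in-plane at ``fiber_axis_angle``;
    their circular cross-sections live in the (cross-axis, depth) plane.
    Centers sit on a hexagonal lattice anchored at the volume midpoint and
    perturbed by seeded jitter; each fiber's radius is drawn from the
    configured diameter distribution. Assignment is Voronoi (nearest
    center), with radii capped so neighbouring fibers keep an
    extracellular gap of at least one voxel.
    """
    nx, ny, nz = config.volume_shape
    dx, dy, dz = config.voxel_size
    if config.fiber_diameter_mean <= 2.0 * max(dx, dy):
        raise ValueError(
            "fiber diameter <= 2 in-plane voxels: geometry undersampled "
            f"(mean {config.fiber_diameter_mean} µm at {max(dx, dy)} µm pixels)"
        )
    rng = np.random.default_rng([config.seed, _STREAM_GEOMETRY])

    _, v2d = _inplane_coords(config)
    vmin, vmax = float(v2d.min()), float(v2d.max())
    zmax = (nz - 1) * dz

    # endomysial gap: at least one in-plane voxel of extracellular space
    # between neighbouring sheaths (fiber cross-sections live in the
    # (cross-axis, depth) plane, but lateral separation is what the
    # in-plane images resolve)
    gap = 1.5 * max(dx, dy)
    # strong positional jitter decorrelates the lattice so the fiber-edge
    # harmonic comb smears into broadband power instead of sharp peaks
    # inside the sarcomere frequency band
    jitter_amp = 0.10 * config.fiber_diameter_mean
    spacing = config.fiber_diameter_mean + gap + 2.0 * jitter_amp

    # hexagonal lattice in the (v, z) cross-section plane, anchored so a
    # center sits at the volume midpoint (makes the one-huge-fiber
    # degenerate case well defined). The lattice rows are tilted by
    # packing_angle_deg relative to the slice plane so that a given depth
    # samples fibers at all packing phases — otherwise per-slice tissue
    # composition would oscillate with depth at the row spacing.
    v_mid, z_mid = 0.5 * (vmin + vmax), 0.5 * zmax
    phi = math.radians(config.packing_angle_deg)
    u1 = spacing * np.array([math.cos(phi), math.sin(phi)])
    u2 = spacing * np.array([math.cos(phi + math.pi / 3.0), math.sin(phi + math.pi / 3.0)])
    half_diag = 0.5 * math.hypot(vmax - vmin, zmax) + 2.0 * spacing
    n_steps = int(math.ceil(half_diag / (spacing * math.sin(math.pi / 3.0)))) + 2
    ij = np.mgrid[-n_steps : n_steps + 1, -n_steps : n_steps + 1].reshape(2, -1).T
    centers = np.array([v_mid, z_mid]) + ij @ np.vstack([u1, u2])
    keep = (
        (centers[:, 0] >= vmin - spacing)
        & (centers[:, 0] <= vmax + spacing)
        & (centers[:, 1] >= -spacing)
        & (centers[:, 1] <= zmax + spacing)
    )
    centers = centers[keep]
    centers += rng.normal(0.0, jitter_amp / 2.0, size=centers.shape).clip(-jitter_amp, jitter_amp)

    radii = rng.normal(config.fiber_diameter_mean, config.fiber_diameter_sd, size=len(centers)) / 2.0
    radii = radii.clip(
        max(1.5 * max(dx, dy), config.fiber_diameter_mean / 2.0 - 2.0 * config.fiber_diameter_sd),
        config.fiber_diameter_mean / 2.0 + 2.0 * config.fiber_diameter_sd,
    )
    tree = cKDTree(centers)
    if len(centers) > 1:
        nn_dist = tree.query(centers, k=2)[0][:, 1]
        radii = np.minimum(radii, (nn_dist - gap) / 2.0)
    radii = radii.clip(min=0.0)

    label = np.zeros((nz, ny, nx), dtype=np.int32)
    tissue = np.zeros((nz, ny, nx), dtype=bool)
    a2d, _ = _inplane_coords(config)
    v_flat = v2d.ravel()
    a_flat = a2d.ravel()
    pts = np.empty((v_flat.size, 2))
    sheath = config.collagen_sheath_thickness
    # fiber undulation: a smooth lateral displacement of the packing frame
    # along the fiber axis (and slowly with depth). Perfectly straight
    # fibers would concentrate all boundary-edge spectral power on a
    # single ridge in the cross-fiber direction and leave tile-width
    # fiber-free bands aligned with the image grid.
    wav_A = config.fiber_waviness_um
    wav_k = 2.0 * math.pi / config.fiber_waviness_period_um
    phi0 = float(rng.uniform(0.0, 2.0 * math.pi))
    for k in range(nz):
        if wav_A > 0:
            pts[:, 0] = v_flat + wav_A * np.sin(wav_k * a_flat + phi0 + 0.3 * wav_k * k * dz)
        else:
            pts[:, 0] = v_flat
        pts[:, 1] = k * dz
        dist, idx = tree.query(pts)
        fiber = dist <= radii[idx]
        label[k] = np.where(fiber, idx + 1, 0).reshape(ny, nx)
        tissue[k] = (dist <= radii[idx] + sheath).reshape(ny, nx)

    # compact labels to 1..n in order of appearance
    present = np.unique(label)
    present = present[present > 0]
    remap = np.zeros(int(label.max()) + 1, dtype=np.int32)
    remap[present] = np.arange(1, len(present) + 1, dtype=np.int32)
    label = remap[label]

    necrosis = _realise_necrosis_mask(config, tissue)
    return GroundTruth(
        fiber_label_map=label,
        necrosis_mask=necrosis,
        tissue_mask=tissue,
        sarcomere_length_true=config.sarcomere_length,
        attenuation_depth_constant_true=dict(config.attenuation_depth_constant),
    )


def _realise_necrosis_mask(config: SimulationConfig, tissue: np.ndarray) -> np.ndarray:
    """Realise the necrosis specification on the tissue grid.

    A dict spec describes an ellipsoid: ``center_um`` (default volume
    center) plus either ``radii_um`` or ``radii_scale`` (relative to the
    volume half-extents). With ``target_fraction`` set, the radii are
    rescaled by bisection until the mask covers that share of tissue
    voxels (deterministic voxel counting); ``scale_axes`` (default
    ``"xyz"``) restricts which radii the bisection rescales, so a
    laterally wide lesion can grow or shrink in depth only. An ndarray
    spec is used directly, clipped to tissue.
    """
    spec = config.necrosis_mask_spec
    nz, ny, nx = tissue.shape
    if spec is None:
        return np.zeros_like(tissue)
    if isinstance(spec, np.ndarray):
        if spec.shape != tissue.shape:
            raise ValueError("explicit necrosis mask shape must match the volume")
        return spec.astype(bool) & tissue
    if not isinstance(spec, dict):
        raise TypeError("necrosis_mask_spec must be None, a dict, or a boolean array")

    dx, dy, dz = config.voxel_size
    extent = (nx * dx, ny * dy, nz * dz)
    center = spec.get("center_um", tuple(e / 2.0 for e in extent))
    if "radii_um" in spec:
        radii = np.asarray(spec["radii_um"], dtype=float)
    else:
        scale = np.asarray(spec.get("radii_scale", (1.0, 1.0, 1.0)), dtype=float)
        radii = scale * np.asarray(extent) / 2.0
    if np.any(radii < 0):
        raise ValueError("ellipsoid radii must be >= 0")
    if np.all(radii == 0):
        return np.zeros_like(tissue)

    x = np.arange(nx) * dx - center[0]
    y = np.arange(ny) * dy - center[1]
    z = np.arange(nz) * dz - center[2]

    scale_axes = str(spec.get("scale_axes", "xyz")).lower()
    axis_on = np.array([ax in scale_axes for ax in "xyz"], dtype=float)

    def mask_at(scale: float) -> np.ndarray:
        rx, ry, rz = radii * (1.0 + (scale - 1.0) * axis_on)
        if rx == 0 or ry == 0 or rz == 0:
            return np.zeros_like(tissue)
        q = (
            (z[:, None, None] / rz) ** 2
            + (y[None, :, None] / ry) ** 2
            + (x[None, None, :] / rx) ** 2
        )
        return (q <= 1.0) & tissue

    target = spec.get("target_fraction")
    if target is None:
        return mask_at(1.0)
    if not (0.0 <= target < 1.0):
        raise ValueError("target_fraction must lie in [0, 1)")
    n_tissue = int(np.count_nonzero(tissue))
    if n_tissue == 0 or target == 0.0:
        return np.zeros_like(tissue)
    lo, hi = 0.0, 1.0
    while np.count_nonzero(mask_at(hi)) / n_tissue < target and hi < 64:
        hi *= 2.0
    for _ in range(40):
        mid = 0.5 * (lo + hi)
        if np.count_nonzero(mask_at(mid)) / n_tissue < target:
            lo = mid
        else:
            hi = mid
        if hi - lo < 1e-4:
            break
    return mask_at(hi)


# ---------------------------------------------------------------------------
# Rendering
# ---------------------------------------------------------------------------

def render_channels(truth: GroundTruth, config: SimulationConfig) -> MultiphotonStack:
    """Render the noiseless, unattenuated 3-channel volume from the truth.

    fSHG: raised sinusoid ``gain * (1 + contrast * cos(2π a / SL_i + φ_i))``
    along the fiber axis, with per-fiber sarcomere length jitter and random
    banding phase. bSHG: collagen sheath (tissue outside fibers). AF:
    uniform with a smooth seeded ±10% texture across the tissue. Inside the
    necrosis mask AF and bSHG are multiplied by their ablation factors,
    while fSHG loses its banding entirely and drops to
    ``gain * ablation`` — necrotic fibers have no sarcomere structure left
    to generate a coherent SHG striation.
    """
    if truth.fiber_label_map.shape != (
        config.volume_shape[2],
        config.volume_shape[1],
        config.volume_shape[0],
    ):
        raise ValueError("truth shape does not match config.volume_shape")
    nz, ny, nx = truth.fiber_label_map.shape
    gains = config.channel_gains
    abl = config.necrosis_ablation
    label = truth.fiber_label_map
    fiber = label > 0
    shell = truth.tissue_mask & ~fiber
    nec = truth.necrosis_mask

    a2d, _ = _inplane_coords(config)

    n_fibers = int(label.max())
    rng = np.random.default_rng([config.seed, _STREAM_GEOMETRY, 7])
    phases = np.zeros(n_fibers + 1)
    sl = np.full(n_fibers + 1, config.sarcomere_length)
    if n_fibers:
        phases[1:] = rng.uniform(0.0, 2.0 * math.pi, n_fibers)
        if config.sarcomere_length_jitter > 0:
            jit = rng.normal(0.0, config.sarcomere_length_jitter, n_fibers).clip(-0.05, 0.05)
            sl[1:] = config.sarcomere_length * (1.0 + jit)

    data = np.zeros((3, nz, ny, nx), dtype=np.float32)

    # fSHG: banding inside fibers, ramping up over myofibril_edge_taper_um
    # from the sarcolemma (a hard edge would put stripe harmonics of the
    # fiber packing into the sarcomere frequency band)
    if n_fibers:
        arg = (2.0 * math.pi) * a2d[None, :, :] / sl[label] + phases[label]
        banding = 1.0 + config.sarcomere_contrast * np.cos(arg)
        fshg = np.where(fiber, gains["fSHG"] * banding, 0.0)
        fshg = np.where(nec & fiber, gains["fSHG"] * abl["fSHG"], fshg)
        if config.myofibril_edge_taper_um > 0:
            dx, dy = config.voxel_size[0], config.voxel_size[1]
            for k in range(nz):
                edge_um = ndimage.distance_transform_edt(fiber[k], sampling=(dy, dx))
                fshg[k] *= np.minimum(edge_um / config.myofibril_edge_taper_um, 1.0)
    else:
        fshg = np.zeros((nz, ny, nx))
    data[CHANNELS.index("fSHG")] = fshg

    # bSHG: collagen sheath
    bshg = np.where(shell, gains["bSHG"], 0.0)
    bshg = np.where(nec, bshg * abl["bSHG"], bshg)
    data[CHANNELS.index("bSHG")] = bshg

    # AF: tissue-wide with smooth texture
    trng = np.random.default_rng([config.seed, _STREAM_TEXTURE])
    texture = trng.standard_normal((nz, ny, nx)).astype(np.float32)
    texture = ndimage.gaussian_filter(texture, sigma=(0, 4, 4))
    sd = float(texture.std())
    if sd > 0:
        texture *= 0.10 / sd
    af_level = np.where(fiber, 1.0, config.af_collagen_factor)
    af = np.where(truth.tissue_mask, gains["AF"] * af_level * (1.0 + texture), 0.0)
    af = np.where(nec, af * abl["AF"], af)
    data[CHANNELS.index("AF")] = np.clip(af, 0.0, None)

    # lateral PSF: without it, hard fiber-boundary edges put square-wave
    # harmonics of the stripe pattern into the sarcomere search band
    if config.psf_sigma_um > 0:
        sig = (0, config.psf_sigma_um / config.voxel_size[1], config.psf_sigma_um / config.voxel_size[0])
        for c in range(3):
            data[c] = ndimage.gaussian_filter(data[c], sigma=sig)

    meta = dict(config.metadata)
    meta["simulated"] = True
    return MultiphotonStack(data, config.voxel_size, CHANNELS, meta)


# ---------------------------------------------------------------------------
# Attenuation and noise
# ---------------------------------------------------------------------------

def apply_attenuation_and_noise(stack: MultiphotonStack, config: SimulationConfig) -> MultiphotonStack:
    """Apply per-channel mono-exponential depth attenuation, then detector noise.

    Slice ``k`` of channel ``c`` is scaled by ``exp(-k*dz / d_c)``
    (``d_c = inf`` leaves the channel flat, the cleared-sample limit).
    Noise is Poisson on the photon counts plus Gaussian read noise and a
    constant detector offset, clipped at zero; each channel draws from its
    own seeded stream so a channel's realisation does not depend on the
    other channels' parameters. With attenuation off and all noise terms
    zero the operation is the identity.
    """
    config.noise.validate()
    atten = _per_channel(config.attenuation_depth_constant, "attenuation_depth_constant")
    if any(d <= 0 for d in atten.values()):
        raise ValueError("attenuation depth constants must be > 0 (inf allowed)")
    depths = stack.depths_um
    noise = config.noise
    out = np.array(stack.data, dtype=np.float64, copy=True)
    for name in stack.channel_names:
        ci = stack.channel_names.index(name)
        d = atten[name]
        if math.isfinite(d):
            out[ci] *= np.exp(-depths / d)[:, None, None]
        if noise.enabled:
            rng = np.random.default_rng(
                [config.seed, _STREAM_NOISE_BASE + CHANNELS.index(name)]
            )
            if noise.poisson:
                out[ci] = rng.poisson(np.clip(out[ci], 0.0, None)).astype(np.float64)
            if noise.read_noise_sd > 0:
                out[ci] += rng.normal(noise.offset, noise.read_noise_sd, size=out[ci].shape)
            elif noise.offset != 0:
                out[ci] += noise.offset
            np.clip(out[ci], 0.0, None, out=out[ci])
    return stack.with_data(out.astype(np.float32))


# ---------------------------------------------------------------------------
# Composition and presets
# ---------------------------------------------------------------------------

def simulate(config: SimulationConfig, out_dir=None) -> tuple[MultiphotonStack, GroundTruth]:
    """Run geometry → rendering → attenuation + noise; optionally save.

    When ``out_dir`` is given, writes ``stack.ome.tif`` (CZYX uint16),
    ``fiber_labels.tif`` / ``necrosis_mask.tif`` / ``tissue_mask.tif``
    truth volumes, and a JSON sidecar with the config and truth summary.
    """
    truth = generate_fiber_geometry(config)
    stack = render_channels(truth, config)
    stack = apply_attenuation_and_noise(stack, config)
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        write_stack(stack, out_dir / "stack.ome.tif")
        import tifffile

        tifffile.imwrite(out_dir / "fiber_labels.tif", truth.fiber_label_map.astype(np.uint16))
        tifffile.imwrite(out_dir / "necrosis_mask.tif", truth.necrosis_mask.astype(np.uint8))
        tifffile.imwrite(out_dir / "tissue_mask.tif", truth.tissue_mask.astype(np.uint8))
        sidecar = {
            "config": config.to_dict(),
            "truth_summary": {
                "n_fibers": int(truth.fiber_label_map.max()),
                "tissue_fraction": truth.tissue_fraction,
                "necrotic_fraction": truth.necrotic_fraction,
                "sarcomere_length_true_um": truth.sarcomere_length_true,
                "attenuation_depth_constant_true_um": {
                    c: ("inf" if math.isinf(v) else v)
                    for c, v in truth.attenuation_depth_constant_true.items()
                },
            },
        }
        (out_dir / "simulation.json").write_text(json.dumps(sidecar, indent=2))
    return stack, truth


#: Named acquisition conditions. "native" models the uncleared muscle with
#: its ~200 µm attenuation depth constant; "cleared" models a TDE-cleared
#: sample (attenuation negligible over a millimetre); "ctx" adds a necrotic
#: sub-volume covering 30% of the tissue to the cleared condition.
PRESETS = {
    "native": {"attenuation_depth_constant": 200.0},
    "cleared": {"attenuation_depth_constant": 5000.0},
    "ctx": {
        "attenuation_depth_constant": 5000.0,
        # laterally wide, depth-bounded lesion covering 30% of the tissue;
        # the target-fraction bisection adjusts its depth extent only
        "necrosis_mask_spec": {
            "target_fraction": 0.30,
            "radii_scale": (1.4, 1.4, 0.55),
            "scale_axes": "z",
        },
    },
}


def preset_config(name: str, seed: int = 0, **overrides) -> SimulationConfig:
    """Build a :class:`SimulationConfig` for a named preset.

    ``overrides`` are applied on top of the preset's parameters, e.g.
    ``preset_config("native", seed=3, volume_shape=(128, 128, 80))``.
    """
    if name not in PRESETS:
        raise KeyError(f"unknown preset {name!r}; choose from {sorted(PRESETS)}")
    params: dict = {"seed": seed, **PRESETS[name], **overrides}
    return SimulationConfig(**params)


def sham_twin(config: SimulationConfig) -> SimulationConfig:
    """The matched healthy control of a necrotic config.

    Same geometry, texture and noise streams (same seed), necrosis
    disabled — AF and bSHG come out bit-identical to the necrotic twin,
    only fSHG differs inside the (removed) lesion.
    """
    return config.replace(necrosis_mask_spec=None)
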