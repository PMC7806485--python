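"""Channel-intensity ratios, tile-wise necrosis mapping, group statistics.

Necrotic myofibers lose their fSHG signal almost completely while keeping
most of their autofluorescence and their collagen-borne bSHG, so the
fSHG:AF ratio collapses locally in necrotic tissue and the bSHG:AF ratio
does not. This module quantifies that contrast three ways:

* per-slice mean-intensity ratios (fSHG:AF, bSHG:AF, bSHG:fSHG, and
  total SHG over AF), the unit of the group statistics;
* a tile grid over each slice labelling tiles necrotic / intact /
  background from their fSHG:AF ratio, yielding a 3D necrotic volume
  fraction and a voxel-resolved lesion map;
* nonparametric group comparisons (two-sided Mann–Whitney U on slice
  ratios) and one-way ANOVA with Tukey HSD for sarcomere-length groups.

Normalising the SHG channels to AF per slice cancels slice-to-slice
intensity fluctuations (laser power, residual attenuation), which is why
ratios rather than raw means carry the necrosis statistics.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from skimage.filters import threshold_otsu
from statsmodels.stats.multicomp import pairwise_tukeyhsd

from .stack_io import MultiphotonStack
from .sarcomere import StackSarcomereResult

logger = logging.getLogger(__name__)

__all__ = [
    "RATIO_NAMES",
    "RatioTable",
    "GroupComparison",
    "NecrosisReport",
    "SarcomereGroupComparison",
    "compute_channel_ratios",
    "map_necrosis_tiles",
    "tile_labels_to_mask",
    "median_tile_ratio",
    "compare_ratio_groups",
    "compare_sarcomere_groups",
]

RATIO_NAMES = ("fshg_af", "bshg_af", "bshg_fshg", "totalshg_af")

TILE_BACKGROUND, TILE_INTACT, TILE_NECROTIC = 0, 1, 2


@dataclass
class RatioTable:
    """Per-slice channel means and ratios for one stack / group.

    ``table`` columns: slice, mean_af, mean_bshg, mean_fshg and the four
    ratios. Ratios with a nonpositive denominator are NaN (undefined) and
    excluded from statistics; their count is reported, never imputed.
    """

    table: pd.DataFrame
    group: str = ""

    def ratio(self, name: str) -> np.ndarray:
        if name not in RATIO_NAMES:
            raise KeyError(f"unknown ratio {name!r}; choose from {RATIO_NAMES}")
        return self.table[name].to_numpy(float)

    def defined(self, name: str) -> np.ndarray:
        """Ratio values with undefined (NaN) entries dropped."""
        vals = self.ratio(name)
        return vals[np.isfinite(vals)]

    def n_undefined(self, name: str) -> int:
        return int(np.count_nonzero(~np.isfinite(self.ratio(name))))


def compute_channel_ratios(
    stack: MultiphotonStack, mask: np.ndarray | None = None, group: str = ""
) -> RatioTable:
    """Per-slice mean pixel intensities and the four intensity ratios.

    With a tissue mask, slice means run over masked voxels only (the
    default analysis); without one they are whole-frame means.
    """
    nz, ny, nx = stack.spatial_shape
    if mask is not None:
        mask = np.asarray(mask, dtype=bool)
        if mask.shape != (nz, ny, nx):
            raise ValueError(f"mask shape {mask.shape} does not match stack {(nz, ny, nx)}")
        counts = mask.sum(axis=(1, 2)).astype(float)

        def slice_means(vol):
            sums = np.where(mask, vol, 0.0).sum(axis=(1, 2))
            return np.where(counts > 0, sums / np.where(counts > 0, counts, 1.0), np.nan)

    else:

        def slice_means(vol):
            return vol.mean(axis=(1, 2))

    af = slice_means(stack.channel("AF"))
    bshg = slice_means(stack.channel("bSHG"))
    fshg = slice_means(stack.channel("fSHG"))

    def safe_div(num, den):
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(den > 0, num / np.where(den > 0, den, 1.0), np.nan)

    df = pd.DataFrame(
        {
            "slice": np.arange(nz),
            "mean_af": af,
            "mean_bshg": bshg,
            "mean_fshg": fshg,
            "fshg_af": safe_div(fshg, af),
            "bshg_af": safe_div(bshg, af),
            "bshg_fshg": safe_div(bshg, fshg),
            "totalshg_af": safe_div(fshg + bshg, af),
        }
    )
    return RatioTable(df, group)


# ---------------------------------------------------------------------------
# Tile-wise necrosis mapping
# ---------------------------------------------------------------------------

@dataclass
class NecrosisReport:
    """Tile-grid necrosis map and its summary.

    ``tile_labels`` is ``(nz, n_tiles_y, n_tiles_x)`` int8 with values
    background (0) / intact (1) / necrotic (2); the label classes
    partition the grid. ``necrotic_fraction`` is the necrotic share of
    tissue (non-background) tiles across the whole volume.
    """

    tile_labels: np.ndarray
    tile_ratio: np.ndarray  # fSHG:AF per tile; NaN where undefined
    tile_size_px: tuple[int, int]
    tile_edges_y: np.ndarray
    tile_edges_x: np.ndarray
    threshold: float
    threshold_rule: str
    necrotic_fraction: float
    n_necrotic: int
    n_intact: int
    n_background: int

    def summary(self) -> dict:
        return {
            "necrotic_fraction": self.necrotic_fraction,
            "threshold": self.threshold,
            "threshold_rule": self.threshold_rule,
            "n_necrotic_tiles": self.n_necrotic,
            "n_intact_tiles": self.n_intact,
            "n_background_tiles": self.n_background,
            "tile_size_px": list(self.tile_size_px),
        }


def _tile_edges(n: int, t: int) -> np.ndarray:
    """Tile start offsets covering [0, n); the last tile absorbs the remainder."""
    edges = np.arange(0, n - n % t, t)
    if edges.size == 0:
        edges = np.array([0])
    return edges


def _tile_sums(plane: np.ndarray, ey: np.ndarray, ex: np.ndarray) -> np.ndarray:
    """Sum a 2D plane over the rectangular tiles defined by edge offsets."""
    return np.add.reduceat(np.add.reduceat(plane, ey, axis=0), ex, axis=1)


def map_necrosis_tiles(
    stack: MultiphotonStack,
    tile_size_um: float = 25.0,
    threshold_rule: str = "otsu",
    mask: np.ndarray | None = None,
    reference_median: float | None = None,
    min_tile_tissue_fraction: float = 0.5,
) -> NecrosisReport:
    """Label a per-slice tile grid necrotic / intact / background.

    Each slice is divided into ``tile_size_um`` × ``tile_size_um``
    in-plane tiles (default 25 µm ≈ half a fiber diameter, fine enough to
    resolve a necrosis demarcation line running between two myofibers).
    A tile is background when its tissue fraction (from ``mask``, or an
    AF-Otsu mask computed here) falls below
    ``min_tile_tissue_fraction``; the rest are labelled necrotic when
    their tissue-restricted mean-fSHG : mean-AF ratio falls below the
    threshold.

    ``threshold_rule``:

    * ``"otsu"`` — Otsu on the histogram of defined tile ratios (needs a
      bimodal mix of necrotic and intact tiles);
    * ``"fixed:V"`` — explicit ratio threshold ``V``;
    * ``"reference"`` — half the median tile ratio of a healthy reference
      (pass ``reference_median``, e.g. from :func:`median_tile_ratio` on
      a sham stack); the rule of choice for possibly-homogeneous stacks.
    """
    nz, ny, nx = stack.spatial_shape
    tpx_x = max(int(round(tile_size_um / stack.dx)), 1)
    tpx_y = max(int(round(tile_size_um / stack.dy)), 1)
    if tpx_x < 4 or tpx_y < 4:
        raise ValueError(
            f"tile size {tile_size_um} µm is under 4 in-plane voxels at "
            f"{stack.dx}×{stack.dy} µm pixels"
        )
    if mask is None:
        from .depth import estimate_tissue_mask

        mask, _ = estimate_tissue_mask(stack)
    else:
        mask = np.asarray(mask, dtype=bool)
        if mask.shape != (nz, ny, nx):
            raise ValueError("mask shape mismatch")

    ey = _tile_edges(ny, tpx_y)
    ex = _tile_edges(nx, tpx_x)
    nty, ntx = ey.size, ex.size
    # per-tile voxel counts (uniform except the remainder-absorbing last tiles)
    ones = np.ones((ny, nx))
    tile_area = _tile_sums(ones, ey, ex)

    af = stack.channel("AF")
    fshg = stack.channel("fSHG")
    labels = np.zeros((nz, nty, ntx), dtype=np.int8)
    ratio = np.full((nz, nty, ntx), np.nan)
    for k in range(nz):
        m = mask[k].astype(np.float64)
        tissue_count = _tile_sums(m, ey, ex)
        tissue_frac = tissue_count / tile_area
        af_sum = _tile_sums(np.where(mask[k], af[k], 0.0), ey, ex)
        fshg_sum = _tile_sums(np.where(mask[k], fshg[k], 0.0), ey, ex)
        with np.errstate(invalid="ignore", divide="ignore"):
            r = np.where(af_sum > 0, fshg_sum / np.where(af_sum > 0, af_sum, 1.0), np.nan)
        fg = (tissue_frac >= min_tile_tissue_fraction) & np.isfinite(r)
        ratio[k] = np.where(fg, r, np.nan)
        labels[k] = np.where(fg, TILE_INTACT, TILE_BACKGROUND)

    defined = ratio[np.isfinite(ratio)]
    if defined.size == 0:
        raise ValueError("no tissue: every tile is background")

    if threshold_rule == "otsu":
        if defined.min() == defined.max():
            threshold = defined.min() - 1.0  # homogeneous ratios: nothing necrotic
        else:
            threshold = float(threshold_otsu(defined))
    elif threshold_rule.startswith("fixed:"):
        threshold = float(threshold_rule.split(":", 1)[1])
    elif threshold_rule == "reference":
        if reference_median is None:
            raise ValueError("threshold_rule 'reference' requires reference_median")
        threshold = 0.5 * float(reference_median)
    else:
        raise ValueError(f"unknown threshold_rule {threshold_rule!r}")

    necrotic = (labels == TILE_INTACT) & np.isfinite(ratio) & (ratio < threshold)
    labels[necrotic] = TILE_NECROTIC
    n_nec = int(np.count_nonzero(labels == TILE_NECROTIC))
    n_int = int(np.count_nonzero(labels == TILE_INTACT))
    n_bg = int(np.count_nonzero(labels == TILE_BACKGROUND))
    frac = n_nec / (n_nec + n_int) if (n_nec + n_int) else 0.0
    return NecrosisReport(
        tile_labels=labels,
        tile_ratio=ratio,
        tile_size_px=(tpx_y, tpx_x),
        tile_edges_y=ey,
        tile_edges_x=ex,
        threshold=threshold,
        threshold_rule=threshold_rule,
        necrotic_fraction=float(frac),
        n_necrotic=n_nec,
        n_intact=n_int,
        n_background=n_bg,
    )


def median_tile_ratio(
    stack: MultiphotonStack,
    tile_size_um: float = 25.0,
    mask: np.ndarray | None = None,
    min_tile_tissue_fraction: float = 0.5,
) -> float:
    """Median defined tile fSHG:AF ratio of a (healthy reference) stack."""
    report = map_necrosis_tiles(
        stack,
        tile_size_um=tile_size_um,
        threshold_rule="fixed:-1",  # label nothing necrotic
        mask=mask,
        min_tile_tissue_fraction=min_tile_tissue_fraction,
    )
    return float(np.nanmedian(report.tile_ratio))


def tile_labels_to_mask(report: NecrosisReport, spatial_shape: tuple[int, int, int]) -> np.ndarray:
    """Expand the necrotic tile labels to a voxel-resolution boolean mask."""
    nz, ny, nx = spatial_shape
    out = np.zeros((nz, ny, nx), dtype=bool)
    ey = np.append(report.tile_edges_y, ny)
    ex = np.append(report.tile_edges_x, nx)
    nec = report.tile_labels == TILE_NECROTIC
    for ty in range(report.tile_labels.shape[1]):
        for tx in range(report.tile_labels.shape[2]):
            ks = nec[:, ty, tx]
            if ks.any():
                out[ks, ey[ty] : ey[ty + 1], ex[tx] : ex[tx + 1]] = True
    return out


# ---------------------------------------------------------------------------
# Group statistics
# ---------------------------------------------------------------------------

@dataclass
class GroupComparison:
    """Two-sided Mann–Whitney U comparison of one ratio between groups."""

    ratio_name: str
    group_a: str
    group_b: str
    statistic: float
    p_value: float
    median_a: float
    median_b: float
    n_a: int
    n_b: int
    test_name: str = "mann-whitney-u (two-sided)"

    def to_dict(self) -> dict:
        return dict(self.__dict__)


def compare_ratio_groups(
    table_a: RatioTable, table_b: RatioTable, ratio_name: str
) -> GroupComparison:
    """Two-sided Mann–Whitney U on per-slice ratios of two groups.

    Undefined (NaN) ratios are dropped first; each group needs at least
    10 defined slices. The test identity is recorded in the result so the
    statistical choice stays auditable.
    """
    a = table_a.defined(ratio_name)
    b = table_b.defined(ratio_name)
    if a.size < 10 or b.size < 10:
        raise ValueError(
            f"need >= 10 defined slices per group; got {a.size} and {b.size}"
        )
    res = stats.mannwhitneyu(a, b, alternative="two-sided")
    return GroupComparison(
        ratio_name=ratio_name,
        group_a=table_a.group,
        group_b=table_b.group,
        statistic=float(res.statistic),
        p_value=float(res.pvalue),
        median_a=float(np.median(a)),
        median_b=float(np.median(b)),
        n_a=int(a.size),
        n_b=int(b.size),
    )


@dataclass
class SarcomereGroupComparison:
    """One-way ANOVA plus Tukey HSD across sarcomere-length groups."""

    anova_f: float
    anova_p: float
    tukey: pd.DataFrame  # columns: group1, group2, meandiff, p_adj, reject
    group_sizes: dict = field(default_factory=dict)

    @property
    def any_pair_significant(self) -> bool:
        return bool(self.tukey["reject"].any())


def _extract_sl_values(values) -> np.ndarray:
    if isinstance(values, StackSarcomereResult):
        values = [e.sarcomere_length_um for e in values.estimates if e.valid]
    arr = np.asarray(list(values), dtype=float)
    return arr[np.isfinite(arr)]


def compare_sarcomere_groups(groups: dict, alpha: float = 0.05) -> SarcomereGroupComparison:
    """ANOVA + Tukey HSD over per-slice sarcomere lengths by group.

    ``groups`` maps group label → sequence of valid SL values (µm) or a
    :class:`~shgmorph.sarcomere.StackSarcomereResult`. Groups with no
    valid estimate are dropped with a warning; at least 2 groups with
    >= 3 valid estimates each are required.
    """
    cleaned: dict[str, np.ndarray] = {}
    for name, values in groups.items():
        arr = _extract_sl_values(values)
        if arr.size == 0:
            logger.warning("compare_sarcomere_groups: dropping group %r (no valid estimates)", name)
            continue
        cleaned[name] = arr
    if len(cleaned) < 2:
        raise ValueError("need >= 2 groups with valid estimates")
    if any(v.size < 3 for v in cleaned.values()):
        small = {k: int(v.size) for k, v in cleaned.items() if v.size < 3}
        raise ValueError(f"each group needs >= 3 valid estimates; too small: {small}")

    f_stat, p = stats.f_oneway(*cleaned.values())
    values = np.concatenate(list(cleaned.values()))
    labels = np.concatenate([[name] * v.size for name, v in cleaned.items()])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # zero-variance groups
        tk = pairwise_tukeyhsd(values, labels, alpha=alpha)
    tukey = pd.DataFrame(
        tk.summary().data[1:],
        columns=[str(c) for c in tk.summary().data[0]],
    ).rename(columns={"p-adj": "p_adj"})
    tukey["reject"] = tukey["reject"].astype(bool)
    return SarcomereGroupComparison(
        anova_f=float(f_stat),
        anova_p=float(p),
        tukey=tukey,
        group_sizes={k: int(v.size) for k, v in cleaned.items()},
    )
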