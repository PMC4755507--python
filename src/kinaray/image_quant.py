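"""Grid alignment, spot quantification and quality control for array scans.

The quantification model is deliberately simple, matching how spotted
peptide arrays are read out in practice:

* a single rigid integer (dx, dy) grid offset, found by normalized
  cross-correlation of the expected spot-profile template against the
  image over a bounded search window;
* per spot, the raw statistic is the mean pixel value in a disk of the
  nominal radius, and the local background is the median of a surrounding
  annulus (median resists bleed-over from neighboring spots);
* net = raw - background; log2_net exists only for positive nets
  (nonpositive nets become missing values downstream, no pseudo-counts);
* unreliable spots are flagged by segmenting the spot above local
  background and testing eccentricity, area and centroid displacement.

Pixel coordinates are 0-based with (x, y) = (column, row).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from functools import lru_cache
from pathlib import Path

import numpy as np
import pandas as pd
from skimage.measure import label, regionprops

from kinaray.layout import ArrayLayout

UINT16_MAX = 65535

#: half-max radius of a Gaussian spot with sigma = radius/2, as a fraction
#: of the nominal radius: sqrt(2 ln 2) / 2
HALF_MAX_RADIUS_FRAC = 0.5887


class AlignmentError(ValueError):
    """Grid alignment cannot be computed (e.g. flat or empty image)."""


class AlignmentBoundaryWarning(UserWarning):
    """Best alignment sits on the search-window boundary."""


@dataclass(frozen=True)
class GridAlignment:
    dx: int
    dy: int
    score: float
    boundary: bool = False

    @property
    def offset(self):
        return (self.dx, self.dy)


@dataclass(frozen=True)
class SpotQuant:
    """One quantified spot."""

    substrate_id: str
    raw_mean: float
    local_background: float
    net: float
    log2_net: float | None
    flags: frozenset = field(default_factory=frozenset)

    @property
    def usable(self) -> bool:
        return not self.flags


@dataclass(frozen=True)
class IrregularityThresholds:
    """Cutoffs for declaring a spot unreliable.

    The assay itself defines no numeric criteria, so these are
    configurable conventions: a segmented region is irregular in shape
    when its eccentricity exceeds ``eccentricity`` or its area deviates
    from the nominal segmented disk area by more than ``area_dev``
    (fractional); it is displaced when its centroid lies more than
    ``displacement_frac`` nominal radii from the expected center.
    """

    eccentricity: float = 0.8
    area_dev: float = 0.5
    displacement_frac: float = 0.5
    seg_frac: float = 0.5
    min_signal: float = 8.0


@lru_cache(maxsize=32)
def _disk_offsets(radius: float):
    r = int(np.ceil(radius))
    y, x = np.mgrid[-r:r + 1, -r:r + 1]
    m = x ** 2 + y ** 2 <= radius ** 2
    return x[m], y[m]


@lru_cache(maxsize=32)
def _annulus_offsets(inner: float, outer: float):
    r = int(np.ceil(outer))
    y, x = np.mgrid[-r:r + 1, -r:r + 1]
    d2 = x ** 2 + y ** 2
    m = (d2 > inner ** 2) & (d2 <= outer ** 2)
    return x[m], y[m]


def align_grid(image, layout: ArrayLayout, search_radius_px: int = 10):
    """Find the rigid integer grid offset by normalized cross-correlation.

    For every candidate (dx, dy) in the square search window, the Pearson
    correlation between the image values under the shifted spot disks and
    the expected Gaussian spot profile is computed; the maximizing offset
    is returned.  Ties are broken by smallest Euclidean offset, then
    row-major (dy, dx) order.

    A best match on the window boundary raises
    :class:`AlignmentBoundaryWarning` (the true offset may lie outside the
    window); a flat image raises :class:`AlignmentError`.
    """
    image = np.asarray(image, dtype=float)
    r = layout.spot_radius_px
    ox, oy = _disk_offsets(r)
    sigma = 0.5 * r
    w = np.exp(-(ox ** 2 + oy ** 2) / (2.0 * sigma ** 2))
    wc = w - w.mean()
    wnorm = np.sqrt((wc ** 2).sum())

    xs, ys = [], []
    for _, _, (cx, cy) in layout.iter_centers():
        xs.append(cx + ox)
        ys.append(cy + oy)
    xs = np.concatenate(xs)
    ys = np.concatenate(ys)
    wall = np.tile(wc, layout.n_spots)
    wallnorm = np.sqrt(layout.n_spots) * wnorm

    R = int(search_radius_px)
    lo_x, hi_x = xs.min() - R, xs.max() + R
    lo_y, hi_y = ys.min() - R, ys.max() + R
    if lo_x < 0 or lo_y < 0 or hi_x >= image.shape[1] or hi_y >= image.shape[0]:
        raise ValueError("image does not accommodate layout plus search radius")

    candidates = [(dx, dy) for dy in range(-R, R + 1) for dx in range(-R, R + 1)]
    candidates.sort(key=lambda o: (o[0] ** 2 + o[1] ** 2, o[1], o[0]))

    best = None
    best_score = -np.inf
    for dx, dy in candidates:
        vals = image[ys + dy, xs + dx]
        vc = vals - vals.mean()
        denom = np.sqrt((vc ** 2).sum()) * wallnorm
        if denom == 0.0:
            continue
        score = float((vc * wall).sum() / denom)
        if score > best_score:
            best_score = score
            best = (dx, dy)
    if best is None:
        raise AlignmentError("flat or empty image: no correlation signal")

    boundary = abs(best[0]) == R or abs(best[1]) == R
    if boundary:
        warnings.warn(
            f"best grid offset {best} lies on the search-window boundary; "
            "the true offset may be out of range",
            AlignmentBoundaryWarning,
        )
    return GridAlignment(dx=best[0], dy=best[1], score=best_score,
                         boundary=boundary)


def quantify_spot(image, center, radius_px, annulus=None,
                  substrate_id: str = "", saturation: int = UINT16_MAX):
    """Quantify one spot: disk mean, annulus-median background, net, log2.

    ``annulus`` gives the background annulus (inner, outer) radii in
    pixels; default (1.5, 2.5) x the spot radius.  The saturated flag is
    set when any disk pixel reaches the bit-depth maximum.
    """
    image = np.asarray(image)
    cx, cy = int(center[0]), int(center[1])
    if annulus is None:
        annulus = (1.5 * radius_px, 2.5 * radius_px)
    inner, outer = annulus
    if inner <= radius_px:
        raise ValueError("annulus inner radius must exceed the spot radius")
    r_out = int(np.ceil(outer))
    if (cx - r_out < 0 or cy - r_out < 0
            or cx + r_out >= image.shape[1] or cy + r_out >= image.shape[0]):
        raise ValueError(f"background annulus at ({cx}, {cy}) falls outside image")

    ox, oy = _disk_offsets(radius_px)
    disk = image[cy + oy, cx + ox].astype(float)
    ax, ay = _annulus_offsets(inner, outer)
    bg = float(np.median(image[cy + ay, cx + ax].astype(float)))

    raw = float(disk.mean())
    net = raw - bg
    flags = set()
    if (disk >= saturation).any():
        flags.add("saturated")
    if net > 0:
        log2_net = float(np.log2(net))
    else:
        log2_net = None
        flags.add("nonpositive_net")
    return SpotQuant(substrate_id=substrate_id, raw_mean=raw,
                     local_background=bg, net=net, log2_net=log2_net,
                     flags=frozenset(flags))


def flag_irregular(image, center, radius_px,
                   thresholds: IrregularityThresholds | None = None):
    """Segment the spot above local background and flag shape/position.

    Returns a frozenset drawn from {irregular_shape, displaced,
    nonpositive_net}; empty for a regular spot.  The segmented region is
    the largest connected component above ``bg + seg_frac * (peak - bg)``
    within a window of twice the nominal radius.
    """
    th = thresholds or IrregularityThresholds()
    image = np.asarray(image, dtype=float)
    cx, cy = int(center[0]), int(center[1])
    half = int(np.ceil(2 * radius_px))
    y0, y1 = cy - half, cy + half + 1
    x0, x1 = cx - half, cx + half + 1
    if y0 < 0 or x0 < 0 or y1 > image.shape[0] or x1 > image.shape[1]:
        raise ValueError("spot window falls outside image")
    win = image[y0:y1, x0:x1]

    ax, ay = _annulus_offsets(1.5 * radius_px, 2.5 * radius_px)
    in_img = ((cy + ay >= 0) & (cy + ay < image.shape[0])
              & (cx + ax >= 0) & (cx + ax < image.shape[1]))
    bg = float(np.median(image[cy + ay[in_img], cx + ax[in_img]]))

    peak = float(win.max())
    if peak - bg < th.min_signal:
        return frozenset({"nonpositive_net"})
    mask = win >= bg + th.seg_frac * (peak - bg)
    lab = label(mask, connectivity=2)
    props = regionprops(lab)
    region = max(props, key=lambda p: p.area)

    flags = set()
    nominal_area = np.pi * (HALF_MAX_RADIUS_FRAC * radius_px) ** 2
    if region.eccentricity > th.eccentricity:
        flags.add("irregular_shape")
    if abs(region.area - nominal_area) / nominal_area > th.area_dev:
        flags.add("irregular_shape")
    crow, ccol = region.centroid
    disp = np.hypot(crow - half, ccol - half)
    if disp > th.displacement_frac * radius_px:
        flags.add("displaced")
    return frozenset(flags)


def quantify_array(image, layout: ArrayLayout, offset=(0, 0),
                   thresholds: IrregularityThresholds | None = None,
                   annulus=None, saturation: int = UINT16_MAX) -> pd.DataFrame:
    """Quantify every layout position; one row per spot.

    ``offset`` is the (dx, dy) grid offset, typically from
    :func:`align_grid`.  The returned GPR-like table has columns block,
    row, col, substrate_id, x, y, raw_mean, background, net, log2_net and
    a comma-joined flags string (empty when the spot is usable).
    """
    records = []
    for blk, row, col, sid in layout.positions:
        cx, cy = layout.spot_center(blk, row, col, offset)
        q = quantify_spot(image, (cx, cy), layout.spot_radius_px,
                          annulus=annulus, substrate_id=sid,
                          saturation=saturation)
        flags = set(q.flags) | set(
            flag_irregular(image, (cx, cy), layout.spot_radius_px, thresholds)
        )
        records.append({
            "block": blk, "row": row, "col": col, "substrate_id": sid,
            "x": cx, "y": cy, "raw_mean": q.raw_mean,
            "background": q.local_background, "net": q.net,
            "log2_net": np.nan if q.log2_net is None else q.log2_net,
            "flags": ",".join(sorted(flags)),
        })
    return pd.DataFrame(records)


def validate_controls(quant_tables: dict, control_ids,
                      tolerance: float = 1.0) -> pd.DataFrame:
    """Compare control-spot levels between slides.

    Computes each slide's mean log2 net intensity over unflagged control
    spots and flags slides deviating from the across-slide median by
    strictly more than ``tolerance`` log2 units.
    """
    control_ids = set(control_ids)
    if not control_ids:
        raise ValueError("no control spots designated")
    rows = []
    for slide, qt in quant_tables.items():
        ctl = qt[qt["substrate_id"].isin(control_ids) & (qt["flags"] == "")]
        if ctl.empty:
            raise ValueError(f"slide {slide} has no usable control spots")
        rows.append({"slide_id": slide,
                     "control_mean_log2": float(ctl["log2_net"].mean()),
                     "n_controls": int(len(ctl))})
    report = pd.DataFrame(rows)
    center = report["control_mean_log2"].median()
    report["deviation"] = report["control_mean_log2"] - center
    report["flagged"] = report["deviation"].abs() > tolerance
    return report


def write_quant_table(table: pd.DataFrame, path, slide_id: str = "") -> None:
    path = Path(path)
    with path.open("w") as fh:
        fh.write(f"# kinaray quantification\n# slide_id\t{slide_id}\n")
        table.to_csv(fh, sep="\t", index=False, na_rep="NA",
                     float_format="%.6f")


def read_quant_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", comment="#", na_values=["NA"])
    df["flags"] = df["flags"].fillna("").astype(str)
    return df
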