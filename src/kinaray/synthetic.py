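"""Synthetic kinome-array experiments with known ground truth.

Generates the three layers a real experiment would provide, so that every
downstream stage can be tested without raw scans:

1. a per-substrate *truth* (baselines, time-course offsets, a planted
   cell-type effect for a chosen fraction of substrates, replicate
   offsets),
2. a log2 intensity matrix following the additive model the analysis
   assumes (value = baseline + time offset + cell-type effect + replicate
   offset + Gaussian noise, with MCAR missingness), and
3. rendered 16-bit grayscale array scans: Gaussian-profile spots on a
   sloped background, with a configurable fraction of spots drawn
   elongated or displaced to exercise the quality-control stage, and a
   known global grid offset to exercise alignment.

Effects live on the log2 scale; rendering exponentiates to linear scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from kinaray.layout import ArrayLayout
from kinaray.preprocess import IntensityMatrix

UINT16_MAX = 65535

#: Gaussian spot scale as a fraction of the nominal spot radius
SPOT_SIGMA_FACTOR = 0.5
#: kernel truncation radius as a multiple of the nominal radius
SPOT_TRUNCATE_FACTOR = 2.0
#: major/minor axis ratio used for elongated (irregular) spots
ELONGATION_RATIO = 3.0


@dataclass(frozen=True)
class SimulationDesign:
    """Parameters of a simulated kinome-array experiment.

    Defaults mirror the profiled study design: two cell types (regulatory
    and effector CD4+ T cells), four stimulation time points (0, 5, 15,
    60 min), three technical replicates per array, and a per-value
    missingness rate chosen so that roughly 850 of 1024 substrates survive
    the replicate-exclusion rule.
    """

    n_substrates: int = 1024
    cell_types: tuple = ("Treg", "Teff")
    time_points_min: tuple = (0, 5, 15, 60)
    n_tech_reps: int = 3
    effect_fraction: float = 0.1
    effect_size_log2: float = 1.0
    rep_effect_sd: float = 0.1
    noise_sd: float = 0.3
    missing_rate: float = 0.09
    seed: int = 0
    # variance structure (convention; the assay defines none)
    baseline_log2_mean: float = 10.0
    baseline_log2_sd: float = 1.0
    time_effect_sd: float = 0.3

    def __post_init__(self):
        if self.n_substrates < 1 or self.n_tech_reps < 1:
            raise ValueError("counts must be >= 1")
        if len(self.cell_types) < 1 or len(self.time_points_min) < 1:
            raise ValueError("need at least one cell type and time point")
        if not 0.0 <= self.effect_fraction <= 1.0:
            raise ValueError("effect_fraction must be in [0, 1]")
        if not 0.0 <= self.missing_rate < 1.0:
            raise ValueError("missing_rate must be in [0, 1)")
        for name in ("rep_effect_sd", "noise_sd", "baseline_log2_sd", "time_effect_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        tp = list(self.time_points_min)
        if len(set(tp)) != len(tp) or sorted(tp) != tp or tp[0] < 0:
            raise ValueError("time points must be distinct, nonnegative, ascending")
        object.__setattr__(self, "cell_types", tuple(self.cell_types))
        object.__setattr__(self, "time_points_min", tuple(self.time_points_min))

    @property
    def effect_cell_type(self) -> str:
        """Cell type carrying the planted effect (first listed, Treg by default)."""
        return self.cell_types[0]

    def to_dict(self) -> dict:
        d = asdict(self)
        d["cell_types"] = list(self.cell_types)
        d["time_points_min"] = list(self.time_points_min)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationDesign":
        d = dict(d)
        for key in ("cell_types", "time_points_min"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)


@dataclass(frozen=True)
class SyntheticTruth:
    """Ground-truth per-substrate parameters of a simulated experiment."""

    substrate_ids: tuple
    baseline: np.ndarray          # (n,) log2 baseline
    time_offsets: np.ndarray      # (n, n_times); first (reference) column is 0
    cell_effect: np.ndarray       # (n,) log2 effect on the effect cell type
    rep_offsets: np.ndarray       # (n, n_reps); first (reference) column is 0
    is_differential: np.ndarray   # (n,) bool

    @property
    def n_substrates(self) -> int:
        return len(self.substrate_ids)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({"substrate_id": self.substrate_ids,
                           "baseline": self.baseline,
                           "cell_effect": self.cell_effect,
                           "is_differential": self.is_differential})
        for j in range(self.time_offsets.shape[1]):
            df[f"time_offset_{j}"] = self.time_offsets[:, j]
        for j in range(self.rep_offsets.shape[1]):
            df[f"rep_offset_{j}"] = self.rep_offsets[:, j]
        return df


def simulate_truth(design: SimulationDesign) -> SyntheticTruth:
    """Draw per-substrate ground-truth parameters.

    Exactly ``round(effect_fraction * n_substrates)`` substrates receive a
    cell-type effect of magnitude ``effect_size_log2`` (random sign); all
    others have a cell-type effect of exactly zero.  Deterministic given
    ``design.seed``.
    """
    rng = np.random.default_rng(design.seed)
    n = design.n_substrates
    n_times = len(design.time_points_min)
    n_reps = design.n_tech_reps

    baseline = rng.normal(design.baseline_log2_mean, design.baseline_log2_sd, n)
    time_offsets = np.zeros((n, n_times))
    if n_times > 1:
        time_offsets[:, 1:] = rng.normal(0.0, design.time_effect_sd, (n, n_times - 1))
    rep_offsets = np.zeros((n, n_reps))
    if n_reps > 1:
        rep_offsets[:, 1:] = rng.normal(0.0, design.rep_effect_sd, (n, n_reps - 1))

    n_diff = int(round(design.effect_fraction * n))
    diff_idx = rng.choice(n, size=n_diff, replace=False)
    cell_effect = np.zeros(n)
    cell_effect[diff_idx] = design.effect_size_log2 * rng.choice([-1.0, 1.0], n_diff)
    is_differential = np.zeros(n, dtype=bool)
    is_differential[diff_idx] = True

    ids = tuple(f"SUB{i + 1:04d}" for i in range(n))
    return SyntheticTruth(ids, baseline, time_offsets, cell_effect,
                          rep_offsets, is_differential)


def simulate_intensity_matrix(
    truth: SyntheticTruth, design: SimulationDesign
) -> IntensityMatrix:
    """Simulate the substrates x samples log2 intensity matrix.

    Each value is ``baseline + time offset + cell-type effect (effect cell
    type only) + replicate offset + N(0, noise_sd)``; values are then
    masked missing independently with probability ``missing_rate``.
    Sample metadata carries cell type, time, replicate, and a slide id of
    the form ``<cell>_t<time>`` (one slide per condition, all replicates
    on it).
    """
    if truth.n_substrates != design.n_substrates:
        raise ValueError("truth does not match design")
    rng = np.random.default_rng(np.random.SeedSequence([design.seed, 1]))
    n = truth.n_substrates

    sample_rows = []
    columns = {}
    for cell in design.cell_types:
        for t_idx, t in enumerate(design.time_points_min):
            for rep in range(1, design.n_tech_reps + 1):
                sid = f"{cell}_t{t}_r{rep}"
                sample_rows.append({
                    "sample_id": sid, "cell_type": cell, "time_min": t,
                    "replicate": rep, "slide_id": f"{cell}_t{t}",
                })
                mean = (truth.baseline
                        + truth.time_offsets[:, t_idx]
                        + truth.rep_offsets[:, rep - 1])
                if cell == design.effect_cell_type:
                    mean = mean + truth.cell_effect
                vals = mean + (rng.normal(0.0, design.noise_sd, n)
                               if design.noise_sd > 0 else 0.0)
                columns[sid] = vals

    values = pd.DataFrame(columns, index=list(truth.substrate_ids))
    values.index.name = "substrate_id"
    if design.missing_rate > 0:
        mask = rng.random(values.shape) < design.missing_rate
        values = values.mask(mask)
    samples = pd.DataFrame(sample_rows)
    return IntensityMatrix(values=values, samples=samples)


# ---------------------------------------------------------------------------
# image rendering


@dataclass(frozen=True)
class ImageRenderSpec:
    """Parameters for rendering a slide scan from per-spot amplitudes.

    Grid geometry (rows, columns, pitch, radius) comes from the
    :class:`~kinaray.layout.ArrayLayout` passed alongside; this spec holds
    the photometric and nuisance parameters.

    ``background_level`` and ``background_gradient`` define a sloped
    background field ``level + gx*x + gy*y`` (16-bit counts).
    ``irregular_fraction`` of spots are independently rendered either
    elongated (axis ratio 3) or displaced by 0.75-1.0 nominal radii.
    ``grid_offset_px`` plants a rigid (dx, dy) grid shift; ``None`` draws
    one uniformly from [-5, 5]^2.
    """

    background_level: float = 500.0
    background_gradient: tuple = (0.02, 0.01)
    irregular_fraction: float = 0.08
    saturation_ceiling: int = UINT16_MAX
    amplitude_scale: float = 1.0
    grid_offset_px: tuple | None = None
    seed: int = 0

    def __post_init__(self):
        if not 0.0 <= self.irregular_fraction <= 1.0:
            raise ValueError("irregular_fraction must be in [0, 1]")
        if self.saturation_ceiling < 1:
            raise ValueError("saturation_ceiling must be >= 1")


@dataclass(frozen=True)
class RenderTruth:
    """What the renderer actually drew: the oracle for quantification tests."""

    grid_offset: tuple
    spots: pd.DataFrame  # substrate_id, block, row, col, x, y, amplitude,
                         # irregular, mode


def spot_kernel(radius_px: int, sigma: float | None = None,
                ratio: float = 1.0, angle: float = 0.0) -> np.ndarray:
    """Gaussian-profile disk kernel, truncated at twice the nominal radius.

    ``ratio`` > 1 elongates the kernel (volume-preserving anisotropic
    scaling) along ``angle``; the truncation ellipse scales with the axes.
    Peak value is 1.
    """
    sigma = SPOT_SIGMA_FACTOR * radius_px if sigma is None else sigma
    half = int(np.ceil(SPOT_TRUNCATE_FACTOR * radius_px * max(1.0, np.sqrt(ratio)))) + 1
    y, x = np.mgrid[-half:half + 1, -half:half + 1].astype(float)
    c, s = np.cos(angle), np.sin(angle)
    u = c * x + s * y        # major axis coordinate
    v = -s * x + c * y
    s_maj = sigma * np.sqrt(ratio)
    s_min = sigma / np.sqrt(ratio)
    r2 = (u / s_maj) ** 2 + (v / s_min) ** 2
    kern = np.exp(-0.5 * r2)
    trunc = SPOT_TRUNCATE_FACTOR * radius_px / sigma
    kern[r2 > trunc ** 2] = 0.0
    return kern


def disk_mean_fraction(radius_px: float, sigma: float | None = None) -> float:
    """Closed-form mean of the unit-peak Gaussian kernel over the nominal disk.

    For a continuous isotropic Gaussian of scale ``sigma`` the mean over a
    disk of radius ``r`` is ``(2 sigma^2 / r^2) * (1 - exp(-r^2 / 2 sigma^2))``.
    """
    sigma = SPOT_SIGMA_FACTOR * radius_px if sigma is None else sigma
    a = radius_px ** 2 / (2.0 * sigma ** 2)
    return (1.0 - np.exp(-a)) / a


def _pixel_disk_mean(radius_px: int) -> float:
    """Pixel-grid mean of the regular kernel over the quantification disk."""
    kern = spot_kernel(radius_px)
    half = kern.shape[0] // 2
    y, x = np.mgrid[-half:half + 1, -half:half + 1]
    disk = x ** 2 + y ** 2 <= radius_px ** 2
    return float(kern[disk].mean())


def render_array_image(
    values, layout: ArrayLayout, spec: ImageRenderSpec
):
    """Render a 16-bit slide scan from per-spot net amplitudes.

    ``values`` gives one linear-scale amplitude per layout position, in
    layout order; it is the *disk-mean* net intensity the quantification
    stage should recover for a regular spot (the peak is scaled up by the
    kernel's pixel disk-mean so the two agree).  Returns the uint16 image
    and a :class:`RenderTruth` carrying the planted grid offset and
    per-spot amplitudes / irregularity flags.
    """
    values = np.asarray(values, dtype=float) * spec.amplitude_scale
    if values.shape != (layout.n_spots,):
        raise ValueError(
            f"need one value per layout position: got {values.shape[0]}, "
            f"layout has {layout.n_spots}"
        )
    rng = np.random.default_rng(spec.seed)
    offset = spec.grid_offset_px
    if offset is None:
        offset = tuple(int(v) for v in rng.integers(-5, 6, size=2))
    dx, dy = int(offset[0]), int(offset[1])

    shape = layout.image_shape()
    yy = np.arange(shape[0], dtype=float)[:, None]
    xx = np.arange(shape[1], dtype=float)[None, :]
    gx, gy = spec.background_gradient
    img = spec.background_level + gx * xx + gy * yy
    img = np.broadcast_to(img, shape).copy()

    pix_mean = _pixel_disk_mean(layout.spot_radius_px)
    irregular = rng.random(layout.n_spots) < spec.irregular_fraction
    modes = np.where(rng.random(layout.n_spots) < 0.5, "elongated", "displaced")
    modes = np.where(irregular, modes, "regular")

    records = []
    for i, (blk, row, col, sid) in enumerate(layout.positions):
        cx, cy = layout.spot_center(blk, row, col, (dx, dy))
        peak = values[i] / pix_mean
        mode = modes[i]
        scx, scy = cx, cy
        if mode == "elongated":
            kern = spot_kernel(layout.spot_radius_px,
                               ratio=ELONGATION_RATIO,
                               angle=rng.uniform(0, np.pi))
        elif mode == "displaced":
            dist = rng.uniform(0.75, 1.0) * layout.spot_radius_px
            theta = rng.uniform(0, 2 * np.pi)
            scx = int(round(cx + dist * np.cos(theta)))
            scy = int(round(cy + dist * np.sin(theta)))
            kern = spot_kernel(layout.spot_radius_px)
        else:
            kern = spot_kernel(layout.spot_radius_px)
        half = kern.shape[0] // 2
        y0, y1 = scy - half, scy + half + 1
        x0, x1 = scx - half, scx + half + 1
        ky0, kx0 = max(0, -y0), max(0, -x0)
        y0, x0 = max(0, y0), max(0, x0)
        y1, x1 = min(shape[0], y1), min(shape[1], x1)
        img[y0:y1, x0:x1] += peak * kern[ky0:ky0 + (y1 - y0), kx0:kx0 + (x1 - x0)]
        records.append({
            "substrate_id": sid, "block": blk, "row": row, "col": col,
            "x": cx, "y": cy, "amplitude": values[i],
            "irregular": bool(irregular[i]), "mode": mode,
        })

    img = np.clip(np.rint(img), 0, spec.saturation_ceiling).astype(np.uint16)
    truth = RenderTruth(grid_offset=(dx, dy), spots=pd.DataFrame(records))
    return img, truth
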