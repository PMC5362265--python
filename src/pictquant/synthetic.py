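"""Synthetic two-channel PICT fields and kinetic time courses with known ground truth.

The generator emulates the live-cell assay's imaging design: yeast cells with
one or two diffraction-limited RFP anchor spots (spindle pole bodies), a
prey-GFP channel with a diffuse cellular signal, a bright sub-nuclear
(nucleolar) accumulation, a configurable fraction of cells whose prey is
recruited to the anchors, and a strong but smoothly varying background field.
Photon shot noise is Poisson; camera read noise is additive Gaussian.

Seed policy
-----------
Scene geometry (cell placement, anchor positions, recruited flags, nucleolus)
is drawn from ``SceneParams.seed``. Photon noise, read noise and the smooth
background realization are drawn from the call-time ``seed``. Consequently
:func:`expected_score` — a noise-free render of the geometry — is the exact
expectation of the true-mask recruitment score over noise realizations at
fixed ``SceneParams``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import ndimage

__all__ = [
    "SceneParams",
    "FieldImage",
    "GroundTruth",
    "KineticParams",
    "PlacementError",
    "simulate_field",
    "simulate_condition",
    "expected_score",
    "measure_true_score",
    "true_masks",
    "simulate_timecourse",
    "simulate_dilution_series",
    "simulate_ct_table",
    "derive_seed",
    "write_condition",
]

_TWO31 = 2**31


def derive_seed(*keys: int) -> int:
    """Deterministic stream seed from integer keys (stable across runs)."""
    return int(np.random.SeedSequence([int(k) for k in keys]).generate_state(1)[0] % _TWO31)


class PlacementError(ValueError):
    """Raised when cells cannot be placed without overlap in the given frame."""


@dataclass
class SceneParams:
    """Generative parameters for one imaged field.

    Amplitudes are peak photon counts of the corresponding Gaussian component;
    ``background_mean``/``background_sd`` set the level and spatial variation
    of the smooth background shared by both channels, with correlation length
    ``background_smoothness`` (px).
    """

    image_shape: tuple[int, int] = (256, 256)
    pixel_size: float = 0.1  # µm / px
    n_cells: int = 12
    anchors_per_cell: int = 2
    anchor_amplitude: float = 2000.0
    prey_amplitude_at_anchor: float = 300.0
    recruited_fraction: float = 0.5
    nucleolus_amplitude: float = 150.0
    psf_sigma: float = 1.5  # px
    cell_diffuse: float = 30.0  # diffuse prey-GFP level inside cells
    background_mean: float = 100.0
    background_sd: float = 25.0
    background_smoothness: float = 25.0  # px
    read_noise_sigma: float = 5.0
    shot_noise: bool = True
    cell_radius_range: tuple[float, float] = (14.0, 20.0)
    seed: int = 0

    def validate(self) -> None:
        if not (0.0 <= self.recruited_fraction <= 1.0):
            raise ValueError("recruited_fraction must lie in [0, 1]")
        if self.anchors_per_cell not in (1, 2):
            raise ValueError("anchors_per_cell must be 1 or 2")
        if self.psf_sigma <= 0:
            raise ValueError("psf_sigma must be > 0")
        for name in ("anchor_amplitude", "prey_amplitude_at_anchor",
                     "nucleolus_amplitude", "cell_diffuse", "background_mean",
                     "background_sd", "read_noise_sigma"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be > 0")
        if self.n_cells < 0:
            raise ValueError("n_cells must be >= 0")

    @property
    def mask_radius(self) -> int:
        """Radius (px) of the ground-truth anchor footprint disk.

        2.5·sigma is where a diffraction-limited Gaussian spot falls to the
        local-mean threshold level, so the analytic footprint matches the
        extent the segmentation workflow labels.
        """
        return max(2, int(round(2.5 * self.psf_sigma)))


@dataclass
class FieldImage:
    """One imaged field: paired anchor (red) / prey (green) pixel arrays."""

    red: np.ndarray
    green: np.ndarray
    pixel_size: float = 0.1
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.red.shape != self.green.shape:
            raise ValueError("red and green channels must share a shape")


@dataclass
class _Cell:
    center: tuple[float, float]
    axes: tuple[float, float]  # semi-axes (major, minor), px
    theta: float
    anchors: list[tuple[float, float]]
    nucleolus_center: tuple[float, float]
    nucleolus_sigma: float
    recruited: bool = False


@dataclass
class GroundTruth:
    """Per-cell/per-anchor truth for one simulated field."""

    cells: list[_Cell]
    anchor_centers: np.ndarray  # (N, 2) row, col
    anchor_cell: np.ndarray  # (N,) cell index
    anchor_recruited: np.ndarray  # (N,) bool
    expected_green_per_anchor: np.ndarray  # summed noise-free green over footprint
    expected_score: float
    mask_radius: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "anchor": np.arange(len(self.anchor_cell)),
            "cell": self.anchor_cell,
            "row": self.anchor_centers[:, 0],
            "col": self.anchor_centers[:, 1],
            "recruited": self.anchor_recruited,
            "expected_green": self.expected_green_per_anchor,
        })


# ---------------------------------------------------------------------------
# scene construction
# ---------------------------------------------------------------------------

def _build_scene(params: SceneParams) -> list[_Cell]:
    rng = np.random.default_rng(params.seed)
    nrows, ncols = params.image_shape
    r_lo, r_hi = params.cell_radius_range
    margin_pad = params.mask_radius + 3.0

    cells: list[_Cell] = []
    attempts, max_attempts = 0, 5000 * max(params.n_cells, 1)
    while len(cells) < params.n_cells:
        attempts += 1
        if attempts > max_attempts:
            raise PlacementError(
                f"could not place {params.n_cells} non-overlapping cells "
                f"(radius {r_lo}-{r_hi} px) in a {nrows}x{ncols} frame"
            )
        a = rng.uniform(r_lo, r_hi)
        b = a * rng.uniform(0.7, 0.9)
        margin = a + margin_pad
        if 2 * margin >= min(nrows, ncols):
            raise PlacementError(
                f"image {nrows}x{ncols} too small for cells of radius {a:.1f} px"
            )
        cy = rng.uniform(margin, nrows - margin)
        cx = rng.uniform(margin, ncols - margin)
        if any(math.hypot(cy - c.center[0], cx - c.center[1]) < a + c.axes[0] + 2
               for c in cells):
            continue
        theta = rng.uniform(0, math.pi)
        u = (math.cos(theta), math.sin(theta))  # major-axis direction (drow, dcol)
        if params.anchors_per_cell == 2:
            sep = min(rng.uniform(15.0, 25.0), 1.6 * a)
            anchors = [
                (cy - 0.5 * sep * u[0], cx - 0.5 * sep * u[1]),
                (cy + 0.5 * sep * u[0], cx + 0.5 * sep * u[1]),
            ]
        else:
            off = rng.uniform(0, 0.3 * a)
            phi = rng.uniform(0, 2 * math.pi)
            anchors = [(cy + off * math.sin(phi), cx + off * math.cos(phi))]
        # nucleolus offset perpendicular to the anchor axis, inside the cell
        perp = (-u[1], u[0])
        side = 1.0 if rng.random() < 0.5 else -1.0
        nuc = (cy + side * 0.5 * b * perp[0], cx + side * 0.5 * b * perp[1])
        cells.append(_Cell((cy, cx), (a, b), theta, anchors, nuc, 0.35 * b))

    k = int(round(params.recruited_fraction * params.n_cells))
    order = rng.permutation(params.n_cells)
    recruited = set(order[:k].tolist())
    for i, c in enumerate(cells):
        c.recruited = i in recruited
    return cells


# ---------------------------------------------------------------------------
# rendering
# ---------------------------------------------------------------------------

def _add_gaussian(img: np.ndarray, center: tuple[float, float],
                  amplitude: float, sigma: float) -> None:
    if amplitude == 0:
        return
    nrows, ncols = img.shape
    r = int(math.ceil(5 * sigma))
    cy, cx = center
    r0, r1 = max(0, int(cy) - r), min(nrows, int(cy) + r + 1)
    c0, c1 = max(0, int(cx) - r), min(ncols, int(cx) + r + 1)
    yy = np.arange(r0, r1)[:, None] - cy
    xx = np.arange(c0, c1)[None, :] - cx
    img[r0:r1, c0:c1] += amplitude * np.exp(-(yy**2 + xx**2) / (2 * sigma**2))


def _ellipse_mask(shape: tuple[int, int], cell: _Cell) -> np.ndarray:
    cy, cx = cell.center
    a, b = cell.axes
    ct, st = math.cos(cell.theta), math.sin(cell.theta)
    yy = np.arange(shape[0])[:, None] - cy
    xx = np.arange(shape[1])[None, :] - cx
    major = yy * ct + xx * st
    minor = -yy * st + xx * ct
    return (major / a) ** 2 + (minor / b) ** 2 <= 1.0


def _render_expectation(params: SceneParams, cells: list[_Cell],
                        background: float | np.ndarray,
                        ) -> tuple[np.ndarray, np.ndarray]:
    """Noise-free expected photon images for both channels."""
    shape = params.image_shape
    red = np.zeros(shape, dtype=np.float64)
    green = np.zeros(shape, dtype=np.float64)
    for cell in cells:
        for anc in cell.anchors:
            _add_gaussian(red, anc, params.anchor_amplitude, params.psf_sigma)
            if cell.recruited:
                _add_gaussian(green, anc, params.prey_amplitude_at_anchor,
                              params.psf_sigma)
        if params.cell_diffuse > 0:
            green[_ellipse_mask(shape, cell)] += params.cell_diffuse
        _add_gaussian(green, cell.nucleolus_center, params.nucleolus_amplitude,
                      cell.nucleolus_sigma)
    red += background
    green += background
    return red, green


def _smooth_background(params: SceneParams, rng: np.random.Generator) -> np.ndarray:
    """Low-frequency Gaussian random field, image mean exactly background_mean."""
    if params.background_mean == 0 and params.background_sd == 0:
        return np.zeros(params.image_shape)
    if params.background_sd == 0:
        return np.full(params.image_shape, params.background_mean)
    white = rng.standard_normal(params.image_shape)
    smooth = ndimage.gaussian_filter(white, params.background_smoothness,
                                     mode="reflect")
    smooth -= smooth.mean()
    sd = smooth.std()
    if sd > 0:
        smooth /= sd
    bg = params.background_mean + params.background_sd * smooth
    return np.clip(bg, 0.0, None)


def _ground_truth(params: SceneParams, cells: list[_Cell]) -> GroundTruth:
    centers, cell_idx, flags = [], [], []
    for i, c in enumerate(cells):
        for anc in c.anchors:
            centers.append(anc)
            cell_idx.append(i)
            flags.append(c.recruited)
    centers_arr = (np.asarray(centers, dtype=float).reshape(-1, 2)
                   if centers else np.empty((0, 2)))
    # noise-free green with constant background: the per-anchor expectation
    green_e = _render_expectation(params, cells, params.background_mean)[1]
    r = params.mask_radius
    yy, xx = np.mgrid[-r:r + 1, -r:r + 1]
    disk = (yy**2 + xx**2) <= r**2
    per_anchor = np.zeros(len(centers))
    nrows, ncols = params.image_shape
    for j, (cy, cx) in enumerate(centers):
        iy, ix = int(round(cy)), int(round(cx))
        r0, c0 = iy - r, ix - r
        sub = green_e[max(0, r0):min(nrows, iy + r + 1),
                      max(0, c0):min(ncols, ix + r + 1)]
        d = disk[max(0, -r0):disk.shape[0] - max(0, iy + r + 1 - nrows),
                 max(0, -c0):disk.shape[1] - max(0, ix + r + 1 - ncols)]
        per_anchor[j] = float(sub[d].sum())
    area = int(disk.sum())
    flags_arr = np.asarray(flags, dtype=bool)
    total_red_area = area * len(centers)
    score = (float(per_anchor[flags_arr].sum()) / total_red_area
             if total_red_area else 0.0)
    return GroundTruth(cells, centers_arr, np.asarray(cell_idx, dtype=int),
                       flags_arr, per_anchor, score, r)


# ---------------------------------------------------------------------------
# public simulation API
# ---------------------------------------------------------------------------

def simulate_field(params: SceneParams, seed: int | None = None,
                   meta: dict | None = None) -> tuple[FieldImage, GroundTruth]:
    """Simulate one two-channel field.

    Geometry comes from ``params.seed``; the background realization and all
    noise come from ``seed`` (default: ``params.seed``). Identical
    ``(params, seed)`` gives bit-identical output.
    """
    params.validate()
    if seed is None:
        seed = params.seed
    cells = _build_scene(params)
    truth = _ground_truth(params, cells)
    noise_rng = np.random.default_rng(seed)
    bg = _smooth_background(params, noise_rng)
    red_e, green_e = _render_expectation(params, cells, bg)
    if params.shot_noise:
        red = noise_rng.poisson(red_e).astype(np.float64)
        green = noise_rng.poisson(green_e).astype(np.float64)
    else:
        red, green = red_e, green_e
    if params.read_noise_sigma > 0:
        red = red + noise_rng.normal(0, params.read_noise_sigma, red.shape)
        green = green + noise_rng.normal(0, params.read_noise_sigma, green.shape)
    fld = FieldImage(red, green, params.pixel_size, dict(meta or {}))
    return fld, truth


def simulate_condition(params: SceneParams, n_replicates: int, n_fields: int,
                       base_seed: int, condition: str = "cond",
                       replicate_cv: float = 0.0,
                       ) -> dict[int, list[tuple[FieldImage, GroundTruth]]]:
    """Simulate ``n_replicates`` biological replicates of ``n_fields`` fields.

    Per-field seeds derive deterministically from ``(base_seed, replicate,
    field)``. ``replicate_cv`` injects replicate-level biological variation as
    a lognormal multiplicative factor on ``prey_amplitude_at_anchor``.
    """
    if n_replicates < 1 or n_fields < 1:
        raise ValueError("n_replicates and n_fields must be >= 1")
    out: dict[int, list[tuple[FieldImage, GroundTruth]]] = {}
    for rep in range(n_replicates):
        factor = 1.0
        if replicate_cv > 0:
            rep_rng = np.random.default_rng(derive_seed(base_seed, rep, 991))
            sigma = math.sqrt(math.log(1 + replicate_cv**2))
            factor = float(rep_rng.lognormal(-0.5 * sigma**2, sigma))
        fields = []
        for fld_idx in range(n_fields):
            geom_seed = derive_seed(base_seed, rep, fld_idx, 0)
            noise_seed = derive_seed(base_seed, rep, fld_idx, 1)
            p = replace(params, seed=geom_seed,
                        prey_amplitude_at_anchor=params.prey_amplitude_at_anchor * factor)
            meta = {"condition": condition, "replicate": rep, "field": fld_idx,
                    "timepoint_min": 0.0}
            fields.append(simulate_field(p, noise_seed, meta))
        out[rep] = fields
    return out


def true_masks(truth: GroundTruth, shape: tuple[int, int]
               ) -> tuple[np.ndarray, np.ndarray]:
    """Ground-truth (anchor, recruited-prey) footprint masks as boolean arrays."""
    anchor = np.zeros(shape, dtype=bool)
    prey = np.zeros(shape, dtype=bool)
    r = truth.mask_radius
    yy, xx = np.mgrid[-r:r + 1, -r:r + 1]
    disk = (yy**2 + xx**2) <= r**2
    for (cy, cx), rec in zip(truth.anchor_centers, truth.anchor_recruited):
        iy, ix = int(round(cy)), int(round(cx))
        r0, r1 = max(0, iy - r), min(shape[0], iy + r + 1)
        c0, c1 = max(0, ix - r), min(shape[1], ix + r + 1)
        d = disk[r0 - (iy - r):disk.shape[0] - ((iy + r + 1) - r1),
                 c0 - (ix - r):disk.shape[1] - ((ix + r + 1) - c1)]
        anchor[r0:r1, c0:c1] |= d
        if rec:
            prey[r0:r1, c0:c1] |= d
    return anchor, prey


def measure_true_score(fld: FieldImage, truth: GroundTruth) -> float:
    """Recruitment score of a field measured with ground-truth masks."""
    anchor, prey = true_masks(truth, fld.green.shape)
    red_area = int(anchor.sum())
    if red_area == 0:
        raise ValueError("field has no anchors")
    yellow = anchor & prey
    return float(fld.green[yellow].sum()) / red_area


def expected_score(params: SceneParams) -> float:
    """Noise-free expectation of the true-mask recruitment score.

    Integrates the generative model (for the geometry of ``params.seed``) over
    the anchor footprints; equals the Monte-Carlo mean of
    :func:`measure_true_score` over noise realizations.
    """
    params.validate()
    cells = _build_scene(params)
    return _ground_truth(params, cells).expected_score


def simulate_anchor_pair_cell(nuclear: bool, seed: int,
                              image_shape: tuple[int, int] = (64, 64),
                              separation_px: float = 20.0,
                              anchor_amplitude: float = 2000.0,
                              prey_amplitude: float = 400.0,
                              psf_sigma: float = 1.5,
                              background_mean: float = 100.0,
                              read_noise_sigma: float = 5.0,
                              ) -> tuple[FieldImage, tuple, tuple]:
    """One cell with two anchoring platforms and a prey of known localization.

    The prey-GFP spot is placed midway between the anchors (``nuclear=True``,
    the nucleus lies between the two spindle pole bodies) or directly on one
    anchor (``nuclear=False``). Returns the field plus the two true anchor
    positions.
    """
    rng = np.random.default_rng(seed)
    cy, cx = image_shape[0] / 2, image_shape[1] / 2
    theta = rng.uniform(0, math.pi)
    u = (math.cos(theta), math.sin(theta))
    jitter = rng.uniform(-1.5, 1.5, 2)
    p0 = (cy + jitter[0] - 0.5 * separation_px * u[0],
          cx + jitter[1] - 0.5 * separation_px * u[1])
    p1 = (cy + jitter[0] + 0.5 * separation_px * u[0],
          cx + jitter[1] + 0.5 * separation_px * u[1])
    if nuclear:
        prey_at = (0.5 * (p0[0] + p1[0]), 0.5 * (p0[1] + p1[1]))
    else:
        prey_at = p0 if rng.random() < 0.5 else p1
    red = np.full(image_shape, background_mean, dtype=np.float64)
    green = np.full(image_shape, background_mean, dtype=np.float64)
    for anc in (p0, p1):
        _add_gaussian(red, anc, anchor_amplitude, psf_sigma)
    _add_gaussian(green, prey_at, prey_amplitude, psf_sigma)
    red = rng.poisson(red).astype(np.float64)
    green = rng.poisson(green).astype(np.float64)
    if read_noise_sigma > 0:
        red += rng.normal(0, read_noise_sigma, image_shape)
        green += rng.normal(0, read_noise_sigma, image_shape)
    return FieldImage(red, green), p0, p1


# ---------------------------------------------------------------------------
# kinetic time courses
# ---------------------------------------------------------------------------

@dataclass
class KineticParams:
    """Ground-truth kinetics of the two Pol I complexes after a medium switch.

    Defaults reproduce the starvation response: Pol I–Rrn3 decays
    exponentially (≈30% loss in the first 15 min, ≈60% total), while the
    inactive homodimer rises along a logistic with its fastest assembly in
    the 15–35 min window.
    """

    rrn3_decay: dict = field(default_factory=lambda: {
        "amplitude": 0.6, "tau": 20.0, "offset": 0.4})
    dimer_rise: dict = field(default_factory=lambda: {
        "lo": 0.0, "hi": 1.0, "t50": 25.0, "steepness": 0.25})
    measurement_noise_sd: float = 0.0  # multiplicative, fraction
    timepoints: tuple[float, ...] = (0, 5, 10, 15, 20, 25, 30, 35, 45, 60, 90, 120)

    def validate(self) -> None:
        if self.rrn3_decay["tau"] <= 0:
            raise ValueError("tau must be > 0")
        if self.dimer_rise["steepness"] <= 0:
            raise ValueError("steepness must be > 0")
        if self.dimer_rise["hi"] < self.dimer_rise["lo"]:
            raise ValueError("logistic asymptotes must be ordered lo <= hi")
        t = np.asarray(self.timepoints, dtype=float)
        if len(t) < 2 or np.any(np.diff(t) <= 0):
            raise ValueError("timepoints must be strictly increasing")


def rrn3_model(t: np.ndarray, amplitude: float, tau: float, offset: float) -> np.ndarray:
    return offset + amplitude * np.exp(-np.asarray(t, dtype=float) / tau)


def dimer_model(t: np.ndarray, lo: float, hi: float, t50: float,
                steepness: float) -> np.ndarray:
    t = np.asarray(t, dtype=float)
    return lo + (hi - lo) / (1.0 + np.exp(-steepness * (t - t50)))


def simulate_timecourse(kp: KineticParams, seed: int = 0):
    """Noisy time courses of both complexes; returns ``{complex_id: TimeCourse}``."""
    from .dynamics import TimeCourse  # local import: dynamics has no synthetic dep

    kp.validate()
    rng = np.random.default_rng(seed)
    t = np.asarray(kp.timepoints, dtype=float)
    out = {}
    for cid, clean in (
        ("pol1_rrn3", rrn3_model(t, **kp.rrn3_decay)),
        ("pol1_dimer", dimer_model(t, **kp.dimer_rise)),
    ):
        v = clean.copy()
        if kp.measurement_noise_sd > 0:
            v = v * (1.0 + rng.normal(0, kp.measurement_noise_sd, v.shape))
        out[cid] = TimeCourse(cid, t.copy(), np.clip(v, 0.0, None))
    return out


# ---------------------------------------------------------------------------
# ChIP-qPCR synthetic tables
# ---------------------------------------------------------------------------

DEFAULT_LOCI = ("35S_promoter", "18S", "25S", "5S", "chrVII_control")


def simulate_dilution_series(amplicons: Sequence[str] = DEFAULT_LOCI,
                             efficiency: float = 1.0, intercept: float = 25.0,
                             n_dilutions: int = 4, ct_sd: float = 0.0,
                             seed: int = 0) -> pd.DataFrame:
    """Serial 10-fold dilution Ct table used to fit per-amplicon standard curves."""
    rng = np.random.default_rng(seed)
    slope = -1.0 / math.log10(1.0 + efficiency)
    rows = []
    for amp in amplicons:
        for d in range(n_dilutions):
            log10_q = -float(d)
            for tech in range(3):
                ct = intercept + slope * log10_q
                if ct_sd > 0:
                    ct += rng.normal(0, ct_sd)
                rows.append({"amplicon": amp, "log10_quantity": log10_q,
                             "technical_replicate": tech, "ct": ct})
    return pd.DataFrame(rows)


def simulate_ct_table(occupancy: dict[tuple[str, str], float],
                      conditions: Sequence[str], loci: Sequence[str] = DEFAULT_LOCI,
                      n_replicates: int = 3, n_technical: int = 3,
                      efficiency: float = 1.0, intercept: float = 25.0,
                      input_ct: float = 20.0, ct_sd: float = 0.15,
                      seed: int = 0) -> pd.DataFrame:
    """Long-format IP/input Ct table with known true IP/input enrichment.

    ``occupancy[(condition, locus)]`` is the true IP/input quantity ratio at
    that locus (relative to the control locus implicitly at ratio 1).
    """
    rng = np.random.default_rng(seed)
    slope = -1.0 / math.log10(1.0 + efficiency)
    rows = []
    for cond in conditions:
        for rep in range(n_replicates):
            for locus in loci:
                ratio = occupancy.get((cond, locus), 1.0)
                q_input = 1.0
                q_ip = ratio * 0.05  # 5% of input pulled down at ratio 1
                for frac, q in (("input", q_input), ("IP", q_ip)):
                    base_ct = intercept + slope * math.log10(q)
                    for tech in range(n_technical):
                        ct = base_ct + (rng.normal(0, ct_sd) if ct_sd > 0 else 0.0)
                        rows.append({"sample": f"{cond}_r{rep}", "fraction": frac,
                                     "amplicon": locus, "condition": cond,
                                     "replicate": rep, "technical_replicate": tech,
                                     "ct": ct})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# export
# ---------------------------------------------------------------------------

def write_condition(outdir, collections: dict[str, dict[int, list]],
                    gain: float = 1.0) -> pd.DataFrame:
    """Write per-field 16-bit TIFF pairs, ground_truth.csv and manifest.csv.

    ``collections`` maps condition name to the output of
    :func:`simulate_condition`. Returns the manifest frame.
    """
    import tifffile
    from pathlib import Path

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest_rows, truth_frames = [], []
    for cond, reps in collections.items():
        for rep, fields in reps.items():
            for idx, (fld, truth) in enumerate(fields):
                stem = f"{cond}_{rep}_{idx}"
                red_path = outdir / f"{stem}_RFP.tif"
                green_path = outdir / f"{stem}_GFP.tif"
                for path, chan in ((red_path, fld.red), (green_path, fld.green)):
                    q = np.clip(chan * gain, 0, 65535).astype(np.uint16)
                    tifffile.imwrite(path, q)
                manifest_rows.append({
                    "field_id": stem, "condition": cond, "replicate": rep,
                    "timepoint_min": fld.meta.get("timepoint_min", 0.0),
                    "red_path": red_path.name, "green_path": green_path.name,
                })
                tf = truth.to_frame()
                tf.insert(0, "field_id", stem)
                truth_frames.append(tf)
    manifest = pd.DataFrame(manifest_rows)
    manifest.to_csv(outdir / "manifest.csv", index=False)
    if truth_frames:
        pd.concat(truth_frames, ignore_index=True).to_csv(
            outdir / "ground_truth.csv", index=False)
    return manifest
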