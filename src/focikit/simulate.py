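"""Seeded synthetic-microscopy and capture-experiment generator with ground truth.

Emulates fields of nuclei expressing GFP-53BP1 after ionizing irradiation:
each nucleus shows a diffuse nucleoplasmic background (free GFP-53BP1) plus
punctate repair foci that resolve over time. Per-cell resolution follows a
single-exponential decay calibrated to the cell's 2-h endpoint, with a rare
"fast resolving" subpopulation. A separate generator simulates rounds of
magnetic capture of laser-tagged cells.

All randomness flows from an integer seed through ``numpy.random.SeedSequence``
so every artefact (trajectories, images, capture counts) is bit-reproducible.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from numpy.random import Generator, SeedSequence, default_rng


class LayoutError(ValueError):
    """Raised when nuclei cannot be placed inside the requested field."""


class ParameterError(ValueError):
    """Raised for invalid simulation parameters."""


# ---------------------------------------------------------------------------
# parameter blocks
# ---------------------------------------------------------------------------

@dataclass
class SimLayout:
    """Geometry of one simulated field of view.

    Nuclei are placed uniformly at random subject to a hard-core constraint:
    centre distance >= sum of radii + ``min_nucleus_gap_px``, and every
    nucleus lies fully inside the image. Distractors (debris) are placed
    outside all nuclei to exercise the object-filtering stage; by default
    one saturated blob and one sub-size speck are added per 10 nuclei.
    """

    image_height_px: int = 512
    image_width_px: int = 512
    n_nuclei: int = 20
    nucleus_radius_px_mean: float = 30.0
    nucleus_radius_px_sd: float = 1.5
    min_nucleus_gap_px: float = 12.0
    n_distractors: int | None = None  # None -> 2 per 10 nuclei (auto)

    def __post_init__(self) -> None:
        if min(self.image_height_px, self.image_width_px) <= 0:
            raise ParameterError("image dimensions must be positive")
        if self.n_nuclei <= 0:
            raise ParameterError("n_nuclei must be positive")
        if self.nucleus_radius_px_mean <= 0 or self.nucleus_radius_px_sd < 0:
            raise ParameterError("nucleus radius parameters invalid")
        if self.min_nucleus_gap_px < 0:
            raise ParameterError("min_nucleus_gap_px must be >= 0")
        if self.n_distractors is None:
            self.n_distractors = 2 * (self.n_nuclei // 10)
        if self.n_distractors < 0:
            raise ParameterError("n_distractors must be >= 0")


@dataclass
class OpticsModel:
    """Intensity scales of the simulated imaging system (ADU).

    ``psf_sigma_px`` defaults to focus_diameter_px / 2.355 so that the full
    width at half maximum of a rendered spot equals the nominal focus
    diameter. Defaults mimic 16-bit camera images sampled at ~0.3 um/px, where
    a U2OS nucleus spans ~60 px and a repair focus ~5 px.
    """

    focus_diameter_px: float = 5.0
    focus_peak_intensity: float = 6000.0
    nucleus_background_intensity_mean: float = 2000.0
    nucleus_background_intensity_cv: float = 0.1
    psf_sigma_px: float | None = None
    bit_depth: int = 16

    def __post_init__(self) -> None:
        if self.focus_diameter_px < 2:
            raise ParameterError("focus_diameter_px must be >= 2")
        if self.psf_sigma_px is None:
            self.psf_sigma_px = self.focus_diameter_px / 2.355
        if self.bit_depth not in (8, 16):
            raise ParameterError("bit_depth must be 8 or 16")
        sat = self.saturation_level
        for name in ("focus_peak_intensity", "nucleus_background_intensity_mean"):
            v = getattr(self, name)
            if not (0 < v <= sat):
                raise ParameterError(f"{name} must lie in (0, {sat}]")

    @property
    def saturation_level(self) -> int:
        return 2 ** self.bit_depth - 1


@dataclass
class NoiseModel:
    """Camera noise: Poisson shot noise on expected photons plus Gaussian read noise."""

    shot_noise: bool = True
    read_noise_sd: float = 3.0
    gain: float = 1.0  # ADU per photon

    def __post_init__(self) -> None:
        if self.read_noise_sd < 0:
            raise ParameterError("read_noise_sd must be >= 0")
        if self.gain <= 0:
            raise ParameterError("gain must be > 0")


@dataclass
class KineticsParams:
    """Population focus-resolution kinetics between the first and last timepoint.

    Initial counts are a discretised truncated normal (negative draws set to
    0). Each cell draws a resolved fraction at the final timepoint: bulk
    cells from a Beta with mean ``bulk_resolved_fraction_at_2h`` and
    concentration ``bulk_fraction_concentration``; fast resolvers (Bernoulli
    ``fast_resolver_fraction``) uniform on
    [``fast_resolved_fraction_at_2h_min``, 1]. Remaining counts decay
    exponentially in time toward that endpoint and are realised by binomial
    thinning, so counts are integers and non-increasing.
    """

    timepoints_min: tuple[float, ...] = (45.0, 60.0, 75.0, 90.0, 120.0)
    initial_count_mean: float = 10.2
    initial_count_sd: float = 2.5
    bulk_resolved_fraction_at_2h: float = 0.25
    bulk_fraction_concentration: float = 20.0
    fast_resolver_fraction: float = 0.01
    fast_resolved_fraction_at_2h_min: float = 0.85

    def __post_init__(self) -> None:
        tps = tuple(float(t) for t in self.timepoints_min)
        if len(tps) < 2 or any(b <= a for a, b in zip(tps, tps[1:])):
            raise ParameterError("timepoints_min must be strictly increasing, >= 2 points")
        self.timepoints_min = tps
        for name in ("bulk_resolved_fraction_at_2h", "fast_resolver_fraction",
                     "fast_resolved_fraction_at_2h_min"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ParameterError(f"{name} must lie in [0, 1]")
        if self.fast_resolved_fraction_at_2h_min <= self.bulk_resolved_fraction_at_2h:
            raise ParameterError(
                "fast_resolved_fraction_at_2h_min must exceed bulk_resolved_fraction_at_2h")
        if self.initial_count_mean < 0 or self.initial_count_sd < 0:
            raise ParameterError("initial count parameters must be >= 0")
        if self.bulk_fraction_concentration <= 0:
            raise ParameterError("bulk_fraction_concentration must be > 0")


@dataclass
class CaptureParams:
    """One magnetic-sorting experiment: tagged cells among a large population."""

    n_total_cells: int = 50_000
    n_tagged: int = 10
    p_capture_positive: float = 0.99
    p_carryover_negative: float = 0.5
    n_rounds: int = 4

    def __post_init__(self) -> None:
        if not (0 <= self.n_tagged <= self.n_total_cells):
            raise ParameterError("need 0 <= n_tagged <= n_total_cells")
        for name in ("p_capture_positive", "p_carryover_negative"):
            if not (0.0 <= getattr(self, name) <= 1.0):
                raise ParameterError(f"{name} must lie in [0, 1]")
        if self.n_rounds < 1:
            raise ParameterError("n_rounds must be >= 1")


@dataclass
class FieldGroundTruth:
    """Planted truth for one simulated field (possibly several timepoints).

    cells: one row per nucleus — geometry, background level, kinetic draw,
        realised counts per timepoint and the realised fast-resolver status
        (resolved fraction between first and last timepoint > 0.85).
    foci: one row per planted focus per timepoint (cell_id, timepoint_min,
        row, col).
    """

    cells: pd.DataFrame
    foci: pd.DataFrame
    distractors: pd.DataFrame
    seed: int
    params: dict = field(default_factory=dict)
    # per-timepoint rigid offsets (cell_id, timepoint_min, drow, dcol); empty = no drift
    drift: pd.DataFrame = field(default_factory=pd.DataFrame)

    def cell_offsets(self, timepoint_min: float | None) -> dict[int, tuple[float, float]]:
        if timepoint_min is None or self.drift.empty:
            return {}
        sel = self.drift[np.isclose(self.drift["timepoint_min"], timepoint_min)]
        return {int(r.cell_id): (r.drow, r.dcol) for r in sel.itertuples()}

    def counts_at(self, timepoint_min: float) -> pd.Series:
        col = f"count_t{timepoint_min:g}"
        return self.cells.set_index("cell_id")[col]


@dataclass
class CaptureOutcome:
    """Result of simulated repeated magnetic capture."""

    n_total_cells: int
    n_tagged: int
    n_rounds: int
    n_captured_positive: int
    n_captured_negative: int
    history: pd.DataFrame  # per-round positives / negatives retained


# ---------------------------------------------------------------------------
# kinetics sampling
# ---------------------------------------------------------------------------

FAST_RESOLVER_THRESHOLD = 0.85


def sample_kinetics(params: KineticsParams, n_cells: int,
                    seed: int | Generator) -> pd.DataFrame:
    """Draw per-cell focus-count trajectories.

    Returns a table with one row per cell: initial count, the drawn endpoint
    resolved fraction ``frac_2h``, the drawn subpopulation flag
    ``fast_drawn``, the expected remaining fraction ``frac_t{t}`` and the
    realised integer count ``count_t{t}`` at each timepoint, the realised
    resolved fraction between first and last timepoint, and the realised
    ``fast_resolver`` status (strictly > 0.85 resolved).
    """
    if n_cells <= 0:
        raise ParameterError("n_cells must be positive")
    rng = seed if isinstance(seed, Generator) else default_rng(seed)

    n0 = np.rint(rng.normal(params.initial_count_mean,
                            params.initial_count_sd, n_cells)).astype(int)
    n0 = np.maximum(n0, 0)

    fast = rng.random(n_cells) < params.fast_resolver_fraction
    m = params.bulk_resolved_fraction_at_2h
    c = params.bulk_fraction_concentration
    frac = np.empty(n_cells)
    if m in (0.0, 1.0):  # degenerate Beta
        frac[:] = m
    else:
        frac[:] = rng.beta(m * c, (1.0 - m) * c, n_cells)
    n_fast = int(fast.sum())
    if n_fast:
        frac[fast] = rng.uniform(params.fast_resolved_fraction_at_2h_min, 1.0, n_fast)

    tps = np.asarray(params.timepoints_min)
    t0, t_end = tps[0], tps[-1]
    # remaining fraction decays exponentially from 1 at t0 to (1 - frac) at t_end
    expo = (tps[None, :] - t0) / (t_end - t0)
    remaining = np.power(np.clip(1.0 - frac, 0.0, 1.0)[:, None], expo)

    counts = np.empty((n_cells, len(tps)), dtype=int)
    counts[:, 0] = n0
    for k in range(1, len(tps)):
        prev = remaining[:, k - 1]
        with np.errstate(divide="ignore", invalid="ignore"):
            p = np.where(prev > 0, remaining[:, k] / prev, 0.0)
        counts[:, k] = rng.binomial(counts[:, k - 1], np.clip(p, 0.0, 1.0))

    with np.errstate(divide="ignore", invalid="ignore"):
        realized = np.where(n0 > 0, 1.0 - counts[:, -1] / np.maximum(n0, 1), np.nan)

    out = pd.DataFrame({
        "cell_id": np.arange(n_cells),
        "initial_count": n0,
        "fast_drawn": fast,
        "frac_2h": frac,
    })
    for j, t in enumerate(tps):
        out[f"frac_t{t:g}"] = remaining[:, j]
        out[f"count_t{t:g}"] = counts[:, j]
    out["resolved_frac_realized"] = realized
    out["fast_resolver"] = (realized > FAST_RESOLVER_THRESHOLD) & (n0 > 0)
    return out


# ---------------------------------------------------------------------------
# geometry
# ---------------------------------------------------------------------------

def _place_nuclei(layout: SimLayout, optics: OpticsModel, rng: Generator) -> pd.DataFrame:
    n = layout.n_nuclei
    radii = np.clip(rng.normal(layout.nucleus_radius_px_mean,
                               layout.nucleus_radius_px_sd, n), 3.0, None)
    elong = rng.uniform(0.9, 1.1, n)          # mild, random ellipticity
    theta = rng.uniform(0.0, np.pi, n)
    h, w = layout.image_height_px, layout.image_width_px
    centers = np.empty((n, 2))
    max_tries = 20_000
    for i in range(n):
        r_eff = radii[i] * max(elong[i], 1.0 / elong[i])
        margin = r_eff + 2.0
        if 2 * margin >= min(h, w):
            raise LayoutError("nucleus does not fit inside the field")
        placed = centers[:i]
        for _ in range(max_tries):
            cand = rng.uniform([margin, margin], [h - margin, w - margin])
            if i == 0:
                centers[i] = cand
                break
            d = np.hypot(*(placed - cand).T)
            req = radii[:i] * np.maximum(elong[:i], 1.0 / elong[:i]) + r_eff \
                + layout.min_nucleus_gap_px
            if np.all(d >= req):
                centers[i] = cand
                break
        else:
            raise LayoutError(
                f"could not place nucleus {i} without overlap; field too crowded")
    bg = np.clip(rng.normal(optics.nucleus_background_intensity_mean,
                            optics.nucleus_background_intensity_mean
                            * optics.nucleus_background_intensity_cv, n),
                 1.0, optics.saturation_level)
    return pd.DataFrame({
        "cell_id": np.arange(n),
        "row": centers[:, 0], "col": centers[:, 1],
        "radius_px": radii,
        "semi_axis_a": radii * elong, "semi_axis_b": radii / elong,
        "theta": theta,
        "background": bg,
    })


def _place_distractors(layout: SimLayout, nuclei: pd.DataFrame,
                       rng: Generator) -> pd.DataFrame:
    """Debris outside all nuclei: alternating saturated blobs and sub-size specks."""
    rows = []
    h, w = layout.image_height_px, layout.image_width_px
    ncr = nuclei[["row", "col"]].to_numpy()
    nrad = nuclei["radius_px"].to_numpy() * 1.1
    for k in range(layout.n_distractors):
        kind = "saturated_blob" if k % 2 == 0 else "speck"
        radius = 25.0 if kind == "saturated_blob" else 1.5
        for _ in range(20_000):
            cand = rng.uniform([radius + 1, radius + 1], [h - radius - 1, w - radius - 1])
            d = np.hypot(*(ncr - cand).T)
            if np.all(d >= nrad + radius + layout.min_nucleus_gap_px):
                rows.append((kind, cand[0], cand[1], radius))
                break
        else:
            break  # field too crowded for more debris; not an error
    return pd.DataFrame(rows, columns=["kind", "row", "col", "radius_px"])


def _sample_positions_in_ellipse(n: int, cell: pd.Series, rng: Generator,
                                 min_sep: float, edge_margin: float) -> np.ndarray:
    """Uniform points in the (margin-shrunk) nucleus ellipse with a soft
    minimum pairwise separation (relaxed geometrically if the nucleus is
    too crowded to honour it)."""
    a = max(cell.semi_axis_a - edge_margin, 1.0)
    b = max(cell.semi_axis_b - edge_margin, 1.0)
    ct, st = np.cos(cell.theta), np.sin(cell.theta)
    pts: list[np.ndarray] = []
    sep = min_sep
    fails = 0
    while len(pts) < n:
        u = np.sqrt(rng.random())
        ang = rng.uniform(0, 2 * np.pi)
        x, y = a * u * np.cos(ang), b * u * np.sin(ang)
        p = np.array([cell.row + x * ct - y * st, cell.col + x * st + y * ct])
        if all(np.hypot(*(p - q)) >= sep for q in pts):
            pts.append(p)
            fails = 0
        else:
            fails += 1
            if fails > 200:
                sep *= 0.8
                fails = 0
    return np.array(pts).reshape(n, 2)


# ---------------------------------------------------------------------------
# rendering
# ---------------------------------------------------------------------------

def _ellipse_mask_bbox(cell: pd.Series, shape: tuple[int, int]):
    a, b, th = cell.semi_axis_a, cell.semi_axis_b, cell.theta
    r_eff = max(a, b)
    r0 = max(int(np.floor(cell.row - r_eff)) - 1, 0)
    r1 = min(int(np.ceil(cell.row + r_eff)) + 2, shape[0])
    c0 = max(int(np.floor(cell.col - r_eff)) - 1, 0)
    c1 = min(int(np.ceil(cell.col + r_eff)) + 2, shape[1])
    rr, cc = np.mgrid[r0:r1, c0:c1]
    dr, dc = rr - cell.row, cc - cell.col
    ct, st = np.cos(th), np.sin(th)
    x = dr * ct + dc * st
    y = -dr * st + dc * ct
    mask = (x / a) ** 2 + (y / b) ** 2 <= 1.0
    return (slice(r0, r1), slice(c0, c1)), mask


def render_field(layout: SimLayout, optics: OpticsModel, noise: NoiseModel,
                 planted: FieldGroundTruth, seed: int | Generator,
                 timepoint_min: float | None = None) -> np.ndarray:
    """Render one timepoint of a planted field into an integer image.

    Nuclei are filled ellipses at their background level; every planted
    focus adds an isotropic Gaussian of amplitude ``focus_peak_intensity``;
    distractors are drawn outside nuclei; shot and read noise are applied
    last and the result is clipped to [0, saturation] at the stated bit
    depth.
    """
    rng = seed if isinstance(seed, Generator) else default_rng(seed)
    h, w = layout.image_height_px, layout.image_width_px
    img = np.zeros((h, w), dtype=float)

    cells = planted.cells
    offsets = planted.cell_offsets(timepoint_min)
    r_eff = np.maximum(cells["semi_axis_a"], cells["semi_axis_b"]).to_numpy()
    if ((cells["row"].to_numpy() - r_eff < 0).any()
            or (cells["row"].to_numpy() + r_eff > h).any()
            or (cells["col"].to_numpy() - r_eff < 0).any()
            or (cells["col"].to_numpy() + r_eff > w).any()):
        raise LayoutError("planted nucleus extends outside the field")

    foci = planted.foci
    if timepoint_min is not None and "timepoint_min" in foci.columns:
        foci = foci[np.isclose(foci["timepoint_min"], timepoint_min)]
    sig = optics.psf_sigma_px

    # GFP-53BP1 redistributes rather than accumulates: the integrated flux
    # planted into a cell's foci is removed from its diffuse background, so
    # whole-nucleus intensity carries no information about the focus count.
    focus_flux = optics.focus_peak_intensity * 2.0 * np.pi * sig ** 2
    n_foci = foci.groupby("cell_id").size() if len(foci) else pd.Series(dtype=int)

    for _, cell in cells.iterrows():
        cell = cell.copy()
        drow, dcol = offsets.get(int(cell.cell_id), (0.0, 0.0))
        cell.row += drow
        cell.col += dcol
        sl, mask = _ellipse_mask_bbox(cell, (h, w))
        area = np.pi * cell.semi_axis_a * cell.semi_axis_b
        depletion = int(n_foci.get(int(cell.cell_id), 0)) * focus_flux / area
        img[sl][mask] = max(cell.background - depletion, 0.1 * cell.background)
    half = int(np.ceil(4 * sig))
    for f in foci.itertuples():
        drow, dcol = offsets.get(int(f.cell_id), (0.0, 0.0))
        frow, fcol = f.row + drow, f.col + dcol
        r0 = max(int(frow) - half, 0)
        r1 = min(int(frow) + half + 1, h)
        c0 = max(int(fcol) - half, 0)
        c1 = min(int(fcol) + half + 1, w)
        rr, cc = np.mgrid[r0:r1, c0:c1]
        img[r0:r1, c0:c1] += optics.focus_peak_intensity * np.exp(
            -((rr - frow) ** 2 + (cc - fcol) ** 2) / (2 * sig ** 2))

    sat = optics.saturation_level
    for d in planted.distractors.itertuples():
        r0 = max(int(d.row - d.radius_px) - 1, 0)
        r1 = min(int(d.row + d.radius_px) + 2, h)
        c0 = max(int(d.col - d.radius_px) - 1, 0)
        c1 = min(int(d.col + d.radius_px) + 2, w)
        rr, cc = np.mgrid[r0:r1, c0:c1]
        m = (rr - d.row) ** 2 + (cc - d.col) ** 2 <= d.radius_px ** 2
        level = sat if d.kind == "saturated_blob" else min(
            2 * optics.nucleus_background_intensity_mean, sat)
        img[rr[m], cc[m]] = level

    if noise.shot_noise:
        img = rng.poisson(np.clip(img, 0, None) / noise.gain).astype(float) * noise.gain
    if noise.read_noise_sd > 0:
        img = img + rng.normal(0.0, noise.read_noise_sd, img.shape)
    img = np.clip(np.rint(img), 0, sat)
    return img.astype(np.uint8 if optics.bit_depth == 8 else np.uint16)


def plant_field(layout: SimLayout, optics: OpticsModel,
                kinetics: KineticsParams, seed: int,
                focus_min_separation_px: float | None = None,
                focus_edge_margin_px: float = 4.0,
                drift_px: float = 0.0) -> FieldGroundTruth:
    """Lay out nuclei, draw kinetics, and plant focus coordinates for every
    timepoint. Foci at later timepoints are nested subsets of the first
    timepoint's foci (resolved foci are removed, surviving ones persist),
    so per-cell counts are non-increasing by construction."""
    ss = SeedSequence(seed)
    r_layout, r_kin, r_foci, _ = [default_rng(s) for s in ss.spawn(4)]

    nuclei = _place_nuclei(layout, optics, r_layout)
    distractors = _place_distractors(layout, nuclei, r_layout)
    traj = sample_kinetics(kinetics, layout.n_nuclei, r_kin)
    cells = nuclei.merge(traj, on="cell_id")

    tps = kinetics.timepoints_min
    if focus_min_separation_px is None:
        focus_min_separation_px = optics.focus_diameter_px
    foci_rows = []
    for _, cell in cells.iterrows():
        n0 = int(cell.initial_count)
        if n0 == 0:
            continue
        pts = _sample_positions_in_ellipse(n0, cell, r_foci,
                                           focus_min_separation_px,
                                           focus_edge_margin_px)
        order = r_foci.permutation(n0)  # resolution order: first k survive
        for t in tps:
            keep = order[: int(cell[f"count_t{t:g}"])]
            for j in keep:
                foci_rows.append((int(cell.cell_id), float(t), pts[j, 0], pts[j, 1]))
    foci = pd.DataFrame(foci_rows, columns=["cell_id", "timepoint_min", "row", "col"])

    drift_rows = []
    if drift_px > 0:
        # rigid per-cell jitter (nucleus plus its foci) at later timepoints
        for t in tps[1:]:
            jit = r_foci.uniform(-drift_px, drift_px, (len(cells), 2))
            for i, cid in enumerate(cells.cell_id):
                drift_rows.append((int(cid), float(t), jit[i, 0], jit[i, 1]))
    drift = pd.DataFrame(drift_rows,
                         columns=["cell_id", "timepoint_min", "drow", "dcol"])

    params = {
        "layout": dataclasses.asdict(layout),
        "optics": dataclasses.asdict(optics),
        "kinetics": dataclasses.asdict(kinetics),
        "focus_min_separation_px": focus_min_separation_px,
        "focus_edge_margin_px": focus_edge_margin_px,
        "drift_px": drift_px,
    }
    return FieldGroundTruth(cells=cells, foci=foci, distractors=distractors,
                            seed=seed, params=params, drift=drift)


def generate_time_course(layout: SimLayout, optics: OpticsModel,
                         noise: NoiseModel, kinetics: KineticsParams,
                         seed: int, drift_px: float = 0.0,
                         ) -> tuple[list[np.ndarray], FieldGroundTruth]:
    """Simulate one field imaged at every kinetics timepoint.

    Returns (images, ground_truth): one image per timepoint with identical
    nucleus positions (centroids jittered by at most ``drift_px`` when
    requested) and focus counts following :func:`sample_kinetics`.
    """
    gt = plant_field(layout, optics, kinetics, seed, drift_px=drift_px)
    render_seeds = SeedSequence(seed).spawn(4)[3].spawn(len(kinetics.timepoints_min))
    images = [render_field(layout, optics, noise, gt,
                           default_rng(s), timepoint_min=t)
              for s, t in zip(render_seeds, kinetics.timepoints_min)]
    return images, gt


# ---------------------------------------------------------------------------
# capture simulation
# ---------------------------------------------------------------------------

def simulate_capture_rounds(params: CaptureParams, seed: int | Generator) -> CaptureOutcome:
    """Simulate repeated magnetic capture of bead-tagged cells.

    Round 1 captures positives ~ Binomial(n_tagged, p_capture_positive) and
    carries over negatives ~ Binomial(n_total - n_tagged,
    p_carryover_negative); each later round re-applies the same retention
    probabilities to the cells captured in the previous round.
    """
    rng = seed if isinstance(seed, Generator) else default_rng(seed)
    pos = params.n_tagged
    neg = params.n_total_cells - params.n_tagged
    hist = []
    for rnd in range(1, params.n_rounds + 1):
        pos = int(rng.binomial(pos, params.p_capture_positive))
        neg = int(rng.binomial(neg, params.p_carryover_negative))
        hist.append((rnd, pos, neg))
    history = pd.DataFrame(hist, columns=["round", "n_positive", "n_negative"])
    return CaptureOutcome(
        n_total_cells=params.n_total_cells, n_tagged=params.n_tagged,
        n_rounds=params.n_rounds, n_captured_positive=pos,
        n_captured_negative=neg, history=history)
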