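"""Automated nuclear 53BP1-focus quantification.

The pipeline mirrors the classical workflow for counting DNA-damage foci in
fluorescence images of nuclei that retain a diffuse pool of free GFP-53BP1:

1. nuclei are segmented on the diffuse background signal by global Otsu
   thresholding after Gaussian smoothing;
2. candidate objects are filtered on size, signal saturation, and shape
   (solidity), optionally discarding border-touching objects;
3. a band-pass (difference-of-Gaussians) filter, computed as a masked
   normalized convolution over the nucleus foreground, enhances objects
   near the size of a single focus without responding to the nuclear
   boundary;
4. foci are called as local maxima of the enhanced image inside each
   retained nucleus, above a per-nucleus automatic threshold (see
   :func:`detect_foci`), with maxima closer than a minimum separation
   merged keeping the brighter one.

Images are 2-D integer or float arrays; coordinates are 0-based (row, col);
masks use 8-connectivity.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from skimage import measure, morphology
from skimage.filters import gaussian, threshold_otsu


@dataclass
class DetectionParams:
    """Tunable knobs of the focus-detection pipeline.

    Band-pass sigmas default to focus_diameter_px / 4 and
    focus_diameter_px / 2 (the classic 1:2 difference-of-Gaussians ratio,
    which keeps the background estimate local enough that neighbouring
    foci do not bias it at realistic densities of ~10 foci per nucleus).
    The default per-nucleus threshold mode 'auto' combines a per-nucleus
    Otsu split of the enhanced values with a noise floor of
    ``local_threshold_k`` propagated noise SDs (see :func:`detect_foci`);
    'mean_sd' (mean + k * SD) and plain per-nucleus 'otsu' are available
    as alternatives. Minimum peak separation defaults to half the focus
    diameter; peaks closer than that merge into the brighter one.
    """

    nucleus_smooth_sigma_px: float = 2.0
    nucleus_area_min_px: float = 800.0
    nucleus_area_max_px: float = 6000.0
    saturation_fraction_max: float = 0.05
    solidity_min: float = 0.85
    exclude_border: bool = True
    saturation_level: float = 65535.0
    focus_diameter_px: float = 5.0
    bandpass_sigma_low_px: float | None = None
    bandpass_sigma_high_px: float | None = None
    local_threshold_k: float = 4.0
    local_threshold_mode: str = "auto"  # or "mean_sd" / "otsu"
    min_separation_px: float | None = None
    rim_exclusion_px: float | None = None  # None -> 2 * nucleus_smooth_sigma_px

    def __post_init__(self) -> None:
        if self.bandpass_sigma_low_px is None:
            self.bandpass_sigma_low_px = self.focus_diameter_px / 4.0
        if self.bandpass_sigma_high_px is None:
            self.bandpass_sigma_high_px = self.focus_diameter_px / 2.0
        if self.min_separation_px is None:
            self.min_separation_px = self.focus_diameter_px / 2.0
        if self.rim_exclusion_px is None:
            # smoothing inflates the mask by a skirt of ~2 sigma; one extra
            # pixel covers pixelation of the skirt boundary
            self.rim_exclusion_px = 2.0 * self.nucleus_smooth_sigma_px + 2.0
        if self.nucleus_area_min_px >= self.nucleus_area_max_px:
            raise ValueError("nucleus_area_min_px must be < nucleus_area_max_px")
        if not (0.0 <= self.saturation_fraction_max <= 1.0):
            raise ValueError("saturation_fraction_max must lie in [0, 1]")
        if not (0.0 < self.solidity_min <= 1.0):
            raise ValueError("solidity_min must lie in (0, 1]")
        if self.bandpass_sigma_low_px >= self.bandpass_sigma_high_px:
            raise ValueError("bandpass_sigma_low_px must be < bandpass_sigma_high_px")
        if self.min_separation_px < 1:
            raise ValueError("min_separation_px must be >= 1")
        if self.local_threshold_mode not in ("auto", "mean_sd", "otsu"):
            raise ValueError(
                "local_threshold_mode must be 'auto', 'mean_sd' or 'otsu'")


NUCLEUS_COLUMNS = ["label", "centroid_row", "centroid_col", "area_px",
                   "mean_intensity", "max_intensity", "solidity",
                   "saturated_frac", "on_border", "passed_filters"]


def _empty_records() -> pd.DataFrame:
    return pd.DataFrame(columns=NUCLEUS_COLUMNS).astype(
        {"label": int, "passed_filters": bool, "on_border": bool})


def segment_nuclei(image: np.ndarray, params: DetectionParams
                   ) -> tuple[np.ndarray, pd.DataFrame]:
    """Segment nuclei by Otsu thresholding the smoothed image.

    Returns an 8-connectivity label mask and one record per connected
    component (centroid, area, intensity and shape statistics measured on
    the original image). A constant image yields zero nuclei with a warning
    rather than an exception.
    """
    image = np.asarray(image)
    if image.ndim != 2:
        raise ValueError("image must be 2-D single channel")
    img = image.astype(float)
    smoothed = gaussian(img, sigma=params.nucleus_smooth_sigma_px,
                        preserve_range=True)
    if np.ptp(smoothed) == 0:
        warnings.warn("constant image: no nuclei detected", stacklevel=2)
        return np.zeros(image.shape, dtype=np.int32), _empty_records()
    # Otsu on log intensities: robust to the strong dark/bright class
    # imbalance of sparse fields and to rare saturated debris, and exactly
    # equivariant to multiplicative intensity rescaling (scaling becomes a
    # shift in log space). The epsilon is tied to the image maximum so the
    # transform itself is scale-free.
    smoothed = np.clip(smoothed, 0.0, None)
    eps = 1e-3 * smoothed.max()
    log_im = np.log(smoothed + eps)
    thr = threshold_otsu(log_im)
    fg = ndi.binary_fill_holes(log_im > thr)
    labels = measure.label(fg, connectivity=2).astype(np.int32)
    if labels.max() == 0:
        return labels, _empty_records()

    props = measure.regionprops(labels, intensity_image=img)
    h, w = image.shape
    rows = []
    for p in props:
        minr, minc, maxr, maxc = p.bbox
        on_border = minr == 0 or minc == 0 or maxr == h or maxc == w
        sat_frac = float(np.mean(p.image_intensity[p.image]
                                 >= params.saturation_level))
        rows.append((p.label, p.centroid[0], p.centroid[1], float(p.area),
                     float(p.intensity_mean), float(p.intensity_max),
                     float(p.solidity), sat_frac, on_border, True))
    records = pd.DataFrame(rows, columns=NUCLEUS_COLUMNS)
    return labels, records


def filter_nuclei(records: pd.DataFrame, mask: np.ndarray,
                  params: DetectionParams
                  ) -> tuple[pd.DataFrame, np.ndarray]:
    """Drop segmented objects that cannot be single healthy nuclei.

    Removes objects outside the allowed area range, objects whose saturated
    pixel fraction exceeds ``saturation_fraction_max``, low-solidity
    (ragged or fused) objects, and optionally border-touching objects.
    Survivors are relabeled consecutively from 1 in both the returned
    records (column ``label``; the original label is kept as
    ``original_label``) and the returned mask.
    """
    if records.empty:
        return records.copy(), mask.copy()
    keep = (
        (records["area_px"] >= params.nucleus_area_min_px)
        & (records["area_px"] <= params.nucleus_area_max_px)
        & (records["saturated_frac"] <= params.saturation_fraction_max)
        & (records["solidity"] >= params.solidity_min)
    )
    if params.exclude_border:
        keep &= ~records["on_border"]
    survivors = records[keep].reset_index(drop=True).copy()
    survivors["original_label"] = survivors["label"]
    survivors["label"] = np.arange(1, len(survivors) + 1)

    relabel = np.zeros(int(mask.max()) + 1, dtype=mask.dtype)
    for new, old in zip(survivors["label"], survivors["original_label"]):
        relabel[int(old)] = new
    new_mask = relabel[mask]
    dropped = records[~keep].copy()
    dropped["passed_filters"] = False
    return survivors, new_mask


def bandpass_enhance(image: np.ndarray, params: DetectionParams,
                     foreground_mask: np.ndarray | None = None) -> np.ndarray:
    """Difference-of-Gaussians band-pass tuned to the focus diameter.

    Computed in floating point: blur(sigma_low) - blur(sigma_high). The
    response is ~0 on constant regions and maximal for blobs whose size
    matches ``focus_diameter_px``.

    When ``foreground_mask`` (e.g. the union of nucleus masks) is given,
    both blurs are masked normalized convolutions — blur(image * m) /
    blur(m) — so the sharp nucleus/background boundary contributes no
    band-pass response and foci near the nuclear rim keep their true
    amplitude; pixels outside the mask are set to 0.
    """
    img = np.asarray(image, dtype=float)
    if foreground_mask is None:
        low = gaussian(img, sigma=params.bandpass_sigma_low_px, preserve_range=True)
        high = gaussian(img, sigma=params.bandpass_sigma_high_px, preserve_range=True)
        return low - high
    m = np.asarray(foreground_mask).astype(float)

    def nblur(sigma: float) -> np.ndarray:
        num = gaussian(img * m, sigma=sigma, preserve_range=True)
        den = gaussian(m, sigma=sigma, preserve_range=True)
        return num / np.maximum(den, 1e-12)

    enh = nblur(params.bandpass_sigma_low_px) - nblur(params.bandpass_sigma_high_px)
    return np.where(m > 0, enh, 0.0)


def _gauss_kernel_1d(sigma: float) -> np.ndarray:
    """Discrete 1-D Gaussian kernel matching scipy/skimage truncation (4 sigma)."""
    half = int(4.0 * sigma + 0.5)
    x = np.arange(-half, half + 1, dtype=float)
    k = np.exp(-x ** 2 / (2 * sigma ** 2))
    return k / k.sum()


def _sep_conv(mask: np.ndarray, kr: np.ndarray, kc: np.ndarray) -> np.ndarray:
    out = ndi.convolve1d(mask.astype(float), kr, axis=0, mode="constant")
    return ndi.convolve1d(out, kc, axis=1, mode="constant")


def nc_noise_factor(foreground_mask: np.ndarray, params: DetectionParams
                    ) -> np.ndarray:
    """Pixelwise noise-amplification factor of the masked band-pass filter.

    For white noise of unit variance on the foreground, the masked
    normalized-convolution difference-of-Gaussians at pixel x is a weighted
    sum with weights w = w_low - w_high determined by the mask geometry;
    its standard deviation is sqrt(sum w^2), returned here as a map. Near
    the nucleus rim fewer pixels contribute, so the factor rises above its
    interior value — a constant threshold would either flood the rim with
    false maxima or reject dim interior foci.
    """
    m = np.asarray(foreground_mask).astype(float)
    kl = _gauss_kernel_1d(params.bandpass_sigma_low_px)
    kh = _gauss_kernel_1d(params.bandpass_sigma_high_px)
    # pad the short kernel to the long one's support for the cross term
    pad = (len(kh) - len(kl)) // 2
    kl_p = np.pad(kl, (max(pad, 0), max(pad, 0)))
    kh_p = np.pad(kh, (max(-pad, 0), max(-pad, 0)))

    a_l = _sep_conv(m, kl, kl)
    a_h = _sep_conv(m, kh, kh)
    q_l = _sep_conv(m, kl ** 2, kl ** 2)
    q_h = _sep_conv(m, kh ** 2, kh ** 2)
    cross = _sep_conv(m, kl_p * kh_p, kl_p * kh_p)
    tiny = 1e-12
    var = (q_l / np.maximum(a_l, tiny) ** 2
           + q_h / np.maximum(a_h, tiny) ** 2
           - 2 * cross / np.maximum(a_l * a_h, tiny))
    return np.sqrt(np.clip(var, 0.0, None))


def core_mask(nucleus_mask: np.ndarray, params: DetectionParams) -> np.ndarray:
    """Foreground eroded by ``rim_exclusion_px``.

    Smoothing before Otsu inflates each nucleus by a dim skirt of roughly
    2 * nucleus_smooth_sigma_px; the bright/dark step across that skirt
    lies *inside* the raw mask and would dominate any band-pass response.
    Enhancement and focus calling therefore run on this eroded core.
    """
    fg = np.asarray(nucleus_mask) > 0
    r = int(round(params.rim_exclusion_px))
    if r <= 0:
        return fg
    return ndi.binary_erosion(fg, structure=morphology.disk(r))


def _robust_noise_sd(values_image: np.ndarray, region: np.ndarray) -> float:
    """Per-region white-noise SD from horizontal first differences
    (median absolute deviation, consistent for Gaussian noise); smooth
    structure and sparse focus edges barely move the median."""
    pair = region[:, :-1] & region[:, 1:]
    if pair.sum() < 8:
        return 0.0
    d = (values_image[:, 1:] - values_image[:, :-1])[pair]
    return 1.4826 * float(np.median(np.abs(d - np.median(d)))) / np.sqrt(2.0)


def _local_maxima_candidates(enhanced: np.ndarray, region_mask: np.ndarray
                             ) -> list[tuple[int, int]]:
    """3x3 local maxima inside a boolean region; each flat plateau
    contributes its lexicographically smallest (row, col) pixel."""
    maxf = ndi.maximum_filter(enhanced, size=3, mode="nearest")
    cand = (enhanced == maxf) & region_mask
    if not cand.any():
        return []
    # collapse plateaus: connected candidates with equal value -> one seed
    lab, n = ndi.label(cand, structure=np.ones((3, 3), dtype=bool))
    out = []
    for i in range(1, n + 1):
        rr, cc = np.nonzero(lab == i)
        k = np.lexsort((cc, rr))[0]
        out.append((int(rr[k]), int(cc[k])))
    return out


def detect_foci(enhanced: np.ndarray, nucleus_mask: np.ndarray,
                records: pd.DataFrame, params: DetectionParams,
                image: np.ndarray | None = None) -> pd.DataFrame:
    """Call foci per nucleus as thresholded local maxima of the enhanced image.

    The per-nucleus automatic threshold depends on
    ``params.local_threshold_mode``:

    * ``'auto'`` (default, requires ``image``): a candidate must exceed
      both the per-nucleus Otsu threshold of the enhanced values (which
      separates focus pixels from the in-nucleus background however dense
      the foci are) and a pixelwise noise floor
      median_j + k * sigma_j * f(x), where sigma_j is the nucleus' white
      noise SD estimated from first differences of the original image and
      f(x) is the band-pass noise-amplification map
      (:func:`nc_noise_factor`) — which keeps empty, noise-only nuclei at
      zero calls. Both pieces are equivariant under intensity rescaling.
    * ``'mean_sd'``: mean + k * SD of enhanced values within the nucleus.
    * ``'otsu'``: per-nucleus Otsu of the enhanced values alone.

    Maxima closer than ``min_separation_px`` are merged keeping the
    brighter one (ties broken toward the smaller (row, col)). Nuclei of
    area < 9 px yield no foci, with a warning.
    """
    if enhanced.shape != nucleus_mask.shape:
        raise ValueError("enhanced image and nucleus mask shapes differ")
    mode = params.local_threshold_mode
    if mode == "auto" and image is None:
        raise ValueError("'auto' threshold mode needs the original image")
    core = core_mask(nucleus_mask, params)
    noise_factor = nc_noise_factor(core, params) if mode == "auto" else None
    img_f = np.asarray(image, dtype=float) if image is not None else None

    n_labels = int(nucleus_mask.max())
    slices = ndi.find_objects(nucleus_mask, max_label=n_labels)
    out_rows = []
    for rec in records.itertuples():
        label = int(rec.label)
        if label < 1 or label > n_labels or slices[label - 1] is None:
            continue
        sr, sc = slices[label - 1]
        # pad one pixel so 3x3 maxima at the bbox edge see their neighbours
        sr = slice(max(sr.start - 1, 0), min(sr.stop + 1, enhanced.shape[0]))
        sc = slice(max(sc.start - 1, 0), min(sc.stop + 1, enhanced.shape[1]))
        sub = enhanced[sr, sc]
        full = nucleus_mask[sr, sc] == label
        if int(full.sum()) < 9:
            warnings.warn(f"nucleus {label} smaller than 9 px: no foci called",
                          stacklevel=2)
            continue
        region = full & core[sr, sc]
        n_px = int(region.sum())
        if n_px == 0:
            continue
        vals = sub[region]
        flat = np.ptp(vals) == 0

        def _passes(r: int, c: int) -> bool:
            return bool(sub[r, c] > thr_base
                        and (floor_map is None or sub[r, c] > floor_map[r, c]))

        floor_map = None
        if mode == "otsu":
            thr_base = threshold_otsu(vals) if not flat else np.inf
        elif mode == "mean_sd":
            thr_base = (float(vals.mean())
                        + params.local_threshold_k * float(vals.std()))
            # strictly-greater rule alone is degenerate on exactly flat input
            thr_base = max(thr_base, float(vals.mean())
                           + 1e-9 * abs(float(rec.mean_intensity)))
        else:  # auto
            thr_base = threshold_otsu(vals) if not flat else np.inf
            med = float(np.median(vals))
            sigma_j = _robust_noise_sd(img_f[sr, sc], region)
            floor = med + params.local_threshold_k * sigma_j * noise_factor[sr, sc]
            # numerical floor: a noiseless flat nucleus has sigma_j == 0 and
            # enhanced residuals ~1e-12 * intensity; keep those at zero calls
            floor_map = np.maximum(floor,
                                   med + 1e-9 * abs(float(rec.mean_intensity)))
            if flat:
                thr_base = -np.inf  # rely on the noise floor
        cands = [(r, c) for (r, c) in _local_maxima_candidates(sub, region)
                 if _passes(r, c)]
        # merge close maxima, brighter wins; deterministic order
        cands.sort(key=lambda rc: (-sub[rc[0], rc[1]], rc[0], rc[1]))
        accepted: list[tuple[int, int]] = []
        for r, c in cands:
            if all(np.hypot(r - ar, c - ac) >= params.min_separation_px
                   for ar, ac in accepted):
                accepted.append((r, c))
        for r, c in accepted:
            out_rows.append((label, r + sr.start, c + sc.start,
                             float(sub[r, c])))
    return pd.DataFrame(out_rows, columns=["nucleus_label", "row", "col",
                                           "enhanced_intensity"])


def count_table(foci: pd.DataFrame, records: pd.DataFrame,
                field_id: str | int, timepoint_min: float) -> pd.DataFrame:
    """Per-nucleus focus counts for one field and timepoint.

    One row per retained nucleus (zero-focus nuclei included) with its
    focus count and mean nuclear intensity. A focus labeled with a nucleus
    absent from ``records`` is a consistency error.
    """
    known = set(records["label"].astype(int)) if len(records) else set()
    if len(foci):
        unknown = set(foci["nucleus_label"].astype(int)) - known
        if unknown:
            raise ValueError(f"foci reference filtered-out nuclei: {sorted(unknown)}")
    counts = (foci.groupby("nucleus_label").size() if len(foci)
              else pd.Series(dtype=int))
    rows = []
    for rec in records.itertuples():
        label = int(rec.label)
        rows.append((field_id, float(timepoint_min), label,
                     int(counts.get(label, 0)), float(rec.mean_intensity)))
    return pd.DataFrame(rows, columns=["field_id", "timepoint_min",
                                       "nucleus_label", "focus_count",
                                       "mean_nuclear_intensity"])


def interior_mean_intensity(image: np.ndarray, mask: np.ndarray,
                            records: pd.DataFrame, params: DetectionParams
                            ) -> pd.DataFrame:
    """Re-measure per-nucleus mean intensity on the eroded interior.

    The raw segmentation component includes the dim smoothed boundary
    skirt, whose extent varies from cell to cell and biases whole-object
    means; the interior is the stable per-cell brightness readout.
    """
    core = core_mask(mask, params)
    img = np.asarray(image, dtype=float)
    records = records.copy()
    n_labels = int(mask.max())
    slices = ndi.find_objects(mask, max_label=n_labels)
    for i, rec in records.iterrows():
        label = int(rec["label"])
        if label < 1 or label > n_labels or slices[label - 1] is None:
            continue
        sl = slices[label - 1]
        region = (mask[sl] == label) & core[sl]
        if region.any():
            records.at[i, "mean_intensity"] = float(img[sl][region].mean())
    return records


def quantify_field(image: np.ndarray, params: DetectionParams,
                   field_id: str | int = 0, timepoint_min: float = 0.0
                   ) -> dict:
    """Run the full pipeline on one image.

    Returns a dict with the label mask, nucleus records, enhanced image,
    focus records, and the per-nucleus count table.
    """
    mask, records = segment_nuclei(image, params)
    records, mask = filter_nuclei(records, mask, params)
    records = interior_mean_intensity(image, mask, records, params)
    enhanced = bandpass_enhance(image, params,
                                foreground_mask=core_mask(mask, params))
    foci = detect_foci(enhanced, mask, records, params, image=image)
    table = count_table(foci, records, field_id, timepoint_min)
    return {"mask": mask, "records": records, "enhanced": enhanced,
            "foci": foci, "table": table}
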