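"""Angiogenesis quantification from trunk fluorescence images.

A single fluorescence image of a vascular-reporter embryo (anterior left,
dorsal up) is reduced to a per-embryo :class:`VesselQuant`:

1. the embryo silhouette is segmented (automatic histogram threshold,
   morphological closing, largest connected component) and its length
   measured along the principal axis;
2. the trunk region of interest (ROI) is split off at the yolk bulge — the
   global maximum of the column-wise thickness profile — and runs to the
   posterior tip;
3. within the ROI a vessel mask is extracted (top-hat background
   subtraction, threshold, thin-object closing, removal of fluorescent
   debris not connected to the axial vessels);
4. the quantified readout is the total area *enclosed* by vessels — the
   topological holes of the vessel mask bounded by the ISVs, the DLAV and
   the DA/PCV.  An incomplete ISV ladder or a missing DLAV encloses
   nothing, which is what makes the measure sensitive to inhibition;
5. ISVs are counted by removing the two axial rails and measuring the
   vertical extent of the remaining rungs: *total* ISVs span at least 20 %
   of the rail separation, *complete* ISVs span at least 90 % of it and
   touch the DLAV band.

Treatment groups are called inhibited when their mean enclosed area is
significantly below the vehicle control (ANOVA + Dunnett against control).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import ndimage
from skimage import filters, measure, morphology

from .plate_model import AngioCategory, MIN_EMBRYOS_PER_GROUP
from .screen_stats import anova_dunnett

logger = logging.getLogger(__name__)

__all__ = [
    "EmbryoMask",
    "VesselQuant",
    "InhibitionCall",
    "segment_embryo",
    "split_head_tail",
    "extract_vessel_mask",
    "measure_enclosed_areas",
    "count_isvs",
    "call_inhibition",
    "analyze_image",
]


@dataclass(frozen=True)
class EmbryoMask:
    """Embryo silhouette with its principal-axis length and tail ROI."""

    mask: np.ndarray
    length_px: float
    roi: tuple[int, int, int, int] | None = None  # (row0, row1, col0, col1)


@dataclass(frozen=True)
class VesselQuant:
    """Per-embryo vessel quantification.

    ``total_isvs``/``complete_isvs`` are ``None`` when the axial rails could
    not be located (``rails_found`` False); enclosed-area measures are
    always defined (zero for an empty mask).
    """

    enclosed_area_px: int
    n_enclosed_regions: int
    total_isvs: int | None
    complete_isvs: int | None
    length_px: float
    rails_found: bool = True

    def __post_init__(self) -> None:
        if self.n_enclosed_regions == 0 and self.enclosed_area_px != 0:
            raise ValueError("no enclosed regions but nonzero enclosed area")
        if (
            self.total_isvs is not None
            and self.complete_isvs is not None
            and not 0 <= self.complete_isvs <= self.total_isvs
        ):
            raise ValueError("complete ISVs must be between 0 and total ISVs")


def segment_embryo(image: np.ndarray) -> EmbryoMask:
    """Segment the embryo body as the largest bright connected component.

    Automatic histogram thresholding, morphological closing to bridge small
    gaps, then the largest 8-connected foreground component.  A fluorescence
    image of a vascular reporter has three intensity classes — background,
    dimly fluorescent body, bright vessels — so a 3-class multi-Otsu split
    is tried first and its lowest threshold used (body and vessels are both
    foreground); genuinely bimodal images fall back to ordinary Otsu.
    Length is the extent of the component along its principal (major) axis.
    """
    img = np.asarray(image, dtype=float)
    if img.ndim != 2:
        raise ValueError("expected a single-channel 2-D image")
    if img.max() == img.min():
        raise ValueError("no embryo detected: image has no contrast")
    try:
        thresh = filters.threshold_multiotsu(img, classes=3)[0]
    except ValueError:  # too few distinct intensities for a 3-class split
        thresh = filters.threshold_otsu(img)
    fg = img > thresh
    if not fg.any():
        raise ValueError("no embryo detected: empty foreground")
    fg = morphology.closing(fg, morphology.disk(3))
    labels = measure.label(fg, connectivity=2)
    if labels.max() == 0:
        raise ValueError("no embryo detected: empty foreground")
    sizes = np.bincount(labels.ravel())
    sizes[0] = 0
    mask = labels == sizes.argmax()

    coords = np.column_stack(np.nonzero(mask)).astype(float)
    centred = coords - coords.mean(axis=0)
    # principal axis via the 2x2 covariance eigenvector
    cov = centred.T @ centred / len(centred)
    eigvals, eigvecs = np.linalg.eigh(cov)
    axis = eigvecs[:, np.argmax(eigvals)]
    proj = centred @ axis
    length = float(proj.max() - proj.min())
    return EmbryoMask(mask=mask, length_px=length)


def split_head_tail(embryo: EmbryoMask) -> EmbryoMask:
    """Locate the tail ROI posterior to the yolk bulge.

    The column-wise thickness profile of the mask (anterior assumed left)
    peaks at the yolk bulge; the ROI spans from just posterior of that peak
    to the posterior tip.  When the profile is degenerate — effectively
    monotone or flat, as for a plain rectangle — the posterior 60 % of the
    embryo is used and a warning logged.
    """
    mask = embryo.mask
    if not mask.any():
        raise ValueError("empty embryo mask")
    cols = np.flatnonzero(mask.any(axis=0))
    c_lo, c_hi = cols[0], cols[-1]
    thickness = mask[:, c_lo : c_hi + 1].sum(axis=0).astype(float)

    # rightmost column achieving the global maximum (plateaus resolve to
    # their posterior edge); the trunk level is the posterior-40% median
    peak = int(np.flatnonzero(thickness == thickness.max())[-1])
    peak_val = thickness[peak]
    trunk_level = float(np.median(thickness[int(0.6 * thickness.size) :]))
    degenerate = peak_val < 1.15 * trunk_level or peak >= 0.9 * thickness.size
    if degenerate:
        logger.warning(
            "thickness profile degenerate (no clear yolk bulge); "
            "falling back to posterior 60%% ROI"
        )
        start = c_lo + int(0.4 * (c_hi - c_lo))
    else:
        start = c_lo + peak + 1

    rows = np.flatnonzero(mask[:, start : c_hi + 1].any(axis=1))
    roi = (int(rows[0]), int(rows[-1]) + 1, int(start), int(c_hi) + 1)
    return EmbryoMask(mask=mask, length_px=embryo.length_px, roi=roi)


def _roi_view(arr: np.ndarray, roi: tuple[int, int, int, int]) -> np.ndarray:
    r0, r1, c0, c1 = roi
    return arr[r0:r1, c0:c1]


def extract_vessel_mask(
    image: np.ndarray,
    roi: tuple[int, int, int, int],
    tophat_radius: int = 12,
    min_axial_width_frac: float = 0.25,
) -> np.ndarray:
    """Boolean vessel mask (DA/PCV, DLAV, ISVs) within the tail ROI.

    White top-hat filtering removes the smooth body/background fluorescence,
    Otsu's threshold binarises the residual bright ridges and a small
    closing heals 1-px breaks.  Components neither wide enough to be an
    axial vessel (bounding box at least ``min_axial_width_frac`` of the ROI
    width: DA/PCV, DLAV or a DLAV fragment) nor connected to one after a
    1-px dilation are discarded as stray fluorescence.  Returns a full-size
    mask that is empty outside the ROI.
    """
    img = np.asarray(image, dtype=float)
    sub = _roi_view(img, roi)
    if sub.size == 0:
        return np.zeros_like(img, dtype=bool)

    tophat = morphology.white_tophat(sub, morphology.disk(tophat_radius))
    if tophat.max() <= 0:
        return np.zeros_like(img, dtype=bool)
    thresh = filters.threshold_otsu(tophat)
    # guard against pure-noise ROIs where Otsu splits the noise histogram:
    # demand a minimum contrast over the residual background scale
    scale = np.median(np.abs(tophat - np.median(tophat)))
    thresh = max(thresh, 6.0 * scale)
    vessel = tophat > thresh
    vessel = morphology.closing(vessel, morphology.disk(1))
    vessel = morphology.remove_small_objects(vessel, max_size=7)

    labels = measure.label(vessel, connectivity=2)
    if labels.max() == 0:
        return np.zeros_like(img, dtype=bool)
    roi_w = sub.shape[1]
    keep = np.zeros(labels.max() + 1, dtype=bool)
    slices = ndimage.find_objects(labels)
    for lab, sl in enumerate(slices, start=1):
        if sl is not None and (sl[1].stop - sl[1].start) >= min_axial_width_frac * roi_w:
            keep[lab] = True
    axial = keep[labels]
    if axial.any():
        grown = morphology.dilation(axial, morphology.disk(1))
        attached = np.unique(labels[grown & (labels > 0)])
        keep[attached] = True
        vessel = keep[labels]
    else:
        vessel = np.zeros_like(vessel)

    out = np.zeros_like(img, dtype=bool)
    _roi_view(out, roi)[:] = vessel
    return out


def measure_enclosed_areas(
    vessel_mask: np.ndarray, roi: tuple[int, int, int, int]
) -> tuple[int, int]:
    """Total area and count of regions fully enclosed by vessels in the ROI.

    Enclosed regions are the topological holes of the vessel mask:
    4-connected background components that do not touch the ROI border.
    Regions bounded only partly by vessels (open toward the border, as when
    the DLAV is missing or an ISV is incomplete) are not counted.
    """
    sub = _roi_view(np.asarray(vessel_mask, dtype=bool), roi)
    if sub.size == 0 or not sub.any():
        return 0, 0
    four_conn = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]])
    holes, n = ndimage.label(~sub, structure=four_conn)
    border = np.unique(
        np.concatenate([holes[0, :], holes[-1, :], holes[:, 0], holes[:, -1]])
    )
    border_set = set(border[border > 0].tolist())
    sizes = np.bincount(holes.ravel(), minlength=n + 1)
    area = 0
    count = 0
    for lab in range(1, n + 1):
        if lab not in border_set:
            area += int(sizes[lab])
            count += 1
    return area, count


def _rail_bands(
    sub: np.ndarray, min_run_frac: float = 0.5
) -> tuple[tuple[int, int], tuple[int, int]] | None:
    """Locate the dorsal (DLAV) and ventral (DA/PCV) rail row bands.

    Rail rows are rows whose vessel occupancy spans at least
    ``min_run_frac`` of the ROI width.  The topmost contiguous block of
    rail rows is the DLAV band, the bottommost the DA/PCV band; they must
    be distinct and separated by a trunk gap.
    """
    occupancy = sub.sum(axis=1) / sub.shape[1]
    rail_rows = np.flatnonzero(occupancy >= min_run_frac)
    if rail_rows.size == 0:
        return None
    blocks = np.split(rail_rows, np.flatnonzero(np.diff(rail_rows) > 1) + 1)
    if len(blocks) < 2:
        return None
    top, bottom = blocks[0], blocks[-1]
    dlav = (int(top[0]), int(top[-1]) + 1)
    axial = (int(bottom[0]), int(bottom[-1]) + 1)
    if axial[0] - dlav[1] < 4:
        return None
    return dlav, axial


def count_isvs(
    vessel_mask: np.ndarray,
    roi: tuple[int, int, int, int],
    total_frac: float = 0.2,
    complete_frac: float = 0.9,
) -> tuple[int | None, int | None, bool]:
    """Count total and complete ISVs between the axial rails.

    Returns ``(total, complete, rails_found)``.  The DLAV and DA/PCV rail
    bands are removed from the mask; each remaining connected component is
    an ISV candidate whose vertical span is compared with the rail
    separation: at least ``total_frac`` of it to count at all, at least
    ``complete_frac`` plus contact with the DLAV band to count as complete.
    When no rail pair is found the counts are reported missing.
    """
    sub = _roi_view(np.asarray(vessel_mask, dtype=bool), roi)
    if sub.size == 0 or not sub.any():
        return None, None, False
    bands = _rail_bands(sub)
    if bands is None:
        return None, None, False
    (dlav_lo, dlav_hi), (ax_lo, ax_hi) = bands
    separation = ax_lo - dlav_hi

    rungs = sub.copy()
    rungs[:dlav_lo, :] = False
    rungs[dlav_lo:dlav_hi, :] = False
    rungs[ax_lo:ax_hi, :] = False
    rungs[ax_hi:, :] = False
    labels = measure.label(rungs, connectivity=2)
    total = 0
    complete = 0
    for sl in ndimage.find_objects(labels):
        if sl is None:
            continue
        height = sl[0].stop - sl[0].start
        if height < total_frac * separation:
            continue
        total += 1
        touches_dlav = sl[0].start <= dlav_hi
        if height >= complete_frac * separation and touches_dlav:
            complete += 1
    return total, complete, True


def analyze_image(image: np.ndarray) -> VesselQuant:
    """Full per-embryo pipeline: segmentation -> ROI -> vessels -> readouts."""
    embryo = split_head_tail(segment_embryo(image))
    assert embryo.roi is not None
    vessels = extract_vessel_mask(image, embryo.roi)
    area, n_regions = measure_enclosed_areas(vessels, embryo.roi)
    total, complete, rails_found = count_isvs(vessels, embryo.roi)
    return VesselQuant(
        enclosed_area_px=area,
        n_enclosed_regions=n_regions,
        total_isvs=total,
        complete_isvs=complete,
        length_px=embryo.length_px,
        rails_found=rails_found,
    )


@dataclass(frozen=True)
class InhibitionCall:
    """Group-level anti-angiogenesis call with its supporting statistics."""

    category: AngioCategory
    adjusted_p: float
    treated_mean_area: float
    control_mean_area: float
    treated_mean_total_isvs: float | None
    treated_mean_complete_isvs: float | None


def call_inhibition(
    treated: Sequence[VesselQuant],
    control: Sequence[VesselQuant],
    alpha: float = 0.05,
) -> InhibitionCall:
    """Call a treated group inhibited versus vehicle control.

    The group means of enclosed vessel area are compared by one-way ANOVA
    with Dunnett's adjustment (the two-group special case of the plate-wide
    analysis); the group is INHIBITED when the adjusted p-value is below
    ``alpha`` and the treated mean is below the control mean.  Mean total
    and complete ISV counts ride along as the deeper per-vessel readout.
    """
    if len(treated) < MIN_EMBRYOS_PER_GROUP or len(control) < MIN_EMBRYOS_PER_GROUP:
        raise ValueError(
            f"need at least {MIN_EMBRYOS_PER_GROUP} embryos per group "
            f"(got {len(treated)} treated, {len(control)} control)"
        )
    t_area = np.array([q.enclosed_area_px for q in treated], dtype=float)
    c_area = np.array([q.enclosed_area_px for q in control], dtype=float)
    _, comparisons = anova_dunnett([c_area, t_area], control_index=0, alpha=alpha)
    adj_p = comparisons[0].adjusted_p
    assert adj_p is not None
    inhibited = adj_p < alpha and t_area.mean() < c_area.mean()

    totals = [float(q.total_isvs) for q in treated if q.total_isvs is not None]
    completes = [float(q.complete_isvs) for q in treated if q.complete_isvs is not None]
    return InhibitionCall(
        category=AngioCategory.INHIBITED if inhibited else AngioCategory.NOT_INHIBITED,
        adjusted_p=float(adj_p),
        treated_mean_area=float(t_area.mean()),
        control_mean_area=float(c_area.mean()),
        treated_mean_total_isvs=float(np.mean(totals)) if totals else None,
        treated_mean_complete_isvs=float(np.mean(completes)) if completes else None,
    )
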