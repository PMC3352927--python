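"""Seeded synthetic phantoms with exact ground truth.

The generators emulate the two imaging readouts of the screening platform:

* **Heart videos** — two elliptical fluorescent chambers over a static body,
  whose radii contract with a pulsatile waveform at the atrial and
  ventricular frequencies.  A control heart beats both chambers at the same
  frequency; a 2:1 atrio-ventricular block beats the atrium at twice the
  ventricular rate; cardiac arrest is the zero-amplitude limit.  Sensor
  noise and (for QC tests) a slow whole-frame drift can be added.
* **Trunk vasculature images** — an embryo silhouette (head blob, ventral
  yolk bulge, tapering trunk) carrying bright vessels: the axial DA/PCV
  band, the dorsal DLAV rail (optionally gapped) and a ladder of ISV rungs,
  each either complete (reaching the DLAV) or truncated mid-height.
* **Dose-response tables** — four-parameter logistic curves with additive
  noise.

Ground truth is always computed from the generator parameters, never from
the rendered pixels, so it is an oracle independent of the analysis path.

The contraction waveform is a raised-cosine pulse raised to the third power
(a brief systole followed by a longer diastole, as in a real cardiac cycle)
plus a second-harmonic overtone emulating the biphasic wall motion of a
contraction/relaxation cycle, with the ventricle lagging the atrium by a
fixed fraction of the cycle (the atrio-ventricular delay).  The combination
was chosen so that the Euclidean-distance signal of a single-rhythm heart is
dominated by the beat frequency — its strongest harmonic carries under 15 %
of the fundamental's periodogram power across the physiological frequency
and amplitude range — matching the near-sinusoidal ED traces of healthy
hearts, while a 2:1 atrio-ventricular block yields two comparable spectral
components at the ventricular and atrial rates.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .cardio_analysis import FrameStack, BRADYCARDIA_BEATS_PER_15S
from .plate_model import CardioCategory

__all__ = [
    "HeartPhantomParams",
    "HeartPhantomTruth",
    "VesselPhantomParams",
    "VesselPhantomTruth",
    "make_heart_video",
    "make_vessel_image",
    "make_dose_response",
]


# ---------------------------------------------------------------------------
# Beating-heart video phantom
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class HeartPhantomParams:
    """Parameters of a synthetic beating-heart video.

    ``amp_ratio`` scales the ventricular contraction depth relative to the
    atrial one; ``motion_amp`` is the overall fractional radius contraction
    (0 switches both chambers off: cardiac arrest).  ``drift_px_per_frame``
    translates the whole scene to emulate an embryo moving during
    recording.  Intensities are on an 8-bit-like scale.
    """

    f_atrial_hz: float = 2.8
    f_ventricular_hz: float = 2.8
    amp_ratio: float = 1.0
    motion_amp: float = 0.35
    noise_sd: float = 2.0
    drift_px_per_frame: float = 0.0
    n_frames: int = 512
    fps: float = 30.0
    frame_shape: tuple[int, int] = (64, 64)
    seed: int = 0

    def __post_init__(self) -> None:
        nyq = self.fps / 2.0
        for f in (self.f_atrial_hz, self.f_ventricular_hz):
            if not 0.0 <= f < nyq:
                raise ValueError(f"frequency {f} Hz outside [0, {nyq}) Hz")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if not 0.0 <= self.motion_amp < 1.0:
            raise ValueError("motion_amp must be in [0, 1)")


@dataclass(frozen=True)
class HeartPhantomTruth:
    """Generator-side ground truth for one heart video."""

    category: CardioCategory
    heart_rate_hz: float
    frequencies_hz: tuple[float, ...]
    drifting: bool

    @property
    def beats_per_15s(self) -> float:
        return self.heart_rate_hz * 15.0


def _intended_category(p: HeartPhantomParams) -> HeartPhantomTruth:
    drifting = p.drift_px_per_frame != 0.0
    if p.motion_amp == 0.0:
        return HeartPhantomTruth(CardioCategory.CARDIAC_ARREST, 0.0, (), drifting)
    freqs = tuple(sorted({p.f_atrial_hz, p.f_ventricular_hz}))
    rate = freqs[0]  # first significant frequency convention
    if len(freqs) > 1:
        return HeartPhantomTruth(CardioCategory.ARRHYTHMIA_21, rate, freqs, drifting)
    if rate * 15.0 < BRADYCARDIA_BEATS_PER_15S:
        return HeartPhantomTruth(CardioCategory.BRADYCARDIA, rate, freqs, drifting)
    return HeartPhantomTruth(CardioCategory.NO_EFFECT, rate, freqs, drifting)


# contraction waveform constants: pulse sharpness, overtone weight and the
# atrio-ventricular lag as a fraction of the ventricular cycle
_PULSE_EXPONENT = 3
_OVERTONE = 0.5
_AV_LAG_CYCLES = 0.18


def _contraction(f_hz: float, t: np.ndarray, lag_s: float) -> np.ndarray:
    """Chamber contraction waveform: cubed raised-cosine pulse + overtone."""
    phase = 2.0 * math.pi * f_hz * (t - lag_s)
    pulse = ((1.0 + np.cos(phase)) / 2.0) ** _PULSE_EXPONENT
    return pulse + (_OVERTONE / 2.0) * np.cos(2.0 * phase)


def make_heart_video(params: HeartPhantomParams) -> tuple[FrameStack, HeartPhantomTruth]:
    """Render a beating-heart video and its ground truth.

    The two chambers sit diagonally in the field over a static dim body;
    each is an anti-aliased disc whose radius contracts by ``motion_amp``
    times the contraction waveform, the ventricle lagging the atrium by the
    atrio-ventricular delay.
    """
    p = params
    truth = _intended_category(p)
    h, w = p.frame_shape
    t = np.arange(p.n_frames) / p.fps
    rng = np.random.default_rng(p.seed)

    yy, xx = np.mgrid[0:h, 0:w].astype(np.float64)
    drift = p.drift_px_per_frame * np.arange(p.n_frames)

    # chamber centres and resting radii scale with the field of view
    c_at = (0.38 * h, 0.38 * w)
    c_ve = (0.62 * h, 0.62 * w)
    r_at = 0.17 * min(h, w)
    r_ve = 0.20 * min(h, w)

    depth_at = p.motion_amp
    depth_ve = p.motion_amp * p.amp_ratio
    zeros = np.zeros_like(t)
    pulse_at = _contraction(p.f_atrial_hz, t, 0.0) if depth_at > 0 else zeros
    lag_s = _AV_LAG_CYCLES / p.f_ventricular_hz if p.f_ventricular_hz > 0 else 0.0
    pulse_ve = _contraction(p.f_ventricular_hz, t, lag_s) if depth_ve > 0 else zeros
    rad_at = r_at * (1.0 - depth_at * pulse_at)
    rad_ve = r_ve * (1.0 - depth_ve * pulse_ve)

    body_r = 0.45 * min(h, w)
    if p.drift_px_per_frame == 0.0:
        d_body = np.hypot(yy - 0.5 * h, xx - 0.5 * w)
        d_at = np.hypot(yy - c_at[0], xx - c_at[1])
        d_ve = np.hypot(yy - c_ve[0], xx - c_ve[1])
        frames = 20.0 + 30.0 * np.clip(body_r - d_body, 0.0, 1.0)
        frames = np.broadcast_to(frames, (p.n_frames, h, w)).copy()
        frames += 140.0 * np.clip(rad_at[:, None, None] - d_at[None], 0.0, 1.0)
        frames += 140.0 * np.clip(rad_ve[:, None, None] - d_ve[None], 0.0, 1.0)
    else:
        frames = np.empty((p.n_frames, h, w), dtype=np.float64)
        for i in range(p.n_frames):
            dy = drift[i]
            d_body = np.hypot(yy - (0.5 * h + dy), xx - (0.5 * w + dy))
            frame = 20.0 + 30.0 * np.clip(body_r - d_body, 0.0, 1.0)
            for (cy0, cx0), r in ((c_at, rad_at[i]), (c_ve, rad_ve[i])):
                d = np.hypot(yy - (cy0 + dy), xx - (cx0 + dy))
                frame += 140.0 * np.clip(r - d, 0.0, 1.0)
            frames[i] = frame
    if p.noise_sd > 0:
        frames += rng.normal(0.0, p.noise_sd, size=frames.shape)
    stack = FrameStack(frames=frames, fps=p.fps)
    return stack, truth


# ---------------------------------------------------------------------------
# Trunk-vasculature image phantom
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class VesselPhantomParams:
    """Parameters of a synthetic trunk-vasculature image.

    The embryo lies horizontally, anterior left, dorsal up.  ``n_isvs``
    rungs are spaced evenly along the trunk; ``complete_flags[i]`` says
    whether rung *i* reaches the DLAV.  ``dlav_gaps`` are (start, end)
    fractions of the trunk span where the DLAV is missing.
    """

    n_isvs: int = 10
    complete_flags: tuple[bool, ...] | None = None
    isv_width_px: int = 4
    dlav_gaps: tuple[tuple[float, float], ...] = ()
    yolk_position_frac: float = 0.30
    noise_sd: float = 2.0
    image_shape: tuple[int, int] = (256, 512)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_isvs < 0:
            raise ValueError("n_isvs must be >= 0")
        if self.isv_width_px < 1:
            raise ValueError("ISV width must be >= 1 px")
        flags = self.complete_flags
        if flags is None:
            flags = (True,) * self.n_isvs
        flags = tuple(bool(f) for f in flags)
        if len(flags) != self.n_isvs:
            raise ValueError("complete_flags length must equal n_isvs")
        object.__setattr__(self, "complete_flags", flags)
        for lo, hi in self.dlav_gaps:
            if not (0.0 <= lo < hi <= 1.0):
                raise ValueError(f"invalid DLAV gap ({lo}, {hi})")
        if not 0.0 <= self.yolk_position_frac <= 0.9:
            raise ValueError("yolk_position_frac must be in [0, 0.9]")


@dataclass(frozen=True)
class VesselPhantomTruth:
    """Geometric ground truth for one vasculature image."""

    total_isvs: int
    complete_isvs: int
    n_enclosed_regions: int
    embryo_mask: np.ndarray = field(repr=False)
    vessel_mask: np.ndarray = field(repr=False)
    yolk_x_px: float
    embryo_x_extent: tuple[int, int]


def _dlav_present(gaps: tuple[tuple[float, float], ...], lo: float, hi: float) -> bool:
    """Whether the DLAV is continuous over the trunk-fraction span [lo, hi]."""
    return not any(g_lo < hi and g_hi > lo for g_lo, g_hi in gaps)


def make_vessel_image(params: VesselPhantomParams) -> tuple[np.ndarray, VesselPhantomTruth]:
    """Render a trunk fluorescence image and its geometric ground truth.

    Intensities: background ~10, embryo body ~70, vessels ~200 (8-bit-like
    scale) plus Gaussian noise.  The ground-truth enclosed-region count is
    the number of consecutive complete-ISV pairs whose DLAV span is
    gap-free; dangling incomplete rungs between them do not split a region.
    """
    p = params
    h, w = p.image_shape
    img = np.full((h, w), 10.0)
    body = np.zeros((h, w), dtype=bool)
    vessels = np.zeros((h, w), dtype=bool)

    yy, xx = np.mgrid[0:h, 0:w].astype(np.float64)

    # embryo silhouette: head disc, horizontal trunk band, ventral yolk bulge
    x0, x1 = 12, w - 12  # anterior/posterior extent
    trunk_top, trunk_bot = int(0.31 * h), int(0.70 * h)
    head_cx, head_cy, head_r = x0 + 45, (trunk_top + trunk_bot) // 2, 45
    body |= np.hypot(yy - head_cy, xx - head_cx) <= head_r
    body |= (yy >= trunk_top) & (yy <= trunk_bot) & (xx >= x0) & (xx <= x1)
    yolk_cx = x0 + p.yolk_position_frac * (x1 - x0)
    yolk = (((xx - yolk_cx) / 38.0) ** 2 + ((yy - 0.78 * h) / (0.26 * h)) ** 2) <= 1.0
    body |= yolk & (xx >= x0) & (xx <= x1)

    # vessel geometry, confined to the tail trunk posterior to the yolk
    vx0 = int(yolk_cx + 45)
    vx1 = x1 - 10
    dlav_rows = (int(0.345 * h), int(0.345 * h) + 6)   # dorsal rail
    da_rows = (int(0.645 * h), int(0.645 * h) + 8)     # DA/PCV axial band
    span = vx1 - vx0

    def frac_to_x(f: float) -> int:
        return int(round(vx0 + f * span))

    # DA/PCV: always continuous
    vessels[da_rows[0]: da_rows[1], vx0:vx1] = True
    # DLAV minus gaps
    dlav_cols = np.ones(w, dtype=bool)
    dlav_cols[:vx0] = False
    dlav_cols[vx1:] = False
    for lo, hi in p.dlav_gaps:
        dlav_cols[frac_to_x(lo): frac_to_x(hi)] = False
    vessels[dlav_rows[0]: dlav_rows[1], dlav_cols] = True

    # ISV rungs, evenly spaced; incomplete rungs stop ~55 % of the way up
    isv_fracs = (
        (np.arange(p.n_isvs) + 0.5) / p.n_isvs if p.n_isvs else np.array([])
    )
    mid_row = int(da_rows[0] - 0.55 * (da_rows[0] - dlav_rows[1]))
    for frac, complete in zip(isv_fracs, p.complete_flags):
        cx = frac_to_x(frac)
        half = p.isv_width_px / 2.0
        col_lo, col_hi = int(math.floor(cx - half)), int(math.ceil(cx + half))
        top = dlav_rows[0] if complete else mid_row
        vessels[top: da_rows[1], col_lo:col_hi] = True

    img[body] = 70.0
    img[vessels & body] = 200.0
    rng = np.random.default_rng(p.seed)
    if p.noise_sd > 0:
        img = img + rng.normal(0.0, p.noise_sd, size=img.shape)

    # ground truth from geometry alone
    complete_x = [f for f, c in zip(isv_fracs, p.complete_flags) if c]
    n_enclosed = sum(
        _dlav_present(p.dlav_gaps, lo, hi)
        for lo, hi in zip(complete_x[:-1], complete_x[1:])
    )
    truth = VesselPhantomTruth(
        total_isvs=p.n_isvs,
        complete_isvs=int(sum(p.complete_flags)),
        n_enclosed_regions=int(n_enclosed),
        embryo_mask=body,
        vessel_mask=vessels & body,
        yolk_x_px=float(yolk_cx),
        embryo_x_extent=(x0, x1),
    )
    return img, truth


# ---------------------------------------------------------------------------
# Dose-response tables
# ---------------------------------------------------------------------------


def make_dose_response(
    ic50: float,
    hill: float,
    top: float,
    bottom: float,
    doses: "np.ndarray | list[float]",
    noise_sd: float = 0.0,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Sample a variable-slope sigmoidal inhibition curve.

    response = bottom + (top - bottom) / (1 + (dose / ic50)**hill) + noise.
    At ``dose == ic50`` the noiseless response is the midpoint
    ``(top + bottom) / 2``.
    """
    doses = np.asarray(doses, dtype=float)
    if np.any(doses <= 0):
        raise ValueError("doses must be > 0")
    response = bottom + (top - bottom) / (1.0 + (doses / ic50) ** hill)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        response = response + rng.normal(0.0, noise_sd, size=doses.shape)
    return doses, response
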