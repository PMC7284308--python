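"""Synthetic cardiac-microtissue data with exact ground truth.

Every input the analysis pipelines consume can be generated here:

* confocal-like multichannel stacks of ellipsoidal nuclei with known
  positions, sizes, identities and proliferative flags, degraded by a planar
  illumination ramp, exponential z-attenuation and additive Gaussian noise;
* striation images with a controlled sarcomere period and orientation jitter;
* bright-field-like movies of a textured tissue deforming under a known
  displacement profile (uniform translation or contraction pulse trains);
* action-potential, beat-amplitude and calcium-transient traces whose
  defining quantities (RMP, APA, APD90, Vmax, notch derivative, amplitude
  CV, transient kinetics) are emitted analytically, never re-measured from
  the rendered signal.

All randomness flows through one ``numpy.random.default_rng(seed)`` per
call; identical recipe + seed gives bit-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from .contraction import BeatSeries
from .stack import ImageStack
from .traces import APTrace, CalciumTrace

__all__ = [
    "StackRecipe",
    "MovieRecipe",
    "APRecipe",
    "BeatRecipe",
    "CalciumRecipe",
    "FrameSequence",
    "generate_stack",
    "generate_striation_image",
    "generate_movie",
    "generate_ap_trace",
    "generate_beat_series",
    "generate_calcium_trace",
    "allocate_identities",
]

#: channel layout of generated stacks: nuclei + one marker per identity + Ki67
CHANNELS = ("dapi", "tnni", "col1a1", "cd31", "ki67")
IDENTITIES = ("CM", "EC", "CF")
#: identity -> marker channel painted on its nuclear footprint
MARKER_OF = {"CM": "tnni", "EC": "cd31", "CF": "col1a1"}

_MAX_PLACEMENT_TRIES = 10_000


# --------------------------------------------------------------------------
# recipes
# --------------------------------------------------------------------------

@dataclass
class StackRecipe:
    """Parameters of a synthetic spheroid stack.

    Defaults emulate a 160x160x64 μm crop of a microtissue imaged at
    0.5 μm/px laterally and 1 μm axial steps, with nuclei 10-13 μm across
    in-plane, a 70/15/15 CM/EC/CF composition and noise at ~10% of the
    nuclear signal.
    """

    n_nuclei: int = 200
    shape_zyx: tuple[int, int, int] = (64, 320, 320)
    um_per_px: float = 0.5
    z_step_um: float = 1.0
    inplane_semi_axes_um: tuple[float, float] = (5.0, 6.5)
    axial_semi_axis_um: tuple[float, float] = (2.8, 3.8)
    min_spacing_um: float = 14.0
    composition: dict[str, float] = field(
        default_factory=lambda: {"CM": 0.70, "EC": 0.15, "CF": 0.15}
    )
    proliferative_fraction: float = 0.2
    nuclear_intensity: float = 170.0
    marker_intensity: float = 150.0
    offmarker_intensity: float = 10.0
    ki67_intensity: float = 150.0
    background_offset: float = 8.0
    noise_sd: float = 17.0
    illumination_gradient: float = 0.15
    z_attenuation: float = 0.004
    n_streaks: int = 0
    streak_intensity: float = 120.0
    streak_width_px: float = 3.0
    seed: int = 0

    def validate(self) -> None:
        if self.n_nuclei < 0:
            raise ValueError("n_nuclei must be >= 0")
        if abs(sum(self.composition.values()) - 1.0) > 1e-9:
            raise ValueError("composition fractions must sum to 1")
        if any(f < 0 or f > 1 for f in self.composition.values()):
            raise ValueError("composition fractions must lie in [0, 1]")
        if self.min_spacing_um <= 0:
            raise ValueError("min_spacing_um must be > 0")
        lo, hi = self.inplane_semi_axes_um
        zlo, zhi = self.axial_semi_axis_um
        if not (0 < lo <= hi and 0 < zlo <= zhi):
            raise ValueError("semi-axis ranges must be positive and ordered")
        if not 0 <= self.proliferative_fraction <= 1:
            raise ValueError("proliferative_fraction must lie in [0, 1]")


@dataclass
class MovieRecipe:
    """Parameters of a synthetic beating-tissue movie.

    ``motion`` selects a uniform ``translation`` (``velocity_px_per_frame``)
    or a ``pulse`` train: each beat moves the texture with a
    sin²-shaped contraction pulse (peak ``peak_um_s``, width ``width_s``)
    followed by a slower relaxation that returns the tissue to rest; the
    relaxation peak speed is ``relax_fraction`` of the contraction peak so
    contraction remains the dominant speed peak of each beat.
    """

    n_frames: int = 150
    fps: float = 100.0
    um_per_px: float = 1.0
    shape: tuple[int, int] = (128, 128)
    motion: str = "pulse"  # "translation" | "pulse" | "none"
    velocity_px_per_frame: tuple[float, float] = (0.0, 0.5)  # (vy, vx)
    peak_um_s: float = 30.0
    width_s: float = 0.2
    period_s: float = 1.0
    relax_fraction: float = 0.6
    direction: tuple[float, float] = (0.0, 1.0)  # (dy, dx), unit-normalized
    region: tuple[float, float, float] | None = None  # (cy, cx, radius_px)
    texture_granularity_px: float = 4.0
    noise_sd: float = 2.0
    seed: int = 0

    def validate(self) -> None:
        if self.fps <= 0:
            raise ValueError("fps must be > 0")
        if self.n_frames < 2:
            raise ValueError("need at least 2 frames")
        if self.motion not in ("translation", "pulse", "none"):
            raise ValueError(f"unknown motion {self.motion!r}")
        if self.motion == "pulse":
            if not 0 < self.relax_fraction <= 1:
                raise ValueError("relax_fraction must lie in (0, 1]")
            if self.width_s * (1 + 1 / self.relax_fraction) > self.period_s:
                raise ValueError(
                    "contraction + relaxation phases exceed the beat period"
                )


@dataclass
class FrameSequence:
    """A rendered movie plus its analytic ground truth."""

    frames: np.ndarray  # (T, H, W) float32
    fps: float
    um_per_px: float
    #: per frame-pair true velocity fields, (T-1, 2, H, W) px/frame (vy, vx)
    true_velocity: np.ndarray
    #: per frame-pair true peak speed, μm/s
    true_speed_um_s: np.ndarray


@dataclass
class APRecipe:
    """Piecewise-analytic action potential: resting -> linear upstroke ->
    optional notch dip -> exponential repolarization."""

    rate_khz: float = 10.0
    rmp_mv: float = -80.0
    apa_mv: float = 110.0
    apd90_ms: float = 300.0
    upstroke_ms: float = 2.0
    notch: bool = False
    notch_depth_mv: float = 14.0
    notch_width_ms: float = 10.0
    n_beats: int = 3
    # slow spontaneous rate: the repolarization tail must decay to well
    # under the 0.1*APA APD90 level before the next diastolic window
    period_ms: float = 2000.0
    noise_sd_mv: float = 0.0
    seed: int = 0

    def validate(self) -> None:
        if self.rate_khz <= 0:
            raise ValueError("sampling rate must be > 0")
        if self.apa_mv <= 0:
            raise ValueError("APA must be > 0")
        if self.notch and self.notch_depth_mv >= self.apa_mv:
            raise ValueError("notch depth must be smaller than the APA")
        if self.apd90_ms <= self.upstroke_ms:
            raise ValueError("APD90 must exceed the upstroke duration")


@dataclass
class BeatRecipe:
    """Periodic beat series with amplitudes rescaled to an exact sample CV."""

    rate_hz: float = 1.0
    n_beats: int = 12
    amplitude_mean: float = 1.0
    amplitude_cv: float = 0.10
    seed: int = 0

    def validate(self) -> None:
        if self.rate_hz <= 0:
            raise ValueError("rate must be > 0")
        if self.amplitude_cv < 0:
            raise ValueError("CV must be >= 0")
        if self.n_beats < 3:
            raise ValueError("need at least 3 beats")


@dataclass
class CalciumRecipe:
    """Calcium transient train: linear rise, single-exponential decay.

    The rise is calibrated so that the 10%-of-amplitude onset rule recovers
    exactly ``time_to_peak_ms``; decay crossings are at ``tau*ln2`` (50%)
    and ``tau*ln10`` (90%) after the peak.
    """

    rate_hz: float = 1000.0  # sampling
    n_transients: int = 5
    # period leaves the transient >= 9 decay constants to return to
    # baseline, so the measured F0 is not inflated by inter-beat tails
    period_s: float = 2.0
    amplitude: float = 1.0
    time_to_peak_ms: float = 150.0
    tau_decay_ms: float = 200.0
    noise_sd: float = 0.0
    caffeine_time_s: float | None = None
    caffeine_factor: float = 1.5
    seed: int = 0

    def validate(self) -> None:
        if self.rate_hz <= 0:
            raise ValueError("sampling rate must be > 0")
        if self.amplitude <= 0 or self.time_to_peak_ms <= 0 or self.tau_decay_ms <= 0:
            raise ValueError("amplitude and kinetics must be positive")


# --------------------------------------------------------------------------
# identity allocation
# --------------------------------------------------------------------------

def allocate_identities(n: int, composition: dict[str, float]) -> list[str]:
    """Deterministic largest-remainder allocation of identities.

    Each identity gets ``floor(f * n)`` nuclei; leftover slots go to the
    identities with the largest fractional parts, ties broken by listing
    order.  The allocation is exact, not stochastic.
    """
    names = list(composition)
    quotas = [composition[k] * n for k in names]
    counts = [int(np.floor(q)) for q in quotas]
    remainder = n - sum(counts)
    order = sorted(
        range(len(names)), key=lambda i: (-(quotas[i] - counts[i]), i)
    )
    for i in order[:remainder]:
        counts[i] += 1
    labels: list[str] = []
    for name, c in zip(names, counts):
        labels.extend([name] * c)
    return labels


# --------------------------------------------------------------------------
# stacks
# --------------------------------------------------------------------------

def _place_nuclei(recipe: StackRecipe, rng: np.random.Generator) -> pd.DataFrame:
    """Rejection-sample nucleus poses with a hard minimum center spacing."""
    nz, ny, nx = recipe.shape_zyx
    lims_um = (nz * recipe.z_step_um, ny * recipe.um_per_px, nx * recipe.um_per_px)
    alo, ahi = recipe.inplane_semi_axes_um
    clo, chi = recipe.axial_semi_axis_um
    centers: list[np.ndarray] = []
    rows = []
    for i in range(recipe.n_nuclei):
        a = rng.uniform(alo, ahi)
        b = rng.uniform(alo, min(a, ahi))
        c = rng.uniform(clo, chi)
        theta = rng.uniform(-np.pi / 2, np.pi / 2)
        placed = False
        for _ in range(_MAX_PLACEMENT_TRIES):
            # keep the ellipsoid fully inside the field
            zc = rng.uniform(c, lims_um[0] - c)
            yc = rng.uniform(a, lims_um[1] - a)
            xc = rng.uniform(a, lims_um[2] - a)
            p = np.array([zc, yc, xc])
            if all(
                np.linalg.norm(p - q) >= recipe.min_spacing_um for q in centers
            ):
                placed = True
                break
        if not placed:
            raise RuntimeError(
                f"could not place nucleus {i}: packing infeasible after "
                f"{_MAX_PLACEMENT_TRIES} tries"
            )
        centers.append(p)
        rows.append(
            dict(center_z_um=zc, center_y_um=yc, center_x_um=xc,
                 a_um=a, b_um=b, c_um=c, theta=theta)
        )
    return pd.DataFrame(rows)


def _paint_footprints(
    canvas: np.ndarray,
    truth: pd.DataFrame,
    which: np.ndarray,
    intensity: float,
    recipe: StackRecipe,
) -> None:
    """Rasterize solid ellipsoids (at the given rows of ``truth``) additively
    replacing canvas values with ``intensity`` on the footprint."""
    nz, ny, nx = canvas.shape
    mpp, zst = recipe.um_per_px, recipe.z_step_um
    for row in truth.loc[which].itertuples():
        a, b, c = row.a_um, row.b_um, row.c_um
        ct, st = np.cos(row.theta), np.sin(row.theta)
        z0 = max(int(np.floor((row.center_z_um - c) / zst)), 0)
        z1 = min(int(np.ceil((row.center_z_um + c) / zst)) + 1, nz)
        y0 = max(int(np.floor((row.center_y_um - a) / mpp)), 0)
        y1 = min(int(np.ceil((row.center_y_um + a) / mpp)) + 1, ny)
        x0 = max(int(np.floor((row.center_x_um - a) / mpp)), 0)
        x1 = min(int(np.ceil((row.center_x_um + a) / mpp)) + 1, nx)
        zz, yy, xx = np.mgrid[z0:z1, y0:y1, x0:x1]
        dz = zz * zst - row.center_z_um
        dy = yy * mpp - row.center_y_um
        dx = xx * mpp - row.center_x_um
        u = dx * ct + dy * st
        v = -dx * st + dy * ct
        inside = (u / a) ** 2 + (v / b) ** 2 + (dz / c) ** 2 <= 1.0
        sub = canvas[z0:z1, y0:y1, x0:x1]
        sub[inside] = intensity


def _paint_streaks(canvas: np.ndarray, recipe: StackRecipe,
                   rng: np.random.Generator) -> None:
    """Fibrous distractors: bright 45°-oriented bands through all slices
    (perpendicular to the 135° line element that is meant to remove them)."""
    nz, ny, nx = canvas.shape
    rr, cc = np.mgrid[0:ny, 0:nx]
    anti = rr + cc  # constant along the 45° (up-right) diagonal
    for _ in range(recipe.n_streaks):
        offset = rng.uniform(0, ny + nx)
        band = np.abs(anti - offset) <= recipe.streak_width_px / 2
        canvas[:, band] = np.maximum(canvas[:, band], recipe.streak_intensity)


def generate_stack(recipe: StackRecipe) -> tuple[ImageStack, pd.DataFrame]:
    """Render a multichannel stack and return it with its ground truth.

    The DAPI channel contains solid ellipsoids at the ground-truth poses;
    each identity's marker channel paints the same nuclear footprints with
    the marker intensity (others receive a low off-target intensity); the
    Ki67 channel paints proliferative nuclei and optional streak
    distractors.  A multiplicative planar illumination ramp, per-slice
    exponential z-attenuation, a constant background offset and additive
    Gaussian noise are then applied per channel, and the result is quantized
    to 8 bit as a camera would.

    Returns ``(stack, truth)`` where ``truth`` has one row per nucleus with
    analytic pose, identity and proliferative flag.
    """
    recipe.validate()
    rng = np.random.default_rng(recipe.seed)
    truth = _place_nuclei(recipe, rng)
    labels = allocate_identities(recipe.n_nuclei, recipe.composition)
    # attach identities in a seeded random order so identity is independent
    # of placement order, while counts stay exact
    perm = rng.permutation(recipe.n_nuclei)
    identity = np.empty(recipe.n_nuclei, dtype=object)
    identity[perm] = labels
    truth["identity"] = identity
    n_pos = int(round(recipe.proliferative_fraction * recipe.n_nuclei))
    prolif = np.zeros(recipe.n_nuclei, dtype=bool)
    prolif[rng.permutation(recipe.n_nuclei)[:n_pos]] = True
    truth["proliferative"] = prolif

    nz, ny, nx = recipe.shape_zyx
    data = np.zeros((len(CHANNELS), nz, ny, nx), dtype=np.float64)
    all_idx = np.ones(recipe.n_nuclei, dtype=bool)
    _paint_footprints(data[0], truth, all_idx, recipe.nuclear_intensity, recipe)
    for ident in IDENTITIES:
        own = CHANNELS.index(MARKER_OF[ident])
        sel = (truth["identity"] == ident).to_numpy()
        for ch_name in ("tnni", "col1a1", "cd31"):
            ch = CHANNELS.index(ch_name)
            level = (recipe.marker_intensity if ch == own
                     else recipe.offmarker_intensity)
            _paint_footprints(data[ch], truth, sel, level, recipe)
    ki = CHANNELS.index("ki67")
    _paint_footprints(data[ki], truth, prolif, recipe.ki67_intensity, recipe)
    if recipe.n_streaks:
        _paint_streaks(data[ki], recipe, rng)

    # degradations: planar ramp (diagonal direction), z-attenuation, offset,
    # additive Gaussian noise, 8-bit quantization
    yy, xx = np.mgrid[0:ny, 0:nx]
    diag = (xx / max(nx - 1, 1) + yy / max(ny - 1, 1)) / 2.0  # in [0, 1]
    ramp = 1.0 + recipe.illumination_gradient * (diag - 0.5)
    atten = (1.0 - recipe.z_attenuation) ** np.arange(nz)
    for ch in range(len(CHANNELS)):
        data[ch] *= ramp[None, :, :]
        data[ch] *= atten[:, None, None]
        data[ch] += recipe.background_offset
        data[ch] += rng.normal(0.0, recipe.noise_sd, size=data[ch].shape)
    data = np.clip(np.rint(data), 0, 255).astype(np.uint8)
    stack = ImageStack(data, recipe.um_per_px, recipe.z_step_um, CHANNELS)
    return stack, truth


# --------------------------------------------------------------------------
# striation images
# --------------------------------------------------------------------------

def generate_striation_image(
    spacing_px: float,
    jitter_deg: float,
    size: tuple[int, int] = (256, 256),
    seed: int = 0,
) -> np.ndarray:
    """Striation pattern whose local orientation jitters around the +x axis.

    The image is a superposition of plane waves of period ``spacing_px``
    whose normals are drawn from a zero-mean Gaussian with SD
    ``jitter_deg`` (random phases), so the spectral energy spreads
    angularly by exactly the requested amount while the Z-band periodicity
    stays fixed.  ``jitter_deg = 0`` gives a single coherent sinusoid whose
    autocorrelation period equals ``spacing_px``; jitter near 180° is
    effectively an isotropic band-pass texture.
    """
    if spacing_px < 4:
        raise ValueError("striation spacing below 4 px would alias")
    rng = np.random.default_rng(seed)
    h, w = size
    if jitter_deg == 0:
        xx = np.arange(w, dtype=float)[None, :]
        img = np.broadcast_to(np.sin(2 * np.pi * xx / spacing_px), size).copy()
        img = img / max(np.abs(img).max(), 1e-12)
        return 127.5 * (1.0 + img)
    # Fourier-ring synthesis: energy on the 1/spacing ring with a Gaussian
    # angular amplitude profile of SD jitter_deg about the +x axis and
    # random phases per bin — the angular energy spread equals the
    # requested orientation jitter exactly, without wave-sampling noise
    fy = np.fft.fftfreq(h)[:, None]
    fx = np.fft.fftfreq(w)[None, :]
    fr = np.hypot(fy, fx)
    ang = np.arctan2(fy, fx)
    dang = (ang + np.pi / 2) % np.pi - np.pi / 2  # fold mod pi about 0
    sigma = np.deg2rad(jitter_deg)
    ring = np.abs(fr - 1.0 / spacing_px) <= 0.75 / min(h, w)
    amp = np.where(ring, np.exp(-(dang**2) / (4 * sigma**2)), 0.0)
    phases = rng.uniform(0, 2 * np.pi, size)
    img = np.real(np.fft.ifft2(amp * np.exp(1j * phases)))
    img = img / max(np.abs(img).max(), 1e-12)
    return 127.5 * (1.0 + img)


# --------------------------------------------------------------------------
# movies
# --------------------------------------------------------------------------

def _pulse_velocity_um_s(t_s: np.ndarray, recipe: MovieRecipe) -> np.ndarray:
    """Signed speed (μm/s) along ``direction`` for the pulse motion model."""
    tau = np.mod(t_s, recipe.period_s)
    w = recipe.width_s
    p_r = recipe.relax_fraction * recipe.peak_um_s
    w_r = w / recipe.relax_fraction  # equal displacement area out and back
    v = np.zeros_like(tau)
    contr = tau < w
    v[contr] = recipe.peak_um_s * np.sin(np.pi * tau[contr] / w) ** 2
    relax = (tau >= w) & (tau < w + w_r)
    v[relax] = -p_r * np.sin(np.pi * (tau[relax] - w) / w_r) ** 2
    return v


def generate_movie(recipe: MovieRecipe) -> FrameSequence:
    """Warp a textured frame under a known displacement profile.

    Frame ``t`` is frame 0 resampled (bilinear) at the cumulative
    ground-truth displacement; per-frame noise is added afterwards.  The
    per-frame-pair true velocity fields (px/frame) and the true peak speed
    profile (μm/s) are returned alongside.
    """
    recipe.validate()
    rng = np.random.default_rng(recipe.seed)
    h, w = recipe.shape
    base = ndimage.gaussian_filter(
        rng.standard_normal((h, w)), sigma=recipe.texture_granularity_px,
        mode="wrap",
    )
    base = 30.0 + 190.0 * (base - base.min()) / (base.max() - base.min())

    t = np.arange(recipe.n_frames) / recipe.fps
    d = np.array(recipe.direction, dtype=float)
    d /= np.linalg.norm(d)
    if recipe.motion == "translation":
        v_px = np.tile(np.array(recipe.velocity_px_per_frame, dtype=float),
                       (recipe.n_frames, 1))  # (T, 2) vy, vx per frame
        disp = np.cumsum(v_px, axis=0) - v_px  # displacement at frame t
    elif recipe.motion == "pulse":
        v_um_s = _pulse_velocity_um_s(t, recipe)  # signed, at frame times
        v_px = (v_um_s / recipe.um_per_px / recipe.fps)[:, None] * d[None, :]
        disp = np.cumsum(v_px, axis=0) - v_px
    else:
        v_px = np.zeros((recipe.n_frames, 2))
        disp = np.zeros((recipe.n_frames, 2))

    if np.abs(disp).max() > min(h, w) / 2:
        raise ValueError("displacement exceeds half the frame size")

    if recipe.region is not None:
        cy, cx, radius = recipe.region
        yy, xx = np.mgrid[0:h, 0:w]
        r = np.hypot(yy - cy, xx - cx)
        weight = np.clip(1.0 - (r / radius) ** 2, 0.0, 1.0)
    else:
        weight = np.ones((h, w))

    yy, xx = np.mgrid[0:h, 0:w].astype(float)
    frames = np.empty((recipe.n_frames, h, w), dtype=np.float32)
    for k in range(recipe.n_frames):
        dy = disp[k, 0] * weight
        dx = disp[k, 1] * weight
        frames[k] = ndimage.map_coordinates(
            base, [yy - dy, xx - dx], order=1, mode="reflect"
        )
    frames += rng.normal(0, recipe.noise_sd,
                         size=frames.shape).astype(np.float32)

    vel = np.empty((recipe.n_frames - 1, 2, h, w), dtype=np.float32)
    step = np.diff(disp, axis=0)  # (T-1, 2) px/frame
    for k in range(recipe.n_frames - 1):
        vel[k, 0] = step[k, 0] * weight
        vel[k, 1] = step[k, 1] * weight
    speed = (np.hypot(step[:, 0], step[:, 1])
             * recipe.um_per_px * recipe.fps)
    return FrameSequence(frames, recipe.fps, recipe.um_per_px, vel, speed)


# --------------------------------------------------------------------------
# traces
# --------------------------------------------------------------------------

def generate_ap_trace(recipe: APRecipe) -> tuple[APTrace, dict]:
    """Piecewise-analytic action potential train with analytic truth.

    Returns ``(trace, truth)`` with ``truth`` holding RMP, APA, APD90
    (from the upstroke instant of maximal dV/dt to 90% repolarization),
    Vmax (mV/ms == V/s) and the minimum analytic derivative within 50 ms
    after the peak (the notch-detection region).
    """
    recipe.validate()
    rng = np.random.default_rng(recipe.seed)
    dt = 1.0 / recipe.rate_khz  # ms per sample
    total_ms = recipe.n_beats * recipe.period_ms
    t = np.arange(0.0, total_ms, dt)
    v = np.full_like(t, recipe.rmp_mv)
    tau = (recipe.apd90_ms - recipe.upstroke_ms) / np.log(10.0)
    lead_ms = 100.0  # diastolic interval before the first upstroke
    peak_times = []
    for b in range(recipe.n_beats):
        t0 = b * recipe.period_ms + lead_ms
        tp = t0 + recipe.upstroke_ms
        peak_times.append(tp)
        up = (t >= t0) & (t < tp)
        v[up] = recipe.rmp_mv + recipe.apa_mv * (t[up] - t0) / recipe.upstroke_ms
        rep = t >= tp
        v[rep] = recipe.rmp_mv + recipe.apa_mv * np.exp(-(t[rep] - tp) / tau)
        if recipe.notch:
            wn = recipe.notch_width_ms
            inn = (t >= tp) & (t < tp + wn)
            v[inn] -= recipe.notch_depth_mv / 2 * (
                1 - np.cos(2 * np.pi * (t[inn] - tp) / wn)
            )
    if recipe.noise_sd_mv > 0:
        v = v + rng.normal(0, recipe.noise_sd_mv, size=v.shape)

    # analytic derivative over the peak region, on a fine grid
    s = np.linspace(0.0, 50.0, 50_001)  # ms after the peak
    dv = -recipe.apa_mv / tau * np.exp(-s / tau)
    if recipe.notch:
        wn = recipe.notch_width_ms
        m = s < wn
        dv[m] -= (recipe.notch_depth_mv * np.pi / wn) * np.sin(
            2 * np.pi * s[m] / wn
        )
    truth = {
        "rmp_mv": recipe.rmp_mv,
        "apa_mv": recipe.apa_mv,
        "peak_mv": recipe.rmp_mv + recipe.apa_mv,
        "apd90_ms": recipe.apd90_ms,
        "vmax_v_s": recipe.apa_mv / recipe.upstroke_ms,
        "min_derivative_peak_region": float(dv.min()),
        "tau_ms": tau,
        "peak_times_ms": np.array(peak_times),
    }
    return APTrace(time_ms=t, v_mv=v, rate_khz=recipe.rate_khz), truth


def generate_beat_series(recipe: BeatRecipe) -> BeatSeries:
    """Strictly periodic beats whose amplitude sample CV is exact.

    Amplitudes are drawn i.i.d. normal and then affinely rescaled so the
    sample CV (SD with the n-1 denominator over the mean) equals
    ``amplitude_cv`` to machine precision.
    """
    recipe.validate()
    rng = np.random.default_rng(recipe.seed)
    times = np.arange(recipe.n_beats) / recipe.rate_hz
    m = recipe.amplitude_mean
    if recipe.amplitude_cv == 0:
        amps = np.full(recipe.n_beats, m)
    else:
        for _ in range(100):
            x = rng.standard_normal(recipe.n_beats)
            s = x.std(ddof=1)
            if s == 0:
                continue
            amps = m + (x - x.mean()) * (recipe.amplitude_cv * m / s)
            if np.all(amps > 0):
                break
        else:
            raise RuntimeError("could not draw positive amplitudes at this CV")
    return BeatSeries(times=times, amplitudes=amps)


def generate_calcium_trace(recipe: CalciumRecipe) -> tuple[CalciumTrace, dict]:
    """Calcium transient train (dF/F) with analytic kinetics.

    Each transient rises linearly over ``time_to_peak_ms / 0.9`` so that the
    10%-of-amplitude onset threshold sits exactly ``time_to_peak_ms`` before
    the peak, then decays as a single exponential with ``tau_decay_ms``.
    If ``caffeine_time_s`` is set, one transient of amplitude
    ``caffeine_factor * amplitude`` is added at that time (pacing stops).
    """
    recipe.validate()
    rng = np.random.default_rng(recipe.seed)
    dt = 1.0 / recipe.rate_hz
    rise_ms = recipe.time_to_peak_ms / 0.9
    dur = recipe.n_transients * recipe.period_s
    if recipe.caffeine_time_s is not None:
        dur = max(dur, recipe.caffeine_time_s) + 3.0
    t = np.arange(0.0, dur, dt)
    f = np.zeros_like(t)
    onsets = [0.1 + k * recipe.period_s for k in range(recipe.n_transients)]
    amps = [recipe.amplitude] * recipe.n_transients
    if recipe.caffeine_time_s is not None:
        onsets.append(recipe.caffeine_time_s + 0.1)
        amps.append(recipe.caffeine_factor * recipe.amplitude)
    peak_times = []
    for t0, amp in zip(onsets, amps):
        tp = t0 + rise_ms / 1000.0
        peak_times.append(tp)
        up = (t >= t0) & (t < tp)
        f[up] = np.maximum(f[up], amp * (t[up] - t0) / (tp - t0))
        dec = t >= tp
        f[dec] = np.maximum(
            f[dec], amp * np.exp(-(t[dec] - tp) * 1000.0 / recipe.tau_decay_ms)
        )
    if recipe.noise_sd > 0:
        f = f + rng.normal(0, recipe.noise_sd, size=f.shape)
    truth = {
        "time_to_peak_ms": recipe.time_to_peak_ms,
        "decay50_ms": recipe.tau_decay_ms * np.log(2.0),
        "decay90_ms": recipe.tau_decay_ms * np.log(10.0),
        "tau_ms": recipe.tau_decay_ms,
        "peak_times_s": np.array(peak_times),
        "amplitude": recipe.amplitude,
    }
    return CalciumTrace(time_s=t, dff=f, rate_hz=recipe.rate_hz), truth
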