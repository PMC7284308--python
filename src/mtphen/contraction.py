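"""Optical-flow contraction analysis for beating microtissues.

Dense frame-to-frame motion is estimated with the classic Horn–Schunck
variational method (brightness constancy + field smoothness, Jacobi
iterations with the standard neighbour-average kernel).  Speeds are
calibrated to μm/s, averaged over a 15×15 μm bin grid inside a region of
interest, and the time course of the maximum-velocity bin forms the
contraction/relaxation profile from which per-beat kinematics are derived:
upstroke and relaxation peak velocities and accelerations, and beat
duration between the 10%-of-peak onset and return-to-baseline crossings.

A beat series (times + amplitudes) feeds the pacing-following classifier:
a tissue follows the stimulation frequency iff its contraction rate is
within ±15% of the pacing rate and the amplitude coefficient of variation
stays below 28%.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

__all__ = [
    "FlowParams",
    "ContractionProfile",
    "BeatSeries",
    "PacingRule",
    "BeatKinematics",
    "horn_schunck",
    "flow_movie",
    "bin_and_select",
    "profile_parameters",
    "beats_from_profile",
    "contraction_direction",
    "normalized_contraction_duration",
    "classify_pacing",
]

# Horn-Schunck neighbour-average kernel
_AVG = np.array(
    [[1 / 12, 1 / 6, 1 / 12], [1 / 6, 0.0, 1 / 6], [1 / 12, 1 / 6, 1 / 12]]
)


@dataclass
class FlowParams:
    """Flow, calibration and binning parameters.

    ``alpha`` weighs field smoothness against brightness constancy and has
    the units of image brightness per pixel; for 8-bit (0-255) movies a
    value well above typical noise-scale gradients (default 20) keeps the
    field from fitting frame noise while leaving coherent tissue motion
    unbiased.
    """

    alpha: float = 20.0
    n_iter: int = 100
    um_per_px: float = 1.0
    fps: float = 100.0
    bin_um: float = 15.0
    selection_um: float = 300.0
    #: top-left corner (row, col) of the selection in px; None = centered
    selection_origin: tuple[int, int] | None = None
    #: "auto" fixes the bin maximal at the global peak frame; a (row, col)
    #: pixel position selects the bin containing it
    bin_mode: str | tuple[float, float] = "auto"

    def __post_init__(self) -> None:
        if self.alpha <= 0:
            raise ValueError("alpha must be > 0")
        if self.n_iter < 1:
            raise ValueError("need at least one iteration")
        if self.bin_um > self.selection_um:
            raise ValueError("bin size must not exceed the selection size")


@dataclass
class ContractionProfile:
    """Time course of the selected bin's speed, with per-bin SD."""

    time_s: np.ndarray
    speed_um_s: np.ndarray
    sd_um_s: np.ndarray
    fps: float
    bin_index: tuple[int, int]
    #: binned speed of every bin at every frame pair, (T-1, nby, nbx)
    binned: np.ndarray | None = None


@dataclass
class BeatSeries:
    """Beat times (s) and amplitudes (a.u.) from a contraction trace."""

    times: np.ndarray
    amplitudes: np.ndarray

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.amplitudes = np.asarray(self.amplitudes, dtype=float)
        if self.times.size != self.amplitudes.size:
            raise ValueError("times and amplitudes must have equal length")
        if self.times.size >= 2 and not np.all(np.diff(self.times) > 0):
            raise ValueError("beat times must be strictly increasing")

    @property
    def rate_hz(self) -> float:
        """Interval-based rate estimate, (n-1) / (t_last - t_first)."""
        if self.times.size < 2:
            raise ValueError("need at least 2 beats for a rate")
        return (self.times.size - 1) / (self.times[-1] - self.times[0])

    @property
    def amplitude_cv(self) -> float:
        """SD (n-1 denominator) over mean of the beat amplitudes."""
        return float(
            self.amplitudes.std(ddof=1) / self.amplitudes.mean()
        )


@dataclass(frozen=True)
class PacingRule:
    """Rate tolerance and amplitude-CV cutoff of the pacing classifier."""

    rate_tolerance: float = 0.15
    cv_cutoff: float = 0.28

    def __post_init__(self) -> None:
        if not 0 < self.rate_tolerance < 1 or not 0 < self.cv_cutoff < 1:
            raise ValueError("tolerances must lie in (0, 1)")


# --------------------------------------------------------------------------
# optical flow
# --------------------------------------------------------------------------

def horn_schunck(
    frame0: np.ndarray,
    frame1: np.ndarray,
    alpha: float = 1.0,
    n_iter: int = 100,
) -> tuple[np.ndarray, np.ndarray]:
    """Dense optical flow between two frames, in px/frame.

    Returns ``(u, v)`` where ``u`` is the x (column) and ``v`` the y (row)
    velocity.  Derivatives use the original 2x2x2 cube-average stencils;
    the smoothness term uses the standard 1/12-1/6 neighbour average;
    iterations start from zero flow, so identical frames give exactly zero.
    """
    f0 = np.asarray(frame0, dtype=float)
    f1 = np.asarray(frame1, dtype=float)
    if f0.shape != f1.shape or f0.ndim != 2:
        raise ValueError("frames must be two equal-size 2D images")
    # correlate, not convolve: the stencils are applied as written, so a
    # pattern moving toward +x yields positive u
    kx = 0.25 * np.array([[-1.0, 1.0], [-1.0, 1.0]])
    ky = 0.25 * np.array([[-1.0, -1.0], [1.0, 1.0]])
    kt = 0.25 * np.ones((2, 2))
    ex = ndimage.correlate(f0, kx) + ndimage.correlate(f1, kx)
    ey = ndimage.correlate(f0, ky) + ndimage.correlate(f1, ky)
    et = ndimage.correlate(f1, kt) - ndimage.correlate(f0, kt)
    u = np.zeros_like(f0)
    v = np.zeros_like(f0)
    denom = alpha**2 + ex**2 + ey**2
    for _ in range(n_iter):
        ubar = ndimage.convolve(u, _AVG)
        vbar = ndimage.convolve(v, _AVG)
        coeff = (ex * ubar + ey * vbar + et) / denom
        u = ubar - ex * coeff
        v = vbar - ey * coeff
    return u, v


def flow_movie(
    frames: np.ndarray, params: FlowParams
) -> np.ndarray:
    """Velocity fields for every consecutive frame pair.

    Frames are mean-normalized first to damp global illumination flicker.
    Returns an array of shape ``(T-1, 2, H, W)`` ordered ``(v, u)`` =
    (row, col) velocity in px/frame.
    """
    frames = np.asarray(frames, dtype=float)
    if frames.ndim != 3 or frames.shape[0] < 2:
        raise ValueError("need a (T, H, W) movie with at least 2 frames")
    means = frames.mean(axis=(1, 2))
    norm = frames * (means.mean() / means)[:, None, None]
    out = np.empty((frames.shape[0] - 1, 2) + frames.shape[1:], dtype=float)
    for k in range(frames.shape[0] - 1):
        u, v = horn_schunck(norm[k], norm[k + 1], params.alpha, params.n_iter)
        out[k, 0] = v
        out[k, 1] = u
    return out


# --------------------------------------------------------------------------
# binning and profile extraction
# --------------------------------------------------------------------------

def bin_and_select(
    fields: np.ndarray, params: FlowParams
) -> ContractionProfile:
    """Average speeds over the bin grid and emit the peak bin's time course.

    Pixel speeds are ``hypot(u, v) * um_per_px * fps`` (μm/s).  Bins of
    ``bin_um`` tile the ``selection_um`` region (centered unless an origin
    is given).  In auto mode the single bin that is maximal at the global
    peak frame is fixed for the whole recording; a manual (row, col)
    position selects the bin containing that pixel.  Per-bin SDs across the
    vectors inside each bin are retained.
    """
    fields = np.asarray(fields, dtype=float)
    if fields.ndim != 4 or fields.shape[1] != 2:
        raise ValueError("fields must have shape (T-1, 2, H, W)")
    nt, _, h, w = fields.shape
    sel_px = int(round(params.selection_um / params.um_per_px))
    sel_px = min(sel_px, h, w)
    bin_px = max(int(round(params.bin_um / params.um_per_px)), 1)
    if params.selection_origin is None:
        r0 = (h - sel_px) // 2
        c0 = (w - sel_px) // 2
    else:
        r0, c0 = params.selection_origin
        if r0 < 0 or c0 < 0 or r0 + sel_px > h or c0 + sel_px > w:
            raise ValueError("selection lies outside the frame")
    nb = sel_px // bin_px
    if nb < 1:
        raise ValueError("selection smaller than one bin")
    cal = params.um_per_px * params.fps
    # bin the vectors first, then take the resultant speed: incoherent
    # (noise) vectors cancel inside a bin, coherent motion does not
    crop = fields[:, :, r0 : r0 + nb * bin_px, c0 : c0 + nb * bin_px]
    blocks = crop.reshape(nt, 2, nb, bin_px, nb, bin_px)
    vmean = blocks.mean(axis=(3, 5))  # (T-1, 2, nb, nb)
    binned = np.hypot(vmean[:, 0], vmean[:, 1]) * cal
    pix_speed = np.hypot(blocks[:, 0], blocks[:, 1]) * cal
    binned_sd = pix_speed.std(axis=(2, 4))
    if params.bin_mode == "auto":
        flat = np.argmax(binned)
        _, bi, bj = np.unravel_index(flat, binned.shape)
    else:
        pr, pc = params.bin_mode
        bi = int((pr - r0) // bin_px)
        bj = int((pc - c0) // bin_px)
        if not (0 <= bi < nb and 0 <= bj < nb):
            raise ValueError("manual bin position outside the selection")
    time = (np.arange(nt) + 0.5) / params.fps
    return ContractionProfile(
        time_s=time,
        speed_um_s=binned[:, bi, bj],
        sd_um_s=binned_sd[:, bi, bj],
        fps=params.fps,
        bin_index=(int(bi), int(bj)),
        binned=binned,
    )


# --------------------------------------------------------------------------
# beat kinematics
# --------------------------------------------------------------------------

@dataclass
class BeatKinematics:
    """Per-beat contraction parameters with across-beat mean and SD."""

    upstroke_velocity_um_s: float
    upstroke_acceleration_um_s2: float
    relaxation_velocity_um_s: float
    relaxation_acceleration_um_s2: float
    beat_duration_s: float
    n_beats: int
    per_beat: dict = field(default_factory=dict, repr=False)
    sd: dict = field(default_factory=dict, repr=False)


def _segment_beats(
    speed: np.ndarray,
    time: np.ndarray,
    threshold_frac: float,
    min_quiet_s: float,
) -> list[tuple[int, int]]:
    """Contiguous active runs (index ranges) separated by sustained rest."""
    peak = speed.max()
    if peak <= 0:
        return []
    dt = float(np.median(np.diff(time)))
    active = speed > threshold_frac * peak
    # bridge momentary dips (e.g. the zero-speed instant between the
    # contraction and relaxation phases of one beat)
    gap = max(int(round(min_quiet_s / dt)), 1)
    active = ndimage.binary_closing(active, structure=np.ones(gap))
    labels, n = ndimage.label(active)
    runs = []
    for lab in range(1, n + 1):
        idx = np.nonzero(labels == lab)[0]
        if speed[idx].max() >= 0.3 * peak:  # reject noise blips
            runs.append((int(idx[0]), int(idx[-1]) + 1))
    return runs


def profile_parameters(
    profile: ContractionProfile,
    min_beats: int = 5,
    threshold_frac: float = 0.1,
    min_quiet_s: float = 0.1,
) -> BeatKinematics:
    """Five kinematic parameters per beat, averaged with SD.

    Each beat runs from the 10%-of-its-peak onset to the return below that
    level.  The contraction phase ends at the speed trough between the
    first and last humps of the beat; upstroke velocity is the peak speed
    before the trough, relaxation velocity the peak speed after it, and the
    accelerations are the extremal time derivatives of speed in the
    corresponding phases.
    """
    speed = np.asarray(profile.speed_um_s, dtype=float)
    time = np.asarray(profile.time_s, dtype=float)
    runs = _segment_beats(speed, time, threshold_frac, min_quiet_s)
    if len(runs) < min_beats:
        raise ValueError(
            f"found {len(runs)} beats, need at least {min_beats}"
        )
    dt = float(np.median(np.diff(time)))
    ups, uaccs, rels, raccs, durs = [], [], [], [], []
    for i0, i1 in runs:
        seg = speed[i0:i1]
        pk = seg.max()
        lvl = threshold_frac * pk
        # refine onset/offset to this beat's own 10% level, sub-sample
        j = i0
        while j > 0 and speed[j - 1] > lvl:
            j -= 1
        if j > 0 and speed[j] > lvl >= speed[j - 1]:
            fr = (speed[j] - lvl) / (speed[j] - speed[j - 1])
            t_on = time[j] - fr * dt
        else:
            t_on = time[j]
        k = i1 - 1
        while k < speed.size - 1 and speed[k + 1] > lvl:
            k += 1
        if k < speed.size - 1 and speed[k] > lvl >= speed[k + 1]:
            fr = (speed[k] - lvl) / (speed[k] - speed[k + 1])
            t_off = time[k] + fr * dt
        else:
            t_off = time[k]
        durs.append(t_off - t_on)
        # humps within the beat
        interior = np.nonzero(
            (seg[1:-1] >= seg[:-2]) & (seg[1:-1] > seg[2:])
            & (seg[1:-1] >= 0.2 * pk)
        )[0] + 1
        if interior.size >= 2:
            h_first, h_last = interior[0], interior[-1]
            trough = h_first + int(np.argmin(seg[h_first : h_last + 1]))
        else:
            trough = int(np.argmax(seg))
        ups.append(seg[: trough + 1].max())
        rels.append(seg[trough:].max())
        dspeed = np.gradient(seg, dt)
        ipk1 = int(np.argmax(seg[: trough + 1]))
        ups_acc = dspeed[: ipk1 + 1].max() if ipk1 >= 0 else 0.0
        uaccs.append(ups_acc)
        ipk2 = trough + int(np.argmax(seg[trough:]))
        raccs.append(np.abs(dspeed[ipk2:]).max())
    sd = {
        "upstroke_velocity": float(np.std(ups, ddof=1)) if len(ups) > 1 else 0.0,
        "beat_duration": float(np.std(durs, ddof=1)) if len(durs) > 1 else 0.0,
    }
    return BeatKinematics(
        upstroke_velocity_um_s=float(np.mean(ups)),
        upstroke_acceleration_um_s2=float(np.mean(uaccs)),
        relaxation_velocity_um_s=float(np.mean(rels)),
        relaxation_acceleration_um_s2=float(np.mean(raccs)),
        beat_duration_s=float(np.mean(durs)),
        n_beats=len(runs),
        per_beat={
            "upstroke_velocity": ups,
            "upstroke_acceleration": uaccs,
            "relaxation_velocity": rels,
            "relaxation_acceleration": raccs,
            "beat_duration": durs,
        },
        sd=sd,
    )


def beats_from_profile(
    profile: ContractionProfile,
    threshold_frac: float = 0.1,
    min_quiet_s: float = 0.1,
) -> BeatSeries:
    """Beat times and amplitudes (contraction-peak speeds) from a profile."""
    speed = np.asarray(profile.speed_um_s, dtype=float)
    time = np.asarray(profile.time_s, dtype=float)
    runs = _segment_beats(speed, time, threshold_frac, min_quiet_s)
    if not runs:
        raise ValueError("no beats detected in profile")
    times, amps = [], []
    for i0, i1 in runs:
        ipk = i0 + int(np.argmax(speed[i0:i1]))
        times.append(time[ipk])
        amps.append(speed[ipk])
    return BeatSeries(times=np.asarray(times), amplitudes=np.asarray(amps))


# --------------------------------------------------------------------------
# directions, durations, pacing
# --------------------------------------------------------------------------

def contraction_direction(u: np.ndarray, v: np.ndarray) -> np.ndarray:
    """Per-vector motion angle ``atan2(v, u)`` in ``(-pi, pi]``.

    Zero vectors have no direction and are masked as NaN.
    """
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    ang = np.arctan2(v, u)
    ang = np.where(ang == -np.pi, np.pi, ang)
    return np.where(np.hypot(u, v) == 0, np.nan, ang)


def normalized_contraction_duration(cd_s: float, ibi_s: float) -> float:
    """Contraction duration normalized by the square root of the inter-beat
    interval, ``cd / sqrt(IBI)`` — removes the trivial rate dependence of
    duration in spontaneously beating tissue."""
    if cd_s <= 0 or ibi_s <= 0:
        raise ValueError("contraction duration and IBI must be positive")
    return cd_s / np.sqrt(ibi_s)


def classify_pacing(
    beats: BeatSeries,
    pacing_hz: float,
    rule: PacingRule = PacingRule(),
) -> bool:
    """True iff the tissue follows the stimulation frequency.

    Follows iff ``|rate - pacing| / pacing <= rate_tolerance`` (rate from
    beat intervals) and the amplitude CV is strictly below ``cv_cutoff``.
    """
    if beats.times.size < 3:
        raise ValueError("need at least 3 beats to classify pacing")
    if pacing_hz <= 0:
        raise ValueError("pacing rate must be positive")
    rate_ok = abs(beats.rate_hz - pacing_hz) / pacing_hz <= rule.rate_tolerance
    cv_ok = beats.amplitude_cv < rule.cv_cutoff
    return bool(rate_ok and cv_ok)
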