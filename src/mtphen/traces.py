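"""Action-potential and calcium-transient analytics.

Feature definitions follow standard cardiac electrophysiology usage:

* RMP — mean diastolic voltage over the 50 ms preceding the upstroke;
* APA — peak voltage minus RMP;
* Vmax — maximal dV/dt during the upstroke (mV/ms, numerically V/s);
* APD90 — time from the Vmax instant to 90% repolarization
  (first crossing of ``peak - 0.9 * APA``);
* I_to notch — minimum of the lightly smoothed derivative within a window
  after the AP peak falling below a negative cutoff (default -3 mV/ms);
* dF/F — background-subtracted fluorescence normalized by a baseline F0
  taken as the mean of the lowest-decile samples;
* transient kinetics — onset (10% of amplitude) to peak, and peak to the
  50% / 90% decay crossings;
* caffeine ratio — first post-caffeine peak amplitude over the mean of the
  four preceding peak amplitudes (a proxy for SR calcium content).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.signal import find_peaks

__all__ = [
    "APTrace",
    "CalciumTrace",
    "NotchRule",
    "APFeatures",
    "TransientKinetics",
    "detect_upstrokes",
    "ap_features",
    "min_peak_region_derivative",
    "detect_notch",
    "notch_fraction",
    "compute_dff",
    "transient_kinetics",
    "caffeine_ratio",
]


@dataclass
class APTrace:
    """Uniformly sampled membrane-voltage recording (mV, sampled at kHz)."""

    time_ms: np.ndarray
    v_mv: np.ndarray
    rate_khz: float
    stimulus_times_ms: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.time_ms = np.asarray(self.time_ms, dtype=float)
        self.v_mv = np.asarray(self.v_mv, dtype=float)
        if self.time_ms.shape != self.v_mv.shape:
            raise ValueError("time and voltage must have equal length")
        if not np.all(np.isfinite(self.v_mv)):
            raise ValueError("voltage trace contains non-finite values")


@dataclass
class CalciumTrace:
    """Uniformly sampled dF/F trace (unitless, time in seconds)."""

    time_s: np.ndarray
    dff: np.ndarray
    rate_hz: float

    def __post_init__(self) -> None:
        self.time_s = np.asarray(self.time_s, dtype=float)
        self.dff = np.asarray(self.dff, dtype=float)
        if not np.all(np.isfinite(self.dff)):
            raise ValueError("trace contains non-finite values")


@dataclass(frozen=True)
class NotchRule:
    """Derivative rule for I_to-notch detection.

    ``cutoff`` is in mV/ms on the smoothed derivative; ``window_ms`` bounds
    the peak region searched after each AP peak.
    """

    cutoff: float = -3.0
    window_ms: float = 50.0

    def __post_init__(self) -> None:
        if self.cutoff >= 0:
            raise ValueError("notch cutoff must be negative")


@dataclass
class APFeatures:
    rmp_mv: float
    apa_mv: float
    apd90_ms: float
    vmax_v_s: float
    n_beats: int
    per_beat: dict = field(default_factory=dict, repr=False)


# --------------------------------------------------------------------------
# action potentials
# --------------------------------------------------------------------------

def detect_upstrokes(
    trace: APTrace,
    dvdt_threshold: float = 5.0,
    sustain_ms: float = 1.0,
    refractory_ms: float = 200.0,
) -> np.ndarray:
    """Indices where an AP upstroke begins.

    An upstroke is a run of samples with dV/dt above ``dvdt_threshold``
    (mV/ms) sustained for at least ``sustain_ms``; starts closer than
    ``refractory_ms`` to the previous one are discarded.
    """
    dt = 1.0 / trace.rate_khz
    dvdt = np.diff(trace.v_mv) / dt
    above = dvdt > dvdt_threshold
    need = max(int(round(sustain_ms / dt)), 1)
    starts: list[int] = []
    i = 0
    n = above.size
    last = -np.inf
    while i < n:
        if above[i]:
            j = i
            while j < n and above[j]:
                j += 1
            if j - i >= need and trace.time_ms[i] - last >= refractory_ms:
                starts.append(i)
                last = trace.time_ms[i]
            i = j
        else:
            i += 1
    return np.asarray(starts, dtype=int)


def ap_features(
    trace: APTrace,
    pre_window_ms: float = 50.0,
) -> APFeatures:
    """Extract RMP, APA, APD90 and Vmax, averaged over detected beats."""
    starts = detect_upstrokes(trace)
    if starts.size == 0:
        raise ValueError("no action potential detected in trace")
    dt = 1.0 / trace.rate_khz
    dvdt = np.diff(trace.v_mv) / dt
    bounds = list(starts[1:]) + [trace.v_mv.size]
    rmps, apas, apds, vmaxs = [], [], [], []
    for i0, iend in zip(starts, bounds):
        pre = max(i0 - int(round(pre_window_ms / dt)), 0)
        if pre == i0:
            continue
        rmp = float(trace.v_mv[pre:i0].mean())
        ipk = i0 + int(np.argmax(trace.v_mv[i0:iend]))
        peak = float(trace.v_mv[ipk])
        apa = peak - rmp
        seg = dvdt[i0 : max(ipk, i0 + 1)]
        ivmax = i0 + int(np.argmax(seg))
        vmax = float(dvdt[ivmax])
        level = peak - 0.9 * apa
        below = np.nonzero(trace.v_mv[ipk:iend] <= level)[0]
        if below.size == 0:
            continue  # repolarization not captured for this beat
        ic = ipk + below[0]
        # sub-sample crossing by linear interpolation
        if ic > ipk and trace.v_mv[ic - 1] > level:
            frac = (trace.v_mv[ic - 1] - level) / (
                trace.v_mv[ic - 1] - trace.v_mv[ic]
            )
            t_cross = trace.time_ms[ic - 1] + frac * dt
        else:
            t_cross = trace.time_ms[ic]
        apds.append(t_cross - trace.time_ms[ivmax])
        rmps.append(rmp)
        apas.append(apa)
        vmaxs.append(vmax)
    if not rmps:
        raise ValueError("no complete action potential (with repolarization)")
    return APFeatures(
        rmp_mv=float(np.mean(rmps)),
        apa_mv=float(np.mean(apas)),
        apd90_ms=float(np.mean(apds)),
        vmax_v_s=float(np.mean(vmaxs)),
        n_beats=len(rmps),
        per_beat={"rmp": rmps, "apa": apas, "apd90": apds, "vmax": vmaxs},
    )


def min_peak_region_derivative(
    trace: APTrace, rule: NotchRule = NotchRule()
) -> float:
    """Minimum smoothed dV/dt (mV/ms) within the post-peak notch window.

    The trace is smoothed with a 3-sample moving mean before
    differentiation to suppress sample-to-sample oscillation, then the
    minimum over ``[peak, peak + window]`` is taken across all beats.
    """
    starts = detect_upstrokes(trace)
    if starts.size == 0:
        raise ValueError("no action potential detected in trace")
    dt = 1.0 / trace.rate_khz
    sm = np.convolve(trace.v_mv, np.ones(3) / 3.0, mode="same")
    dvdt = np.diff(sm) / dt
    win = int(round(rule.window_ms / dt))
    bounds = list(starts[1:]) + [trace.v_mv.size]
    lo = np.inf
    for i0, iend in zip(starts, bounds):
        ipk = i0 + int(np.argmax(trace.v_mv[i0:iend]))
        seg = dvdt[ipk : min(ipk + win, dvdt.size)]
        if seg.size:
            lo = min(lo, float(seg.min()))
    if not np.isfinite(lo):
        raise ValueError("empty peak region")
    return lo


def detect_notch(trace: APTrace, rule: NotchRule = NotchRule()) -> bool:
    """True iff the minimum post-peak derivative falls below the cutoff."""
    return min_peak_region_derivative(trace, rule) < rule.cutoff


def notch_fraction(
    traces: list[APTrace], rule: NotchRule = NotchRule()
) -> float:
    """Percentage of traces flagged as notched."""
    if not traces:
        raise ValueError("no traces given")
    flags = [detect_notch(tr, rule) for tr in traces]
    return 100.0 * sum(flags) / len(flags)


# --------------------------------------------------------------------------
# calcium
# --------------------------------------------------------------------------

def _baseline(x: np.ndarray) -> float:
    """Mean of the lowest-decile samples (the F0 convention)."""
    k = max(int(np.ceil(x.size / 10)), 1)
    return float(np.sort(x)[:k].mean())


def compute_dff(
    source: np.ndarray,
    background: np.ndarray,
    rate_hz: float,
) -> CalciumTrace:
    """Background-subtracted, baseline-normalized fluorescence.

    Movie mode (``source`` is (t, y, x)): the tissue mask is the maximum
    projection thresholded at its overall mean plus SD; ``background`` is a
    boolean (y, x) mask of a region outside the tissue.  Trace mode
    (``source`` is 1D): ``background`` is the matching background trace.
    In both modes ``F = mean(in mask) - mean(background)``, ``F0`` is the
    mean of the lowest-decile samples of F, and ``dF/F = (F - F0) / F0``.
    """
    source = np.asarray(source, dtype=float)
    if source.ndim == 3:
        maxproj = source.max(axis=0)
        thr = maxproj.mean() + maxproj.std()
        mask = maxproj > thr
        if not mask.any():
            if np.ptp(maxproj) == 0:  # degenerate flat recording
                mask = np.ones_like(mask)
            else:
                raise ValueError("tissue mask is empty at mean+SD threshold")
        bg = np.asarray(background, dtype=bool)
        if bg.shape != maxproj.shape or not bg.any():
            raise ValueError("background must be a nonempty (y, x) mask")
        f = source[:, mask].mean(axis=1) - source[:, bg].mean(axis=1)
    elif source.ndim == 1:
        bg_trace = np.asarray(background, dtype=float)
        if bg_trace.shape != source.shape:
            raise ValueError("background trace must match the F trace")
        f = source - bg_trace
    else:
        raise ValueError("source must be a 1D trace or a (t, y, x) movie")
    f0 = _baseline(f)
    if f0 <= 0:
        if np.allclose(f, f[0]):
            dff = np.zeros_like(f)
        else:
            raise ValueError(f"non-positive baseline F0 = {f0:g}")
    else:
        dff = (f - f0) / f0
    t = np.arange(f.size) / rate_hz
    return CalciumTrace(time_s=t, dff=dff, rate_hz=rate_hz)


def _detect_transient_peaks(
    trace: CalciumTrace, min_separation_s: float = 0.3
) -> np.ndarray:
    x = trace.dff
    span = x.max() - x.min()
    if span <= 0:
        return np.array([], dtype=int)
    peaks, _ = find_peaks(
        x,
        prominence=0.3 * span,
        distance=max(int(min_separation_s * trace.rate_hz), 1),
    )
    return peaks


@dataclass
class TransientKinetics:
    time_to_peak_ms: float
    decay50_ms: float
    decay90_ms: float
    n_transients: int


def transient_kinetics(
    trace: CalciumTrace,
    onset_fraction: float = 0.1,
) -> TransientKinetics:
    """Per-transient kinetics, averaged over transients.

    The onset is the last crossing of ``baseline + onset_fraction *
    amplitude`` before the peak; decay times run from the peak to the first
    crossings of 50% and 10% of the amplitude above baseline.  Transients
    whose 90% decay is not reached before the next onset (or end of record)
    are excluded with a warning.
    """
    peaks = _detect_transient_peaks(trace)
    if peaks.size == 0:
        raise ValueError("no calcium transient detected")
    x, t = trace.dff, trace.time_s
    base = _baseline(x)
    ttps, d50s, d90s = [], [], []
    for k, ipk in enumerate(peaks):
        amp = x[ipk] - base
        if amp <= 0:
            continue
        lo = peaks[k - 1] if k > 0 else 0
        hi = peaks[k + 1] if k + 1 < peaks.size else x.size
        lvl_on = base + onset_fraction * amp
        pre = np.nonzero(x[lo:ipk] <= lvl_on)[0]
        if pre.size == 0:
            continue
        i_on = lo + pre[-1]
        # sub-sample onset crossing
        if x[i_on + 1] > x[i_on]:
            frac = (lvl_on - x[i_on]) / (x[i_on + 1] - x[i_on])
        else:
            frac = 0.0
        t_on = t[i_on] + frac * (t[i_on + 1] - t[i_on])
        ttps.append((t[ipk] - t_on) * 1000.0)

        def _decay_time(level: float) -> float | None:
            post = np.nonzero(x[ipk:hi] <= level)[0]
            if post.size == 0:
                return None
            ic = ipk + post[0]
            if ic > ipk and x[ic - 1] > level:
                fr = (x[ic - 1] - level) / (x[ic - 1] - x[ic])
                tc = t[ic - 1] + fr * (t[ic] - t[ic - 1])
            else:
                tc = t[ic]
            return (tc - t[ipk]) * 1000.0

        d50 = _decay_time(base + 0.5 * amp)
        d90 = _decay_time(base + 0.1 * amp)
        if d50 is None or d90 is None:
            warnings.warn(
                f"transient at t={t[ipk]:.3f}s not followed by 90% decay; "
                "excluded",
                stacklevel=2,
            )
            ttps.pop()
            continue
        d50s.append(d50)
        d90s.append(d90)
    if not d50s:
        raise ValueError("no transient with complete decay")
    return TransientKinetics(
        time_to_peak_ms=float(np.mean(ttps)),
        decay50_ms=float(np.mean(d50s)),
        decay90_ms=float(np.mean(d90s)),
        n_transients=len(d50s),
    )


def caffeine_ratio(trace: CalciumTrace, caffeine_time_s: float) -> float:
    """First post-caffeine peak amplitude over the mean of the last four
    pre-caffeine peak amplitudes (each measured from its local baseline)."""
    peaks = _detect_transient_peaks(trace)
    x, t = trace.dff, trace.time_s
    amps = []
    for k, ipk in enumerate(peaks):
        lo = peaks[k - 1] if k > 0 else 0
        local_base = x[lo:ipk].min() if ipk > lo else x[ipk]
        amps.append(x[ipk] - local_base)
    amps = np.asarray(amps)
    pre = peaks[t[peaks] < caffeine_time_s]
    post = peaks[t[peaks] >= caffeine_time_s]
    if pre.size < 4 or post.size < 1:
        raise ValueError(
            f"need >= 4 pre-caffeine and >= 1 post-caffeine peaks, "
            f"found {pre.size} and {post.size}"
        )
    pre_amp = amps[np.isin(peaks, pre)][-4:].mean()
    post_amp = amps[np.isin(peaks, post)][0]
    return float(post_amp / pre_amp)
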