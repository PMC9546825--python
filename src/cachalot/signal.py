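"""Click-level signal processing.

Three stages mirror the acoustic front end of the survey analysis:
band-pass filtering with decimation to 96 kHz, energy-threshold click
detection, and measurement of the slant delay — the lag between a click's
direct arrival and its surface-reflected echo — by autocorrelation of the
clip's amplitude envelope.

The surface echo is phase-inverted by reflection, which would make it a
*negative* peak in the raw autocorrelation; the slant delay is therefore
read off the envelope of the autocorrelation (magnitude of its analytic
signal), normalized so the zero-lag value is 1, which makes the 0.02
acceptance threshold well defined.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal as sps

__all__ = [
    "ClickClip",
    "RejectionReason",
    "SlantDelayMeasurement",
    "bandpass_decimate",
    "detect_clicks",
    "measure_slant_delay",
    "qc_slant_delays",
]

TARGET_FS = 96_000
BAND_HZ = (2_000.0, 20_000.0)
#: accepted slant-delay lag window (s); the lower bound keeps the search
#: out of the direct click itself
DELAY_WINDOW_S = (0.0005, 0.015)
CORRELATION_THRESHOLD = 0.02
#: minimum accepted slant-delay measurements for an event to enter depth analysis
MIN_CLICKS_PER_EVENT = 8


class RejectionReason(str, enum.Enum):
    none = "none"
    below_threshold = "below_threshold"
    outside_window = "outside_window"
    qc_outlier = "qc_outlier"


@dataclass
class ClickClip:
    """A short two-channel recording around one detected click."""

    waveform: np.ndarray  # (n,) or (n, n_channels)
    fs: int
    click_time_s: float = 0.0
    event_id: int | str = 0

    def __post_init__(self) -> None:
        self.waveform = np.asarray(self.waveform, dtype=float)


@dataclass
class SlantDelayMeasurement:
    """One slant-delay measurement with its acceptance state."""

    tau_s: float
    correlation_value: float
    accepted: bool
    rejection_reason: RejectionReason = RejectionReason.none
    click_time_s: float = 0.0
    event_id: int | str = 0


def bandpass_decimate(audio: np.ndarray, fs_in: int) -> np.ndarray:
    """4th-order Butterworth band-pass 2–20 kHz, then decimate to 96 kHz.

    The filter is applied zero-phase (forward-backward). ``fs_in`` must be
    an integer multiple of 96 kHz for exact decimation.
    """
    if fs_in < TARGET_FS:
        raise ValueError("input sample rate below 96 kHz")
    if fs_in % TARGET_FS != 0:
        raise ValueError("input sample rate must be an integer multiple of 96 kHz")
    x = np.asarray(audio, dtype=float)
    sos = sps.butter(4, BAND_HZ, btype="bandpass", fs=fs_in, output="sos")
    y = sps.sosfiltfilt(sos, x, axis=0)
    factor = fs_in // TARGET_FS
    if factor > 1:
        # band already limited to 20 kHz << new Nyquist; plain subsampling is safe
        y = y[::factor] if y.ndim == 1 else y[::factor, :]
    return y


def detect_clicks(
    audio: np.ndarray,
    fs: int,
    threshold_db: float = 12.0,
    *,
    window_s: float = 0.001,
    decay_s: float = 1.0,
    refractory_s: float = 0.020,
) -> np.ndarray:
    """Energy-threshold click detector on band-passed audio.

    Short-window RMS (1 ms default — comparable to a sperm whale click
    pulse) is compared against a running noise-floor estimate
    (exponential moving average with time constant ``decay_s``, frozen
    while triggered so clicks do not inflate the floor). A detection is
    emitted when the window exceeds the floor by ``threshold_db``; its
    time is refined to the energy peak inside the window, and a
    refractory period suppresses re-triggering within 20 ms.

    Returns detection times in seconds.
    """
    x = np.asarray(audio, dtype=float)
    if x.ndim > 1:
        x = x[:, 0]
    if x.size == 0:
        return np.empty(0)

    hop = max(1, int(round(window_s / 2 * fs)))
    win = max(1, int(round(window_s * fs)))
    # windowed RMS via cumulative sum of energy
    e = np.concatenate([[0.0], np.cumsum(x * x)])
    starts = np.arange(0, max(1, x.size - win + 1), hop)
    rms = np.sqrt((e[starts + win] - e[starts]) / win)

    alpha = (hop / fs) / decay_s
    ratio_lin = 10.0 ** (threshold_db / 20.0)
    floor = max(float(np.median(rms)), 1e-12)
    detections: list[float] = []
    last = -np.inf
    for s, r in zip(starts, rms):
        tc = (s + win / 2) / fs
        if r >= ratio_lin * floor:
            if tc - last >= refractory_s:
                peak = s + int(np.argmax(np.abs(x[s : s + win])))
                detections.append(peak / fs)
            last = tc
        else:
            floor = (1 - alpha) * floor + alpha * max(r, 1e-12)
    return np.asarray(detections)


def _envelope(x: np.ndarray) -> np.ndarray:
    return np.abs(sps.hilbert(x))


def measure_slant_delay(
    clip: ClickClip,
    *,
    window_s: tuple[float, float] = DELAY_WINDOW_S,
    threshold: float = CORRELATION_THRESHOLD,
    echo_sign: int = -1,
) -> SlantDelayMeasurement:
    """Measure the click → surface-echo lag from one clip.

    Computes the normalized autocorrelation of the clip's (mean-removed)
    analytic-signal envelope and selects the highest local peak with
    correlation ≥ ``threshold`` inside the lag window (0.0005–0.015 s by
    default). Clips that do not cover the full window after the click
    onset are rejected ``outside_window``; clips with no qualifying peak
    are rejected ``below_threshold``.
    """
    x = clip.waveform
    if x.ndim > 1:
        x = x[:, 0]
    fs = clip.fs
    n = x.size
    lo = int(np.ceil(window_s[0] * fs))
    hi = int(np.floor(window_s[1] * fs))

    def rejected(reason: RejectionReason) -> SlantDelayMeasurement:
        return SlantDelayMeasurement(
            np.nan, 0.0, False, reason, clip.click_time_s, clip.event_id
        )

    if n < hi + 1:
        return rejected(RejectionReason.outside_window)
    onset = int(np.argmax(np.abs(x)))
    if n - onset < hi:
        return rejected(RejectionReason.outside_window)

    xc = x - x.mean()
    denom = float(np.dot(xc, xc))
    if denom <= 0:
        return rejected(RejectionReason.below_threshold)
    # envelope of the waveform autocorrelation, zero-lag normalized to 1:
    # the envelope makes the phase-inverted surface echo show up as a
    # positive peak at its lag
    raw = sps.fftconvolve(xc, xc[::-1])[n - 1 :] / denom
    ac = _envelope(raw)

    # the accepted measurement is the best local *peak* inside the lag
    # window; an above-threshold in-window shoulder without a peak means
    # the governing structure (click lobe or merged echo) lies inside the
    # in-click exclusion zone below 0.0005 s
    peaks, _ = sps.find_peaks(ac[: hi + 1])
    peaks = peaks[ac[peaks] >= threshold]
    in_window = peaks[peaks >= lo]
    if in_window.size == 0:
        if float(ac[lo : hi + 1].max()) >= threshold:
            return rejected(RejectionReason.outside_window)
        return rejected(RejectionReason.below_threshold)
    best = int(in_window[np.argmax(ac[in_window])])
    # refine on the raw autocorrelation: the surface reflection is
    # phase-inverted, so the echo term is a sharp carrier-resolution
    # trough (sign ``echo_sign``) near the envelope peak
    half = max(3, int(round(0.5e-4 * fs)))
    lo_r = max(1, best - half)
    hi_r = min(ac.size - 2, best + half)
    k0 = lo_r + int(np.argmax(echo_sign * raw[lo_r : hi_r + 1]))
    tau = float(k0)
    y0, y1, y2 = raw[k0 - 1], raw[k0], raw[k0 + 1]
    denom2 = y0 - 2 * y1 + y2
    if denom2 != 0 and np.sign(denom2) != np.sign(y1):
        offset = 0.5 * (y0 - y2) / denom2
        if abs(offset) <= 1:
            tau += offset
    return SlantDelayMeasurement(
        tau / fs, float(ac[best]), True, RejectionReason.none,
        clip.click_time_s, clip.event_id,
    )


def qc_slant_delays(
    measurements: list[SlantDelayMeasurement],
    window: int = 11,
    k: float = 3.0,
    min_clicks: int = MIN_CLICKS_PER_EVENT,
    coherence_tol_s: float = 2e-4,
    n_passes: int = 2,
) -> tuple[list[SlantDelayMeasurement], bool]:
    """Automated stand-in for the manual slant-delay review.

    A whale's slant delay drifts slowly and smoothly as it moves through
    the water column, so the accepted delays of one event, ordered by
    click time, are smoothed with a rolling median and points whose
    residual exceeds ``k`` × MAD are re-flagged ``qc_outlier``
    (iterating ``n_passes`` times so clusters of false peaks fall out).
    The event is usable for depth analysis only if at least
    ``min_clicks`` accepted measurements remain *and* the surviving
    series is pattern-coherent — its median absolute residual stays
    below ``coherence_tol_s``. Events whose delays are dominated by
    false peaks (typically shallow whales whose echoes merge with the
    click) fail that test, the automated analogue of an event failing
    manual review for lack of surface-reflected echoes.

    Returns ``(measurements, event_accepted)``; the input order is kept.
    """
    out = list(measurements)
    median_resid = 0.0
    for _ in range(max(1, n_passes)):
        idx = [i for i, m in enumerate(out) if m.accepted]
        if len(idx) < 3:
            break
        order = sorted(idx, key=lambda i: out[i].click_time_s)
        tau = np.array([out[i].tau_s for i in order])
        smooth = (
            pd.Series(tau).rolling(window, center=True, min_periods=1).median().to_numpy()
        )
        resid = np.abs(tau - smooth)
        mad = 1.4826 * np.median(np.abs(resid - np.median(resid)))
        # tolerance floors: a few samples at 96 kHz for near-constant
        # series, and a small fraction of the event's delay excursion so
        # smoothing lag on a steep trend is not flagged
        span = float(np.percentile(tau, 95) - np.percentile(tau, 5))
        cutoff = max(k * mad, 0.06 * span, 5e-5)
        median_resid = float(np.median(resid))
        changed = False
        for i, r in zip(order, resid):
            if r > cutoff:
                m = out[i]
                out[i] = SlantDelayMeasurement(
                    m.tau_s, m.correlation_value, False,
                    RejectionReason.qc_outlier, m.click_time_s, m.event_id,
                )
                changed = True
        if not changed:
            break
    n_ok = sum(m.accepted for m in out)
    return out, n_ok >= min_clicks and median_resid <= coherence_tol_s


def measurements_to_frame(measurements: list[SlantDelayMeasurement]) -> pd.DataFrame:
    """Per-click measurement table (the module's CSV interface)."""
    return pd.DataFrame(
        {
            "event_id": [m.event_id for m in measurements],
            "click_time_s": [m.click_time_s for m in measurements],
            "tau_s": [m.tau_s for m in measurements],
            "correlation": [m.correlation_value for m in measurements],
            "accepted": [m.accepted for m in measurements],
            "reason": [m.rejection_reason.value for m in measurements],
        }
    )
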