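"""Automated sleep-spindle detection on bipolar N2-sleep EEG.

The detector is an envelope-threshold design of the classic family: band-pass
the derivation to the sigma band (11-15 Hz), take the smoothed magnitude of
the analytic signal, and mark maximal intervals where the envelope exceeds
both a per-derivation relative threshold (mean + 2 SD of that subject's N2
envelope) and an absolute amplitude floor. Supra-threshold runs closer than
the merge gap are fused; surviving runs must last 0.5-3 s. For every event
the oscillation frequency (interpolated sigma-band spectral peak) and the
mean sigma-band power are computed, and the event is labelled slow
(11-13 Hz) or fast (13-15 Hz) by that frequency.

A final source-assignment step handles volume conduction between
electrode-sharing derivations: a detected event whose peak envelope is well
below that of a temporally overlapping event on another derivation of the
same hemisphere is treated as a conducted copy and discarded. The relative
threshold is computed per derivation, not pooled across hemispheres —
pooling would bias detection against the low-amplitude (lesioned) side and
inflate the asymmetry ratio.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
from scipy import signal
from scipy.fft import next_fast_len

from .eeg_io import BipolarRecording, LEFT_DERIVATIONS, zero_phase_bandpass

__all__ = [
    "SIGMA_BAND",
    "SLOW_BAND",
    "FAST_BAND",
    "DetectorParams",
    "SpindleEvent",
    "sigma_filter",
    "sigma_envelope",
    "detect_spindles",
    "event_osc_frequency",
    "event_mean_power",
    "classify_band",
]

SIGMA_BAND = (11.0, 15.0)
SLOW_BAND = (11.0, 13.0)   # [11, 13)
FAST_BAND = (13.0, 15.0)   # [13, 15]
BANDS = {"full": SIGMA_BAND, "slow": SLOW_BAND, "fast": FAST_BAND}


@dataclass(frozen=True)
class DetectorParams:
    """Tunable detector parameters (all exposed, all logged with outputs)."""

    sigma_band: tuple[float, float] = SIGMA_BAND
    envelope_smooth_s: float = 0.2
    threshold_mode: str = "mean_plus_k_sd"   # or "percentile"
    threshold_value: float = 2.0             # k, or the percentile
    min_abs_amplitude_uv: float = 5.0
    min_dur_s: float = 0.5
    max_dur_s: float = 3.0
    merge_gap_s: float = 0.25
    #: discard events whose peak envelope is < this fraction of a temporally
    #: overlapping event on another same-hemisphere derivation (volume
    #: conduction rejection); None disables the step
    source_assignment_ratio: float | None = 0.7

    def __post_init__(self) -> None:
        if not self.min_dur_s < self.max_dur_s:
            raise ValueError("min_dur_s must be < max_dur_s")
        if self.threshold_mode not in ("mean_plus_k_sd", "percentile"):
            raise ValueError(f"unknown threshold_mode: {self.threshold_mode}")

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class SpindleEvent:
    """One detected spindle on one derivation, in original recording time."""

    derivation: str
    onset_s: float
    offset_s: float
    osc_freq_hz: float
    mean_power_uv2: float
    band: str = "full"
    peak_envelope_uv: float = 0.0
    subject_id: str = ""

    @property
    def duration_s(self) -> float:
        return self.offset_s - self.onset_s


def sigma_filter(x: np.ndarray, fs: float,
                 band: tuple[float, float] = SIGMA_BAND) -> np.ndarray:
    """Zero-phase sigma-band FIR filter, length preserved."""
    lo, hi = band
    if fs < 2 * hi * 1.2:
        raise ValueError(f"sampling rate {fs} too low for band {band}")
    return zero_phase_bandpass(x, lo, hi, fs, transition_hz=1.5)


def sigma_envelope(filtered: np.ndarray, fs: float, smooth_s: float = 0.2) -> np.ndarray:
    """Instantaneous-amplitude envelope, moving-average smoothed.

    Magnitude of the analytic (Hilbert) signal, then a centred moving
    average of width smooth_s. Non-negative, same length as the input.
    """
    if smooth_s < 2.0 / 15.0:
        raise ValueError("smooth_s must cover at least two cycles at 15 Hz")
    filtered = np.asarray(filtered, dtype=np.float64)
    n = filtered.shape[-1]
    nfft = next_fast_len(n)
    env = np.abs(signal.hilbert(filtered, N=nfft, axis=-1))[..., :n]
    win = max(1, int(round(smooth_s * fs)))
    kernel = np.ones(win) / win
    if env.ndim == 1:
        return signal.fftconvolve(env, kernel, mode="same")
    return signal.fftconvolve(env, kernel[None, :], mode="same", axes=-1)


def _threshold(env: np.ndarray, params: DetectorParams) -> float:
    if params.threshold_mode == "mean_plus_k_sd":
        return float(env.mean() + params.threshold_value * env.std())
    return float(np.percentile(env, params.threshold_value))


def _supra_runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """Maximal True runs as half-open (start, stop) index pairs."""
    d = np.diff(mask.astype(np.int8), prepend=0, append=0)
    starts = np.flatnonzero(d == 1)
    stops = np.flatnonzero(d == -1)
    return list(zip(starts, stops))


def _merge_runs(runs: list[tuple[int, int]], max_gap: int) -> list[tuple[int, int]]:
    if not runs:
        return []
    merged = [runs[0]]
    for s, e in runs[1:]:
        ps, pe = merged[-1]
        if s - pe < max_gap:
            merged[-1] = (ps, e)
        else:
            merged.append((s, e))
    return merged


def event_osc_frequency(event_samples: np.ndarray, fs: float,
                        band: tuple[float, float] = SIGMA_BAND) -> float:
    """Dominant oscillation frequency of one event within the sigma band.

    Hann-tapered spectrum of the whole event, zero-padded to at least
    0.25 Hz bin spacing, peak located inside the band and refined by
    parabolic interpolation. Exact ties break to the lower frequency.
    """
    x = np.asarray(event_samples, dtype=np.float64)
    n = x.size
    if n < 2 * fs / band[0]:
        raise ValueError("event too short to estimate oscillation frequency "
                         "(needs at least two cycles at the band floor)")
    nfft = max(next_fast_len(n), int(round(fs / 0.25)))
    spec = np.abs(np.fft.rfft(x * np.hanning(n), nfft)) ** 2
    freqs = np.fft.rfftfreq(nfft, 1.0 / fs)
    in_band = (freqs >= band[0]) & (freqs <= band[1])
    idx_band = np.flatnonzero(in_band)
    p = spec[idx_band]
    k_rel = int(np.argmax(p))          # argmax takes the first maximum: lower f
    k = idx_band[k_rel]
    # parabolic refinement on log power, clamped to the band
    if 0 < k < spec.size - 1 and spec[k] > 0:
        with np.errstate(divide="ignore"):
            la, lb, lc = np.log(spec[k - 1:k + 2] + 1e-300)
        denom = la - 2 * lb + lc
        delta = 0.5 * (la - lc) / denom if abs(denom) > 1e-12 else 0.0
        delta = float(np.clip(delta, -0.5, 0.5))
    else:
        delta = 0.0
    f = float(freqs[k] + delta * (freqs[1] - freqs[0]))
    return float(np.clip(f, band[0], band[1]))


def event_mean_power(event_samples: np.ndarray, fs: float,
                     band: tuple[float, float] = SIGMA_BAND,
                     prefiltered: bool = False) -> float:
    """Mean band-limited power of one event in microvolts squared.

    Mean of the squared band-filtered signal over the event duration; for a
    pure sinusoid of amplitude A this is A**2 / 2.
    """
    x = np.asarray(event_samples, dtype=np.float64)
    if not prefiltered:
        x = sigma_filter(x, fs, band)
    return float(np.mean(x ** 2))


def classify_band(osc_freq_hz: float) -> str:
    """slow for f < 13 Hz, fast for f >= 13 Hz; 11-15 Hz only."""
    if not (SIGMA_BAND[0] <= osc_freq_hz <= SIGMA_BAND[1]):
        raise ValueError(f"oscillation frequency {osc_freq_hz} outside 11-15 Hz")
    return "slow" if osc_freq_hz < 13.0 else "fast"


def _detect_one(filt: np.ndarray, env: np.ndarray, times: np.ndarray, fs: float,
                params: DetectorParams) -> list[SpindleEvent]:
    thr = max(_threshold(env, params), params.min_abs_amplitude_uv)
    runs = _merge_runs(_supra_runs(env >= thr),
                       max_gap=int(round(params.merge_gap_s * fs)))
    events = []
    min_n = int(round(params.min_dur_s * fs))
    max_n = int(round(params.max_dur_s * fs))
    for s, e in runs:
        if not (min_n <= e - s <= max_n):
            continue
        # reject runs spanning a discontinuity in the concatenated N2 data
        if times[e - 1] - times[s] > (e - 1 - s) / fs + 0.5:
            continue
        seg = filt[s:e]
        try:
            f = event_osc_frequency(seg, fs, params.sigma_band)
        except ValueError:
            continue
        events.append(SpindleEvent(
            derivation="",
            onset_s=float(times[s]),
            offset_s=float(times[e - 1] + 1.0 / fs),
            osc_freq_hz=f,
            mean_power_uv2=event_mean_power(seg, fs, prefiltered=True),
            band=classify_band(f),
            peak_envelope_uv=float(env[s:e].max()),
        ))
    return events


def _assign_sources(events: list[SpindleEvent], ratio: float) -> list[SpindleEvent]:
    """Drop events dominated by a simultaneous same-hemisphere event.

    Bipolar derivations share electrodes, so one focal spindle leaves
    attenuated copies on neighbouring derivations of the same hemisphere.
    An event is kept only if its peak envelope is at least `ratio` times the
    largest peak envelope among temporally overlapping events on the other
    derivations of that hemisphere.
    """
    left = set(LEFT_DERIVATIONS)
    keep: list[SpindleEvent] = []
    for hemi_left in (True, False):
        evs = sorted((e for e in events if (e.derivation in left) == hemi_left),
                     key=lambda e: e.onset_s)
        n = len(evs)
        dominated = [False] * n
        for i, ev in enumerate(evs):
            j = i + 1
            while j < n and evs[j].onset_s < ev.offset_s:
                o = evs[j]
                if o.derivation != ev.derivation and ev.onset_s < o.offset_s:
                    if ev.peak_envelope_uv < ratio * o.peak_envelope_uv:
                        dominated[i] = True
                    if o.peak_envelope_uv < ratio * ev.peak_envelope_uv:
                        dominated[j] = True
                j += 1
        keep.extend(e for i, e in enumerate(evs) if not dominated[i])
    return keep


def detect_spindles(bip: BipolarRecording,
                    params: DetectorParams = DetectorParams()) -> list[SpindleEvent]:
    """Detect spindle events on every non-excluded derivation.

    Requires at least 300 s of N2 data. Events are returned in original
    recording time; per-derivation thresholds are computed over that
    subject's whole N2 data for that derivation.
    """
    if bip.duration_s < 300.0:
        raise ValueError(
            f"need >= 300 s of N2 data per derivation, got {bip.duration_s:.1f} s")
    filt_all = sigma_filter(bip.data, bip.fs, params.sigma_band)
    env_all = sigma_envelope(filt_all, bip.fs, params.envelope_smooth_s)
    all_events: list[SpindleEvent] = []
    for i, name in enumerate(bip.derivations):
        if name in bip.excluded:
            continue
        if not np.any(bip.data[i]):
            continue
        evs = _detect_one(filt_all[i], env_all[i], bip.sample_times, bip.fs, params)
        for ev in evs:
            ev.derivation = name
            ev.subject_id = bip.subject_id
        all_events.extend(evs)
    if params.source_assignment_ratio is not None:
        all_events = _assign_sources(all_events, params.source_assignment_ratio)
    all_events.sort(key=lambda e: (e.derivation, e.onset_s))
    return all_events


def event_density_per_min(events: list[SpindleEvent], derivation: str,
                          total_n2_s: float) -> float:
    n = sum(1 for e in events if e.derivation == derivation)
    return 60.0 * n / total_n2_s
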