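"""Seeded synthetic infant N2-sleep EEG cohorts with known ground truth.

The generator emulates what the analysis pipeline needs from infant N2
sleep: a 1/f-like Gaussian background on every referential electrode plus
transient 11-15 Hz spindle bursts, injected simultaneously and homologously
on the left and right derivation electrode pairs, with the
lesioned-hemisphere burst amplitude multiplied by a per-region asymmetry
factor a. Since spindle power scales with amplitude squared, a region with
factor a has a ground-truth SPA of a**2.

Each burst is injected on the target derivation's two electrodes with
opposite half-amplitude waveforms, so the target derivation sees the full
amplitude while electrode-sharing derivations see half-amplitude
volume-conduction copies — the geometry the detector's source-assignment
step is built for. (With ten 10-20 electrodes and five derivations per
hemisphere the montage graph has cycles, so no referential injection can
confine an event to exactly one derivation.)

Cohort generation is calibrated so that group-level SPA distributions
resemble the clinical picture of unilateral perinatal stroke: the unilateral
CP (UCP) group draws region factors from left-skewed ceiling distributions
(median CO-fast SPA 0.56, all UCP subjects below the diagnostic region of
typical values), the typical-outcome group from a log-normal centred on
symmetry. All randomness flows from one master seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .eeg_io import (REQUIRED_ELECTRODES, N2Segment, RawRecording, write_edf)
from .spa import REGION_MAP, REGIONS

__all__ = [
    "SubjectSpec",
    "CohortSpec",
    "GroundTruthEvent",
    "SyntheticSubject",
    "SyntheticCohort",
    "synth_background",
    "synth_spindle",
    "synth_subject",
    "synth_cohort",
    "simulate_spa_null",
    "UCP_SPA_CALIBRATION",
    "TYPICAL_SPA_LOG_SD",
    "SPINDLE_TAPER_MEAN_SQUARE",
]

# ---------------------------------------------------------------------------
# Calibration constants (versioned; tuned once against the target group
# medians/IQRs, see docs/methods.md)
# ---------------------------------------------------------------------------

#: UCP group: per-region SPA drawn as ceiling * exp(-Exponential(mu)) with
#: mu = ln(ceiling/median)/ln 2, i.e. a hard ceiling with median as stated.
#: (region: (ceiling, median)) — fast-band group medians.
UCP_SPA_CALIBRATION: dict[str, tuple[float, float]] = {
    "FC": (0.85, 0.72),
    "FT": (0.95, 0.62),
    "CT": (0.80, 0.71),
    "CO": (0.62, 0.56),
    "TO": (1.05, 0.84),
}

#: typical-outcome group: log-normal SPA with median 1.0 and this log-sd
#: (gives an interquartile range of about 0.32 around symmetry)
TYPICAL_SPA_LOG_SD = 0.236

#: mean square of the Tukey(0.5) taper used for spindle bursts; the mean
#: power of a tapered burst of amplitude A is A^2/2 * this constant
SPINDLE_TAPER_MEAN_SQUARE = 0.6875  # (1-alpha) + alpha*3/8 for alpha = 0.5


@dataclass(frozen=True)
class SubjectSpec:
    """Generation parameters for one synthetic subject."""

    subject_id: str = "S001"
    group: str = "typical"            # "UCP" | "typical"
    lesion_side: str = "left"
    duration_s: float = 600.0
    fs: float = 256.0
    spindle_rate_per_min: float = 3.0     # per derivation (per region)
    freq_means_hz: tuple[float, float] = (12.2, 13.8)   # slow/fast mixture peaks
    freq_sd_hz: float = 0.4
    freq_clip_hz: tuple[float, float] = (11.3, 14.7)
    dur_range_s: tuple[float, float] = (1.0, 2.0)
    base_amp_uv: float = 30.0
    amp_cv: float = 0.1
    asymmetry: dict[str, float] = field(default_factory=dict)  # region -> a
    noise_exponent: float = 1.5
    noise_rms_uv: float = 15.0
    seed: int = 0

    def factor(self, region: str) -> float:
        return self.asymmetry.get(region, 1.0)


@dataclass(frozen=True)
class CohortSpec:
    """Cohort-level generation parameters.

    Defaults mirror the study cohort: 13 UCP and 27 typical-outcome infants,
    about 55% left-sided lesions, UCP asymmetry factors drawn from the
    calibrated group distributions.
    """

    n_ucp: int = 13
    n_typical: int = 27
    left_lesion_fraction: float = 0.55
    female_fraction: float = 0.48
    master_seed: int = 0
    subject_defaults: SubjectSpec = SubjectSpec()

    def __post_init__(self) -> None:
        if self.n_ucp < 1 or self.n_typical < 1:
            raise ValueError("group sizes must be >= 1")


@dataclass
class GroundTruthEvent:
    region: str
    onset_s: float
    duration_s: float
    freq_hz: float
    amp_left_uv: float
    amp_right_uv: float

    @property
    def band(self) -> str:
        return "slow" if self.freq_hz < 13.0 else "fast"


@dataclass
class SyntheticSubject:
    spec: SubjectSpec
    recording: RawRecording
    events: list[GroundTruthEvent]
    n2_segments: list[N2Segment]
    true_spa: dict[str, float]        # region -> a^2

    @property
    def outcome(self) -> str:
        return self.spec.group


@dataclass
class SyntheticCohort:
    spec: CohortSpec
    subjects: list[SyntheticSubject]

    def metadata(self) -> pd.DataFrame:
        rows = []
        rng = np.random.default_rng(np.random.SeedSequence(
            [self.spec.master_seed, 0xC0F]))
        sexes = rng.random(len(self.subjects)) < self.spec.female_fraction
        for s, fem in zip(self.subjects, sexes):
            rows.append({
                "subject_id": s.spec.subject_id,
                "lesion_side": s.spec.lesion_side,
                "outcome": s.spec.group,
                "sex": "F" if fem else "M",
            })
        return pd.DataFrame(rows)

    def true_spa_table(self) -> pd.DataFrame:
        rows = []
        for s in self.subjects:
            row = {"subject_id": s.spec.subject_id, "outcome": s.spec.group}
            row.update({f"{r}_true_SPA": s.true_spa[r] for r in REGIONS})
            rows.append(row)
        return pd.DataFrame(rows)

    def write(self, outdir) -> None:
        """Write the cohort in the layout the pipeline consumes:
        EDF per subject + metadata CSV + N2 sidecar CSV + ground-truth TSV."""
        from pathlib import Path

        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        manifest = []
        seg_rows = []
        for s in self.subjects:
            edf_path = outdir / f"{s.spec.subject_id}.edf"
            write_edf(s.recording, edf_path)
            manifest.append({"subject_id": s.spec.subject_id,
                             "edf_path": edf_path.name,
                             "lesion_side": s.spec.lesion_side,
                             "outcome": s.spec.group})
            seg_rows += [{"subject_id": s.spec.subject_id,
                          "start_s": seg.start_s, "end_s": seg.end_s}
                         for seg in s.n2_segments]
        meta = self.metadata()
        pd.DataFrame(manifest).merge(meta[["subject_id", "sex"]]).to_csv(
            outdir / "manifest.csv", index=False)
        pd.DataFrame(seg_rows).to_csv(outdir / "n2_segments.csv", index=False)
        self.true_spa_table().to_csv(outdir / "ground_truth_spa.csv", index=False)
        ev_rows = [{
            "subject_id": s.spec.subject_id, "region": e.region,
            "onset_s": e.onset_s, "duration_s": e.duration_s,
            "freq_hz": e.freq_hz, "amp_left_uv": e.amp_left_uv,
            "amp_right_uv": e.amp_right_uv, "band": e.band,
        } for s in self.subjects for e in s.events]
        pd.DataFrame(ev_rows).to_csv(outdir / "ground_truth_events.tsv",
                                     sep="\t", index=False)


# ---------------------------------------------------------------------------
# Signal primitives
# ---------------------------------------------------------------------------

def synth_background(duration_s: float, fs: float, exponent: float = 1.5,
                     rms_uv: float = 15.0,
                     rng: np.random.Generator | int | None = None) -> np.ndarray:
    """Gaussian 1/f**exponent background noise with the requested RMS.

    Spectrally shaped white noise: the amplitude spectrum is scaled by
    f**(-exponent/2) (DC excluded) and the result is rescaled to rms_uv.
    """
    if duration_s <= 0:
        raise ValueError("duration must be positive")
    rng = np.random.default_rng(rng)
    n = int(round(duration_s * fs))
    freqs = np.fft.rfftfreq(n, 1.0 / fs)
    spec = rng.normal(size=freqs.size) + 1j * rng.normal(size=freqs.size)
    shape = np.zeros_like(freqs)
    shape[1:] = freqs[1:] ** (-exponent / 2.0)
    x = np.fft.irfft(spec * shape, n)
    x *= rms_uv / np.sqrt(np.mean(x ** 2))
    return x


def synth_spindle(freq_hz: float, duration_s: float, amp_uv: float, fs: float,
                  phase: float = 0.0) -> np.ndarray:
    """Tukey(0.5)-tapered sinusoidal burst.

    The mean power of the pure waveform is amp**2/2 times the taper's
    mean-square constant (SPINDLE_TAPER_MEAN_SQUARE).
    """
    if not 11.0 <= freq_hz <= 15.0:
        raise ValueError("spindle frequency must lie in 11-15 Hz")
    if not 0.5 <= duration_s <= 3.0:
        raise ValueError("spindle duration must lie in 0.5-3 s")
    from scipy.signal.windows import tukey

    n = int(round(duration_s * fs))
    t = np.arange(n) / fs
    return amp_uv * tukey(n, 0.5) * np.sin(2 * np.pi * freq_hz * t + phase)


# ---------------------------------------------------------------------------
# Subject and cohort synthesis
# ---------------------------------------------------------------------------

def _schedule_events(spec: SubjectSpec, segments: list[N2Segment],
                     rng: np.random.Generator) -> list[GroundTruthEvent]:
    """Poisson-like homogeneous event schedule, non-overlapping, one shared
    schedule per subject (homologous left/right bursts are simultaneous)."""
    total_rate_hz = len(REGIONS) * spec.spindle_rate_per_min / 60.0
    min_gap = 0.6  # keep distinct events clear of the detector's merge gap
    events: list[GroundTruthEvent] = []
    for seg in segments:
        t = seg.start_s + 2.0
        while True:
            t += rng.exponential(1.0 / total_rate_hz)
            dur = rng.uniform(*spec.dur_range_s)
            if t + dur > seg.end_s - 2.0:
                break
            region = REGIONS[rng.integers(len(REGIONS))]
            mean = spec.freq_means_hz[int(rng.random() < 0.5)]
            freq = float(np.clip(rng.normal(mean, spec.freq_sd_hz),
                                 *spec.freq_clip_hz))
            amp = spec.base_amp_uv * math.exp(rng.normal(0.0, spec.amp_cv))
            a = spec.factor(region)
            if spec.lesion_side == "left":
                amp_l, amp_r = a * amp, amp
            else:
                amp_l, amp_r = amp, a * amp
            events.append(GroundTruthEvent(region, float(t), float(dur),
                                           freq, amp_l, amp_r))
            t += dur + min_gap
    return events


def synth_subject(spec: SubjectSpec) -> SyntheticSubject:
    """Generate one subject: 10-channel referential recording, ground-truth
    events, and N2 annotations.

    Spindles for a region are injected on that region's derivation electrode
    pair with opposite half-amplitude waveforms on the two electrodes, left
    and right simultaneously, the lesioned side scaled by the region factor.
    The recording is N2 except for a short mid-recording gap.
    """
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 0xEE6]))
    fs, dur = spec.fs, spec.duration_s
    n = int(round(dur * fs))
    data = np.empty((len(REQUIRED_ELECTRODES), n))
    for i in range(len(REQUIRED_ELECTRODES)):
        data[i] = synth_background(dur, fs, spec.noise_exponent,
                                   spec.noise_rms_uv, rng)

    gap_mid = min(300.0, dur / 2.0)
    segments = [N2Segment(5.0, gap_mid, spec.subject_id),
                N2Segment(gap_mid + 5.0, dur - 2.0, spec.subject_id)]

    chan_index = {e: i for i, e in enumerate(REQUIRED_ELECTRODES)}
    events = _schedule_events(spec, segments, rng)
    feasible = []
    for ev in events:
        start = int(round(ev.onset_s * fs))
        wave = synth_spindle(ev.freq_hz, ev.duration_s, 1.0, fs,
                             phase=rng.uniform(0, 2 * np.pi))
        stop = start + wave.size
        if stop > n:
            continue
        left_pair, right_pair = (REGION_MAP[ev.region][0].split("-"),
                                 REGION_MAP[ev.region][1].split("-"))
        for (e1, e2), amp in ((left_pair, ev.amp_left_uv),
                              (right_pair, ev.amp_right_uv)):
            data[chan_index[e1], start:stop] += 0.5 * amp * wave
            data[chan_index[e2], start:stop] -= 0.5 * amp * wave
        feasible.append(ev)

    rec = RawRecording(
        subject_id=spec.subject_id,
        channel_labels=list(REQUIRED_ELECTRODES),
        fs=fs, data=data,
        annotations=[("N2", s.start_s, s.end_s) for s in segments],
    )
    true_spa = {r: spec.factor(r) ** 2 for r in REGIONS}
    return SyntheticSubject(spec, rec, feasible, segments, true_spa)


def _draw_ucp_factors(rng: np.random.Generator) -> dict[str, float]:
    out = {}
    for r, (ceiling, median) in UCP_SPA_CALIBRATION.items():
        mu = math.log(ceiling / median) / math.log(2.0)
        spa = ceiling * math.exp(-rng.exponential(mu))
        out[r] = math.sqrt(spa)
    return out


def _draw_typical_factors(rng: np.random.Generator) -> dict[str, float]:
    return {r: math.sqrt(math.exp(rng.normal(0.0, TYPICAL_SPA_LOG_SD)))
            for r in REGIONS}


def synth_cohort(spec: CohortSpec = CohortSpec()) -> SyntheticCohort:
    """Generate a full cohort, deterministic under the master seed."""
    ss = np.random.SeedSequence(spec.master_seed)
    subject_seeds = ss.generate_state(spec.n_ucp + spec.n_typical) >> 1
    rng = np.random.default_rng(np.random.SeedSequence([spec.master_seed, 0xFAC]))
    subjects = []
    for k in range(spec.n_ucp + spec.n_typical):
        ucp = k < spec.n_ucp
        group = "UCP" if ucp else "typical"
        sid = f"{'UCP' if ucp else 'TYP'}{k + 1 if ucp else k - spec.n_ucp + 1:03d}"
        side = "left" if rng.random() < spec.left_lesion_fraction else "right"
        factors = _draw_ucp_factors(rng) if ucp else _draw_typical_factors(rng)
        sub_spec = replace(spec.subject_defaults, subject_id=sid, group=group,
                           lesion_side=side, asymmetry=factors,
                           seed=int(subject_seeds[k]))
        subjects.append(synth_subject(sub_spec))
    return SyntheticCohort(spec, subjects)


# ---------------------------------------------------------------------------
# Fast SPA-level simulation (no EEG) for statistical calibration checks
# ---------------------------------------------------------------------------

def simulate_spa_null(n_a: int = 13, n_b: int = 27, n_columns: int = 500,
                      log_sd: float = TYPICAL_SPA_LOG_SD,
                      seed: int = 0) -> np.ndarray:
    """Simulate SPA index columns under interhemispheric symmetry.

    Both groups draw from the same log-normal centred on SPA = 1, so any
    Mann-Whitney rejection is a type-I error. Returns the per-column
    two-sided p-values.
    """
    from .stats import mann_whitney_u

    rng = np.random.default_rng(seed)
    pvals = np.empty(n_columns)
    for i in range(n_columns):
        a = np.exp(rng.normal(0.0, log_sd, n_a))
        b = np.exp(rng.normal(0.0, log_sd, n_b))
        pvals[i] = mann_whitney_u(a, b).p
    return pvals
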