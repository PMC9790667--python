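"""EDF input/output, filtering, bipolar montage and N2 extraction.

Infant sleep EEG arrives as referential EDF recordings with the ten 10-20
electrodes Fp1, Fp2, F3, F4, C3, C4, T3, T4, O1, O2 sampled at 256 Hz.
Analysis runs on a longitudinal bipolar montage of ten derivations (five
homologous left/right pairs) restricted to visually staged N2 sleep.

Reading uses MNE's EDF reader; writing uses a minimal EDF writer included
here (16-bit samples, one-second data records) so synthetic cohorts can be
round-tripped through the same clinical file format.
"""

from __future__ import annotations

import csv
import math
import struct
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import signal

__all__ = [
    "REQUIRED_ELECTRODES",
    "DERIVATIONS",
    "LEFT_DERIVATIONS",
    "RIGHT_DERIVATIONS",
    "RawRecording",
    "BipolarRecording",
    "N2Segment",
    "ChannelError",
    "EligibilityError",
    "read_edf",
    "write_edf",
    "apply_filters",
    "make_bipolar",
    "extract_n2",
    "read_sidecar_segments",
    "read_sidecar_bad_channels",
    "MIN_N2_SECONDS",
]

#: electrodes the analysis montage needs, 10-20 names
REQUIRED_ELECTRODES = ("Fp1", "Fp2", "F3", "F4", "C3", "C4", "T3", "T4", "O1", "O2")

#: analysis derivations, left block then right block; C3-T3/C4-T4 are
#: synthesized from referential channels to provide the centro-temporal region
DERIVATIONS = (
    "Fp1-C3", "C3-O1", "Fp1-T3", "T3-O1", "C3-T3",
    "Fp2-C4", "C4-O2", "Fp2-T4", "T4-O2", "C4-T4",
)
LEFT_DERIVATIONS = DERIVATIONS[:5]
RIGHT_DERIVATIONS = DERIVATIONS[5:]

#: eligibility floor: at least 5 minutes of clear N2 sleep per subject
MIN_N2_SECONDS = 300.0

TARGET_FS = 256.0

#: reference-suffix decorations seen across vendor EDF dialects
_LABEL_STRIP = ("-REF", "-LE", "-A1", "-A2", "-AVG", "-M1", "-M2")
_LABEL_PREFIX = ("EEG ", "EEG")


class ChannelError(ValueError):
    """A required electrode is missing or inconsistent across channels."""


class EligibilityError(ValueError):
    """The subject does not meet the N2-duration inclusion criterion."""


def canonical_label(label: str) -> str | None:
    """Map a vendor channel label onto a canonical 10-20 electrode name.

    Matching is case-insensitive and strips common reference suffixes
    ("C3-REF", "EEG C3-A1", ...). Returns None for non-EEG channels.
    """
    s = label.strip()
    for pre in _LABEL_PREFIX:
        if s.upper().startswith(pre.upper()):
            s = s[len(pre):].strip()
    for suf in _LABEL_STRIP:
        if s.upper().endswith(suf):
            s = s[: -len(suf)].strip()
    for e in REQUIRED_ELECTRODES:
        if s.upper() == e.upper():
            return e
    return None


@dataclass
class RawRecording:
    """Referential multichannel EEG in microvolts.

    data has shape (n_channels, n_samples); annotations are
    (label, start_s, end_s) triples in seconds from recording start,
    intervals half-open [start, end).
    """

    subject_id: str
    channel_labels: list[str]
    fs: float
    data: np.ndarray
    annotations: list[tuple[str, float, float]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")
        if self.data.ndim != 2 or self.data.shape[0] != len(self.channel_labels):
            raise ValueError("data must be (n_channels, n_samples)")

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs

    def channel(self, electrode: str) -> np.ndarray:
        for i, lab in enumerate(self.channel_labels):
            if canonical_label(lab) == electrode:
                return self.data[i]
        raise ChannelError(f"electrode not found: {electrode}")


@dataclass
class BipolarRecording:
    """Bipolar-derivation EEG, optionally restricted to N2 samples.

    sample_times maps each retained sample back to seconds in the original
    recording so detected event onsets stay in original recording time.
    """

    subject_id: str
    derivations: list[str]
    fs: float
    data: np.ndarray
    excluded: set[str] = field(default_factory=set)
    sample_times: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.sample_times is None:
            self.sample_times = np.arange(self.data.shape[1]) / self.fs
        self.sample_times = np.asarray(self.sample_times, dtype=np.float64)

    @property
    def duration_s(self) -> float:
        return self.data.shape[1] / self.fs

    def derivation(self, name: str) -> np.ndarray:
        return self.data[self.derivations.index(name)]


@dataclass(frozen=True)
class N2Segment:
    """One annotated N2-sleep interval, [start_s, end_s) in recording time."""

    start_s: float
    end_s: float
    recording_id: str = ""

    def __post_init__(self) -> None:
        if self.end_s <= self.start_s:
            raise ValueError("N2 segment must have end_s > start_s")

    @property
    def duration_s(self) -> float:
        return self.end_s - self.start_s


# ---------------------------------------------------------------------------
# EDF reading (MNE) and minimal EDF writing
# ---------------------------------------------------------------------------

def read_edf(path: str | Path, subject_id: str | None = None) -> RawRecording:
    """Read an EDF/EDF+ file into a RawRecording (microvolts).

    Annotations present in the file (EDF+ annotation channel) are parsed into
    (label, start_s, end_s) triples. Recordings not sampled at 256 Hz are
    resampled to 256 Hz with MNE's anti-aliased polyphase resampler.
    """
    import mne

    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    raw = mne.io.read_raw_edf(path, preload=True, verbose="error")

    found: dict[str, str] = {}
    for lab in raw.ch_names:
        canon = canonical_label(lab)
        if canon is not None and canon not in found:
            found[canon] = lab
    missing = [e for e in REQUIRED_ELECTRODES if e not in found]
    if missing:
        raise ChannelError(f"required electrodes missing from EDF: {missing}")

    raw.pick([found[e] for e in REQUIRED_ELECTRODES])
    if abs(raw.info["sfreq"] - TARGET_FS) > 1e-9:
        raw.resample(TARGET_FS, verbose="error")
    data_uv = raw.get_data() * 1e6  # MNE returns volts

    annotations = [
        (str(a["description"]), float(a["onset"]), float(a["onset"]) + float(a["duration"]))
        for a in raw.annotations
    ]
    return RawRecording(
        subject_id=subject_id or path.stem,
        channel_labels=list(REQUIRED_ELECTRODES),
        fs=float(raw.info["sfreq"]),
        data=data_uv,
        annotations=annotations,
    )


def _ascii(value: object, width: int) -> bytes:
    s = str(value)
    if len(s) > width:
        s = s[:width]
    return s.ljust(width).encode("ascii")


def write_edf(rec: RawRecording, path: str | Path) -> Path:
    """Write a RawRecording to a plain EDF file.

    16-bit samples, one-second data records; the physical range per channel
    is taken from the data (symmetric, with headroom), so a round trip is
    exact up to 16-bit quantization. The recording is zero-padded to a whole
    number of one-second records. Annotations are not embedded; N2 segments
    travel in sidecar CSVs.
    """
    path = Path(path)
    fs = rec.fs
    if abs(fs - round(fs)) > 1e-9:
        raise ValueError("EDF writer requires an integer sampling rate")
    spr = int(round(fs))  # samples per record per channel (1-s records)
    nchan = len(rec.channel_labels)
    n = rec.n_samples
    nrec = math.ceil(n / spr)
    data = np.zeros((nchan, nrec * spr))
    data[:, :n] = rec.data

    phys_max = np.max(np.abs(data), axis=1)
    phys_max = np.where(phys_max < 1e-6, 1.0, phys_max * 1.0001)
    dig_max, dig_min = 32767, -32768

    with open(path, "wb") as f:
        f.write(_ascii(0, 8))
        f.write(_ascii(rec.subject_id, 80))
        f.write(_ascii("Startdate X X X X", 80))
        f.write(_ascii("01.01.20", 8))
        f.write(_ascii("00.00.00", 8))
        f.write(_ascii(256 + 256 * nchan, 8))
        f.write(_ascii("", 44))
        f.write(_ascii(nrec, 8))
        f.write(_ascii(1, 8))
        f.write(_ascii(nchan, 4))
        for lab in rec.channel_labels:
            f.write(_ascii(lab, 16))
        for _ in range(nchan):
            f.write(_ascii("AgAgCl electrode", 80))
        for _ in range(nchan):
            f.write(_ascii("uV", 8))
        for pm in phys_max:
            f.write(_ascii(f"{-pm:.6g}"[:8], 8))
        for pm in phys_max:
            f.write(_ascii(f"{pm:.6g}"[:8], 8))
        for _ in range(nchan):
            f.write(_ascii(dig_min, 8))
        for _ in range(nchan):
            f.write(_ascii(dig_max, 8))
        for _ in range(nchan):
            f.write(_ascii("", 80))
        for _ in range(nchan):
            f.write(_ascii(spr, 8))
        for _ in range(nchan):
            f.write(_ascii("", 32))

        # physical -> digital, per EDF linear scaling
        pmin = -phys_max
        scale = (dig_max - dig_min) / (phys_max - pmin)
        for r in range(nrec):
            for c in range(nchan):
                chunk = data[c, r * spr:(r + 1) * spr]
                dig = np.round((chunk - pmin[c]) * scale[c] + dig_min)
                dig = np.clip(dig, dig_min, dig_max).astype("<i2")
                f.write(struct.pack(f"<{spr}h", *dig))
    return path


# ---------------------------------------------------------------------------
# Filtering and montage
# ---------------------------------------------------------------------------

def _fir_bandpass(lo_hz: float, hi_hz: float, fs: float,
                  transition_hz: float) -> np.ndarray:
    """Linear-phase FIR band-pass (Hamming), odd length."""
    numtaps = int(3.3 * fs / transition_hz)
    numtaps += (numtaps + 1) % 2
    return signal.firwin(numtaps, [lo_hz, hi_hz], pass_zero=False, fs=fs)


def zero_phase_bandpass(x: np.ndarray, lo_hz: float, hi_hz: float, fs: float,
                        transition_hz: float = 0.6) -> np.ndarray:
    """Apply a zero-phase FIR band-pass along the last axis, length preserved.

    The symmetric FIR kernel is applied by centred FFT convolution, which is
    exactly zero-phase and avoids the group delay of a causal pass.
    """
    if hi_hz >= fs / 2:
        raise ValueError(f"upper cut-off {hi_hz} Hz must be below Nyquist ({fs / 2} Hz)")
    if lo_hz >= hi_hz:
        raise ValueError("lower cut-off must be below upper cut-off")
    h = _fir_bandpass(lo_hz, hi_hz, fs, transition_hz)
    x = np.asarray(x, dtype=np.float64)
    one_d = x.ndim == 1
    y = signal.fftconvolve(np.atleast_2d(x), h[None, :], mode="same", axes=1)
    return y[0] if one_d else y


def apply_filters(rec: RawRecording, hp_hz: float = 0.3, lp_hz: float = 70.0) -> RawRecording:
    """Band-pass every channel between hp_hz and lp_hz, zero phase.

    Defaults follow routine clinical review settings: 0.3 Hz high-pass to
    remove drift/DC, 70 Hz low-pass. Length is preserved.
    """
    if lp_hz >= rec.fs / 2:
        raise ValueError(f"low-pass cut-off {lp_hz} Hz >= Nyquist for fs={rec.fs}")
    if hp_hz >= lp_hz:
        raise ValueError("hp_hz must be below lp_hz")
    out = zero_phase_bandpass(rec.data, hp_hz, lp_hz, rec.fs, transition_hz=2 * hp_hz)
    return RawRecording(rec.subject_id, list(rec.channel_labels), rec.fs, out,
                        list(rec.annotations))


def make_bipolar(rec: RawRecording, excluded: set[str] | None = None) -> BipolarRecording:
    """Build the ten-derivation longitudinal bipolar montage.

    Each derivation is the sample-wise difference of its two referential
    electrodes; the centro-temporal pair C3-T3/C4-T4 is synthesized the same
    way (equivalently (C3-O1) − (T3-O1)).
    """
    rows = []
    for name in DERIVATIONS:
        a, b = name.split("-")
        rows.append(rec.channel(a) - rec.channel(b))
    return BipolarRecording(
        subject_id=rec.subject_id,
        derivations=list(DERIVATIONS),
        fs=rec.fs,
        data=np.vstack(rows),
        excluded=set(excluded or ()),
    )


def merge_segments(segments: list[N2Segment]) -> list[N2Segment]:
    """Merge overlapping/adjacent segments into disjoint sorted intervals."""
    if not segments:
        return []
    segs = sorted(segments, key=lambda s: s.start_s)
    merged = [segs[0]]
    for s in segs[1:]:
        last = merged[-1]
        if s.start_s <= last.end_s:
            if s.end_s > last.end_s:
                merged[-1] = N2Segment(last.start_s, s.end_s, last.recording_id)
        else:
            merged.append(s)
    return merged


def extract_n2(rec: RawRecording, segments: list[N2Segment],
               excluded: set[str] | None = None,
               min_total_s: float = MIN_N2_SECONDS) -> BipolarRecording:
    """Montage the recording and keep only annotated N2 samples.

    Returns a BipolarRecording whose sample_times give the original
    recording time of every retained sample. Subjects with less than
    min_total_s of N2 (default 300 s) are refused with EligibilityError.
    """
    segs = merge_segments(segments)
    for s in segs:
        if s.end_s > rec.duration_s + 0.5 / rec.fs or s.start_s < 0:
            raise ValueError(
                f"N2 segment [{s.start_s}, {s.end_s}) outside recording "
                f"duration {rec.duration_s:.1f} s")
    total = sum(s.duration_s for s in segs)
    if total < min_total_s:
        raise EligibilityError(
            f"subject {rec.subject_id}: {total:.1f} s of N2 < required {min_total_s:.0f} s")

    bip = make_bipolar(rec, excluded=excluded)
    idx = np.concatenate([
        np.arange(int(round(s.start_s * rec.fs)), int(round(s.end_s * rec.fs)))
        for s in segs
    ])
    idx = idx[idx < bip.data.shape[1]]
    return BipolarRecording(
        subject_id=rec.subject_id,
        derivations=list(bip.derivations),
        fs=rec.fs,
        data=bip.data[:, idx],
        excluded=set(excluded or ()),
        sample_times=idx / rec.fs,
    )


def segments_from_annotations(rec: RawRecording, label: str = "N2") -> list[N2Segment]:
    """Collect N2 segments from recording annotations with the given label."""
    return [N2Segment(a[1], a[2], rec.subject_id)
            for a in rec.annotations if a[0].upper() == label.upper()]


def bad_channels_from_annotations(rec: RawRecording, prefix: str = "BAD_") -> set[str]:
    return {a[0][len(prefix):] for a in rec.annotations if a[0].startswith(prefix)}


# ---------------------------------------------------------------------------
# Sidecar CSVs (subject_id, start_s, end_s) and (subject_id, derivation)
# ---------------------------------------------------------------------------

def read_sidecar_segments(path: str | Path, subject_id: str) -> list[N2Segment]:
    """Read N2 segments for one subject from a sidecar CSV."""
    out: list[N2Segment] = []
    with open(path, newline="") as f:
        for row in csv.DictReader(f):
            if row["subject_id"] == subject_id:
                out.append(N2Segment(float(row["start_s"]), float(row["end_s"]), subject_id))
    return out


def read_sidecar_bad_channels(path: str | Path, subject_id: str) -> set[str]:
    """Read excluded derivations for one subject from a sidecar CSV."""
    out: set[str] = set()
    with open(path, newline="") as f:
        for row in csv.DictReader(f):
            if row["subject_id"] == subject_id:
                out.add(row["derivation"])
    return out
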