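"""Filtering, Pan–Tompkins R-peak detection and cycle segmentation.

The chain applied to every recording before generation or recognition:

1. zero-phase high-pass (0.5 Hz) removes respiratory baseline drift,
2. zero-phase notch (60 Hz) removes powerline interference,
3. Pan–Tompkins detection locates R peaks,
4. an R-centred window around each peak is resampled to a fixed length and
   max-abs normalised, yielding one :class:`CycleSegment` per beat.

Filtering is zero-phase (forward-backward) so R-peak latency is preserved.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from scipy import signal

from .synthetic import EcgRecording

__all__ = [
    "FilterConfig",
    "SegmentationConfig",
    "CycleSegment",
    "CycleSequence",
    "highpass_baseline_removal",
    "notch_powerline",
    "preprocess_recording",
    "detect_r_peaks",
    "segment_cycles",
    "build_cycle_sequences",
    "save_cycle_bank",
    "load_cycle_bank",
]


@dataclass(frozen=True)
class FilterConfig:
    highpass_cutoff: float = 0.5  # Hz
    notch_freq: float = 60.0  # Hz
    notch_q: float = 30.0
    filter_order: int = 3

    def validate(self, fs: float) -> None:
        if not 0 < self.highpass_cutoff < self.notch_freq < fs / 2:
            raise ValueError(
                "require 0 < highpass_cutoff < notch_freq < fs/2 "
                f"(got {self.highpass_cutoff}, {self.notch_freq}, fs={fs})"
            )


@dataclass(frozen=True)
class SegmentationConfig:
    """R-centred cycle window: ``pre_r_s`` before to ``post_r_s`` after the
    peak, resampled to ``cycle_len`` samples.  The asymmetric default covers
    P through T at rest and after exercise."""

    pre_r_s: float = 0.25
    post_r_s: float = 0.45
    cycle_len: int = 256

    def __post_init__(self) -> None:
        if self.pre_r_s <= 0 or self.post_r_s <= 0:
            raise ValueError("window extents must be positive")
        if self.cycle_len < 32:
            raise ValueError("cycle_len must be >= 32")


@dataclass
class CycleSegment:
    """One amplitude-normalised heartbeat cycle."""

    subject_id: str
    state: str
    session: int
    source: str  # "real" or "synthetic"
    values: np.ndarray

    def __post_init__(self) -> None:
        if self.source not in ("real", "synthetic"):
            raise ValueError("source must be 'real' or 'synthetic'")
        self.values = np.asarray(self.values, dtype=np.float64)


@dataclass
class CycleSequence:
    """An ordered run of cycles used as one recognition input."""

    cycles: list[CycleSegment]
    subject_id: str
    scheme: str = "Real1~5"

    def __post_init__(self) -> None:
        lens = {len(c.values) for c in self.cycles}
        if len(lens) > 1:
            raise ValueError("all cycles in a sequence must share one length")

    def stacked(self) -> np.ndarray:
        """Cycles concatenated into one 1D vector (n_cycles * cycle_len)."""
        return np.concatenate([c.values for c in self.cycles])


def highpass_baseline_removal(
    rec: EcgRecording, cfg: FilterConfig = FilterConfig()
) -> EcgRecording:
    """Zero-phase Butterworth high-pass at ``cfg.highpass_cutoff``."""
    if rec.fs <= 2 * cfg.highpass_cutoff:
        raise ValueError("highpass cutoff must be below Nyquist")
    sos = signal.butter(
        cfg.filter_order, cfg.highpass_cutoff, btype="highpass", fs=rec.fs, output="sos"
    )
    return rec.with_samples(signal.sosfiltfilt(sos, rec.samples))


def notch_powerline(rec: EcgRecording, cfg: FilterConfig = FilterConfig()) -> EcgRecording:
    """Zero-phase IIR notch at ``cfg.notch_freq`` (quality ``cfg.notch_q``)."""
    if rec.fs <= 2 * cfg.notch_freq:
        raise ValueError("notch frequency must be below Nyquist")
    b, a = signal.iirnotch(cfg.notch_freq, cfg.notch_q, fs=rec.fs)
    return rec.with_samples(signal.filtfilt(b, a, rec.samples))


def preprocess_recording(
    rec: EcgRecording, cfg: FilterConfig = FilterConfig()
) -> EcgRecording:
    """High-pass then notch; the standard two-stage cleanup."""
    cfg.validate(rec.fs)
    return notch_powerline(highpass_baseline_removal(rec, cfg), cfg)


# ---------------------------------------------------------------------------
# Pan–Tompkins QRS detection
# ---------------------------------------------------------------------------


def _pan_tompkins_stages(x: np.ndarray, fs: float) -> tuple[np.ndarray, np.ndarray]:
    """Band-pass 5–15 Hz, five-point derivative, squaring, 150 ms moving
    integration.  Returns (band-passed signal, integrated signal)."""
    sos = signal.butter(3, [5.0, 15.0], btype="bandpass", fs=fs, output="sos")
    bp = signal.sosfiltfilt(sos, x)
    # classic five-point derivative kernel (1/8)(2, 1, 0, -1, -2) * fs
    kernel = np.array([2.0, 1.0, 0.0, -1.0, -2.0]) * fs / 8.0
    deriv = np.convolve(bp, kernel, mode="same")
    squared = deriv**2
    win = max(1, int(round(0.150 * fs)))
    # normalise by the actual in-bounds window size so edge beats do not droop
    coverage = np.convolve(np.ones_like(squared), np.ones(win), mode="same")
    mwi = np.convolve(squared, np.ones(win), mode="same") / coverage
    return bp, mwi


def detect_r_peaks(rec: EcgRecording) -> np.ndarray:
    """Pan–Tompkins QRS detection with dual adaptive thresholds.

    Stages: 5–15 Hz band-pass, five-point derivative, squaring, 150 ms
    moving-window integration, adaptive signal/noise levels with search-back
    at half threshold when a 1.66*RR gap opens, a 200 ms refractory period,
    and final refinement to the local band-passed maximum within ±50 ms.
    Detections are invariant to global amplitude scaling (thresholds adapt
    to the running signal and noise levels).
    """
    x = np.asarray(rec.samples, dtype=np.float64)
    fs = rec.fs
    if len(x) < 2 * fs:
        raise ValueError("recording must be at least 2 s long")
    bp, mwi = _pan_tompkins_stages(x, fs)

    refractory = int(round(0.200 * fs))
    # candidate peaks of the integrated waveform; -inf padding lets a QRS
    # riding the record boundary surface as a candidate too
    padded = np.concatenate([[-np.inf], mwi, [-np.inf]])
    cand, _ = signal.find_peaks(padded, distance=refractory)
    cand = cand - 1
    if len(cand) == 0:
        return np.array([], dtype=np.int64)

    # initialise levels from the first two seconds
    init = mwi[: int(2 * fs)]
    spki = 0.6 * float(np.max(init))
    npki = 0.5 * float(np.mean(init))
    threshold = npki + 0.25 * (spki - npki)

    qrs: list[int] = []
    rr_hist: list[float] = []

    def accept(idx: int, level: float) -> None:
        nonlocal spki
        spki = 0.125 * level + 0.875 * spki
        if qrs:
            rr_hist.append((idx - qrs[-1]) / fs)
            if len(rr_hist) > 8:
                rr_hist.pop(0)
        qrs.append(idx)

    for idx in cand:
        level = mwi[idx]
        if qrs and idx - qrs[-1] < refractory:
            continue
        if level > threshold:
            accept(int(idx), float(level))
        else:
            npki = 0.125 * float(level) + 0.875 * npki
        threshold = npki + 0.25 * (spki - npki)

        # search-back: if the gap since the last QRS exceeds 1.66 * mean RR,
        # take the best candidate in the gap at half threshold
        if qrs and rr_hist:
            rr_mean = float(np.mean(rr_hist))
            if (idx - qrs[-1]) / fs > 1.66 * rr_mean:
                gap = [
                    c
                    for c in cand
                    if qrs[-1] + refractory < c < idx and mwi[c] > 0.5 * threshold
                ]
                if gap:
                    best = int(max(gap, key=lambda c: mwi[c]))
                    accept(best, float(mwi[best]))
                    qrs.sort()

    if not qrs:
        return np.array([], dtype=np.int64)

    # refine each detection to the band-passed local maximum within ±50 ms
    half = int(round(0.050 * fs))
    refined = []
    for idx in sorted(set(qrs)):
        lo, hi = max(0, idx - half), min(len(bp), idx + half + 1)
        refined.append(lo + int(np.argmax(bp[lo:hi])))
    refined = np.asarray(sorted(set(refined)), dtype=np.int64)
    # enforce refractory after refinement
    keep = [0]
    for i in range(1, len(refined)):
        if refined[i] - refined[keep[-1]] >= refractory:
            keep.append(i)
    return refined[keep]


def segment_cycles(
    rec: EcgRecording,
    peaks: Sequence[int] | np.ndarray,
    cfg: SegmentationConfig = SegmentationConfig(),
    source: str = "real",
) -> list[CycleSegment]:
    """Extract an R-centred window per peak, resample to ``cycle_len`` and
    max-abs normalise.  Peaks whose window overruns the record are dropped."""
    peaks = np.asarray(peaks, dtype=np.int64)
    if len(peaks) == 0:
        raise ValueError("peaks must be nonempty")
    pre = int(round(cfg.pre_r_s * rec.fs))
    post = int(round(cfg.post_r_s * rec.fs))
    out: list[CycleSegment] = []
    for pk in peaks:
        lo, hi = pk - pre, pk + post
        if lo < 0 or hi > len(rec.samples):
            continue
        window = rec.samples[lo:hi]
        resampled = signal.resample(window, cfg.cycle_len)
        peak_abs = np.max(np.abs(resampled))
        if peak_abs == 0:
            continue
        out.append(
            CycleSegment(
                subject_id=rec.subject_id,
                state=rec.state,
                session=rec.session,
                source=source,
                values=resampled / peak_abs,
            )
        )
    return out


def build_cycle_sequences(
    segments: Iterable[CycleSegment], n_cycles: int = 5
) -> list[CycleSequence]:
    """Group cycles per (subject, state, session) and cut non-overlapping
    consecutive runs of ``n_cycles``; groups with fewer cycles are skipped."""
    groups: dict[tuple[str, str, int], list[CycleSegment]] = {}
    for seg in segments:
        groups.setdefault((seg.subject_id, seg.state, seg.session), []).append(seg)
    sequences: list[CycleSequence] = []
    for key in sorted(groups):
        segs = groups[key]
        for i in range(len(segs) // n_cycles):
            chunk = segs[i * n_cycles : (i + 1) * n_cycles]
            sequences.append(CycleSequence(cycles=chunk, subject_id=key[0]))
    return sequences


# ---------------------------------------------------------------------------
# Cycle-bank persistence: .npz archive + JSON sidecar with per-row labels
# ---------------------------------------------------------------------------


def save_cycle_bank(segments: Sequence[CycleSegment], path: str | Path) -> Path:
    path = Path(path)
    values = np.stack([s.values for s in segments])
    np.savez_compressed(path, values=values)
    meta = [
        {
            "subject_id": s.subject_id,
            "state": s.state,
            "session": s.session,
            "source": s.source,
        }
        for s in segments
    ]
    path.with_suffix(".json").write_text(json.dumps(meta))
    return path if path.suffix == ".npz" else path.with_suffix(".npz")


def load_cycle_bank(path: str | Path) -> list[CycleSegment]:
    path = Path(path)
    if path.suffix != ".npz":
        path = path.with_suffix(".npz")
    values = np.load(path)["values"]
    meta = json.loads(path.with_suffix(".json").read_text())
    return [
        CycleSegment(
            subject_id=m["subject_id"],
            state=m["state"],
            session=int(m["session"]),
            source=m["source"],
            values=v,
        )
        for m, v in zip(meta, values)
    ]
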