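"""Synthetic single-lead ECG study generator.

Produces labelled, noisy, multi-state, multi-subject ECG recordings with known
ground truth (R-peak sample indices, per-subject morphology) so that every
downstream stage — filtering, QRS detection, cycle segmentation, adversarial
generation and recognition — can be exercised and scored without access to a
clinical dataset.

The beat model is a sum of five Gaussians, one per wave (P, Q, R, S, T), each
parameterised by a phase angle relative to the R event, an amplitude in mV and
a Gaussian width in radians.  Acquisition state (lying, standing, before or
after exercise) modulates heart rate and compresses the P/T phase angles
toward the QRS complex, emulating the well-known post-exercise waveform
change.  Noise is additive: sinusoidal baseline drift, 60 Hz powerline
interference and broadband Gaussian muscle noise.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

__all__ = [
    "WAVES",
    "STATES",
    "SubjectMorphology",
    "StateProfile",
    "NoiseSpec",
    "EcgRecording",
    "DEFAULT_WAVE_RANGES",
    "DEFAULT_STATE_PROFILES",
    "DEFAULT_NOISE",
    "generate_subject_bank",
    "synthesize_recording",
    "generate_study",
    "write_recording_csv",
    "read_recording_csv",
]

WAVES = ("P", "Q", "R", "S", "T")
STATES = ("lying", "standing", "before_exercise", "after_exercise")

# Per-wave (theta, amp, width) sampling ranges for the subject bank.
# theta in radians relative to the R event, amp in mV, width in radians.
# Centres follow textbook lead-I morphology; the spread gives each subject a
# distinct but physiologically plausible waveform.
DEFAULT_WAVE_RANGES: dict[str, dict[str, tuple[float, float]]] = {
    "P": {"theta": (-1.25, -0.85), "amp": (0.08, 0.22), "width": (0.18, 0.30)},
    "Q": {"theta": (-0.28, -0.16), "amp": (-0.16, -0.04), "width": (0.07, 0.12)},
    "R": {"theta": (0.0, 0.0), "amp": (0.80, 1.40), "width": (0.08, 0.13)},
    "S": {"theta": (0.16, 0.28), "amp": (-0.30, -0.08), "width": (0.07, 0.12)},
    "T": {"theta": (1.25, 1.75), "amp": (0.15, 0.45), "width": (0.30, 0.50)},
}


@dataclass(frozen=True)
class SubjectMorphology:
    """Five-wave beat template of one subject.

    ``wave_params`` maps each wave name to ``(theta, amp, width)``.
    """

    subject_id: str
    wave_params: dict[str, tuple[float, float, float]]

    def __post_init__(self) -> None:
        thetas = {w: self.wave_params[w][0] for w in WAVES}
        amps = {w: self.wave_params[w][1] for w in WAVES}
        widths = {w: self.wave_params[w][2] for w in WAVES}
        order = [thetas[w] for w in WAVES]
        if not all(a < b for a, b in zip(order, order[1:])):
            raise ValueError("wave phase angles must be ordered P < Q < R < S < T")
        if abs(thetas["R"]) > 1e-12:
            raise ValueError("theta_R must be 0 (R is the fiducial point)")
        if amps["R"] <= 0:
            raise ValueError("amp_R must be positive")
        if any(abs(amps[w]) >= amps["R"] for w in ("P", "Q", "S", "T")):
            raise ValueError("R must be the dominant deflection")
        if any(widths[w] <= 0 for w in WAVES):
            raise ValueError("wave widths must be strictly positive")


@dataclass(frozen=True)
class StateProfile:
    """Heart rate and P/T timing compression for one acquisition state."""

    state: str
    hr_mean: float  # bpm
    hr_sd: float  # bpm
    compression: float  # in (0, 1]; scales |theta_P| and theta_T toward 0

    def __post_init__(self) -> None:
        if self.state not in STATES:
            raise ValueError(f"unknown state {self.state!r}")
        if not 0 < self.compression <= 1:
            raise ValueError("compression must lie in (0, 1]")
        if self.hr_mean <= 0 or self.hr_sd < 0:
            raise ValueError("hr_mean must be > 0 and hr_sd >= 0")
        if self.state == "after_exercise" and self.hr_mean <= 120:
            raise ValueError("after_exercise requires hr_mean > 120 bpm")


# Resting states share a similar rate; standing sits slightly higher;
# the post-exercise state keeps the rate above 120 bpm and pulls the P and
# T waves toward the QRS complex.
DEFAULT_STATE_PROFILES: dict[str, StateProfile] = {
    "lying": StateProfile("lying", hr_mean=62.0, hr_sd=2.5, compression=1.0),
    "standing": StateProfile("standing", hr_mean=74.0, hr_sd=3.5, compression=0.92),
    "before_exercise": StateProfile(
        "before_exercise", hr_mean=65.0, hr_sd=3.0, compression=0.97
    ),
    "after_exercise": StateProfile(
        "after_exercise", hr_mean=128.0, hr_sd=5.0, compression=0.70
    ),
}


@dataclass(frozen=True)
class NoiseSpec:
    """Additive noise model: baseline drift + powerline + broadband."""

    baseline_amp: float = 0.15  # mV
    baseline_freq: float = 0.25  # Hz, below the 0.5 Hz high-pass corner
    powerline_amp: float = 0.05  # mV at powerline_freq
    powerline_freq: float = 60.0  # Hz
    broadband_sd: float = 0.02  # mV, Gaussian

    def __post_init__(self) -> None:
        if min(self.baseline_amp, self.powerline_amp, self.broadband_sd) < 0:
            raise ValueError("noise amplitudes must be >= 0")
        if not 0 < self.baseline_freq < 0.5:
            raise ValueError("baseline_freq must lie in (0, 0.5) Hz")


DEFAULT_NOISE = NoiseSpec()
NOISELESS = NoiseSpec(baseline_amp=0.0, powerline_amp=0.0, broadband_sd=0.0)


@dataclass
class EcgRecording:
    """A labelled single-lead recording in mV.

    ``truth_r_peaks`` carries ground-truth R sample indices and is present
    only for synthetic data.
    """

    subject_id: str
    state: str
    session: int
    fs: float
    samples: np.ndarray
    truth_r_peaks: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=np.float64)
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        if self.truth_r_peaks is not None:
            self.truth_r_peaks = np.asarray(self.truth_r_peaks, dtype=np.int64)
            if np.any(np.diff(self.truth_r_peaks) <= 0):
                raise ValueError("truth_r_peaks must be strictly increasing")

    @property
    def duration_s(self) -> float:
        return len(self.samples) / self.fs

    def with_samples(self, samples: np.ndarray) -> "EcgRecording":
        return EcgRecording(
            self.subject_id,
            self.state,
            self.session,
            self.fs,
            samples,
            None if self.truth_r_peaks is None else self.truth_r_peaks.copy(),
        )


def _draw_morphology(rng: np.random.Generator, subject_id: str) -> SubjectMorphology:
    params: dict[str, tuple[float, float, float]] = {}
    for w in WAVES:
        r = DEFAULT_WAVE_RANGES[w]
        theta = rng.uniform(*r["theta"]) if w != "R" else 0.0
        amp = rng.uniform(*r["amp"])
        width = rng.uniform(*r["width"])
        params[w] = (theta, amp, width)
    return SubjectMorphology(subject_id=subject_id, wave_params=params)


def generate_subject_bank(n_subjects: int, seed: int) -> list[SubjectMorphology]:
    """Draw ``n_subjects`` distinct morphologies from the documented ranges.

    Deterministic given ``seed``; raises ``ValueError`` for ``n_subjects < 2``
    because recognition needs at least two classes.
    """
    if n_subjects < 2:
        raise ValueError("n_subjects must be >= 2 (recognition needs >= 2 classes)")
    rng = np.random.default_rng(seed)
    bank = [_draw_morphology(rng, f"S{i + 1:03d}") for i in range(n_subjects)]
    return bank


def _compressed_params(
    m: SubjectMorphology, compression: float
) -> dict[str, tuple[float, float, float]]:
    out = dict(m.wave_params)
    for w in ("P", "T"):
        theta, amp, width = out[w]
        out[w] = (theta * compression, amp, width)
    return out


def synthesize_recording(
    m: SubjectMorphology,
    p: StateProfile,
    noise: NoiseSpec = DEFAULT_NOISE,
    duration_s: float = 60.0,
    fs: float = 2000.0,
    seed: int = 0,
    session: int = 1,
) -> EcgRecording:
    """Render one recording: Gaussian-wave beats + stochastic RR + noise.

    Per-beat RR intervals are Normal(60/hr_mean, 60*hr_sd/hr_mean**2),
    truncated to >= 0.3 s.  Each beat contributes one Gaussian per wave,
    centred at ``t_R + theta/(2*pi) * RR`` with width ``width/(2*pi) * RR``
    seconds, so faster beats are proportionally compressed.  Ground-truth
    R-peak sample indices are recorded for every beat inside the recording.
    """
    if duration_s <= 0 or fs <= 0:
        raise ValueError("duration_s and fs must be positive")
    rng = np.random.default_rng(seed)
    n = int(round(duration_s * fs))
    t = np.arange(n) / fs
    sig = np.zeros(n)

    rr_mean = 60.0 / p.hr_mean
    rr_sd = 60.0 * p.hr_sd / p.hr_mean**2
    params = _compressed_params(m, p.compression)

    # R times: first beat placed half a mean interval in.  A beat whose QRS
    # cannot be rendered completely before the record ends is not started,
    # so every ground-truth R peak has its full deflection in the signal.
    qrs_margin = 0.05  # s
    r_times: list[float] = []
    t_r = rr_mean / 2
    while t_r < duration_s - qrs_margin:
        r_times.append(t_r)
        rr = max(0.3, rng.normal(rr_mean, rr_sd)) if rr_sd > 0 else rr_mean
        t_r += rr
    r_arr = np.asarray(r_times)

    # Per-beat effective RR (distance to the next beat; last uses the mean).
    rr_eff = np.empty(len(r_arr))
    if len(r_arr) > 1:
        rr_eff[:-1] = np.diff(r_arr)
    rr_eff[-1] = rr_mean

    for t_peak, rr in zip(r_arr, rr_eff):
        for w in WAVES:
            theta, amp, width = params[w]
            centre = t_peak + theta / (2 * np.pi) * rr
            sd = width / (2 * np.pi) * rr
            lo = max(0, int((centre - 5 * sd) * fs))
            hi = min(n, int((centre + 5 * sd) * fs) + 1)
            if hi > lo:
                sig[lo:hi] += amp * np.exp(-((t[lo:hi] - centre) ** 2) / (2 * sd**2))

    if noise.baseline_amp > 0:
        sig += noise.baseline_amp * np.sin(
            2 * np.pi * noise.baseline_freq * t + rng.uniform(0, 2 * np.pi)
        )
    if noise.powerline_amp > 0:
        sig += noise.powerline_amp * np.sin(
            2 * np.pi * noise.powerline_freq * t + rng.uniform(0, 2 * np.pi)
        )
    if noise.broadband_sd > 0:
        sig += rng.normal(0.0, noise.broadband_sd, size=n)

    peaks = np.round(r_arr * fs).astype(np.int64)
    peaks = peaks[peaks < n]
    return EcgRecording(
        subject_id=m.subject_id,
        state=p.state,
        session=session,
        fs=fs,
        samples=sig,
        truth_r_peaks=peaks,
    )


def generate_study(
    n_subjects: int,
    states: Sequence[StateProfile] | None = None,
    sessions_per_subject: int = 3,
    duration_s: float = 60.0,
    fs: float = 2000.0,
    noise: NoiseSpec = DEFAULT_NOISE,
    seed: int = 0,
) -> list[EcgRecording]:
    """Simulate the acquisition protocol: every subject in every state,
    ``sessions_per_subject`` times.

    The session index varies the RR/noise random stream while the subject's
    morphology stays fixed, emulating repeated visits.
    """
    if states is None:
        states = [DEFAULT_STATE_PROFILES[s] for s in STATES]
    if len(states) == 0:
        raise ValueError("states must be nonempty")
    if sessions_per_subject < 1:
        raise ValueError("sessions_per_subject must be >= 1")
    bank = generate_subject_bank(n_subjects, seed)
    ss = np.random.SeedSequence(seed)
    # One child seed per (subject, state, session) keeps streams independent.
    children = ss.spawn(n_subjects * len(states) * sessions_per_subject)
    recs: list[EcgRecording] = []
    i = 0
    for m in bank:
        for p in states:
            for session in range(1, sessions_per_subject + 1):
                sub_seed = int(children[i].generate_state(1)[0] % (2**31))
                i += 1
                recs.append(
                    synthesize_recording(
                        m, p, noise, duration_s, fs, seed=sub_seed, session=session
                    )
                )
    return recs


def write_recording_csv(rec: EcgRecording, out_dir: str | Path) -> Path:
    """Write ``S{subject}_{state}_{session}.csv`` (time_s, mv) plus a JSON
    sidecar with sampling rate and ground-truth R peaks."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    stem = f"{rec.subject_id}_{rec.state}_{rec.session}"
    csv_path = out_dir / f"{stem}.csv"
    t = np.arange(len(rec.samples)) / rec.fs
    np.savetxt(
        csv_path,
        np.column_stack([t, rec.samples]),
        delimiter=",",
        header="time_s,mv",
        comments="",
        fmt="%.6f",
    )
    meta = {
        "subject_id": rec.subject_id,
        "state": rec.state,
        "session": rec.session,
        "fs": rec.fs,
        "truth_r_peaks": None
        if rec.truth_r_peaks is None
        else rec.truth_r_peaks.tolist(),
    }
    (out_dir / f"{stem}.json").write_text(json.dumps(meta))
    return csv_path


def read_recording_csv(csv_path: str | Path) -> EcgRecording:
    """Read a recording written by :func:`write_recording_csv`.

    Falls back to filename parsing and sample spacing when no sidecar exists,
    so externally produced two-column CSVs load too.
    """
    csv_path = Path(csv_path)
    data = np.loadtxt(csv_path, delimiter=",", skiprows=1)
    t, mv = data[:, 0], data[:, 1]
    sidecar = csv_path.with_suffix(".json")
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())
        peaks = meta["truth_r_peaks"]
        return EcgRecording(
            subject_id=meta["subject_id"],
            state=meta["state"],
            session=int(meta["session"]),
            fs=float(meta["fs"]),
            samples=mv,
            truth_r_peaks=None if peaks is None else np.asarray(peaks),
        )
    parts = csv_path.stem.split("_")
    if len(parts) >= 3:
        # states may themselves contain underscores (e.g. after_exercise)
        subject, state, session = parts[0], "_".join(parts[1:-1]), int(parts[-1])
    else:
        subject, state, session = csv_path.stem, "lying", 1
    fs = 1.0 / float(np.median(np.diff(t)))
    return EcgRecording(subject, state, session, fs, mv)
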