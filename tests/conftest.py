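"""Shared fixtures.

Heavy artefacts (the 3-subject adversarially trained generator, the
multi-seed scheme battery) are session-scoped so the whole suite pays for
them once.  Everything is generated programmatically from seeds.
"""

from __future__ import annotations

import time

import numpy as np
import pytest

import ecgacgan as eg
from ecgacgan.synthetic import NoiseSpec


def make_cycle_bank(
    n_subjects: int,
    per_class: int,
    seed: int,
    duration_s: float = 65.0,
    fs: float = 500.0,
    state: str = "lying",
    sessions: tuple[int, ...] = (1, 2, 3),
    broadband_sd: float = 0.02,
) -> dict[str, list[eg.CycleSegment]]:
    """Simulate, filter, detect and segment; returns per-subject cycles."""
    bank = eg.generate_subject_bank(n_subjects, seed=seed)
    profile = eg.DEFAULT_STATE_PROFILES[state]
    out: dict[str, list[eg.CycleSegment]] = {}
    for m in bank:
        segs: list[eg.CycleSegment] = []
        for sess in sessions:
            rec = eg.synthesize_recording(
                m,
                profile,
                NoiseSpec(broadband_sd=broadband_sd),
                duration_s,
                fs,
                seed=seed * 1000 + sess,
                session=sess,
            )
            clean = eg.preprocess_recording(rec)
            peaks = eg.detect_r_peaks(clean)
            segs.extend(eg.segment_cycles(clean, peaks))
            if len(segs) >= per_class:
                break
        out[m.subject_id] = segs[:per_class]
    return out


@pytest.fixture(scope="session")
def toy_bank() -> dict[str, list[eg.CycleSegment]]:
    """3 subjects x 230 cycles: 200 for adversarial training, 30 held out.

    80 s recordings at ~62 bpm yield ~82 beats per session, so three
    sessions comfortably cover the 230 cycles."""
    return make_cycle_bank(3, per_class=230, seed=11, duration_s=80.0)


@pytest.fixture(scope="session")
def toy_gan(toy_bank):
    """The scaled-down generation study: 200 cycles/class, 300 epochs.

    Returns (checkpoint, train cycles, held-out cycles, synthetic cycles,
    training wall time in seconds).
    """
    train = [c for k in sorted(toy_bank) for c in toy_bank[k][:200]]
    held = [c for k in sorted(toy_bank) for c in toy_bank[k][200:]]
    t0 = time.time()
    ckpt = eg.train_acgan(
        train, cfg=eg.GanTrainConfig(epochs=300, batch_size=64, seed=0)
    )
    elapsed = time.time() - t0
    synth = [
        c for cls in ckpt.classes for c in eg.generate_cycles(ckpt, cls, 20, seed=9)
    ]
    return ckpt, train, held, synth, elapsed


BATTERY_SEEDS = (0, 1, 2, 3, 4)


@pytest.fixture(scope="session")
def scheme_battery():
    """Full pipeline at desk scale over five fixture seeds."""
    reports = []
    for s in BATTERY_SEEDS:
        cfg = eg.ExperimentConfig(
            seed_fixture=s, seed_gan=100 + s, seed_ensemble=200 + s
        )
        reports.append(eg.run_experiment(cfg))
    return reports


MICRO_CONFIG = dict(
    n_subjects=3,
    duration_s=10.0,
    fs=400.0,
    gan_epochs=8,
    gan_cycles_per_class=40,
    member_epochs=8,
    n_members=3,
    schemes=("Real1~5", "Real1~4+Synthetic1"),
    seed_fixture=7,
    seed_gan=8,
    seed_ensemble=9,
)


@pytest.fixture(scope="session")
def micro_report_pair():
    """The same tiny experiment run twice, for reproducibility checks."""
    r1 = eg.run_experiment(eg.ExperimentConfig(**MICRO_CONFIG))
    r2 = eg.run_experiment(eg.ExperimentConfig(**MICRO_CONFIG))
    return r1, r2
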