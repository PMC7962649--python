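"""Similarity scoring between real and generated ECG cycles.

Two measures are used.  Cosine similarity compares each generated cycle
against the class's mean real cycle.  The cross-correlation distance compares
the normalised cross-correlation waveform of (current real cycle, synthetic
cycle) with that of (current real cycle, next real cycle) by Euclidean
distance: a synthetic cycle that behaves like a genuine next beat gives a
distance near 0, while cycles of a different subject give larger distances.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .preprocessing import CycleSegment

__all__ = [
    "SimilarityReport",
    "cosine_similarity",
    "cross_correlation",
    "xcorr_euclidean_distance",
    "evaluate_generation",
    "write_similarity_csv",
    "read_similarity_csv",
]


def _check_vec(v: np.ndarray, name: str) -> np.ndarray:
    v = np.asarray(v, dtype=np.float64)
    if np.linalg.norm(v) == 0:
        raise ValueError(f"{name} has zero norm")
    return v


def cosine_similarity(a: Sequence[float], b: Sequence[float]) -> float:
    """dot(a, b) / (||a|| * ||b||); symmetric and scale-invariant."""
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    if a.shape != b.shape:
        raise ValueError("length mismatch")
    a = _check_vec(a, "a")
    b = _check_vec(b, "b")
    return float(np.dot(a, b) / (np.linalg.norm(a) * np.linalg.norm(b)))


def cross_correlation(a: Sequence[float], b: Sequence[float]) -> np.ndarray:
    """Full normalised cross-correlation (length 2L-1).

    Normalised by ||a||*||b|| so the autocorrelation peak equals 1.  Lag
    convention follows ``numpy.correlate(a, b, "full")``: the entry at index
    ``L-1+k`` is sum_i a[i+k] * b[i], so a copy of ``a`` delayed by ``k``
    samples peaks at lag ``+k``.
    """
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    if a.shape != b.shape:
        raise ValueError("length mismatch")
    a = _check_vec(a, "a")
    b = _check_vec(b, "b")
    return np.correlate(a, b, mode="full") / (np.linalg.norm(a) * np.linalg.norm(b))


def xcorr_euclidean_distance(
    current: CycleSegment | np.ndarray,
    next_real: CycleSegment | np.ndarray,
    synthetic: CycleSegment | np.ndarray,
) -> float:
    """Euclidean distance between the two cross-correlation waveforms,
    scaled by sqrt(2L-1) so the value is a per-lag RMS difference.

    Zero when the synthetic cycle equals (or is a positive rescaling of)
    the genuine next cycle.
    """
    cur = current.values if isinstance(current, CycleSegment) else np.asarray(current)
    nxt = (
        next_real.values if isinstance(next_real, CycleSegment) else np.asarray(next_real)
    )
    syn = (
        synthetic.values if isinstance(synthetic, CycleSegment) else np.asarray(synthetic)
    )
    if not (cur.shape == nxt.shape == syn.shape):
        raise ValueError("length mismatch")
    ref = cross_correlation(cur, nxt)
    gen = cross_correlation(cur, syn)
    return float(np.linalg.norm(gen - ref) / np.sqrt(len(ref)))


@dataclass
class SimilarityReport:
    per_class_cosine: dict[str, float]
    per_class_xcorr_dist: dict[str, float]
    overall_cosine: float
    overall_xcorr_dist: float

    def __post_init__(self) -> None:
        vals = list(self.per_class_cosine.values()) + [self.overall_cosine]
        if any(not -1 - 1e-9 <= v <= 1 + 1e-9 for v in vals):
            raise ValueError("cosine values must lie in [-1, 1]")
        dists = list(self.per_class_xcorr_dist.values()) + [self.overall_xcorr_dist]
        if any(d < 0 for d in dists):
            raise ValueError("distances must be >= 0")


def _group(cycles: Sequence[CycleSegment]) -> dict[str, list[CycleSegment]]:
    out: dict[str, list[CycleSegment]] = {}
    for c in cycles:
        out.setdefault(c.subject_id, []).append(c)
    return out


def evaluate_generation(
    real_cycles: Sequence[CycleSegment],
    synthetic_cycles: Sequence[CycleSegment],
    max_triples_per_class: int = 200,
    seed: int = 0,
) -> SimilarityReport:
    """Score a synthetic cycle bank against the real one, per class.

    Cosine: mean over each class's synthetic cycles of the similarity to
    that class's mean real cycle.  Distance: mean over sampled
    (current, next, synthetic) triples, with (current, next) consecutive
    real cycles of the class.
    """
    if len(real_cycles) == 0 or len(synthetic_cycles) == 0:
        raise ValueError("both cycle sets must be nonempty")
    real_by = _group(real_cycles)
    syn_by = _group(synthetic_cycles)
    classes = sorted(set(real_by) & set(syn_by))
    if not classes:
        raise ValueError("real and synthetic class sets are disjoint")
    rng = np.random.default_rng(seed)

    per_cos: dict[str, float] = {}
    per_dist: dict[str, float] = {}
    for cls in classes:
        reals = real_by[cls]
        syns = syn_by[cls]
        mean_real = np.mean([c.values for c in reals], axis=0)
        per_cos[cls] = float(
            np.mean([cosine_similarity(s.values, mean_real) for s in syns])
        )
        if len(reals) >= 2:
            n_pairs = len(reals) - 1
            n_draw = min(max_triples_per_class, n_pairs * len(syns))
            pair_idx = rng.integers(0, n_pairs, size=n_draw)
            syn_idx = rng.integers(0, len(syns), size=n_draw)
            dists = [
                xcorr_euclidean_distance(reals[i], reals[i + 1], syns[j])
                for i, j in zip(pair_idx, syn_idx)
            ]
            per_dist[cls] = float(np.mean(dists))
        else:
            per_dist[cls] = float("nan")

    return SimilarityReport(
        per_class_cosine=per_cos,
        per_class_xcorr_dist=per_dist,
        overall_cosine=float(np.mean(list(per_cos.values()))),
        overall_xcorr_dist=float(np.nanmean(list(per_dist.values()))),
    )


def write_similarity_csv(report: SimilarityReport, path: str | Path) -> Path:
    """One row per class plus an 'overall' row."""
    path = Path(path)
    rows = [
        {
            "class": cls,
            "cosine": report.per_class_cosine[cls],
            "xcorr_distance": report.per_class_xcorr_dist[cls],
        }
        for cls in sorted(report.per_class_cosine)
    ]
    rows.append(
        {
            "class": "overall",
            "cosine": report.overall_cosine,
            "xcorr_distance": report.overall_xcorr_dist,
        }
    )
    pd.DataFrame(rows).to_csv(path, index=False, float_format="%.10g")
    return path


def read_similarity_csv(path: str | Path) -> SimilarityReport:
    df = pd.read_csv(path)
    per = df[df["class"] != "overall"]
    overall = df[df["class"] == "overall"].iloc[0]
    return SimilarityReport(
        per_class_cosine=dict(zip(per["class"], per["cosine"])),
        per_class_xcorr_dist=dict(zip(per["class"], per["xcorr_distance"])),
        overall_cosine=float(overall["cosine"]),
        overall_xcorr_dist=float(overall["xcorr_distance"]),
    )
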