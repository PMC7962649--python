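"""Cosine and cross-correlation-distance metrics against independent oracles."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ecgacgan.preprocessing import CycleSegment
from ecgacgan.similarity import (
    SimilarityReport,
    cosine_similarity,
    cross_correlation,
    evaluate_generation,
    read_similarity_csv,
    write_similarity_csv,
    xcorr_euclidean_distance,
)


def brute_force_xcorr(a, b):
    """O(L^2) direct sum-of-products oracle, normalised like the library."""
    a, b = np.asarray(a, float), np.asarray(b, float)
    L = len(a)
    out = np.zeros(2 * L - 1)
    for lag in range(-(L - 1), L):
        s = 0.0
        for i in range(L):
            j = i + lag
            if 0 <= j < L:
                s += a[j] * b[i]
        out[lag + L - 1] = s
    return out / (np.linalg.norm(a) * np.linalg.norm(b))


def test_cosine_identity_antiparallel_and_known_value():
    v = np.array([3.0, -1.0, 2.0])
    assert cosine_similarity(v, v) == pytest.approx(1.0)
    assert cosine_similarity(v, -v) == pytest.approx(-1.0)
    assert cosine_similarity([1, 0], [1, 1]) == pytest.approx(0.70711, abs=1e-5)


@given(
    a=st.lists(st.floats(-10, 10), min_size=3, max_size=8),
    b=st.lists(st.floats(-10, 10), min_size=3, max_size=8),
    alpha=st.floats(0.1, 10),
    beta=st.floats(0.1, 10),
)
@settings(deadline=None, derandomize=True)
def test_cosine_symmetric_and_scale_invariant(a, b, alpha, beta):
    n = min(len(a), len(b))
    a, b = np.array(a[:n]), np.array(b[:n])
    if np.linalg.norm(a) < 1e-6 or np.linalg.norm(b) < 1e-6:
        return
    c = cosine_similarity(a, b)
    assert c == pytest.approx(cosine_similarity(b, a))
    assert c == pytest.approx(cosine_similarity(alpha * a, beta * b), abs=1e-9)
    assert -1 - 1e-12 <= c <= 1 + 1e-12


def test_cosine_rejects_zero_norm_and_length_mismatch():
    with pytest.raises(ValueError):
        cosine_similarity([0, 0], [1, 1])
    with pytest.raises(ValueError):
        cosine_similarity([1, 2, 3], [1, 2])


def test_autocorrelation_peak_is_one_at_zero_lag():
    v = np.array([1.0, -2.0, 0.5, 3.0])
    xc = cross_correlation(v, v)
    assert len(xc) == 2 * len(v) - 1
    assert np.argmax(xc) == len(v) - 1
    assert xc[len(v) - 1] == pytest.approx(1.0)


def test_shifted_copy_peaks_at_the_shift_lag():
    rng = np.random.default_rng(0)
    v = rng.normal(size=32)
    k = 5
    shifted = np.roll(v, k)
    shifted[:k] = 0  # delayed copy
    xc = cross_correlation(shifted, v)
    assert np.argmax(xc) - (len(v) - 1) == k


@given(
    st.lists(st.integers(-5, 5), min_size=2, max_size=16),
    st.lists(st.integers(-5, 5), min_size=2, max_size=16),
)
@settings(deadline=None, derandomize=True, max_examples=200)
def test_cross_correlation_matches_brute_force_oracle(a, b):
    n = min(len(a), len(b))
    a, b = np.array(a[:n], float), np.array(b[:n], float)
    if not np.any(a) or not np.any(b):
        return
    np.testing.assert_allclose(
        cross_correlation(a, b), brute_force_xcorr(a, b), atol=1e-9
    )


def _seg(values, subject="s1"):
    return CycleSegment(subject, "lying", 1, "real", np.asarray(values, float))


def test_xcorr_distance_zero_for_identical_and_scaled_synthetic():
    rng = np.random.default_rng(1)
    cur, nxt = rng.normal(size=64), rng.normal(size=64)
    assert xcorr_euclidean_distance(cur, nxt, nxt) == pytest.approx(0.0, abs=1e-12)
    assert xcorr_euclidean_distance(cur, nxt, 2.0 * nxt) == pytest.approx(0.0, abs=1e-12)
    with pytest.raises(ValueError):
        xcorr_euclidean_distance(cur, nxt, nxt[:32])


def test_same_subject_distance_below_cross_subject(toy_bank):
    """Genuine next-beat stand-ins score closer than other subjects' cycles."""
    subjects = sorted(toy_bank)
    rng = np.random.default_rng(2)
    wins = total = 0
    for s in subjects:
        own = toy_bank[s][:50]
        for other in subjects:
            if other == s:
                continue
            foreign = toy_bank[other][:50]
            for _ in range(30):
                i = rng.integers(0, len(own) - 1)
                d_same = xcorr_euclidean_distance(
                    own[i], own[i + 1], own[rng.integers(len(own))]
                )
                d_cross = xcorr_euclidean_distance(
                    own[i], own[i + 1], foreign[rng.integers(len(foreign))]
                )
                total += 1
                wins += d_same < d_cross
    assert wins / total >= 0.90


def test_evaluate_generation_on_self_copy_is_perfect():
    """With zero within-class variance a copied bank scores cosine 1 and
    distance 0 (the references equal the copies exactly)."""
    rng = np.random.default_rng(3)
    reals = []
    for i in range(2):
        template = rng.normal(size=32)
        reals += [_seg(template.copy(), subject=f"s{i}") for _ in range(6)]
    copies = [
        CycleSegment(c.subject_id, c.state, c.session, "synthetic", c.values.copy())
        for c in reals
    ]
    rep = evaluate_generation(reals, copies)
    for v in rep.per_class_cosine.values():
        assert v == pytest.approx(1.0, abs=1e-9)
    for d in rep.per_class_xcorr_dist.values():
        assert d == pytest.approx(0.0, abs=1e-9)
    assert rep.overall_cosine == pytest.approx(1.0, abs=1e-9)


def test_evaluate_generation_rejects_disjoint_classes():
    a = [_seg(np.ones(8), "s1")]
    b = [CycleSegment("s2", "lying", 1, "synthetic", np.ones(8))]
    with pytest.raises(ValueError):
        evaluate_generation(a, b)


def test_overall_mean_is_mean_of_balanced_class_means():
    rng = np.random.default_rng(4)
    reals, synths = [], []
    for i in range(3):
        for _ in range(5):
            reals.append(_seg(rng.normal(size=16), f"s{i}"))
            synths.append(
                CycleSegment(f"s{i}", "lying", 1, "synthetic", rng.normal(size=16))
            )
    rep = evaluate_generation(reals, synths)
    assert rep.overall_cosine == pytest.approx(
        np.mean(list(rep.per_class_cosine.values()))
    )
    assert rep.overall_xcorr_dist == pytest.approx(
        np.mean(list(rep.per_class_xcorr_dist.values()))
    )


def test_similarity_report_roundtrips_through_csv(tmp_path):
    rep = SimilarityReport(
        per_class_cosine={"s1": 0.97, "s2": 0.91},
        per_class_xcorr_dist={"s1": 0.12, "s2": 0.34},
        overall_cosine=0.94,
        overall_xcorr_dist=0.23,
    )
    path = write_similarity_csv(rep, tmp_path / "sim.csv")
    back = read_similarity_csv(path)
    assert back.per_class_cosine == pytest.approx(rep.per_class_cosine)
    assert back.per_class_xcorr_dist == pytest.approx(rep.per_class_xcorr_dist)
    assert back.overall_cosine == pytest.approx(rep.overall_cosine)
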