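"""Parallel member training, top-3 selection, fusion and recognition."""

import numpy as np
import pytest

from ecgacgan.ensemble import (
    EnsembleConfig,
    MemberConfig,
    MemberResult,
    build_retraining_set,
    default_member_grid,
    rank_and_select,
    retrain_and_recognize,
    stratified_split,
    train_member,
)
from ecgacgan.preprocessing import CycleSegment, CycleSequence


def _sequences(n_subjects=3, per_subject=24, cycle_len=64, seed=0):
    """Well-separated per-subject waveforms, five cycles per sequence."""
    rng = np.random.default_rng(seed)
    t = np.linspace(0, 1, cycle_len)
    seqs = []
    for s in range(n_subjects):
        base = np.exp(-((t - 0.2 - 0.1 * s) ** 2) / 0.003) + 0.3 * np.sin(
            2 * np.pi * (s + 1) * t
        )
        for i in range(per_subject):
            cycles = []
            for _ in range(5):
                w = base + rng.normal(0, 0.05, cycle_len)
                cycles.append(
                    CycleSegment(
                        f"s{s}", "lying", 1 + i % 3, "real", w / np.max(np.abs(w))
                    )
                )
            seqs.append(CycleSequence(cycles=cycles, subject_id=f"s{s}"))
    return seqs


def _scaled(member_id=0, **kw):
    defaults = dict(
        member_id=member_id, epochs=12, batch_size=16, dropout=0.3, strict=False
    )
    defaults.update(kw)
    return MemberConfig(**defaults)


class TestMemberConfigGrid:
    def test_strict_mode_enforces_the_canonical_grid(self):
        with pytest.raises(ValueError):
            MemberConfig(member_id=0, dropout=0.8)
        with pytest.raises(ValueError):
            MemberConfig(member_id=0, epochs=600)
        with pytest.raises(ValueError):
            MemberConfig(member_id=0, batch_size=128)
        with pytest.raises(ValueError):
            MemberConfig(member_id=0, lr=0.01)
        MemberConfig(member_id=0, lr=0.01, allow_lr_override=True)  # explicit flag
        MemberConfig(member_id=0, epochs=750, batch_size=512, dropout=0.7)

    def test_default_grid_covers_epochs_batch_and_dropout_variation(self):
        grid = default_member_grid(6, paper_faithful=True)
        assert {(c.epochs, c.batch_size) for c in grid} == {
            (500, 256),
            (500, 512),
            (750, 256),
            (750, 512),
        }
        assert {c.dropout for c in grid} == {0.50, 0.70}
        assert len({c.member_id for c in grid}) == 6

    def test_ensemble_config_invariants(self):
        with pytest.raises(ValueError):
            EnsembleConfig(n_members=2)
        with pytest.raises(ValueError):
            EnsembleConfig(pooling="avg")


class TestSelection:
    def _results(self, accs):
        dummy = np.zeros((1, 4))
        return [
            MemberResult(
                member_id=i,
                config=_scaled(i),
                val_accuracy=a,
                fused_outputs=dummy,
                train_subjects=["s0"],
                classes=["s0", "s1"],
                network=None,
            )
            for i, a in enumerate(accs)
        ]

    def test_top3_by_accuracy(self):
        out = rank_and_select(self._results([0.90, 0.80, 0.95, 0.70, 0.85]), k=3)
        assert [r.member_id for r in out] == [2, 0, 4]

    def test_ties_break_toward_lower_member_id(self):
        out = rank_and_select(self._results([0.5] * 5), k=3)
        assert [r.member_id for r in out] == [0, 1, 2]

    def test_exactly_k_members_all_selected(self):
        out = rank_and_select(self._results([0.1, 0.2, 0.3]), k=3)
        assert [r.member_id for r in out] == [2, 1, 0]

    def test_too_few_members_rejected(self):
        with pytest.raises(ValueError):
            rank_and_select(self._results([0.9, 0.8]), k=3)

    def test_selection_is_pure_and_repeatable(self):
        results = self._results([0.90, 0.80, 0.95, 0.70, 0.85])
        a = [r.member_id for r in rank_and_select(results, k=3)]
        b = [r.member_id for r in rank_and_select(results, k=3)]
        assert a == b


@pytest.fixture(scope="module")
def trained_trio():
    seqs = _sequences()
    train, val = stratified_split(seqs, val_fraction=0.25, seed=1)
    results = [
        train_member(train, val, _scaled(i, seed=10 + i, conv_channels=(4, 8)))
        for i in range(3)
    ]
    return train, val, results


def test_member_training_reaches_high_validation_accuracy(trained_trio):
    _, _, results = trained_trio
    assert max(r.val_accuracy for r in results) >= 0.9


def test_member_training_is_seed_deterministic(trained_trio):
    train, val, results = trained_trio
    again = train_member(train, val, _scaled(0, seed=10, conv_channels=(4, 8)))
    assert again.val_accuracy == results[0].val_accuracy
    np.testing.assert_array_equal(again.fused_outputs, results[0].fused_outputs)


def test_member_rejects_single_subject():
    seqs = [s for s in _sequences() if s.subject_id == "s0"]
    train, val = seqs[:12], seqs[12:]
    with pytest.raises(ValueError):
        train_member(train, val, _scaled(0))


def test_fusion_concatenates_aligned_member_features(trained_trio):
    _, _, results = trained_trio
    fused, subjects = build_retraining_set(results)
    h = results[0].fused_outputs.shape[1]
    assert fused.shape == (len(subjects), 3 * h)
    np.testing.assert_array_equal(fused[:, :h], results[0].fused_outputs)

    shuffled = MemberResult(
        member_id=9,
        config=results[0].config,
        val_accuracy=results[0].val_accuracy,
        fused_outputs=results[0].fused_outputs[::-1],
        train_subjects=list(reversed(results[0].train_subjects)),
        classes=results[0].classes,
        network=results[0].network,
    )
    with pytest.raises(ValueError):
        build_retraining_set([shuffled, results[1], results[2]])


def test_member_order_permutation_keeps_accuracy(trained_trio):
    train, _, results = trained_trio
    probes = train[:30]
    accs = []
    for order in ([0, 1, 2], [2, 0, 1]):
        sel = [results[i] for i in order]
        fused = build_retraining_set(sel)
        accs.append(retrain_and_recognize(fused, probes, sel, seed=3))
    assert abs(accs[0] - accs[1]) <= 0.02


def test_recognition_on_training_probes_is_near_perfect(trained_trio):
    train, _, results = trained_trio
    fused = build_retraining_set(results)
    acc = retrain_and_recognize(fused, train, results, seed=4)
    assert acc >= 0.9


def test_empty_comparison_rejected(trained_trio):
    _, _, results = trained_trio
    fused = build_retraining_set(results)
    with pytest.raises(ValueError):
        retrain_and_recognize(fused, [], results, seed=5)


def test_unseen_probe_subject_counts_as_error(trained_trio, caplog):
    train, _, results = trained_trio
    fused = build_retraining_set(results)
    stranger = _sequences(n_subjects=4, per_subject=2, seed=9)
    probes = [s for s in stranger if s.subject_id == "s3"][:2]
    import logging

    with caplog.at_level(logging.WARNING, logger="ecgacgan.ensemble"):
        acc = retrain_and_recognize(fused, probes, results, seed=6)
    assert acc == 0.0
    assert any("unseen" in r.message for r in caplog.records)


def test_stratified_split_keeps_every_subject_in_both_halves():
    seqs = _sequences(n_subjects=4, per_subject=8)
    train, val = stratified_split(seqs, val_fraction=0.25, seed=2)
    subjects = {s.subject_id for s in seqs}
    assert {s.subject_id for s in train} == subjects
    assert {s.subject_id for s in val} == subjects
    assert len(train) + len(val) == len(seqs)
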