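"""Conditional adversarial generator/discriminator: contracts and training."""

import numpy as np
import pytest

import ecgacgan as eg
from ecgacgan.acgan import (
    DiscriminatorSpec,
    GanTrainConfig,
    GeneratorSpec,
    TrainingDiverged,
    build_discriminator,
    build_generator,
    generate_cycles,
    load_checkpoint,
    save_checkpoint,
    train_acgan,
)
from ecgacgan.preprocessing import CycleSegment
from ecgacgan.similarity import cosine_similarity

L = 64  # short cycles keep the unit tests fast


def _tiny_specs(n_classes=2):
    g = GeneratorSpec(
        noise_len=L, n_classes=n_classes, channels_per_layer=(6,) * 9
    )
    d = DiscriminatorSpec(
        cycle_len=L, n_classes=n_classes, conv_layers=3, channels_per_layer=(6, 8, 8)
    )
    return g, d


def _tiny_cycles(n_classes=2, per_class=24, seed=0):
    """Smooth, clearly class-separated waveforms on a short grid."""
    rng = np.random.default_rng(seed)
    t = np.linspace(0, 1, L)
    out = []
    for c in range(n_classes):
        sign = 1.0 if c % 2 else -1.0
        base = np.exp(-((t - 0.25 - 0.3 * c) ** 2) / 0.02) + sign * 0.5 * np.exp(
            -((t - 0.75 + 0.2 * c) ** 2) / 0.03
        )
        for _ in range(per_class):
            wave = base + rng.normal(0, 0.02, size=L)
            out.append(
                CycleSegment(
                    f"s{c}", "lying", 1, "real", wave / np.max(np.abs(wave))
                )
            )
    return out


def test_generator_spec_skeleton_is_enforced():
    with pytest.raises(ValueError):
        GeneratorSpec(conv_layers=8)
    with pytest.raises(ValueError):
        GeneratorSpec(pool_layers=3)
    with pytest.raises(ValueError):
        GeneratorSpec(channels_per_layer=(4,) * 8)


def test_discriminator_must_be_shallower_than_generator():
    with pytest.raises(ValueError):
        DiscriminatorSpec(conv_layers=9, channels_per_layer=(4,) * 9)


def test_untrained_generator_output_contract():
    g_spec, _ = _tiny_specs()
    gen = build_generator(g_spec, seed=0)
    z = np.random.default_rng(1).standard_normal((5, L))
    out = gen.forward(z, np.array([0, 1, 0, 1, 1]))
    assert out.shape == (5, L)
    assert np.all(out >= -1) and np.all(out <= 1)
    again = build_generator(g_spec, seed=0).forward(z, np.array([0, 1, 0, 1, 1]))
    np.testing.assert_array_equal(out, again)
    with pytest.raises(ValueError):
        gen.forward(z, np.array([0, 1, 0, 1, 2]))  # class id out of range


def test_discriminator_heads_batching_and_normalisation():
    _, d_spec = _tiny_specs(n_classes=3)
    d_spec = DiscriminatorSpec(
        cycle_len=L, n_classes=3, conv_layers=2, channels_per_layer=(4, 4)
    )
    dis = build_discriminator(d_spec, seed=0)
    x = np.random.default_rng(2).standard_normal((7, L))
    src, cls = dis.forward(x)
    assert src.shape == (7,) and cls.shape == (7, 3)
    probs = dis.class_probabilities(x)
    np.testing.assert_allclose(probs.sum(axis=1), 1.0, atol=1e-6)
    assert np.all(probs >= 0)
    with pytest.raises(ValueError):
        dis.forward(x[:, : L // 2])


def test_zero_epochs_returns_initialisation():
    cycles = _tiny_cycles()
    g_spec, d_spec = _tiny_specs()
    ckpt = train_acgan(cycles, g_spec, d_spec, GanTrainConfig(epochs=0, seed=3))
    assert all(len(v) == 0 for v in ckpt.history.values())
    init = train_acgan(cycles, g_spec, d_spec, GanTrainConfig(epochs=0, seed=3))
    for a, b in zip(ckpt.g_weights, init.g_weights):
        np.testing.assert_array_equal(a, b)


def test_training_is_seed_deterministic():
    cycles = _tiny_cycles()
    g_spec, d_spec = _tiny_specs()
    cfg = GanTrainConfig(epochs=5, batch_size=16, seed=4)
    h1 = train_acgan(cycles, g_spec, d_spec, cfg).history
    h2 = train_acgan(cycles, g_spec, d_spec, cfg).history
    assert h1 == h2


def test_single_class_input_rejected():
    cycles = [c for c in _tiny_cycles() if c.subject_id == "s0"]
    with pytest.raises(ValueError):
        train_acgan(cycles)


def test_divergence_raises_named_epoch():
    cycles = _tiny_cycles()
    g_spec, d_spec = _tiny_specs()
    cfg = GanTrainConfig(epochs=30, batch_size=16, seed=5, lr_g=5e3, lr_d=5e3)
    with pytest.raises(TrainingDiverged) as err:
        train_acgan(cycles, g_spec, d_spec, cfg)
    assert err.value.epoch >= 0


@pytest.fixture(scope="module")
def tiny_trained():
    cycles = _tiny_cycles(per_class=40)
    g_spec, d_spec = _tiny_specs()
    ckpt = train_acgan(
        cycles,
        g_spec,
        d_spec,
        GanTrainConfig(epochs=150, batch_size=16, seed=6, pretrain_epochs=60),
    )
    return cycles, ckpt


def test_training_output_range_and_finite_history(tiny_trained):
    _, ckpt = tiny_trained
    assert all(np.isfinite(v).all() for v in ckpt.history.values())
    out = generate_cycles(ckpt, "s0", 4, seed=0)
    values = np.stack([c.values for c in out])
    assert np.all(values >= -1) and np.all(values <= 1)


def test_generated_cycles_tagged_and_deterministic(tiny_trained):
    _, ckpt = tiny_trained
    out = generate_cycles(ckpt, "s1", 5, seed=7)
    assert len(out) == 5
    assert all(c.source == "synthetic" and c.subject_id == "s1" for c in out)
    again = generate_cycles(ckpt, "s1", 5, seed=7)
    for a, b in zip(out, again):
        np.testing.assert_array_equal(a.values, b.values)
    with pytest.raises(ValueError):
        generate_cycles(ckpt, "nope", 1)


def test_class_conditioning_separates_outputs(tiny_trained):
    cycles, ckpt = tiny_trained
    gen = ckpt.build_generator()
    z = np.random.default_rng(8).standard_normal((6, L))
    out0 = gen.forward(z, np.zeros(6, dtype=int))
    out1 = gen.forward(z, np.ones(6, dtype=int))
    assert np.linalg.norm(out0 - out1) > 0
    # generated cycles resemble their own class mean more than the other's
    means = {
        s: np.mean([c.values for c in cycles if c.subject_id == s], axis=0)
        for s in ("s0", "s1")
    }
    for cls, other in (("s0", "s1"), ("s1", "s0")):
        gen_cycles = generate_cycles(ckpt, cls, 10, seed=9)
        own = np.mean([cosine_similarity(c.values, means[cls]) for c in gen_cycles])
        cross = np.mean([cosine_similarity(c.values, means[other]) for c in gen_cycles])
        assert own > cross


def test_training_improves_similarity_over_early_checkpoint(tiny_trained):
    """At a fixed seed the final generator beats its epoch-10 ancestor."""
    cycles, ckpt = tiny_trained
    g_spec, d_spec = _tiny_specs()
    early = train_acgan(
        cycles,
        g_spec,
        d_spec,
        GanTrainConfig(epochs=10, batch_size=16, seed=6, pretrain_epochs=60),
    )

    def mean_cosine(checkpoint):
        scores = []
        for s in ("s0", "s1"):
            mean_real = np.mean(
                [c.values for c in cycles if c.subject_id == s], axis=0
            )
            for c in generate_cycles(checkpoint, s, 10, seed=10):
                scores.append(cosine_similarity(c.values, mean_real))
        return np.mean(scores)

    assert mean_cosine(ckpt) >= mean_cosine(early)


def test_checkpoint_roundtrip(tmp_path, tiny_trained):
    _, ckpt = tiny_trained
    path = save_checkpoint(ckpt, tmp_path / "gan.npz")
    back = load_checkpoint(path)
    assert back.classes == ckpt.classes
    assert back.epoch == ckpt.epoch
    assert back.generator_spec == ckpt.generator_spec
    assert back.history == ckpt.history
    a = generate_cycles(ckpt, "s0", 3, seed=11)
    b = generate_cycles(back, "s0", 3, seed=11)
    for x, y in zip(a, b):
        np.testing.assert_array_equal(x.values, y.values)
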