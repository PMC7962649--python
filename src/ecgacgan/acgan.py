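"""Auxiliary-classifier adversarial generation of one-cycle ECG signals.

The generator maps (noise of the same length as the target cycle, class id)
to a cycle in [-1, 1]; the class id enters through a learned embedding that
gates the noise vector element-wise.  Its body is nine 1D convolutional
layers with two max-pooling stages and a fully connected output head — a
deliberately deeper stack than the discriminator, which is a shallower CNN
(default four convolutional layers) with two heads: a real/fake source score
and an auxiliary class classifier.

Training follows the standard auxiliary-classifier formulation: the
discriminator minimises a binary source loss plus the categorical class loss
on both real and generated cycles; the generator minimises the fooling term
plus the class loss on its own outputs.  Any non-finite loss aborts training
with :class:`TrainingDiverged` naming the epoch.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

from . import nn
from .preprocessing import CycleSegment

__all__ = [
    "GeneratorSpec",
    "DiscriminatorSpec",
    "GanTrainConfig",
    "GanCheckpoint",
    "TrainingDiverged",
    "Generator",
    "Discriminator",
    "build_generator",
    "build_discriminator",
    "train_acgan",
    "generate_cycles",
    "save_checkpoint",
    "load_checkpoint",
]


class TrainingDiverged(RuntimeError):
    """Raised when a loss becomes non-finite during adversarial training."""

    def __init__(self, epoch: int, which: str):
        super().__init__(f"non-finite {which} loss at epoch {epoch}")
        self.epoch = epoch


@dataclass(frozen=True)
class GeneratorSpec:
    """Nine conv layers, two pooling stages, one fully connected head."""

    noise_len: int = 256  # equals cycle_len
    n_classes: int = 2
    conv_layers: int = 9
    pool_layers: int = 2
    channels_per_layer: tuple[int, ...] = (4, 4, 6, 6, 8, 8, 10, 10, 12)
    pool_after: tuple[int, ...] = (3, 6)  # pool follows these conv layers
    kernel: int = 9
    leaky_slope: float = 0.2
    combine: str = "mul"  # how the class embedding meets the noise

    def __post_init__(self) -> None:
        if self.conv_layers != 9:
            raise ValueError("generator must have exactly 9 conv layers")
        if self.pool_layers != 2 or len(self.pool_after) != 2:
            raise ValueError("generator must have exactly 2 pooling layers")
        if len(self.channels_per_layer) != 9:
            raise ValueError("channels_per_layer must list 9 entries")
        if any(c <= 0 for c in self.channels_per_layer):
            raise ValueError("channel counts must be positive")
        if self.n_classes < 2:
            raise ValueError("need at least 2 classes")
        if self.combine not in ("mul", "add"):
            raise ValueError("combine must be 'mul' or 'add'")


@dataclass(frozen=True)
class DiscriminatorSpec:
    """Shallower CNN with a source head and an auxiliary class head."""

    cycle_len: int = 256
    n_classes: int = 2
    conv_layers: int = 4
    channels_per_layer: tuple[int, ...] = (8, 12, 16, 16)
    kernel: int = 9
    leaky_slope: float = 0.2

    def __post_init__(self) -> None:
        if not 1 <= self.conv_layers < 9:
            raise ValueError(
                "discriminator must be strictly shallower than the generator "
                "(conv_layers < 9)"
            )
        if len(self.channels_per_layer) != self.conv_layers:
            raise ValueError("channels_per_layer must match conv_layers")


@dataclass(frozen=True)
class GanTrainConfig:
    """``pretrain_epochs`` runs a short supervised warm-up of the generator
    (regression onto real cycles of the conditioned class) before the
    adversarial phase.  This anchors the class embedding to the true class
    identities; without it, small conditional GANs can settle into an
    equilibrium where the generator and the auxiliary classifier agree on a
    *permuted* class code."""

    epochs: int = 300
    batch_size: int = 64
    lr_g: float = 2e-4
    lr_d: float = 2e-4
    seed: int = 0
    label_smoothing: float = 0.0  # real-source target becomes 1 - value
    pretrain_epochs: int = 40
    select_best: bool = True  # keep the checkpoint with best class-mean cosine
    eval_every: int = 10  # epochs between generation-quality evaluations

    def __post_init__(self) -> None:
        if self.epochs < 0 or self.batch_size <= 0:
            raise ValueError("epochs must be >= 0 and batch_size positive")
        if self.lr_g <= 0 or self.lr_d <= 0:
            raise ValueError("learning rates must be positive")
        if not 0 <= self.label_smoothing < 0.5:
            raise ValueError("label_smoothing must lie in [0, 0.5)")
        if self.pretrain_epochs < 0:
            raise ValueError("pretrain_epochs must be >= 0")
        if self.eval_every < 1:
            raise ValueError("eval_every must be >= 1")


class Generator:
    """Callable network mapping (noise, class id) -> cycle in [-1, 1]."""

    def __init__(self, spec: GeneratorSpec, seed: int):
        self.spec = spec
        rng = np.random.default_rng(seed)
        self.embedding = nn.Embedding(spec.n_classes, spec.noise_len, rng)
        layers: list[nn.Layer] = []
        c_in = 1
        length = spec.noise_len
        for i, c_out in enumerate(spec.channels_per_layer, start=1):
            layers.append(nn.Conv1d(c_in, c_out, spec.kernel, rng))
            layers.append(nn.LeakyReLU(spec.leaky_slope))
            if i in spec.pool_after:
                layers.append(nn.MaxPool1d(2))
                length //= 2
            c_in = c_out
        layers.append(nn.Flatten())
        layers.append(nn.Dense(c_in * length, spec.noise_len, rng))
        layers.append(nn.Tanh())
        self.net = nn.Sequential(*layers)
        self._z: np.ndarray | None = None
        self._emb: np.ndarray | None = None

    def forward(self, z: np.ndarray, class_ids: np.ndarray) -> np.ndarray:
        class_ids = np.asarray(class_ids, dtype=np.int64)
        if class_ids.min() < 0 or class_ids.max() >= self.spec.n_classes:
            raise ValueError("class id out of range")
        z = z.astype(nn.DTYPE)
        e = self.embedding.forward(class_ids).astype(nn.DTYPE)
        h = z * e if self.spec.combine == "mul" else z + e
        self._z, self._emb = z, e
        return self.net.forward(h[:, None, :])

    def backward(self, g: np.ndarray) -> None:
        gh = self.net.backward(g)[:, 0, :]
        ge = gh * self._z if self.spec.combine == "mul" else gh
        self.embedding.backward(ge)

    def params(self) -> list[nn.Param]:
        return self.embedding.params() + self.net.params()

    def generate(self, class_ids: np.ndarray, rng: np.random.Generator) -> np.ndarray:
        z = rng.standard_normal((len(class_ids), self.spec.noise_len))
        return self.forward(z, class_ids)


class Discriminator:
    """Shared conv trunk feeding a source head and a class head."""

    def __init__(self, spec: DiscriminatorSpec, seed: int):
        self.spec = spec
        rng = np.random.default_rng(seed)
        layers: list[nn.Layer] = []
        c_in = 1
        length = spec.cycle_len
        for c_out in spec.channels_per_layer:
            layers.append(nn.Conv1d(c_in, c_out, spec.kernel, rng))
            layers.append(nn.LeakyReLU(spec.leaky_slope))
            layers.append(nn.MaxPool1d(2))
            length //= 2
            c_in = c_out
        layers.append(nn.Flatten())
        self.trunk = nn.Sequential(*layers)
        feat = c_in * length
        self.src_head = nn.Dense(feat, 1, rng)
        self.cls_head = nn.Dense(feat, spec.n_classes, rng)

    def forward(self, x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        if x.shape[-1] != self.spec.cycle_len:
            raise ValueError(
                f"expected cycles of length {self.spec.cycle_len}, got {x.shape[-1]}"
            )
        feats = self.trunk.forward(x[:, None, :].astype(nn.DTYPE))
        return self.src_head.forward(feats)[:, 0], self.cls_head.forward(feats)

    def class_probabilities(self, x: np.ndarray) -> np.ndarray:
        return nn.softmax(self.forward(x)[1])

    def backward(self, g_src: np.ndarray, g_cls: np.ndarray) -> None:
        gt = self.src_head.backward(g_src[:, None]) + self.cls_head.backward(g_cls)
        self.trunk.backward(gt)

    def params(self) -> list[nn.Param]:
        return self.trunk.params() + self.src_head.params() + self.cls_head.params()


def build_generator(spec: GeneratorSpec, seed: int = 0) -> Generator:
    return Generator(spec, seed)


def build_discriminator(spec: DiscriminatorSpec, seed: int = 0) -> Discriminator:
    return Discriminator(spec, seed)


@dataclass
class GanCheckpoint:
    generator_spec: GeneratorSpec
    discriminator_spec: DiscriminatorSpec
    classes: list[str]
    epoch: int
    g_weights: list[np.ndarray]
    d_weights: list[np.ndarray]
    history: dict[str, list[float]]  # d_source, d_class, g_source, g_class
    best_epoch: int = -1  # epoch of the retained weights when select_best

    def build_generator(self) -> Generator:
        g = Generator(self.generator_spec, seed=0)
        for p, w in zip(g.params(), self.g_weights):
            p.value = w.astype(nn.DTYPE).copy()
        return g

    def build_discriminator(self) -> Discriminator:
        d = Discriminator(self.discriminator_spec, seed=0)
        for p, w in zip(d.params(), self.d_weights):
            p.value = w.astype(nn.DTYPE).copy()
        return d


def _class_index(cycles: Sequence[CycleSegment]) -> tuple[list[str], np.ndarray]:
    classes = sorted({c.subject_id for c in cycles})
    idx = {c: i for i, c in enumerate(classes)}
    return classes, np.array([idx[c.subject_id] for c in cycles], dtype=np.int64)


def train_acgan(
    cycles: Sequence[CycleSegment],
    g_spec: GeneratorSpec | None = None,
    d_spec: DiscriminatorSpec | None = None,
    cfg: GanTrainConfig = GanTrainConfig(),
) -> GanCheckpoint:
    """Adversarially train generator and discriminator on labelled cycles.

    Deterministic given ``cfg.seed``.  ``epochs=0`` returns the untouched
    initialisation with an empty loss history.
    """
    classes, labels = _class_index(cycles)
    if len(classes) < 2:
        raise ValueError("training needs cycles from at least 2 classes")
    x_all = np.stack([c.values for c in cycles]).astype(nn.DTYPE)
    cycle_len = x_all.shape[1]
    if g_spec is None:
        g_spec = GeneratorSpec(noise_len=cycle_len, n_classes=len(classes))
    if d_spec is None:
        d_spec = DiscriminatorSpec(cycle_len=cycle_len, n_classes=len(classes))
    if g_spec.noise_len != cycle_len or d_spec.cycle_len != cycle_len:
        raise ValueError("spec lengths must match the cycle length")
    if g_spec.n_classes != len(classes) or d_spec.n_classes != len(classes):
        raise ValueError("spec n_classes must match the number of classes present")

    rng = np.random.default_rng(cfg.seed)
    gen = Generator(g_spec, seed=int(rng.integers(2**31)))
    dis = Discriminator(d_spec, seed=int(rng.integers(2**31)))
    opt_g = nn.Adam(gen.params(), lr=cfg.lr_g)
    opt_d = nn.Adam(dis.params(), lr=cfg.lr_d)

    n = len(x_all)
    bs = min(cfg.batch_size, n)
    real_target = 1.0 - cfg.label_smoothing
    history: dict[str, list[float]] = {
        "d_source": [],
        "d_class": [],
        "g_source": [],
        "g_class": [],
        "eval_cosine": [],
    }

    # supervised warm-up: regress generated cycles onto real cycles of the
    # conditioned class (converges toward the class-conditional mean), so the
    # adversarial phase starts from correctly aligned class conditioning
    # fixed evaluation probe: class-conditional samples scored against the
    # class-mean cycles; drives checkpoint selection when select_best is set
    n_eval = 16
    class_means = np.stack(
        [x_all[labels == i].mean(axis=0) for i in range(len(classes))]
    )
    y_eval = np.repeat(np.arange(len(classes)), n_eval)
    z_eval = np.random.default_rng((cfg.seed + 777) % 2**31).standard_normal(
        (len(y_eval), cycle_len)
    )

    def eval_cosine() -> float:
        out = gen.forward(z_eval, y_eval).astype(np.float64)
        refs = class_means[y_eval]
        num = (out * refs).sum(axis=1)
        den = np.linalg.norm(out, axis=1) * np.linalg.norm(refs, axis=1)
        return float(np.mean(num / np.where(den == 0, 1.0, den)))

    best_score = -np.inf
    best_epoch = -1
    best_g: list[np.ndarray] | None = None

    def consider(epoch: int) -> None:
        nonlocal best_score, best_epoch, best_g
        score = eval_cosine()
        history["eval_cosine"].append(score)
        if cfg.select_best and score > best_score:
            best_score = score
            best_epoch = epoch
            best_g = [p.value.copy() for p in gen.params()]

    warmup = cfg.pretrain_epochs if cfg.epochs > 0 else 0  # epochs=0 is a no-op
    if warmup:
        opt_warm = nn.Adam(gen.params(), lr=1e-3, beta1=0.9)
        for _ in range(warmup):
            order = rng.permutation(n)
            for start in range(0, n - bs + 1, bs):
                batch = order[start : start + bs]
                z = rng.standard_normal((bs, cycle_len))
                out = gen.forward(z, labels[batch])
                g_mse = (2.0 * (out - x_all[batch]) / out.size).astype(nn.DTYPE)
                opt_warm.zero_grad()
                gen.backward(g_mse)
                opt_warm.step()

    if cfg.epochs > 0:
        consider(0)  # post-warm-up baseline

    loss_keys = ("d_source", "d_class", "g_source", "g_class")
    for epoch in range(cfg.epochs):
        order = rng.permutation(n)
        ep = {k: 0.0 for k in loss_keys}
        n_batches = 0
        for start in range(0, n - bs + 1, bs):
            batch = order[start : start + bs]
            xr, yr = x_all[batch], labels[batch]

            # --- discriminator step: real batch + equally sized fake batch
            yf = rng.integers(0, len(classes), size=bs)
            zf = rng.standard_normal((bs, cycle_len))
            xf = gen.forward(zf, yf)  # no G update here
            opt_d.zero_grad()
            x_in = np.concatenate([xr, xf])
            src, cls = dis.forward(x_in)
            src_t = np.concatenate([np.full(bs, real_target), np.zeros(bs)])
            loss_src, g_src = nn.bce_with_logits(src, src_t)
            loss_cls, g_cls = nn.softmax_ce(cls, np.concatenate([yr, yf]))
            dis.backward(g_src, g_cls)
            opt_d.step()

            # --- generator step: fool the source head, satisfy the class head
            yg = rng.integers(0, len(classes), size=bs)
            zg = rng.standard_normal((bs, cycle_len))
            xg = gen.forward(zg, yg)
            opt_g.zero_grad()
            opt_d.zero_grad()  # D grads from this pass are discarded
            src_g, cls_g = dis.forward(xg)
            loss_gs, gg_src = nn.bce_with_logits(src_g, np.ones(bs))
            loss_gc, gg_cls = nn.softmax_ce(cls_g, yg)
            # propagate through D into the generated cycles
            gt = dis.src_head.backward(gg_src[:, None]) + dis.cls_head.backward(gg_cls)
            gx = dis.trunk.backward(gt)[:, 0, :]
            gen.backward(gx)
            opt_g.step()

            for key, val in (
                ("d_source", loss_src),
                ("d_class", loss_cls),
                ("g_source", loss_gs),
                ("g_class", loss_gc),
            ):
                if not np.isfinite(val):
                    raise TrainingDiverged(epoch, key)
                ep[key] += val
            n_batches += 1
        for key in loss_keys:
            history[key].append(ep[key] / max(1, n_batches))
        if (epoch + 1) % cfg.eval_every == 0 or epoch + 1 == cfg.epochs:
            consider(epoch + 1)

    # the generator comes from the best-scoring epoch; the discriminator is
    # always the final one (its auxiliary classifier only sharpens with time)
    d_out = [p.value.copy() for p in dis.params()]
    if cfg.select_best and best_g is not None:
        g_out = best_g
    else:
        g_out = [p.value.copy() for p in gen.params()]
        best_epoch = cfg.epochs
    return GanCheckpoint(
        generator_spec=g_spec,
        discriminator_spec=d_spec,
        classes=classes,
        epoch=cfg.epochs,
        g_weights=g_out,
        d_weights=d_out,
        history=history,
        best_epoch=best_epoch,
    )


def generate_cycles(
    ckpt: GanCheckpoint, class_id: str | int, n: int, seed: int = 0
) -> list[CycleSegment]:
    """Sample ``n`` synthetic cycles for one class from a trained checkpoint."""
    if isinstance(class_id, str):
        if class_id not in ckpt.classes:
            raise ValueError(f"unknown class {class_id!r}")
        cls_idx = ckpt.classes.index(class_id)
    else:
        if not 0 <= class_id < len(ckpt.classes):
            raise ValueError(f"class index {class_id} out of range")
        cls_idx = int(class_id)
    gen = ckpt.build_generator()
    rng = np.random.default_rng(seed)
    out = gen.generate(np.full(n, cls_idx, dtype=np.int64), rng)
    return [
        CycleSegment(
            subject_id=ckpt.classes[cls_idx],
            state="generated",
            session=0,
            source="synthetic",
            values=row.astype(np.float64),
        )
        for row in out
    ]


def save_checkpoint(ckpt: GanCheckpoint, path: str | Path) -> Path:
    path = Path(path)
    arrays = {f"g_{i}": w for i, w in enumerate(ckpt.g_weights)}
    arrays.update({f"d_{i}": w for i, w in enumerate(ckpt.d_weights)})
    np.savez_compressed(path, **arrays)
    meta = {
        "generator_spec": _spec_dict(ckpt.generator_spec),
        "discriminator_spec": _spec_dict(ckpt.discriminator_spec),
        "classes": ckpt.classes,
        "epoch": ckpt.epoch,
        "history": ckpt.history,
        "best_epoch": ckpt.best_epoch,
        "n_g": len(ckpt.g_weights),
        "n_d": len(ckpt.d_weights),
    }
    path.with_suffix(".json").write_text(json.dumps(meta))
    return path if path.suffix == ".npz" else path.with_suffix(".npz")


def load_checkpoint(path: str | Path) -> GanCheckpoint:
    path = Path(path)
    if path.suffix != ".npz":
        path = path.with_suffix(".npz")
    data = np.load(path)
    meta = json.loads(path.with_suffix(".json").read_text())
    gs = meta["generator_spec"]
    ds = meta["discriminator_spec"]
    return GanCheckpoint(
        generator_spec=GeneratorSpec(
            **{
                k: tuple(v) if isinstance(v, list) else v
                for k, v in gs.items()
            }
        ),
        discriminator_spec=DiscriminatorSpec(
            **{
                k: tuple(v) if isinstance(v, list) else v
                for k, v in ds.items()
            }
        ),
        classes=list(meta["classes"]),
        epoch=int(meta["epoch"]),
        g_weights=[data[f"g_{i}"] for i in range(meta["n_g"])],
        d_weights=[data[f"d_{i}"] for i in range(meta["n_d"])],
        history={k: list(v) for k, v in meta["history"].items()},
        best_epoch=int(meta.get("best_epoch", -1)),
    )


def _spec_dict(spec) -> dict:
    from dataclasses import asdict

    return {k: list(v) if isinstance(v, tuple) else v for k, v in asdict(spec).items()}
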