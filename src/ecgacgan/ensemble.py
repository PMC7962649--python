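"""User recognition with a parallel ensemble of 1D CNNs.

Several small convolutional classifiers ("members") with deliberately
different hyperparameters are trained on five-cycle sequences.  The three
members with the best validation accuracy are kept; their penultimate-layer
feature vectors are concatenated per input into a fused registration set, a
single dense classifier is retrained on it, and recognition passes each
comparison sequence through the three members and the retrained head.

In strict ("paper-faithful") mode member hyperparameters are confined to the
grid epochs in {500, 750}, batch size in {256, 512}, dropout in [0.50, 0.70]
and learning rate 0.001; scaled-down members for desk-size experiments relax
the grid via ``strict=False``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from . import nn
from .preprocessing import CycleSequence

__all__ = [
    "MemberConfig",
    "MemberResult",
    "EnsembleConfig",
    "MemberNet",
    "default_member_grid",
    "stratified_split",
    "train_member",
    "rank_and_select",
    "build_retraining_set",
    "retrain_and_recognize",
]

logger = logging.getLogger(__name__)

_ALLOWED_EPOCHS = (500, 750)
_ALLOWED_BATCH = (256, 512)


@dataclass(frozen=True)
class MemberConfig:
    member_id: int
    epochs: int = 500
    batch_size: int = 256
    dropout: float = 0.5
    lr: float = 0.001
    conv_channels: tuple[int, ...] = (8, 16)
    kernel: int = 9
    pool: int = 4
    hidden: int = 64
    seed: int = 0
    strict: bool = True  # enforce the canonical hyperparameter grid
    allow_lr_override: bool = False

    def __post_init__(self) -> None:
        if self.strict:
            if self.epochs not in _ALLOWED_EPOCHS:
                raise ValueError(f"epochs must be one of {_ALLOWED_EPOCHS}")
            if self.batch_size not in _ALLOWED_BATCH:
                raise ValueError(f"batch_size must be one of {_ALLOWED_BATCH}")
            if not 0.50 <= self.dropout <= 0.70:
                raise ValueError("dropout must lie in [0.50, 0.70]")
            if self.lr != 0.001 and not self.allow_lr_override:
                raise ValueError("lr is fixed at 0.001 unless allow_lr_override is set")
        else:
            if self.epochs < 0 or self.batch_size <= 0 or self.lr <= 0:
                raise ValueError("invalid scaled-down member configuration")
            if not 0 <= self.dropout < 1:
                raise ValueError("dropout must lie in [0, 1)")
        if len(self.conv_channels) < 1 or self.pool < 1 or self.hidden < 1:
            raise ValueError("invalid architecture parameters")


@dataclass
class MemberResult:
    member_id: int
    config: MemberConfig
    val_accuracy: float
    fused_outputs: np.ndarray  # penultimate features, one row per train input
    train_subjects: list[str]
    classes: list[str]
    network: "MemberNet"

    def __post_init__(self) -> None:
        if not 0 <= self.val_accuracy <= 1:
            raise ValueError("val_accuracy must lie in [0, 1]")
        if self.fused_outputs.shape[0] != len(self.train_subjects):
            raise ValueError("fused_outputs row count must equal input count")


@dataclass(frozen=True)
class EnsembleConfig:
    n_members: int = 6
    top_k: int = 3
    pooling: str = "max"
    n_cycles_per_template: int = 5

    def __post_init__(self) -> None:
        if self.n_members < 3 or self.top_k > self.n_members:
            raise ValueError("need n_members >= 3 and top_k <= n_members")
        if self.pooling != "max":
            raise ValueError("pooling is fixed to max")


# Per-member architecture variation: each member looks at the sequence with a
# different receptive field / width so the ensemble sees different features.
_MEMBER_VARIANTS: list[dict] = [
    {"conv_channels": (8, 16), "kernel": 9},
    {"conv_channels": (12, 16), "kernel": 7},
    {"conv_channels": (8, 24), "kernel": 11},
    {"conv_channels": (12, 24), "kernel": 9},
    {"conv_channels": (16, 16), "kernel": 7},
    {"conv_channels": (8, 16), "kernel": 13},
]


def default_member_grid(
    n_members: int = 6,
    paper_faithful: bool = True,
    epochs_override: int | None = None,
    batch_override: int | None = None,
    seed: int = 0,
) -> list[MemberConfig]:
    """The default parallel grid: epochs x batch crossed with two dropout
    settings.  ``paper_faithful=False`` swaps in scaled-down epochs/batch for
    desk-size fixtures while keeping the dropout/architecture variation."""
    grid = [
        (500, 256, 0.50),
        (500, 512, 0.50),
        (750, 256, 0.50),
        (750, 512, 0.50),
        (500, 256, 0.70),
        (750, 512, 0.70),
    ]
    out = []
    for i in range(n_members):
        epochs, batch, dropout = grid[i % len(grid)]
        variant = _MEMBER_VARIANTS[i % len(_MEMBER_VARIANTS)]
        if not paper_faithful:
            epochs = epochs_override if epochs_override is not None else 50
            batch = batch_override if batch_override is not None else 32
        out.append(
            MemberConfig(
                member_id=i,
                epochs=epochs,
                batch_size=batch,
                dropout=dropout,
                strict=paper_faithful,
                seed=seed + i,
                **variant,
            )
        )
    return out


class MemberNet:
    """conv -> max-pool alternation -> dense hidden -> softmax head.

    The five cycles of a sequence are concatenated into one 1D signal.
    ``embed`` exposes the penultimate (hidden) activations used for fusion.
    """

    def __init__(self, cfg: MemberConfig, input_len: int, n_classes: int):
        rng = np.random.default_rng(cfg.seed)
        layers: list[nn.Layer] = []
        c_in, length = 1, input_len
        for c_out in cfg.conv_channels:
            layers.append(nn.Conv1d(c_in, c_out, cfg.kernel, rng))
            layers.append(nn.LeakyReLU(0.2))
            layers.append(nn.MaxPool1d(cfg.pool))
            length //= cfg.pool
            c_in = c_out
        layers.append(nn.Flatten())
        layers.append(nn.Dropout(cfg.dropout, rng))
        layers.append(nn.Dense(c_in * length, cfg.hidden, rng))
        layers.append(nn.LeakyReLU(0.2))
        self.body = nn.Sequential(*layers)
        self.head = nn.Dense(cfg.hidden, n_classes, rng)
        self.n_classes = n_classes

    def forward(self, x: np.ndarray, training: bool) -> tuple[np.ndarray, np.ndarray]:
        self.body.set_training(training)
        h = self.body.forward(x[:, None, :].astype(nn.DTYPE))
        return h, self.head.forward(h)

    def backward(self, g_logits: np.ndarray) -> None:
        self.body.backward(self.head.backward(g_logits))

    def params(self) -> list[nn.Param]:
        return self.body.params() + self.head.params()

    def embed(self, x: np.ndarray) -> np.ndarray:
        """Penultimate features in evaluation mode."""
        return self.forward(x, training=False)[0]

    def predict_logits(self, x: np.ndarray) -> np.ndarray:
        return self.forward(x, training=False)[1]


def _design_matrix(seqs: Sequence[CycleSequence]) -> tuple[np.ndarray, list[str]]:
    x = np.stack([s.stacked() for s in seqs])
    return x, [s.subject_id for s in seqs]


def stratified_split(
    sequences: Sequence[CycleSequence], val_fraction: float = 0.25, seed: int = 0
) -> tuple[list[CycleSequence], list[CycleSequence]]:
    """Per-subject split so every subject appears in both halves."""
    rng = np.random.default_rng(seed)
    by_subject: dict[str, list[CycleSequence]] = {}
    for s in sequences:
        by_subject.setdefault(s.subject_id, []).append(s)
    train, val = [], []
    for subject in sorted(by_subject):
        group = by_subject[subject]
        order = rng.permutation(len(group))
        n_val = max(1, int(round(val_fraction * len(group)))) if len(group) > 1 else 0
        for j, idx in enumerate(order):
            (val if j < n_val else train).append(group[idx])
    return train, val


def train_member(
    train: Sequence[CycleSequence],
    val: Sequence[CycleSequence],
    cfg: MemberConfig,
) -> MemberResult:
    """Train one parallel member and score it on the validation split."""
    x_train, subj_train = _design_matrix(train)
    x_val, subj_val = _design_matrix(val)
    classes = sorted(set(subj_train))
    if len(classes) < 2:
        raise ValueError("training needs at least 2 subjects")
    if set(subj_val) - set(classes):
        raise ValueError("validation contains subjects unseen in training")
    idx = {c: i for i, c in enumerate(classes)}
    y_train = np.array([idx[s] for s in subj_train])
    y_val = np.array([idx[s] for s in subj_val])

    net = MemberNet(cfg, input_len=x_train.shape[1], n_classes=len(classes))
    opt = nn.Adam(net.params(), lr=cfg.lr, beta1=0.9)
    rng = np.random.default_rng(cfg.seed + 1)
    n = len(x_train)
    bs = min(cfg.batch_size, n)
    for epoch in range(cfg.epochs):
        order = rng.permutation(n)
        for start in range(0, n, bs):
            batch = order[start : start + bs]
            _, logits = net.forward(x_train[batch], training=True)
            loss, g = nn.softmax_ce(logits, y_train[batch])
            if not np.isfinite(loss):
                raise RuntimeError(f"member {cfg.member_id} diverged at epoch {epoch}")
            opt.zero_grad()
            net.backward(g)
            opt.step()

    val_pred = net.predict_logits(x_val).argmax(axis=1)
    val_acc = float(np.mean(val_pred == y_val)) if len(y_val) else 0.0
    fused = net.embed(x_train)
    return MemberResult(
        member_id=cfg.member_id,
        config=cfg,
        val_accuracy=val_acc,
        fused_outputs=fused,
        train_subjects=subj_train,
        classes=classes,
        network=net,
    )


def rank_and_select(results: Sequence[MemberResult], k: int = 3) -> list[MemberResult]:
    """Top-k members by validation accuracy; ties broken by lower member id."""
    if len(results) < k:
        raise ValueError(f"need at least {k} member results, got {len(results)}")
    ranked = sorted(results, key=lambda r: (-r.val_accuracy, r.member_id))
    return list(ranked[:k])


def build_retraining_set(
    selected: Sequence[MemberResult],
) -> tuple[np.ndarray, list[str]]:
    """Concatenate the selected members' penultimate features per input."""
    if len(selected) != 3:
        raise ValueError("fusion expects exactly 3 selected members")
    ref = selected[0].train_subjects
    for r in selected[1:]:
        if r.train_subjects != ref:
            raise ValueError("member outputs are not aligned to the same inputs")
    fused = np.concatenate([r.fused_outputs for r in selected], axis=1)
    return fused, list(ref)


def retrain_and_recognize(
    fused_train: tuple[np.ndarray, Sequence[str]],
    comparison: Sequence[CycleSequence],
    selected_members: Sequence[MemberResult],
    seed: int = 0,
    epochs: int = 200,
    lr: float = 0.001,
) -> float:
    """Retrain a dense classifier on fused features and identify probes.

    Each comparison sequence is embedded by the three selected members,
    concatenated and classified; returns the fraction identified correctly.
    Probes from subjects absent at enrollment can never be correct and are
    counted as errors (with a logged warning).
    """
    if len(comparison) == 0:
        raise ValueError("comparison set must be nonempty")
    x_fused, subjects = fused_train
    x_fused = np.asarray(x_fused, dtype=nn.DTYPE)
    classes = selected_members[0].classes
    idx = {c: i for i, c in enumerate(classes)}
    y = np.array([idx[s] for s in subjects])

    rng = np.random.default_rng(seed)
    head = nn.Dense(x_fused.shape[1], len(classes), np.random.default_rng(seed))
    opt = nn.Adam([*head.params()], lr=lr, beta1=0.9)
    n = len(x_fused)
    bs = min(128, n)
    for _ in range(epochs):
        order = rng.permutation(n)
        for start in range(0, n, bs):
            batch = order[start : start + bs]
            logits = head.forward(x_fused[batch])
            _, g = nn.softmax_ce(logits, y[batch])
            opt.zero_grad()
            head.backward(g)
            opt.step()

    x_cmp, subj_cmp = _design_matrix(comparison)
    unseen = sorted(set(subj_cmp) - set(classes))
    if unseen:
        logger.warning("comparison subjects unseen at enrollment: %s", unseen)
    emb = np.concatenate([m.network.embed(x_cmp) for m in selected_members], axis=1)
    pred = head.forward(emb.astype(nn.DTYPE)).argmax(axis=1)
    correct = [
        classes[p] == s if s in idx else False for p, s in zip(pred, subj_cmp)
    ]
    return float(np.mean(correct))
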