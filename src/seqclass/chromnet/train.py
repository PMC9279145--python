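"""Label generation, on-the-fly sampling and the training loop."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from ..formats import (
    GenomeSequence,
    IntervalSet,
    ProfileCompendium,
    Window,
)
from .model import SequenceModel, one_hot

__all__ = [
    "LabelIndex",
    "make_labels",
    "Partition",
    "OnTheFlySampler",
    "TrainConfig",
    "train",
]


class LabelIndex:
    """Per-profile merged interval indexes for fast centre-bp lookups."""

    def __init__(self, compendium: ProfileCompendium):
        self.compendium = compendium

    def labels_at(self, contig: str, centers: np.ndarray) -> np.ndarray:
        """(n, T) binary labels: label[t] = 1 iff the centre bp lies in a
        peak of profile t."""
        out = np.zeros((len(centers), len(self.compendium)), dtype=float)
        for t, profile in enumerate(self.compendium):
            out[:, t] = profile.peaks.contains_many(contig, centers)
        return out


def make_labels(
    windows: Sequence[Window], compendium: ProfileCompendium
) -> np.ndarray:
    """Binary label matrix ``(n_windows, n_profiles)`` from centre-bp peak
    overlap. Profile filtering (e.g. a minimum peak count) is applied
    upstream via :meth:`ProfileCompendium.filter_min_peaks`."""
    index = LabelIndex(compendium)
    out = np.zeros((len(windows), len(compendium)), dtype=float)
    by_contig: dict[str, list[int]] = {}
    for i, w in enumerate(windows):
        by_contig.setdefault(w.contig, []).append(i)
    for contig, idxs in by_contig.items():
        # a contig with no peaks in any profile is legitimate (all-zero
        # labels, e.g. a peak-free held-out contig)
        centers = np.array([windows[i].center for i in idxs])
        out[np.array(idxs)] = index.labels_at(contig, centers)
    return out


@dataclass(frozen=True)
class Partition:
    """Chromosome-holdout specification."""

    train_contigs: tuple[str, ...]
    val_contigs: tuple[str, ...]
    test_contigs: tuple[str, ...]

    def validate(self, genome: GenomeSequence) -> None:
        known = set(genome.names)
        for group, names in (
            ("train", self.train_contigs),
            ("val", self.val_contigs),
            ("test", self.test_contigs),
        ):
            missing = set(names) - known
            if missing:
                raise ValueError(f"{group} contigs not in genome: {sorted(missing)}")


class OnTheFlySampler:
    """Draws fresh, uniformly positioned training windows every step.

    Positions are sampled length-weighted across the requested contigs;
    windows overlapping the blacklist or containing N are rejected and
    redrawn, so almost every sample comes from a unique genomic interval.
    """

    def __init__(
        self,
        genome: GenomeSequence,
        compendium: ProfileCompendium,
        contigs: Sequence[str],
        seq_len: int,
        blacklist: Optional[IntervalSet] = None,
        seed: int = 0,
        shuffle_labels: bool = False,
    ):
        self.genome = genome
        self.index = LabelIndex(compendium)
        self.contigs = list(contigs)
        self.seq_len = seq_len
        self.blacklist = blacklist
        self.rng = np.random.default_rng(seed)
        self.shuffle_labels = shuffle_labels
        lengths = genome.lengths
        usable = [
            c for c in self.contigs if lengths[c] >= seq_len
        ]
        if not usable:
            raise ValueError("no contig long enough for the requested window")
        self.usable = usable
        sizes = np.array([lengths[c] - seq_len + 1 for c in usable], dtype=float)
        self.weights = sizes / sizes.sum()

    def _draw_center(self) -> tuple[str, int]:
        half = self.seq_len // 2
        lengths = self.genome.lengths
        for _ in range(1000):
            contig = self.usable[int(self.rng.choice(len(self.usable), p=self.weights))]
            center = int(self.rng.integers(half, lengths[contig] - half + 1))
            start, end = center - half, center + half
            if self.blacklist is not None and self.blacklist.overlaps(
                contig, start, end
            ):
                continue
            if "N" in self.genome.fetch(contig, start, end):
                continue
            return contig, center
        raise RuntimeError("could not draw a valid window in 1000 attempts")

    def sample(self, batch_size: int) -> tuple[np.ndarray, np.ndarray]:
        seqs: list[str] = []
        labels = np.zeros((batch_size, len(self.index.compendium)))
        half = self.seq_len // 2
        for i in range(batch_size):
            contig, center = self._draw_center()
            seqs.append(self.genome.fetch(contig, center - half, center + half))
            label_center = center
            if self.shuffle_labels:
                # decouple labels from sequence: read them at a random
                # other position on the same contig
                _, label_center = self._draw_center_on(contig)
            labels[i] = self.index.labels_at(contig, np.array([label_center]))[0]
        return one_hot(seqs), labels

    def _draw_center_on(self, contig: str) -> tuple[str, int]:
        half = self.seq_len // 2
        length = self.genome.lengths[contig]
        center = int(self.rng.integers(half, length - half + 1))
        return contig, center


# ---------------------------------------------------------------------------
# Optimizers
# ---------------------------------------------------------------------------


class _SGD:
    def __init__(self, params: dict[str, np.ndarray], lr: float, momentum: float):
        self.params = params
        self.lr = lr
        self.momentum = momentum
        self.velocity = {k: np.zeros_like(v) for k, v in params.items()}

    def step(self, grads: dict[str, np.ndarray]) -> None:
        for k, p in self.params.items():
            v = self.velocity[k]
            v *= self.momentum
            v -= self.lr * grads[k]
            p += v


class _Adam:
    def __init__(self, params: dict[str, np.ndarray], lr: float):
        self.params = params
        self.lr = lr
        self.beta1, self.beta2, self.eps = 0.9, 0.999, 1e-8
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.t = 0

    def step(self, grads: dict[str, np.ndarray]) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for k, p in self.params.items():
            g = grads[k]
            self.m[k] = b1 * self.m[k] + (1 - b1) * g
            self.v[k] = b2 * self.v[k] + (1 - b2) * g * g
            mhat = self.m[k] / (1 - b1**self.t)
            vhat = self.v[k] / (1 - b2**self.t)
            p -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


@dataclass
class TrainConfig:
    n_steps: int = 500
    batch_size: int = 64
    lr: float = 2e-3
    optimizer: str = "sgd"  # "sgd" (momentum 0.9) or "adam"
    momentum: float = 0.9
    val_interval: int = 50
    n_val_samples: int = 256
    seed: int = 0
    shuffle_labels: bool = False
    # step decay: multiply lr by `lr_decay` every `lr_decay_interval` steps
    lr_decay: float = 1.0
    lr_decay_interval: int = 0
    # checkpoint selection: "auroc" (mean validation AUROC over profiles
    # with enough positives; robust to confidence miscalibration) or "loss"
    selection: str = "auroc"


def train(
    model: SequenceModel,
    genome: GenomeSequence,
    compendium: ProfileCompendium,
    partition: Partition,
    train_config: Optional[TrainConfig] = None,
    blacklist: Optional[IntervalSet] = None,
) -> list[dict]:
    """Train with on-the-fly sampling; the best-validation-loss checkpoint
    is restored into ``model`` before returning. Returns the step history.

    Aborts with a diagnostic if no profile has a single peak on the
    training contigs (nothing to learn).
    """
    cfg = train_config if train_config is not None else TrainConfig()
    partition.validate(genome)

    train_set = set(partition.train_contigs)
    any_positive = any(
        rec.contig in train_set for p in compendium for rec in p.peaks
    )
    if not any_positive:
        raise ValueError(
            "no positive labels in any profile on training contigs "
            f"{sorted(train_set)}: check peak files and partition"
        )

    seed_seq = np.random.SeedSequence(cfg.seed).spawn(2)
    sampler = OnTheFlySampler(
        genome,
        compendium,
        partition.train_contigs,
        model.config.seq_len,
        blacklist=blacklist,
        seed=int(seed_seq[0].generate_state(1)[0]),
        shuffle_labels=cfg.shuffle_labels,
    )
    val_sampler = OnTheFlySampler(
        genome,
        compendium,
        partition.val_contigs,
        model.config.seq_len,
        blacklist=blacklist,
        seed=int(seed_seq[1].generate_state(1)[0]),
    )
    x_val, y_val = val_sampler.sample(cfg.n_val_samples)

    params = model.parameters()
    if cfg.optimizer == "sgd":
        opt = _SGD(params, cfg.lr, cfg.momentum)
    elif cfg.optimizer == "adam":
        opt = _Adam(params, cfg.lr)
    else:
        raise ValueError(f"unknown optimizer {cfg.optimizer!r}")

    history: list[dict] = []
    best_score = -np.inf
    best_state = model.get_state()
    for step in range(1, cfg.n_steps + 1):
        x, y = sampler.sample(cfg.batch_size)
        loss = model.loss_and_grad(x, y)
        opt.step(model.gradients())
        if cfg.lr_decay_interval and step % cfg.lr_decay_interval == 0:
            opt.lr *= cfg.lr_decay
        record = {"step": step, "train_loss": loss}
        if step % cfg.val_interval == 0 or step == cfg.n_steps:
            val_loss = model.loss(x_val, y_val)
            record["val_loss"] = val_loss
            if cfg.selection == "auroc":
                val_auroc = _mean_auroc(model.predict(x_val), y_val)
                record["val_auroc"] = val_auroc
                score = val_auroc if np.isfinite(val_auroc) else -val_loss
            else:
                score = -val_loss
            if score > best_score:
                best_score = score
                best_state = model.get_state()
        history.append(record)
    if cfg.n_steps > 0:
        model.set_state(best_state)
    return history


def _mean_auroc(probs: np.ndarray, labels: np.ndarray, min_positives: int = 10) -> float:
    from sklearn.metrics import roc_auc_score

    values = []
    for j in range(labels.shape[1]):
        y = labels[:, j]
        n_pos = y.sum()
        if n_pos >= min_positives and n_pos < len(y):
            values.append(roc_auc_score(y, probs[:, j]))
    return float(np.mean(values)) if values else np.nan
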