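"""Fine-tuning pretrained (or fresh) backbones on downstream tasks.

A task model is a backbone plus a fresh linear decoder. Residue-resolution
tasks apply the decoder per position; protein-resolution tasks mean-pool
the final embeddings over non-pad positions first. Classification heads are
trained with cross-entropy over softmax probabilities, regression heads
(n_classes = 1) with mean squared error on the raw scalar. By default the
backbone is updated together with the head; ``freeze_backbone`` restricts
training to the head (frozen-feature mode).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .autograd import Tensor
from .nn import Module, Linear, Adam, clip_global_norm
from .vocab import build_vocabulary, encode
from .tasks import TaskSpec, TaskDataset
from .metrics import classification_report, regression_report, MetricsReport
from .pretrain import CosineSchedule, cosine_lr

__all__ = ["FinetuneConfig", "TaskModel", "attach_head", "pool_protein",
           "finetune", "evaluate"]


def pool_protein(embeddings: np.ndarray, pad_mask=None) -> np.ndarray:
    """Arithmetic mean of embedding rows over non-pad positions, (L,D)->(D,)."""
    embeddings = np.asarray(embeddings, dtype=np.float64)
    if pad_mask is None:
        pad_mask = np.ones(embeddings.shape[0])
    pad_mask = np.asarray(pad_mask, dtype=np.float64)
    total = pad_mask.sum()
    if total == 0:
        raise ValueError("cannot pool an all-pad sequence")
    return (embeddings * pad_mask[:, None]).sum(axis=0) / total


@dataclass
class FinetuneConfig:
    epochs: int = 10
    batch_size: int = 32
    lr: float = 1e-4
    min_lr: float = 0.0
    grad_clip: float = 1.0
    freeze_backbone: bool = False
    early_stop_patience: int = 5
    val_fraction: float = 0.1
    seed: int = 0


class TaskModel(Module):
    """Backbone + linear decoding head for one task."""

    def __init__(self, backbone, spec: TaskSpec, seed: int = 0):
        self.backbone = backbone
        self.spec = spec
        dim = backbone.config.embed_dim
        self.head = Linear(dim, spec.n_classes, np.random.default_rng(seed))

    def forward(self, ids: np.ndarray, pad_mask: np.ndarray | None = None):
        """Scores: (B, L, n_classes) residue / (B, n_classes) protein level."""
        h = self.backbone.embed(ids)  # (B, L, D)
        if self.spec.resolution == "residue":
            return self.head(h)
        if pad_mask is None:
            pad_mask = np.ones(np.atleast_2d(ids).shape, dtype=np.float64)
        m = Tensor(np.asarray(pad_mask, dtype=np.float64)[..., None])
        counts = m.data.sum(axis=1)
        if np.any(counts == 0):
            raise ValueError("cannot pool an all-pad sequence")
        pooled = (h * m).sum(axis=1) * Tensor(1.0 / counts)
        return self.head(pooled)

    def trainable_parameters(self, freeze_backbone: bool):
        return self.head.parameters() if freeze_backbone else self.parameters()


def attach_head(backbone, spec: TaskSpec, seed: int = 0) -> TaskModel:
    """Attach a fresh linear decoder (D -> n_classes) to a backbone."""
    return TaskModel(backbone, spec, seed=seed)


# ------------------------------------------------------------------- batching

def _encode_records(records, max_len: int):
    vocab = build_vocabulary()
    pad = vocab.pad_id
    out = []
    for i, rec in enumerate(records):
        ids = encode(rec.sequence, vocab, max_len=max_len,
                     on_overflow="error").ids
        out.append((ids, rec.label))
    return out, pad


def _batches(encoded, batch_size, pad, rng=None, residue=False):
    order = np.arange(len(encoded))
    if rng is not None:
        rng.shuffle(order)
    for start in range(0, len(order), batch_size):
        sel = order[start:start + batch_size]
        chunk = [encoded[i] for i in sel]
        L = max(len(ids) for ids, _ in chunk)
        ids = np.full((len(chunk), L), pad, dtype=np.int64)
        mask = np.zeros((len(chunk), L), dtype=np.float64)
        for i, (s, _) in enumerate(chunk):
            ids[i, :len(s)] = s
            mask[i, :len(s)] = 1.0
        if residue:
            labels = np.zeros((len(chunk), L), dtype=np.int64)
            for i, (s, lab) in enumerate(chunk):
                labels[i, :len(s)] = [int(c) for c in lab]
        else:
            labels = np.array([lab for _, lab in chunk])
        yield ids, mask, labels


def _batch_loss(model: TaskModel, ids, mask, labels):
    spec = model.spec
    if spec.task_type == "regression":
        pred = model.forward(ids, pad_mask=mask).reshape(-1)
        resid = pred - Tensor(labels.astype(np.float64))
        return (resid * resid).mean()
    if spec.resolution == "residue":
        scores = model.forward(ids)          # (B, L, K)
        return scores.cross_entropy(labels, mask)
    scores = model.forward(ids, pad_mask=mask)   # (B, K)
    return scores.cross_entropy(labels.astype(np.int64),
                                np.ones(len(labels)))


def finetune(task_model: TaskModel, dataset: TaskDataset,
             config: FinetuneConfig | None = None):
    """Train on the train split, early-stop on a validation slice, then
    evaluate on the test split. Returns (task_model, MetricsReport)."""
    config = config or FinetuneConfig()
    dataset.validate()
    train = dataset.split("train")
    if not train:
        raise ValueError("dataset has no train split")
    rng = np.random.default_rng(config.seed)
    max_len = task_model.backbone.config.max_len
    encoded, pad = _encode_records(train, max_len)
    n_val = max(1, int(len(encoded) * config.val_fraction))
    perm = rng.permutation(len(encoded))
    val_set = [encoded[i] for i in perm[:n_val]]
    train_set = [encoded[i] for i in perm[n_val:]]
    residue = task_model.spec.resolution == "residue"
    params = task_model.trainable_parameters(config.freeze_backbone)
    opt = Adam(params, lr=config.lr)
    steps_per_epoch = int(np.ceil(len(train_set) / config.batch_size))
    schedule = CosineSchedule(initial_lr=config.lr, min_lr=config.min_lr,
                              total_steps=config.epochs * steps_per_epoch)
    best_val, best_state, patience = np.inf, None, 0
    step = 0
    for _epoch in range(config.epochs):
        for ids, mask, labels in _batches(train_set, config.batch_size, pad,
                                          rng=rng, residue=residue):
            loss = _batch_loss(task_model, ids, mask, labels)
            task_model.zero_grad()
            loss.backward()
            clip_global_norm(params, config.grad_clip)
            opt.step(lr=cosine_lr(step, schedule))
            step += 1
        val_loss = 0.0
        for ids, mask, labels in _batches(val_set, config.batch_size, pad,
                                          residue=residue):
            val_loss += float(_batch_loss(task_model, ids, mask,
                                          labels).data) * len(ids)
        val_loss /= len(val_set)
        if val_loss < best_val - 1e-6:
            best_val = val_loss
            best_state = [p.data.copy() for p in task_model.parameters()]
            patience = 0
        else:
            patience += 1
            if patience >= config.early_stop_patience:
                break
    if best_state is not None:
        for p, saved in zip(task_model.parameters(), best_state):
            p.data = saved
    report = evaluate(task_model, dataset.split("test") or dataset.split("train"))
    return task_model, report


def evaluate(task_model: TaskModel, records,
             batch_size: int = 32) -> MetricsReport:
    """Metric report on labeled records, per the task's metric set."""
    if not records:
        raise ValueError("no records to evaluate")
    spec = task_model.spec
    encoded, pad = _encode_records(records, task_model.backbone.config.max_len)
    residue = spec.resolution == "residue"
    y_true, y_score = [], []
    for ids, mask, labels in _batches(encoded, batch_size, pad,
                                      residue=residue):
        if spec.task_type == "regression":
            pred = task_model.forward(ids, pad_mask=mask).data.reshape(-1)
            y_true.extend(labels.tolist())
            y_score.extend(pred.tolist())
            continue
        if residue:
            scores = task_model.forward(ids).softmax(axis=-1).data
            keep = mask.astype(bool)
            y_true.extend(labels[keep].tolist())
            probs = scores[keep]
        else:
            probs = task_model.forward(ids, pad_mask=mask) \
                .softmax(axis=-1).data
            y_true.extend(labels.tolist())
        if spec.n_classes == 2:
            y_score.extend(probs[:, 1].tolist())
        else:
            y_score.extend(probs.tolist())
    if spec.task_type == "regression":
        return regression_report(y_true, y_score)
    return classification_report(y_true, np.asarray(y_score),
                                 n_classes=spec.n_classes)
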