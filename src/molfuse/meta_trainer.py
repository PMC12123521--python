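"""Reptile meta-learning over molecular property tasks.

One *task* is one binary endpoint. Meta-training repeatedly samples few-shot
episodes (class-balanced support set, 1:5 support:query ratio), adapts a
copy of the meta-parameters on the support set with plain gradient descent
(``inner_steps`` steps at learning rate α), takes one further step on the
query loss at rate β, and moves the meta-parameters a fraction ε toward the
mean adapted parameters:

    θ ← θ + ε · mean_t(θ″_t − θ)

Plain (momentum-free) gradient descent keeps the θ″−θ direction the
first-order Reptile meta-gradient. Defaults follow the experimental recipe:
1000 batches × 10 cycles, 3 tasks per batch, 5 support iterations, learning
rate 0.001, 2-way/3-shot episodes; the meta step ε (0.1) is standard
Reptile practice. Checkpoint selection keeps the θ with the best mean
validation ROC-AUC across tasks.

Fine-tuning continues gradient descent on one task's scaffold-split
training molecules, selecting the epoch with the best validation ROC-AUC.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from sklearn.metrics import roc_auc_score

from .data_io import MoleculeRecord, SplitAssignment, render_depiction, scaffold_split
from .fusion_model import MolPropertyModel, masked_bce
from .hier_graph import HierMolGraph, build_hier_graph
from .image_autoencoder import ImageEncoder, encode_image

logger = logging.getLogger(__name__)


def roc_auc(scores, labels) -> float:
    """Area under the ROC curve (the Mann–Whitney pair statistic).

    Raises ``ValueError`` when only one class is present.
    """
    labels = np.asarray(labels, dtype=float)
    scores = np.asarray(scores, dtype=float)
    if len(np.unique(labels)) < 2:
        raise ValueError("ROC-AUC is undefined for single-class labels")
    return float(roc_auc_score(labels, scores))


@dataclass
class TaskData:
    """One binary-endpoint task with its scaffold split."""

    name: str
    records: list[MoleculeRecord]
    labels: np.ndarray  # (n,) with NaN = missing
    split: SplitAssignment

    def labeled_idx(self, split: str) -> np.ndarray:
        idx = {"train": self.split.train_idx, "valid": self.split.valid_idx,
               "test": self.split.test_idx}[split]
        return np.array([i for i in idx if not np.isnan(self.labels[i])], dtype=int)


@dataclass
class EpisodeBatch:
    """A few-shot task instance: disjoint support and query triples."""

    task_id: str
    support: list[tuple[HierMolGraph, np.ndarray, float]]
    query: list[tuple[HierMolGraph, np.ndarray, float]]


@dataclass
class MetaState:
    """Meta-parameters θ plus the bookkeeping of the outer loop."""

    theta: np.ndarray
    best_theta: np.ndarray | None = None
    best_metric: float = -np.inf
    history: list[dict] = field(default_factory=list)


class FeatureCache:
    """Lazily built per-SMILES hierarchical graphs and image embeddings,
    shared across tasks (molecules recur between tasks by construction)."""

    def __init__(self, encoder: ImageEncoder | None):
        self.encoder = encoder
        self._graphs: dict[str, HierMolGraph] = {}
        self._embeds: dict[str, np.ndarray] = {}

    def graph(self, smiles: str) -> HierMolGraph:
        if smiles not in self._graphs:
            self._graphs[smiles] = build_hier_graph(smiles)
        return self._graphs[smiles]

    def embedding(self, smiles: str) -> np.ndarray:
        if smiles not in self._embeds:
            if self.encoder is None:
                self._embeds[smiles] = np.zeros(768, np.float32)
            else:
                self._embeds[smiles] = encode_image(render_depiction(smiles), self.encoder)
        return self._embeds[smiles]

    def triple(self, rec: MoleculeRecord, label: float):
        return (self.graph(rec.smiles), self.embedding(rec.smiles), float(label))


def sample_episode(task: TaskData, cache: FeatureCache, way: int = 2, shot: int = 3,
                   ratio: int = 5, rng: np.random.Generator | None = None,
                   split: str = "train") -> EpisodeBatch | None:
    """Class-balanced support (``shot`` per class) plus a query set of
    ``ratio``·|support| molecules from the remainder. Support and query are
    disjoint by molecule. Returns None (with a logged warning) when the task
    lacks ``shot``·(1+``ratio``) labeled molecules per class."""
    rng = rng or np.random.default_rng()
    idx = task.labeled_idx(split)
    y = task.labels[idx]
    pos, neg = idx[y == 1], idx[y == 0]
    need = shot * (1 + ratio)
    if len(pos) < need or len(neg) < need:
        logger.warning("task %s skipped: needs %d labeled molecules per class", task.name, need)
        return None
    pos = rng.permutation(pos)
    neg = rng.permutation(neg)
    support_idx = np.concatenate([pos[:shot], neg[:shot]])
    rest = np.concatenate([pos[shot:], neg[shot:]])
    query_idx = rng.permutation(rest)[: ratio * len(support_idx)]
    mk = lambda i: cache.triple(task.records[i], task.labels[i])
    return EpisodeBatch(task.name, [mk(i) for i in support_idx], [mk(i) for i in query_idx])


def _gd_step(model: MolPropertyModel, batch, lr: float) -> float:
    graphs = [t[0] for t in batch]
    embeds = [t[1] for t in batch]
    labels = np.array([[t[2]] for t in batch])
    model.zero_grad()
    loss = masked_bce(model.forward_batch(graphs, embeds), labels)
    loss.backward()
    val = float(loss.data)
    if not np.isfinite(val):
        raise FloatingPointError("non-finite training loss")
    for p in model.parameters():
        if p.grad is not None:
            p.data = p.data - p.data.dtype.type(lr) * p.grad
    return val


def inner_adapt(model: MolPropertyModel, theta: np.ndarray, episode: EpisodeBatch,
                inner_steps: int = 5, alpha: float = 0.001, beta: float = 0.001) -> np.ndarray:
    """θ → θ′ (``inner_steps`` support steps at α) → θ″ (one query step at β).

    The meta-parameters ``theta`` are untouched; the adapted flat vector θ″
    is returned.
    """
    model.set_flat(theta)
    for _ in range(inner_steps):
        _gd_step(model, episode.support, alpha)
    if beta != 0.0:
        _gd_step(model, episode.query, beta)
    return model.get_flat()


def reptile_outer_update(theta: np.ndarray, adapted: list[np.ndarray], eps: float) -> np.ndarray:
    """θ ← θ + ε · mean_t(θ″_t − θ)."""
    if not adapted:
        raise ValueError("need at least one adapted parameter vector")
    return theta + eps * (np.mean(adapted, axis=0) - theta)


def predict_scores(model: MolPropertyModel, task: TaskData, cache: FeatureCache,
                   idx: np.ndarray) -> np.ndarray:
    graphs = [cache.graph(task.records[i].smiles) for i in idx]
    embeds = [cache.embedding(task.records[i].smiles) for i in idx]
    return model.predict_batch(graphs, embeds)[:, 0]


def evaluate(model: MolPropertyModel, theta: np.ndarray, task: TaskData,
             cache: FeatureCache, split: str = "valid") -> float:
    """ROC-AUC of θ on one split of a task."""
    model.set_flat(theta)
    idx = task.labeled_idx(split)
    return roc_auc(predict_scores(model, task, cache, idx), task.labels[idx])


def _mean_valid_auc(model, theta, tasks, cache) -> float:
    aucs = []
    for t in tasks:
        idx = t.labeled_idx("valid")
        if len(idx) and len(np.unique(t.labels[idx])) == 2:
            aucs.append(evaluate(model, theta, t, cache, "valid"))
    return float(np.mean(aucs)) if aucs else np.nan


def meta_train(tasks: list[TaskData], model: MolPropertyModel, cache: FeatureCache,
               batches: int = 1000, cycles: int = 10, tasks_per_batch: int = 3,
               inner_steps: int = 5, lr: float = 0.001, meta_step: float = 0.1,
               way: int = 2, shot: int = 3, ratio: int = 5, seed: int = 0,
               eval_every: int = 5) -> MetaState:
    """Reptile training over a pool of tasks.

    Every batch samples ``tasks_per_batch`` episodes, adapts each one with
    ``inner_adapt`` (α = β = ``lr``) and applies the outer interpolation.
    Every ``eval_every`` batches the mean validation ROC-AUC across tasks is
    logged and the best θ checkpointed.
    """
    if len(tasks) < 1:
        raise ValueError("meta-training needs at least one task")
    rng = np.random.default_rng(seed)
    state = MetaState(theta=model.get_flat())
    for cycle in range(cycles):
        for b in range(batches):
            adapted = []
            for _ in range(tasks_per_batch):
                task = tasks[rng.integers(len(tasks))]
                ep = sample_episode(task, cache, way, shot, ratio, rng)
                if ep is None:
                    continue
                adapted.append(inner_adapt(model, state.theta, ep, inner_steps, lr, lr))
            if adapted:
                state.theta = reptile_outer_update(state.theta, adapted, meta_step)
            if (b + 1) % eval_every == 0 or b == batches - 1:
                auc = _mean_valid_auc(model, state.theta, tasks, cache)
                state.history.append({"cycle": cycle, "batch": b, "valid_auc": auc})
                logger.info("cycle %d batch %d mean valid ROC-AUC %.4f", cycle, b, auc)
                if np.isfinite(auc) and auc > state.best_metric:
                    state.best_metric = auc
                    state.best_theta = state.theta.copy()
    if state.best_theta is None:
        state.best_theta = state.theta.copy()
    model.set_flat(state.best_theta)
    return state


def finetune(model: MolPropertyModel, theta_init: np.ndarray, task: TaskData,
             cache: FeatureCache, epochs: int = 15, lr: float = 0.01,
             batch_size: int = 32, seed: int = 0,
             max_train: int | None = None) -> tuple[np.ndarray, list[dict]]:
    """Gradient-descent fine-tuning on one task's training split.

    Tracks the best validation ROC-AUC over epochs and returns that θ with
    the per-epoch history. ``epochs=0`` returns ``theta_init`` unchanged.
    ``max_train`` caps the adaptation set with a class-balanced subsample
    (few-shot fine-tuning); None uses the full training split.
    """
    rng = np.random.default_rng(seed)
    model.set_flat(theta_init)
    train_idx = task.labeled_idx("train")
    if max_train is not None and len(train_idx) > max_train:
        y = task.labels[train_idx]
        pos, neg = train_idx[y == 1], train_idx[y == 0]
        k = max_train // 2
        train_idx = np.concatenate([
            rng.permutation(pos)[: min(k, len(pos))],
            rng.permutation(neg)[: max_train - min(k, len(pos))],
        ])
    best_theta, best_auc = theta_init.copy(), -np.inf
    history: list[dict] = []
    for epoch in range(epochs):
        order = rng.permutation(train_idx)
        losses = []
        for lo in range(0, len(order), batch_size):
            chunk = order[lo : lo + batch_size]
            batch = [cache.triple(task.records[i], task.labels[i]) for i in chunk]
            losses.append(_gd_step(model, batch, lr))
        theta = model.get_flat()
        try:
            auc = evaluate(model, theta, task, cache, "valid")
        except ValueError:
            auc = np.nan
        history.append({"epoch": epoch, "train_loss": float(np.mean(losses)), "valid_auc": auc})
        if np.isfinite(auc) and auc > best_auc:
            best_auc, best_theta = auc, theta.copy()
        model.set_flat(theta)
    model.set_flat(best_theta)
    return best_theta, history


def make_task(name: str, records: list[MoleculeRecord], seed: int = 0,
              split: SplitAssignment | None = None) -> TaskData:
    """Bundle records carrying a single endpoint into a TaskData with a
    scaffold split."""
    labels = np.array([r.label_for(name) for r in records])
    if split is None:
        split = scaffold_split(records, seed=seed)
    return TaskData(name, records, labels, split)
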