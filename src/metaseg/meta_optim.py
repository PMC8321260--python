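"""Meta-update rules for learning a segmentation initialization.

Three optimization-based meta-learners over a shared abstraction:

``interpolation`` (the method of interest)
    Sample a support batch from the whole example pool, take ``k`` inner
    SGD steps at rate ``alpha``, sample an independent query batch from the
    *same* pool, take one more SGD step on it, and move the initialization
    a fraction ``beta`` of the way toward the adapted parameters:
    ``theta <- theta + beta * (theta' - theta)``.

``reptile``
    Same interpolation update, but all inner steps are taken on a single
    sampled batch (no query step).

``maml``
    Support and query batches come from disjoint example partitions; the
    outer update follows the gradient of the query loss *through* the inner
    adaptation (exactly, via inner-trajectory Hessians, or in the common
    first-order approximation).

A "task" is realized as one class-equipartitioned batch of examples, so an
episode always mixes every source tissue class.  All functions are pure in
the parameter vector: the input ``theta`` is never mutated.

The differentiable model is abstracted as an *objective*: any object with
``value_and_grad(theta, batch) -> (loss, grad)``; second-order MAML
additionally requires ``value_grad_hess``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

__all__ = [
    "MetaConfig",
    "TaskPool",
    "EpisodeBatch",
    "SamplingScheme",
    "sample_batch",
    "inner_adapt",
    "meta_step_ours",
    "meta_step_reptile",
    "meta_step_maml",
    "meta_train",
]


@dataclass(frozen=True)
class MetaConfig:
    """Meta-training hyper-parameters.

    alpha: inner-loop learning rate (also used for the single query step).
    beta: outer interpolation step size in (0, 1].
    k: inner gradient steps for the interpolation method (and MAML).
    k_reptile: inner steps for Reptile (4 is the reported sweet spot).
    batch_size: examples per episode batch.
    equipartition: enforce equal per-class counts within a batch.
    """

    alpha: float = 1e-3
    beta: float = 0.4
    k: int = 3
    k_reptile: int = 4
    batch_size: int = 6
    equipartition: bool = True

    def __post_init__(self):
        if self.alpha <= 0:
            raise ValueError("alpha must be > 0")
        if not 0.0 <= self.beta <= 1.0:
            raise ValueError("beta must lie in [0, 1]")
        if self.k < 0 or self.k_reptile < 1 or self.batch_size < 1:
            raise ValueError("invalid step/batch configuration")


class TaskPool:
    """A population of examples grouped by tissue class: the p(T) stand-in.

    Examples are any objects exposing ``class_id`` and ``example_id``
    attributes (segmentation examples in practice, toy tasks in tests).
    """

    def __init__(self, examples: Sequence):
        examples = list(examples)
        if not examples:
            raise ValueError("empty task pool")
        self.examples = examples
        self.by_class: dict = {}
        for ex in examples:
            self.by_class.setdefault(ex.class_id, []).append(ex)

    @property
    def classes(self) -> list:
        return sorted(self.by_class, key=str)

    def __len__(self) -> int:
        return len(self.examples)

    def class_counts(self) -> dict:
        return {c: len(v) for c, v in self.by_class.items()}

    def example_ids(self) -> set:
        return {ex.example_id for ex in self.examples}

    def split(self, rng: np.random.Generator, fraction: float = 0.5) -> tuple["TaskPool", "TaskPool"]:
        """Disjoint stratified partition (per class), e.g. for MAML pools."""
        a, b = [], []
        for c in self.classes:
            idx = rng.permutation(len(self.by_class[c]))
            n_a = max(1, int(round(fraction * len(idx))))
            if n_a >= len(idx):
                n_a = len(idx) - 1
            members = self.by_class[c]
            a.extend(members[i] for i in idx[:n_a])
            b.extend(members[i] for i in idx[n_a:])
        return TaskPool(a), TaskPool(b)


@dataclass(frozen=True)
class EpisodeBatch:
    """One sampled batch of examples with its episodic role."""

    examples: tuple
    role: str = "single"  # support | query | single

    def __len__(self) -> int:
        return len(self.examples)

    def example_ids(self) -> set:
        return {ex.example_id for ex in self.examples}


@dataclass(frozen=True)
class SamplingScheme:
    """How episode batches are drawn from the example population.

    ``unified_pool`` (and ``single_batch``) draw every batch from the whole
    pool; ``split_pools`` requires a prior disjoint support/query partition
    and routes each role to its own partition, as MAML prescribes.
    """

    mode: str = "unified_pool"
    support_pool: TaskPool | None = None
    query_pool: TaskPool | None = None

    def __post_init__(self):
        if self.mode not in ("unified_pool", "split_pools", "single_batch"):
            raise ValueError(f"unknown sampling mode {self.mode!r}")
        if self.mode == "split_pools" and (self.support_pool is None or self.query_pool is None):
            raise ValueError("split_pools requires explicit support and query pools")


def sample_batch(
    pool: TaskPool,
    scheme: SamplingScheme,
    cfg: MetaConfig,
    rng: np.random.Generator,
    role: str = "single",
) -> EpisodeBatch:
    """Draw one episode batch according to the sampling scheme."""
    if scheme.mode == "split_pools":
        if role == "support":
            pool = scheme.support_pool
        elif role == "query":
            pool = scheme.query_pool
        else:
            raise ValueError("split_pools sampling needs role 'support' or 'query'")
    picked = []
    if cfg.equipartition:
        classes = pool.classes
        if cfg.batch_size % len(classes) != 0:
            raise ValueError(
                f"batch_size {cfg.batch_size} not divisible by {len(classes)} classes"
            )
        per = cfg.batch_size // len(classes)
        for c in classes:
            members = pool.by_class[c]
            if len(members) < per:
                raise ValueError(f"class {c!r} has {len(members)} examples, needs {per}")
            idx = rng.choice(len(members), size=per, replace=False)
            picked.extend(members[i] for i in idx)
    else:
        if len(pool) < cfg.batch_size:
            raise ValueError("pool smaller than batch size")
        idx = rng.choice(len(pool), size=cfg.batch_size, replace=False)
        picked.extend(pool.examples[i] for i in idx)
    return EpisodeBatch(examples=tuple(picked), role=role)


def _interpolate(theta: np.ndarray, theta_prime: np.ndarray, beta: float) -> np.ndarray:
    """theta + beta * (theta_prime - theta), exact at both endpoints."""
    if beta == 0.0:
        return np.array(theta, copy=True)
    if beta == 1.0:
        return np.array(theta_prime, copy=True)
    return theta + beta * (theta_prime - theta)


def inner_adapt(
    theta: np.ndarray,
    batch: EpisodeBatch,
    alpha: float,
    k: int,
    objective,
    loss_out: list | None = None,
) -> np.ndarray:
    """``k`` plain SGD steps on one batch; returns the adapted vector.

    The input ``theta`` is not mutated.  Per-step pre-update losses are
    appended to ``loss_out`` when provided.
    """
    theta = np.array(theta, copy=True)
    for step in range(k):
        loss, grad = objective.value_and_grad(theta, batch)
        if not np.all(np.isfinite(grad)):
            raise FloatingPointError(f"non-finite gradient at inner step {step}")
        if loss_out is not None:
            loss_out.append(float(loss))
        theta = theta - alpha * grad
    return theta


def meta_step_ours(
    theta: np.ndarray,
    pool: TaskPool,
    cfg: MetaConfig,
    rng: np.random.Generator,
    objective,
    scheme: SamplingScheme | None = None,
    support_batch: EpisodeBatch | None = None,
    query_batch: EpisodeBatch | None = None,
    record: dict | None = None,
) -> np.ndarray:
    """One interpolation meta-update with unified-pool support/query batches.

    ``k`` inner steps on the support batch, one query step at the same rate,
    then ``theta + beta * (theta' - theta)``.  Pre-sampled batches may be
    injected (used by equivalence tests and pipelines).
    """
    scheme = scheme or SamplingScheme("unified_pool")
    if support_batch is None:
        support_batch = sample_batch(pool, scheme, cfg, rng, role="support")
    losses: list = []
    theta_k = inner_adapt(theta, support_batch, cfg.alpha, cfg.k, objective, loss_out=losses)
    if query_batch is None:
        query_batch = sample_batch(pool, scheme, cfg, rng, role="query")
    q_loss, q_grad = objective.value_and_grad(theta_k, query_batch)
    if not np.all(np.isfinite(q_grad)):
        raise FloatingPointError("non-finite gradient on query step")
    theta_prime = theta_k - cfg.alpha * q_grad
    if record is not None:
        record["loss_support"] = losses[0] if losses else float("nan")
        record["loss_query"] = float(q_loss)
    return _interpolate(theta, theta_prime, cfg.beta)


def meta_step_reptile(
    theta: np.ndarray,
    pool: TaskPool,
    cfg: MetaConfig,
    rng: np.random.Generator,
    objective,
    scheme: SamplingScheme | None = None,
    batch: EpisodeBatch | None = None,
    k: int | None = None,
    record: dict | None = None,
) -> np.ndarray:
    """One Reptile meta-update: all inner steps on a single sampled batch."""
    scheme = scheme or SamplingScheme("unified_pool")
    if batch is None:
        batch = sample_batch(pool, scheme, cfg, rng, role="single")
    k = cfg.k_reptile if k is None else k
    losses: list = []
    theta_prime = inner_adapt(theta, batch, cfg.alpha, k, objective, loss_out=losses)
    if record is not None:
        record["loss_support"] = losses[0] if losses else float("nan")
        record["loss_query"] = losses[-1] if losses else float("nan")
    return _interpolate(theta, theta_prime, cfg.beta)


def meta_step_maml(
    theta: np.ndarray,
    support_pool: TaskPool,
    query_pool: TaskPool,
    cfg: MetaConfig,
    rng: np.random.Generator,
    objective,
    first_order: bool = True,
    beta_maml: float | None = None,
    support_batch: EpisodeBatch | None = None,
    query_batch: EpisodeBatch | None = None,
    record: dict | None = None,
) -> np.ndarray:
    """One MAML meta-update with disjoint support/query example partitions.

    Second-order mode differentiates the query loss through the inner SGD
    trajectory exactly, using the objective's Hessian on the support batch
    (available on toy objectives); first-order mode drops those terms and
    uses the raw query gradient at the adapted parameters.

    Unlike the interpolation methods, MAML's outer update is a plain
    gradient step, so its rate lives on the learning-rate scale: the
    default is ``cfg.alpha``, overridable via ``beta_maml``.
    """
    beta = cfg.alpha if beta_maml is None else beta_maml
    scheme = SamplingScheme("split_pools", support_pool=support_pool, query_pool=query_pool)
    if support_batch is None:
        support_batch = sample_batch(support_pool, scheme, cfg, rng, role="support")
    if query_batch is None:
        query_batch = sample_batch(query_pool, scheme, cfg, rng, role="query")

    theta = np.array(theta, copy=True)
    if first_order:
        theta_s = inner_adapt(theta, support_batch, cfg.alpha, cfg.k, objective)
        q_loss, meta_grad = objective.value_and_grad(theta_s, query_batch)
    else:
        if not hasattr(objective, "value_grad_hess"):
            raise NotImplementedError(
                "second-order MAML needs an objective with value_grad_hess"
            )
        iterates = [theta]
        cur = theta
        for _ in range(cfg.k):
            _, g = objective.value_and_grad(cur, support_batch)
            cur = cur - cfg.alpha * g
            iterates.append(cur)
        theta_s = cur
        q_loss, v = objective.value_and_grad(theta_s, query_batch)
        # backpropagate through theta_s = prod_i (I - alpha H_i) applied to theta
        for point in reversed(iterates[:-1]):
            _, _, h = objective.value_grad_hess(point, support_batch)
            h = np.asarray(h, dtype=np.float64)
            hv = h @ v if h.ndim == 2 else h * v
            v = v - cfg.alpha * hv
        meta_grad = v
    if not np.all(np.isfinite(meta_grad)):
        raise FloatingPointError("non-finite MAML meta-gradient")
    if record is not None:
        record["loss_query"] = float(q_loss)
        record["loss_support"] = float(objective.value_and_grad(theta, support_batch)[0])
    return theta - beta * meta_grad


_METHODS = ("ours", "maml", "reptile")


def meta_train(
    theta0: np.ndarray,
    pool: TaskPool,
    method: str,
    cfg: MetaConfig,
    n_iterations: int,
    rng: np.random.Generator,
    objective,
    first_order_maml: bool = True,
) -> tuple[np.ndarray, dict]:
    """Apply the selected meta-step ``n_iterations`` times.

    For MAML the pool is first split into disjoint, stratified support and
    query partitions.  Returns the final parameter vector and a history of
    per-iteration support/query losses and parameter displacement norms.
    """
    if method not in _METHODS:
        raise ValueError(f"unknown meta method {method!r}; expected one of {_METHODS}")
    theta = np.array(theta0, copy=True)
    history = {"iteration": [], "loss_support": [], "loss_query": [], "step_norm": []}
    support_pool = query_pool = None
    if method == "maml":
        support_pool, query_pool = pool.split(rng)
    for it in range(n_iterations):
        rec: dict = {}
        if method == "ours":
            new = meta_step_ours(theta, pool, cfg, rng, objective, record=rec)
        elif method == "reptile":
            new = meta_step_reptile(theta, pool, cfg, rng, objective, record=rec)
        else:
            new = meta_step_maml(
                theta, support_pool, query_pool, cfg, rng, objective,
                first_order=first_order_maml, record=rec,
            )
        history["iteration"].append(it)
        history["loss_support"].append(rec.get("loss_support", float("nan")))
        history["loss_query"].append(rec.get("loss_query", float("nan")))
        history["step_norm"].append(float(np.linalg.norm(new - theta)))
        theta = new
    return theta, history
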