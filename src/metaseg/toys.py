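"""Tiny analytic task families used to verify the meta-update rules.

A toy task is "reach the point c": its loss is a quadratic ``a/2 (theta-c)^2``
applied elementwise, so every inner-loop and meta-update has a closed form
that the real implementation can be checked against.  These tasks plug into
the same episodic machinery (TaskPool, EpisodeBatch, objectives) as real
segmentation examples.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["QuadraticTask", "QuadraticObjective", "common_minimum_pool"]


@dataclass(frozen=True)
class QuadraticTask:
    """Target point and curvature of one quadratic toy task."""

    c: float
    class_id: str = "toy"
    example_id: int = 0
    curvature: float = 1.0


class QuadraticObjective:
    """Batch loss ``mean_e a_e/2 * (theta - c_e)^2`` with exact derivatives."""

    def value_and_grad(self, theta: np.ndarray, batch) -> tuple[float, np.ndarray]:
        theta = np.asarray(theta, dtype=np.float64)
        losses = []
        grad = np.zeros_like(theta)
        for ex in batch.examples:
            diff = theta - ex.c
            losses.append(0.5 * ex.curvature * float(np.sum(diff * diff)))
            grad += ex.curvature * diff
        n = len(batch.examples)
        return float(np.mean(losses)), grad / n

    def value_grad_hess(self, theta: np.ndarray, batch):
        loss, grad = self.value_and_grad(theta, batch)
        hess = np.full_like(np.asarray(theta, dtype=np.float64),
                            np.mean([ex.curvature for ex in batch.examples]))
        return loss, grad, hess


def common_minimum_pool(minimum: float, n_classes: int = 3, n_per_class: int = 4,
                        curvature_spread: float = 0.5,
                        rng: np.random.Generator | None = None):
    """Pool of quadratic tasks sharing one minimizer but varying curvature.

    Every meta-method should contract toward ``minimum`` on this family.
    """
    from .meta_optim import TaskPool

    rng = rng or np.random.default_rng(0)
    tasks = []
    eid = 0
    for ci in range(n_classes):
        for _ in range(n_per_class):
            a = float(1.0 + curvature_spread * rng.uniform(-1, 1))
            tasks.append(QuadraticTask(c=minimum, class_id=f"class{ci}",
                                       example_id=eid, curvature=a))
            eid += 1
    return TaskPool(tasks)
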