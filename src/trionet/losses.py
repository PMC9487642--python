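"""Training objectives: focal classification loss and the Mendelian-constraint loss.

The per-sample genotype head is trained with a focal loss over the 21
genotype classes.  The trio objective adds MCVLoss: the product distribution
p_trio(i,j,k) = p_c,i * p_p1,j * p_p2,k is scored against the valid-degree
prior beta, giving the expected valid degree

    V_trio = sum_{i,j,k} beta(i,j,k) * p_c,i * p_p1,j * p_p2,k,

and MCVLoss = -alpha * log(V_trio + eps).  Predictions concentrated on
Mendelian-consistent triples drive V_trio towards (1-mu)^2 ~ 1 and the loss
towards 0; mass on violating triples is penalised on a log scale.

All functions are batch-first numpy; gradients used by the trainer live here
next to the losses they differentiate.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .genotype_space import BetaTable, MISMATCH_TABLE, N_GENOTYPES, build_beta_table

__all__ = [
    "LossConfig",
    "focal_loss",
    "focal_grad_logits",
    "trio_valid_degree",
    "mcv_loss",
    "mcv_grad_probs",
    "combined_loss",
    "softmax",
]


@dataclass(frozen=True)
class LossConfig:
    """Constants of the combined objective.

    alpha weighs the Mendelian penalty (0 disables it); epsilon caps the log;
    mu is the per-generation mutation rate feeding the beta table;
    focal_gamma is the focusing exponent; l2_weight scales the weight penalty.
    """

    alpha: float = 1.0
    epsilon: float = 1e-9
    mu: float = 1e-8
    focal_gamma: float = 2.0
    l2_weight: float = 0.0

    def __post_init__(self) -> None:
        if self.alpha < 0:
            raise ValueError("alpha must be >= 0")
        if not 0 < self.epsilon < 1e-2:
            raise ValueError("epsilon must be a small positive number")

    def beta_table(self) -> BetaTable:
        return build_beta_table(self.mu)


def softmax(logits: np.ndarray, axis: int = -1) -> np.ndarray:
    z = logits - logits.max(axis=axis, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=axis, keepdims=True)


def _as_batch(p: np.ndarray) -> np.ndarray:
    p = np.asarray(p, dtype=np.float64)
    return p[None, :] if p.ndim == 1 else p


def _check_normalized(p: np.ndarray, name: str, tol: float = 1e-5) -> None:
    s = p.sum(axis=-1)
    if np.any(np.abs(s - 1.0) > tol) or np.any(p < -tol):
        raise ValueError(f"{name} is not a normalized probability distribution")


def _label_indices(labels: np.ndarray) -> np.ndarray:
    labels = np.asarray(labels)
    if labels.ndim >= 1 and labels.shape[-1] == N_GENOTYPES and labels.dtype != np.int64:
        return labels.argmax(axis=-1)
    if labels.ndim == 2 and labels.shape[-1] == N_GENOTYPES:
        return labels.argmax(axis=-1)
    return labels.astype(np.intp)


def focal_loss(
    labels: np.ndarray,
    probs: np.ndarray,
    gamma: float = 2.0,
    epsilon: float = 1e-9,
) -> float:
    """Batch-mean focal loss -(1 - p_t)^gamma * log(p_t).

    ``labels`` may be class indices or one-hot rows; ``probs`` are softmax
    outputs over the 21 genotype classes.  gamma = 0 recovers cross-entropy.
    """
    probs = _as_batch(probs)
    _check_normalized(probs, "probs")
    idx = np.atleast_1d(_label_indices(labels))
    pt = probs[np.arange(probs.shape[0]), idx]
    return float(np.mean(-((1.0 - pt) ** gamma) * np.log(pt + epsilon)))


def focal_grad_logits(
    labels: np.ndarray,
    probs: np.ndarray,
    gamma: float = 2.0,
    epsilon: float = 1e-9,
) -> np.ndarray:
    """d(batch-mean focal loss)/d(logits), with probs = softmax(logits)."""
    probs = _as_batch(probs)
    n = probs.shape[0]
    idx = np.atleast_1d(_label_indices(labels))
    pt = probs[np.arange(n), idx]
    # dL/dp_t of the focal form; all other dL/dp_i are zero
    dl_dpt = gamma * (1.0 - pt) ** (gamma - 1.0) * np.log(pt + epsilon) - (
        (1.0 - pt) ** gamma
    ) / (pt + epsilon)
    # softmax Jacobian collapsed against the single nonzero component
    grad = -probs * (dl_dpt * pt)[:, None]
    grad[np.arange(n), idx] += dl_dpt * pt
    return grad / n


# masks of the three beta branches over the (child, p1, p2) triple space
_CLASS_MASKS = tuple((MISMATCH_TABLE == m).astype(np.float64) for m in (0, 1, 2))


def _child_side_components(pp1: np.ndarray, pp2: np.ndarray) -> np.ndarray:
    """A[m, b, i] = sum_{j,k} 1[mismatch(i,j,k)=m] * p_p1[b,j] * p_p2[b,k]."""
    return np.stack(
        [np.einsum("ijk,bj,bk->bi", mask, pp1, pp2, optimize=True) for mask in _CLASS_MASKS]
    )


def trio_valid_degree(
    p_c: np.ndarray,
    p_p1: np.ndarray,
    p_p2: np.ndarray,
    beta: BetaTable,
) -> np.ndarray | float:
    """Expected valid degree V_trio of the predicted trio distribution.

    Computed in grouped form: the product mass falling in each of the three
    mismatch classes is accumulated first, then weighted by the class's beta
    value.  Equal to the direct 9261-term sum to ~1e-16.
    Returns a scalar for 1-D inputs, else a length-B vector.
    """
    scalar = np.asarray(p_c).ndim == 1
    pc, p1, p2 = _as_batch(p_c), _as_batch(p_p1), _as_batch(p_p2)
    for name, p in (("p_c", pc), ("p_p1", p1), ("p_p2", p2)):
        _check_normalized(p, name)
    comps = _child_side_components(p1, p2)
    masses = np.einsum("mbi,bi->mb", comps, pc)
    v = np.asarray(beta.branch_values) @ masses
    return float(v[0]) if scalar else v


def mcv_loss(
    p_c: np.ndarray,
    p_p1: np.ndarray,
    p_p2: np.ndarray,
    config: LossConfig | None = None,
    beta: BetaTable | None = None,
) -> float:
    """Batch-mean Mendelian-constraint violation loss -alpha * log(V_trio + eps)."""
    config = config or LossConfig()
    if config.alpha == 0.0:
        return 0.0
    beta = beta or config.beta_table()
    v = np.atleast_1d(trio_valid_degree(p_c, p_p1, p_p2, beta))
    return float(np.mean(-config.alpha * np.log(v + config.epsilon)))


def mcv_grad_probs(
    p_c: np.ndarray,
    p_p1: np.ndarray,
    p_p2: np.ndarray,
    config: LossConfig,
    beta: BetaTable | None = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Gradients of the batch-mean MCVLoss w.r.t. the three probability rows."""
    beta = beta or config.beta_table()
    pc, p1, p2 = _as_batch(p_c), _as_batch(p_p1), _as_batch(p_p2)
    n = pc.shape[0]
    bv = beta.values
    dv_dc = np.einsum("ijk,bj,bk->bi", bv, p1, p2, optimize=True)
    dv_dp1 = np.einsum("ijk,bi,bk->bj", bv, pc, p2, optimize=True)
    dv_dp2 = np.einsum("ijk,bi,bj->bk", bv, pc, p1, optimize=True)
    v = np.einsum("bi,bi->b", dv_dc, pc)
    scale = (-config.alpha / (v + config.epsilon) / n)[:, None]
    return scale * dv_dc, scale * dv_dp1, scale * dv_dp2


def combined_loss(
    probs: tuple[np.ndarray, np.ndarray, np.ndarray],
    labels: tuple[np.ndarray, np.ndarray, np.ndarray],
    config: LossConfig | None = None,
    l2_term: float = 0.0,
    beta: BetaTable | None = None,
) -> float:
    """Three focal terms + MCVLoss + an L2 penalty supplied by the model.

    ``probs`` and ``labels`` are (child, parent1, parent2) tuples with aligned
    batch dimensions.
    """
    config = config or LossConfig()
    pc, p1, p2 = (_as_batch(p) for p in probs)
    if not (pc.shape[0] == p1.shape[0] == p2.shape[0]):
        raise ValueError("misaligned batch sizes across trio members")
    for lab, p in zip(labels, (pc, p1, p2)):
        if np.atleast_1d(_label_indices(lab)).shape[0] != p.shape[0]:
            raise ValueError("labels misaligned with predictions")
    total = sum(
        focal_loss(lab, p, config.focal_gamma, config.epsilon)
        for lab, p in zip(labels, (pc, p1, p2))
    )
    total += mcv_loss(pc, p1, p2, config, beta)
    return float(total + l2_term)
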