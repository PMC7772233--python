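"""Loss family: supervised cross-entropy plus an f-divergence-to-uniform
regularizer for unlabeled target-domain predictions.

The semi-supervised objective is

    L(x_s, x_t) = L_S(p_s, y_s) + lambda * L_T(p_t)

where ``L_S`` is pixel-mean cross-entropy on labeled source-domain slices and
``L_T = -D_f(p_t || U)`` is the negated f-divergence between each pixel's
predicted class distribution and the uniform distribution ``U = 1/C``:

    L_T = -(1/C) * sum_c f(C * p_c),   averaged over pixels.

Minimizing ``L_T`` pushes unlabeled predictions *away* from uniform, i.e.
toward confident class assignments, which implicitly moves features away from
the decision boundary.  Two divergences are provided: KL (``f(x) = x log x``)
and Pearson chi-square (``f(x) = x^2 - 1``).  The chi-square choice is
preferred because its per-pixel gradient is bounded (the binary closed form
is ``2 - 4p``), whereas KL's (``log(1-p) - log p``) blows up at confident
pixels and concentrates the update on easy samples.

All losses are means over pixels and batch, so ``lambda`` is independent of
batch and image size.  Probabilities are clamped at 1e-12 inside logarithms
only; the chi-square path is polynomial and needs no clamping.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np

EPS = 1e-12


@dataclass(frozen=True)
class DivergenceKind:
    """A convex generator f with f(1) = 0; instances: ``KL``, ``PEARSON_CHI2``."""

    name: str
    f: Callable[[np.ndarray], np.ndarray]


def _f_kl(x: np.ndarray) -> np.ndarray:
    # x log x with the standard limit f(0) = 0.
    x = np.asarray(x, dtype=np.float64)
    return np.where(x > 0, x * np.log(np.clip(x, EPS, None)), 0.0)


def _f_chi2(x: np.ndarray) -> np.ndarray:
    return np.asarray(x, dtype=np.float64) ** 2 - 1.0


KL = DivergenceKind("kl", _f_kl)
PEARSON_CHI2 = DivergenceKind("pearson_chi2", _f_chi2)
DIVERGENCES = {d.name: d for d in (KL, PEARSON_CHI2)}


def get_divergence(name: str | DivergenceKind) -> DivergenceKind:
    if isinstance(name, DivergenceKind):
        return name
    try:
        return DIVERGENCES[name]
    except KeyError:
        raise ValueError(
            f"unknown divergence {name!r}; choose from {sorted(DIVERGENCES)}"
        ) from None


@dataclass
class LossConfig:
    lambda_weight: float = 0.1
    divergence: DivergenceKind = field(default_factory=lambda: PEARSON_CHI2)
    num_classes: int = 2

    def __post_init__(self) -> None:
        self.divergence = get_divergence(self.divergence)
        if self.lambda_weight < 0:
            raise ValueError("lambda_weight must be nonnegative")
        if self.num_classes < 2:
            raise ValueError("num_classes must be >= 2")


# ---------------------------------------------------------------------------
# Supervised cross-entropy


def _as_batched(p: np.ndarray, y: np.ndarray | None = None):
    """Accept (H, W, C) / (N, H, W, C) probability maps; return batched views."""
    p = np.asarray(p, dtype=np.float64)
    if p.ndim == 3:
        p = p[None]
        y = None if y is None else np.asarray(y)[None]
    elif y is not None:
        y = np.asarray(y)
    return p, y


def supervised_loss(p: np.ndarray, y: np.ndarray) -> float:
    """Pixel-mean cross-entropy -mean(log p[true class]); nonnegative."""
    p, y = _as_batched(p, y)
    C = p.shape[-1]
    if y.min() < 0 or y.max() >= C:
        raise ValueError(f"labels must lie in [0, {C}), got range "
                         f"[{y.min()}, {y.max()}]")
    pt = np.take_along_axis(p, y[..., None], axis=-1)[..., 0]
    return float(-np.log(np.clip(pt, EPS, None)).mean())


def supervised_loss_grad(p: np.ndarray, y: np.ndarray) -> np.ndarray:
    """d supervised_loss / d p, same shape as p (batched mean included)."""
    p, y = _as_batched(p, y)
    onehot = np.zeros_like(p)
    np.put_along_axis(onehot, y[..., None], 1.0, axis=-1)
    n_pix = p[..., 0].size
    return -onehot / np.clip(p, EPS, None) / n_pix


# ---------------------------------------------------------------------------
# Divergence-to-uniform target loss


def target_loss(p: np.ndarray, kind: str | DivergenceKind = PEARSON_CHI2) -> float:
    """Pixel-mean of -(1/C) sum_c f(C p_c); <= 0, equal to 0 iff p is uniform."""
    kind = get_divergence(kind)
    p, _ = _as_batched(p)
    C = p.shape[-1]
    per_pixel = -(1.0 / C) * kind.f(C * p).sum(axis=-1)
    return float(per_pixel.mean())


def target_loss_grad(p: np.ndarray, kind: str | DivergenceKind = PEARSON_CHI2
                     ) -> np.ndarray:
    """d target_loss / d p (unconstrained derivative; simplex handled by the
    softmax backward of the caller)."""
    kind = get_divergence(kind)
    p, _ = _as_batched(p)
    C = p.shape[-1]
    n_pix = p[..., 0].size
    if kind.name == "pearson_chi2":
        df = 2.0 * C * p  # f'(Cp) = 2Cp
    elif kind.name == "kl":
        df = np.log(np.clip(C * p, EPS, None)) + 1.0
    else:  # pragma: no cover - registry is closed
        raise ValueError(kind.name)
    return -df / n_pix


def total_loss(p_s: np.ndarray, y_s: np.ndarray, p_t: np.ndarray | None,
               config: LossConfig) -> float:
    """Combined objective L_S + lambda * L_T; reduces to L_S when lambda=0."""
    ls = supervised_loss(p_s, y_s)
    if config.lambda_weight == 0 or p_t is None:
        return ls
    return ls + config.lambda_weight * target_loss(p_t, config.divergence)


# ---------------------------------------------------------------------------
# Binary-case gradient references (analysis only, not used in backprop)


def binary_gradient_reference(p: float | np.ndarray,
                              kind: str | DivergenceKind) -> float | np.ndarray:
    """Closed-form dL_T/dp for the binary case along the simplex (p, 1-p).

    KL: log(1-p) - log(p), unbounded at the endpoints; Pearson chi-square:
    2 - 4p, bounded by 2.  These are the published reference forms used in
    the gradient-imbalance analysis; training gradients flow through
    :func:`target_loss_grad` instead.
    """
    kind = get_divergence(kind)
    p = np.asarray(p, dtype=np.float64)
    if kind.name == "kl":
        if np.any((p <= 0) | (p >= 1)):
            raise ValueError(
                "KL reference gradient is unbounded at p in {0, 1}; "
                "evaluate strictly inside (0, 1)"
            )
        out = np.log(1.0 - p) - np.log(p)
    else:
        out = 2.0 - 4.0 * p
    return float(out) if out.ndim == 0 else out
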