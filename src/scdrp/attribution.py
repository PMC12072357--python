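"""Integrated-gradients attribution of predictions to pathway dimensions.

Each shared-latent dimension corresponds to a pathway (or a free row),
so attributing the classifier's probability output to its latent inputs
reads directly as pathway importance.  For cell z and dimension d,

    IG_d(z) = (z_d - baseline_d) * mean_{m=1..M} dF/dz_d |_{baseline + ((m-1/2)/M)(z - baseline)}

a midpoint Riemann approximation of the path integral from the
baseline (default: the all-zeros latent vector) to z, where F is the
classifier probability.  As M grows, sum_d IG_d converges to
F(z) - F(baseline) (the completeness axiom), which the tests exploit.
Per-pathway importance is summarized as the mean absolute IG across
cells; the mean signed IG indicates sensitivity- (positive) vs
resistance-aligned (negative) pathways.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._autodiff import Tensor
from .model import ModelParameters, classify


@dataclass
class AttributionResult:
    ig: np.ndarray  # cells x latent_dim_shared
    mean_abs: np.ndarray
    ranks: np.ndarray  # dimension indices, descending mean_abs
    pathway_names: list[str]
    baseline: np.ndarray
    n_steps: int

    def summary(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "dimension": np.arange(self.ig.shape[1]),
                "pathway": self.pathway_names,
                "mean_abs_ig": self.mean_abs,
                "mean_signed_ig": self.ig.mean(axis=0),
            }
        )


def integrated_gradients(
    params: ModelParameters,
    z: np.ndarray,
    baseline: np.ndarray | None = None,
    n_steps: int = 64,
    predict_fn=None,
) -> np.ndarray:
    """Per-cell, per-dimension IG of the classifier probability.

    ``predict_fn(Tensor) -> Tensor`` may replace the classifier (used by
    tests with analytically tractable surrogates).
    """
    z = np.atleast_2d(np.asarray(z, dtype=np.float64))
    if baseline is None:
        baseline = np.zeros(z.shape[1])
    baseline = np.asarray(baseline, dtype=np.float64).reshape(-1)
    if baseline.size != z.shape[1]:
        raise ValueError(
            f"baseline width {baseline.size} != latent width {z.shape[1]}"
        )
    if n_steps < 2:
        raise ValueError("n_steps must be >= 2")
    if predict_fn is None:
        predict_fn = lambda t: classify(t, params)  # noqa: E731
    grad_sum = np.zeros_like(z)
    diff = z - baseline[None, :]
    for m in range(1, n_steps + 1):
        alpha = (m - 0.5) / n_steps  # midpoint rule: O(1/M^2) quadrature error
        point = Tensor(baseline[None, :] + alpha * diff, requires_grad=True)
        out = predict_fn(point)
        out.sum().backward()  # rows are independent, so batch the gradient
        grad_sum += point.grad
    return diff * grad_sum / n_steps


def attribute(
    params: ModelParameters,
    z: np.ndarray,
    baseline: np.ndarray | None = None,
    n_steps: int = 64,
) -> AttributionResult:
    """IG for a batch of shared-latent vectors, with pathway summaries."""
    ig = integrated_gradients(params, z, baseline=baseline, n_steps=n_steps)
    mean_abs = np.abs(ig).mean(axis=0)
    names = params.mask_row_names or [f"dim_{d}" for d in range(ig.shape[1])]
    order = sorted(range(ig.shape[1]), key=lambda d: (-mean_abs[d], names[d]))
    if baseline is None:
        baseline = np.zeros(ig.shape[1])
    return AttributionResult(
        ig=ig,
        mean_abs=mean_abs,
        ranks=np.array(order),
        pathway_names=list(names),
        baseline=np.asarray(baseline, dtype=np.float64).reshape(-1),
        n_steps=n_steps,
    )


def rank_pathways(res: AttributionResult, top_k: int) -> list[tuple[str, float, float]]:
    """Top-k dimensions by mean absolute IG.

    Returns (pathway_name, mean_abs, sign_summary) where sign_summary is
    the mean signed IG across cells.
    """
    if top_k > res.ig.shape[1]:
        raise ValueError(f"top_k={top_k} exceeds latent width {res.ig.shape[1]}")
    signed = res.ig.mean(axis=0)
    return [
        (res.pathway_names[d], float(res.mean_abs[d]), float(signed[d]))
        for d in res.ranks[:top_k]
    ]
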