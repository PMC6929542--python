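"""Drug-drug similarity kernels.

Two similarities drive the predictor:

* the **Gaussian interaction profile (GIP) kernel** on the rows of the
  interaction matrix,

  .. math:: G_{ij} = \\exp(-\\gamma_d \\, \\lVert y_i - y_j \\rVert^2),
            \\qquad
            \\gamma_d = \\gamma'_d \\Big/ \\Big(\\tfrac1N \\sum_i
            \\lVert y_i \\rVert^2\\Big),

  so the bandwidth is normalised by the mean squared interaction-profile
  norm and the kernel is scale-free in Y;

* the **Pearson correlation** of the binary feature vectors, used by the
  KNN cold-start for drugs without any known interaction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .data import FeatureMatrix, InteractionMatrix, KernelMatrix, atomic_write_text
from .errors import DegenerateNetworkError, InvalidParameterError

__all__ = ["GipParams", "gip_kernel", "pearson_similarity", "write_similarity_matrix"]


@dataclass(frozen=True)
class GipParams:
    """Bandwidth scaling gamma'_d for the GIP kernel (default 1)."""

    gamma_prime: float = 1.0

    def __post_init__(self) -> None:
        if not (self.gamma_prime > 0):
            raise InvalidParameterError("gamma_prime must be > 0")


def gip_kernel(Y: InteractionMatrix, params: GipParams = GipParams()) -> KernelMatrix:
    """Gaussian interaction-profile kernel on the rows of Y.

    The bandwidth gamma_d = gamma'_d / (mean squared profile norm), with the
    mean taken over all N drugs including all-zero rows.  Raises
    :class:`DegenerateNetworkError` when Y is all zero (the bandwidth would
    divide by zero).
    """
    values = Y.values
    sq_norms = np.einsum("ij,ij->i", values, values)
    mean_sq = sq_norms.mean()
    if mean_sq == 0:
        raise DegenerateNetworkError(
            "degenerate network: interaction matrix is all zero, GIP bandwidth undefined"
        )
    gamma = params.gamma_prime / mean_sq
    # squared profile distances via the Gram matrix; clip tiny negatives
    d2 = sq_norms[:, None] + sq_norms[None, :] - 2.0 * (values @ values.T)
    np.clip(d2, 0.0, None, out=d2)
    g = np.exp(-gamma * d2)
    g = (g + g.T) / 2.0
    np.fill_diagonal(g, 1.0)
    return KernelMatrix(g, Y.drug_index, kind="gip")


def pearson_similarity(V: FeatureMatrix) -> KernelMatrix:
    """Pearson correlation of feature vectors across the F feature positions.

    Rows with a constant vector (all-0 or all-1 features) have undefined
    correlation; they are flagged degenerate and given similarity 0 to every
    drug (including themselves) so one featureless drug does not abort a
    batch run — 0 is the "no evidence" weight for the downstream KNN fill.
    """
    if V.n_features < 2:
        raise InvalidParameterError(
            "pearson_similarity requires at least 2 feature positions"
        )
    x = V.values
    centered = x - x.mean(axis=1, keepdims=True)
    sd = np.sqrt(np.einsum("ij,ij->i", centered, centered) / V.n_features)
    degenerate = sd == 0

    denom = np.where(degenerate, 1.0, sd)
    cov = (centered @ centered.T) / V.n_features
    s = cov / denom[:, None] / denom[None, :]
    s[degenerate, :] = 0.0
    s[:, degenerate] = 0.0
    np.clip(s, -1.0, 1.0, out=s)
    s = (s + s.T) / 2.0
    diag = np.where(degenerate, 0.0, 1.0)
    np.fill_diagonal(s, diag)
    return KernelMatrix(s, V.drug_index, kind="pearson", degenerate=degenerate)


def write_similarity_matrix(K: KernelMatrix, path: str) -> None:
    """Write a square similarity matrix as TSV with ids on the first row/column."""
    ids = K.drug_index.ids
    lines = ["\t".join(("drug_id",) + ids)]
    for i, drug in enumerate(ids):
        lines.append(drug + "\t" + "\t".join(f"{v:.6f}" for v in K.values[i]))
    atomic_write_text(path, "\n".join(lines) + "\n")
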