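"""The DDIGIP predictor: KNN cold-start fill, GIP kernel, RLS scoring.

The pipeline scores every unordered drug pair from a known drug-drug
interaction (DDI) network:

1. **Cold start** — drugs with no known interaction ("new drugs") have an
   all-zero interaction profile, which carries no signal.  When a binary
   feature table is available, their rows are pre-filled with a similarity-
   weighted average of the profiles of their K nearest neighbours under the
   Pearson feature similarity:

   .. math:: y'_{ij} = \\frac{\\sum_{l \\in K_{set}} S_{il}\\, y_{lj}}
                            {\\sum_{l \\in K_{set}} S_{il}}.

2. **GIP kernel** — a Gaussian kernel on the (possibly filled) interaction
   profiles gives the drug-drug similarity matrix G.

3. **RLS scoring** — kernel regularized least squares in closed form,

   .. math:: \\hat Y_p = G\\,(G + \\sigma I)^{-1}\\, Y, \\qquad
             Y_p = (\\hat Y_p + \\hat Y_p^\\top)/2,

   where the same filled matrix serves both as the kernel input and as the
   label matrix Y.

:class:`DdigipModel` wraps the pipeline statsmodels-style: build the model
from data, call :meth:`~DdigipModel.fit`, and read predictions, rankings and
a text summary off the returned :class:`DdigipResults`.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from typing import Optional

import numpy as np
import pandas as pd
import scipy.linalg

from .data import (
    DrugIndex,
    FeatureMatrix,
    InteractionMatrix,
    KernelMatrix,
    PredictionMatrix,
    align,
    ranked_candidate_pairs,
    read_edge_list,
    read_feature_table,
    write_ranked_pairs,
)
from .errors import DegenerateNetworkError, InvalidParameterError
from .similarity import GipParams, gip_kernel, pearson_similarity

__all__ = ["DdigipParams", "knn_fill", "rls_scores", "ddigip_predict", "DdigipModel", "DdigipResults"]


@dataclass(frozen=True)
class DdigipParams:
    """Tunable parameters of the DDIGIP pipeline.

    sigma
        RLS regularization strength (default 1).
    gamma_prime
        GIP kernel bandwidth scaling (default 1).
    k_neighbors
        Number of nearest neighbours for the cold-start fill (default 9).
    knn_enabled
        Whether to run the cold-start fill.  ``None`` (default) means "on
        whenever a feature table is supplied".
    """

    sigma: float = 1.0
    gamma_prime: float = 1.0
    k_neighbors: int = 9
    knn_enabled: Optional[bool] = None

    def __post_init__(self) -> None:
        if not (self.sigma > 0):
            raise InvalidParameterError("sigma must be > 0")
        if not (self.gamma_prime > 0):
            raise InvalidParameterError("gamma_prime must be > 0")
        if int(self.k_neighbors) != self.k_neighbors or self.k_neighbors < 1:
            raise InvalidParameterError("k_neighbors must be a positive integer")

    def resolve_knn(self, features_present: bool) -> bool:
        return features_present if self.knn_enabled is None else bool(self.knn_enabled)

    def to_dict(self) -> dict:
        return {
            "sigma": self.sigma,
            "gamma_prime": self.gamma_prime,
            "k_neighbors": int(self.k_neighbors),
            "knn_enabled": self.knn_enabled,
        }


def knn_fill(
    Y: InteractionMatrix,
    S: KernelMatrix,
    K: int,
    feature_missing: Optional[np.ndarray] = None,
) -> InteractionMatrix:
    """Impute interaction profiles for new drugs from feature similarity.

    A "new drug" is one whose row of Y is all zero.  For each new drug whose
    features are neither missing nor degenerate, the K most feature-similar
    drugs *that themselves have at least one known interaction* form the
    neighbour set; the new row is their similarity-weighted average profile.
    Filled values are written symmetrically; when two new drugs face each
    other, the two independently computed values are averaged.  All rows of
    drugs with known interactions are returned unchanged.
    """
    if K < 1:
        raise InvalidParameterError("K must be >= 1")
    n = Y.n_drugs
    ids = Y.drug_index.ids
    values = Y.values
    degrees = (values != 0).sum(axis=1)
    new = degrees == 0
    eligible = np.flatnonzero(~new)

    skip = np.asarray(S.degenerate, dtype=bool).copy()
    if feature_missing is not None:
        skip |= np.asarray(feature_missing, dtype=bool)

    fills: dict[int, np.ndarray] = {}
    for i in np.flatnonzero(new):
        if skip[i]:
            warnings.warn(
                f"drug {ids[i]!r} has missing/degenerate features; cold-start fill skipped",
                stacklevel=2,
            )
            continue
        if eligible.size == 0:
            warnings.warn("no drugs with known interactions; cold-start fill skipped", stacklevel=2)
            continue
        if eligible.size < K:
            warnings.warn(
                f"drug {ids[i]!r}: only {eligible.size} eligible neighbours for K={K}; using all",
                stacklevel=2,
            )
        # top-K by similarity, ties broken by ascending drug identifier
        order = sorted(eligible, key=lambda l: (-S.values[i, l], ids[l]))
        k_set = np.array(order[: min(K, len(order))])
        weights = S.values[i, k_set]
        denom = weights.sum()
        if denom <= 0:
            warnings.warn(
                f"drug {ids[i]!r}: non-positive neighbour similarity sum; row left zero",
                stacklevel=2,
            )
            continue
        fills[i] = (weights @ values[k_set, :]) / denom

    out = values.copy()
    filled = sorted(fills)
    filled_set = set(filled)
    for i in filled:
        row = fills[i]
        for j in range(n):
            if j == i:
                continue
            if j in filled_set:
                if j > i:  # each new-new pair handled once, averaged
                    v = (fills[i][j] + fills[j][i]) / 2.0
                    out[i, j] = out[j, i] = v
            else:
                out[i, j] = out[j, i] = row[j]
    np.fill_diagonal(out, 0.0)
    binary = Y.binary and not fills
    return InteractionMatrix(out, Y.drug_index, binary=binary)


def rls_scores(G: KernelMatrix, Y: InteractionMatrix, sigma: float) -> PredictionMatrix:
    """Closed-form RLS scoring: Y_p = sym(G (G + sigma I)^-1 Y).

    Solved with a symmetric positive-definite factorization of G + sigma I;
    no explicit inverse is formed.
    """
    if not (sigma > 0):
        raise InvalidParameterError("sigma must be > 0")
    if not np.isfinite(G.values).all() or not np.isfinite(Y.values).all():
        raise InvalidParameterError("non-finite entries in kernel or interaction matrix")
    a = G.values + sigma * np.eye(len(G.drug_index))
    x = scipy.linalg.solve(a, Y.values, assume_a="pos")
    y_hat = G.values @ x
    y_p = (y_hat + y_hat.T) / 2.0
    return PredictionMatrix(y_p, Y.drug_index)


def ddigip_predict(
    Y: InteractionMatrix,
    features: Optional[FeatureMatrix] = None,
    params: DdigipParams = DdigipParams(),
    feature_similarity: Optional[KernelMatrix] = None,
) -> PredictionMatrix:
    """Run the full pipeline: optional KNN fill, GIP kernel, RLS scores.

    ``feature_similarity`` may carry a precomputed Pearson matrix (it depends
    only on the features, so validation loops reuse it); the GIP kernel is
    always recomputed because its bandwidth depends on the training matrix.
    """
    return _predict_verbose(Y, features, params, feature_similarity).prediction


@dataclass
class _PipelineOutput:
    prediction: PredictionMatrix
    kernel: KernelMatrix
    filled: InteractionMatrix
    n_filled: int


def _predict_verbose(
    Y: InteractionMatrix,
    features: Optional[FeatureMatrix],
    params: DdigipParams,
    feature_similarity: Optional[KernelMatrix] = None,
) -> _PipelineOutput:
    use_knn = params.resolve_knn(features is not None)
    work = Y
    n_filled = 0
    if use_knn:
        if feature_similarity is None:
            if features is None:
                raise InvalidParameterError("knn_enabled requires a feature table")
            feature_similarity = pearson_similarity(features)
        missing = features.missing if features is not None else None
        before = (Y.values != 0).any(axis=1)
        work = knn_fill(Y, feature_similarity, params.k_neighbors, feature_missing=missing)
        after = (work.values != 0).any(axis=1)
        n_filled = int((after & ~before).sum())
    g = gip_kernel(work, GipParams(params.gamma_prime))
    pred = rls_scores(g, work, params.sigma)
    return _PipelineOutput(pred, g, work, n_filled)


class DdigipModel:
    """DDI prediction model over a known-interaction network.

    Parameters
    ----------
    interactions
        Binary symmetric interaction matrix of known DDIs.
    features
        Optional binary feature table; enables the cold-start fill for
        drugs without known interactions.  Aligned to the interaction
        matrix (sorted union of drug ids) at construction.
    params
        Pipeline parameters; defaults are sigma=1, gamma'_d=1, K=9.
    """

    def __init__(
        self,
        interactions: InteractionMatrix,
        features: Optional[FeatureMatrix] = None,
        params: Optional[DdigipParams] = None,
    ) -> None:
        if features is not None and interactions.drug_index.ids != features.drug_index.ids:
            interactions, features = align(interactions, features)
        self.interactions = interactions
        self.features = features
        self.params = params or DdigipParams()

    @classmethod
    def from_files(
        cls,
        interactions_path: str,
        features_path: Optional[str] = None,
        header: bool = False,
        params: Optional[DdigipParams] = None,
    ) -> "DdigipModel":
        features = read_feature_table(features_path) if features_path else None
        drug_ids = features.drug_index if features is not None else None
        interactions = read_edge_list(interactions_path, drug_ids=None, header=header)
        if drug_ids is not None:
            # re-read constrained to the union so unknown-id errors surface
            union = interactions.drug_index.union(drug_ids)
            interactions = read_edge_list(interactions_path, drug_ids=union, header=header)
        return cls(interactions, features, params)

    def fit(self) -> "DdigipResults":
        """Score every drug pair; returns a results object."""
        out = _predict_verbose(self.interactions, self.features, self.params)
        return DdigipResults(self, out)

    def cross_validate(self, n_folds: int = 5, repeats: int = 10, seed: int = 0):
        from . import evaluation

        plan = evaluation.make_folds(self.interactions, n_folds, repeats, seed)
        return evaluation.cross_validate(self.interactions, self.features, self.params, plan)

    def denovo_validate(self):
        from . import evaluation

        if self.features is None:
            raise InvalidParameterError("de novo validation requires a feature table")
        return evaluation.denovo_validate(self.interactions, self.features, self.params)


class DdigipResults:
    """Fitted DDIGIP scores with ranking and summary helpers."""

    def __init__(self, model: DdigipModel, output: _PipelineOutput) -> None:
        self.model = model
        self.prediction = output.prediction
        self.kernel = output.kernel
        self.filled_interactions = output.filled
        self.n_cold_start_filled = output.n_filled
        self.params = model.params

    @property
    def drug_index(self) -> DrugIndex:
        return self.prediction.drug_index

    def scores(self) -> np.ndarray:
        return self.prediction.values

    def top_pairs(self, n: int = 10) -> pd.DataFrame:
        """Highest-scoring candidate pairs not already known to interact."""
        rows = ranked_candidate_pairs(self.prediction, self.model.interactions, n)
        return pd.DataFrame(
            {
                "rank": np.arange(1, len(rows) + 1),
                "drug_id_1": [r[0] for r in rows],
                "drug_id_2": [r[1] for r in rows],
                "score": [r[2] for r in rows],
            }
        )

    def save_ranked(self, path: str, top: int) -> None:
        write_ranked_pairs(self.prediction, self.model.interactions, path, top)

    def summary(self, top: int = 5) -> str:
        y = self.model.interactions
        n = y.n_drugs
        m = len(y.known_pairs())
        lines = [
            "DDIGIP prediction results",
            "=" * 25,
            f"drugs:                {n}",
            f"known interactions:   {m}",
            f"cold-start filled:    {self.n_cold_start_filled}",
            f"sigma:                {self.params.sigma}",
            f"gamma_prime:          {self.params.gamma_prime}",
            f"k_neighbors:          {self.params.k_neighbors}",
            f"knn fill active:      {self.params.resolve_knn(self.model.features is not None)}",
            "",
            f"top {top} candidate pairs (descending score):",
        ]
        for _, row in self.top_pairs(top).iterrows():
            lines.append(
                f"  {int(row['rank']):>4}  {row['drug_id_1']}  {row['drug_id_2']}"
                f"  {row['score']:.6f}"
            )
        return "\n".join(lines)
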