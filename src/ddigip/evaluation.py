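"""Cross-validation, de novo drug validation, and rank-based AUC.

Validation follows the standard link-prediction protocol on a symmetric
interaction matrix:

* **k-fold CV** partitions the unordered *known* pairs (not matrix cells)
  into near-equal folds; each fold in turn is hidden by zeroing both
  symmetric entries, the predictor is retrained on the masked matrix, and
  the hidden pairs are ranked against the candidate universe — all
  unordered pairs unknown in the *original* matrix.

* **De novo validation** hides every interaction of one drug at a time,
  so the drug becomes a cold-start case, and ranks its true partners
  against its unknown partners.

AUC is the Wilcoxon-Mann-Whitney statistic (ties get half credit), i.e.
the area under the empirical ROC curve.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np
from scipy.stats import rankdata

from .data import FeatureMatrix, InteractionMatrix
from .errors import DegenerateNetworkError, InvalidParameterError
from .model import DdigipParams, ddigip_predict
from .similarity import pearson_similarity

__all__ = [
    "FoldPlan",
    "EvalReport",
    "make_folds",
    "auc_rank",
    "cross_validate",
    "denovo_validate",
    "grid_search_k",
]


@dataclass(frozen=True)
class FoldPlan:
    """Assignment of known pairs to folds, independently per repeat.

    ``pairs`` is the (m, 2) array of unordered known pairs (i < j);
    ``assignment[r][p]`` is the fold id of pair p in repeat r.
    """

    n_folds: int
    repeats: int
    seed: int
    pairs: np.ndarray
    assignment: np.ndarray

    def test_pairs(self, repeat: int, fold: int) -> np.ndarray:
        return self.pairs[self.assignment[repeat] == fold]


@dataclass
class EvalReport:
    """AUC results of a validation protocol.

    ``auc_per_fold`` holds one AUC per repeat x fold (CV) or per drug
    (de novo); ``auc_mean``/``auc_sd`` summarise it.  De novo reports
    additionally carry ``pooled_auc`` (one AUC over all drugs' scores
    combined) and the per-drug breakdown.
    """

    protocol: str
    auc_per_fold: list[float]
    auc_mean: float
    auc_sd: float
    params: dict
    seed: Optional[int] = None
    n_folds: Optional[int] = None
    repeats: Optional[int] = None
    pooled_auc: Optional[float] = None
    auc_per_drug: dict[str, float] = field(default_factory=dict)
    skipped_drugs: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        out = {
            "protocol": self.protocol,
            "params": self.params,
            "auc_per_fold": self.auc_per_fold,
            "auc_mean": self.auc_mean,
            "auc_sd": self.auc_sd,
        }
        if self.seed is not None:
            out["seed"] = self.seed
        if self.n_folds is not None:
            out["n_folds"] = self.n_folds
        if self.repeats is not None:
            out["repeats"] = self.repeats
        if self.pooled_auc is not None:
            out["pooled_auc"] = self.pooled_auc
        if self.auc_per_drug:
            out["auc_per_drug"] = self.auc_per_drug
        if self.skipped_drugs:
            out["skipped_drugs"] = self.skipped_drugs
        return out


def _summarise(aucs: Sequence[float]) -> tuple[float, float]:
    arr = np.asarray(aucs, dtype=float)
    mean = float(arr.mean())
    sd = float(arr.std(ddof=1)) if arr.size > 1 else 0.0
    return mean, sd


def make_folds(Y: InteractionMatrix, n_folds: int, repeats: int, seed: int) -> FoldPlan:
    """Uniform random partition of known pairs into near-equal folds.

    Fold sizes within a repeat differ by at most one; repeats are
    independent; the whole plan is reproducible from ``seed`` (PCG64).
    """
    if n_folds < 2:
        raise InvalidParameterError("n_folds must be >= 2")
    if repeats < 1:
        raise InvalidParameterError("repeats must be >= 1")
    pairs = Y.known_pairs()
    m = len(pairs)
    if m < n_folds:
        raise InvalidParameterError(f"{m} known pairs cannot fill {n_folds} folds")
    rng = np.random.default_rng(seed)
    base = np.arange(m) % n_folds
    assignment = np.empty((repeats, m), dtype=int)
    for r in range(repeats):
        assignment[r] = base[rng.permutation(m)]
    return FoldPlan(n_folds, repeats, seed, pairs, assignment)


def auc_rank(pos_scores: Sequence[float], neg_scores: Sequence[float]) -> float:
    """Wilcoxon-Mann-Whitney AUC: P(pos > neg) + 0.5 * P(tie)."""
    pos = np.asarray(pos_scores, dtype=float)
    neg = np.asarray(neg_scores, dtype=float)
    if pos.size == 0 or neg.size == 0:
        raise InvalidParameterError("auc_rank requires non-empty score lists")
    ranks = rankdata(np.concatenate([pos, neg]))
    rank_sum = ranks[: pos.size].sum()
    u = rank_sum - pos.size * (pos.size + 1) / 2.0
    return float(u / (pos.size * neg.size))


Predictor = Callable[[InteractionMatrix, Optional[FeatureMatrix], DdigipParams], "np.ndarray"]


def _default_predictor(train, features, params, feature_similarity=None):
    return ddigip_predict(train, features, params, feature_similarity=feature_similarity).values


def cross_validate(
    Y: InteractionMatrix,
    features: Optional[FeatureMatrix],
    params: DdigipParams,
    plan: FoldPlan,
    predictor: Optional[Callable] = None,
) -> EvalReport:
    """k-fold CV over known pairs with per-fold AUC.

    For each repeat x fold the training matrix is the original Y with both
    symmetric entries of every test pair zeroed.  Positives are the test
    pairs' scores; negatives are the scores of all unordered pairs unknown
    in the original Y.  ``predictor`` may replace the DDIGIP pipeline (used
    by harness checks); it receives (train, features, params) and returns a
    score matrix.
    """
    iu, ju = np.triu_indices(Y.n_drugs, k=1)
    unknown_mask = Y.values[iu, ju] == 0
    neg_i, neg_j = iu[unknown_mask], ju[unknown_mask]

    feature_similarity = pearson_similarity(features) if features is not None else None
    if predictor is None:
        def predictor(train, feats, prms):  # noqa: ANN001 - local closure
            return _default_predictor(train, feats, prms, feature_similarity)

    aucs: list[float] = []
    for r in range(plan.repeats):
        for f in range(plan.n_folds):
            test = plan.test_pairs(r, f)
            train = Y.values.copy()
            train[test[:, 0], test[:, 1]] = 0.0
            train[test[:, 1], test[:, 0]] = 0.0
            if not train.any():
                raise DegenerateNetworkError(
                    f"repeat {r}, fold {f}: removing the test fold empties the network"
                )
            train_m = InteractionMatrix(train, Y.drug_index, binary=Y.binary)
            scores = np.asarray(predictor(train_m, features, params))
            pos = scores[test[:, 0], test[:, 1]]
            neg = scores[neg_i, neg_j]
            aucs.append(auc_rank(pos, neg))
    mean, sd = _summarise(aucs)
    return EvalReport(
        protocol=f"cv{plan.n_folds}",
        auc_per_fold=aucs,
        auc_mean=mean,
        auc_sd=sd,
        params=params.to_dict(),
        seed=plan.seed,
        n_folds=plan.n_folds,
        repeats=plan.repeats,
    )


def denovo_validate(
    Y: InteractionMatrix,
    features: FeatureMatrix,
    params: DdigipParams,
    feature_similarity=None,
) -> EvalReport:
    """Leave-one-drug-out validation for cold-start prediction.

    Each drug with at least one known DDI is made "new" in turn by zeroing
    its row and column; the pipeline (with the KNN fill treating it as a
    cold-start drug) then scores it against every other drug.  Positives
    are its true partners in the original Y, negatives its non-partners.
    Reports per-drug AUCs plus one pooled AUC over all drugs combined.
    """
    if feature_similarity is None:
        feature_similarity = pearson_similarity(features)
    ids = Y.drug_index.ids
    n = Y.n_drugs
    degrees = Y.degrees()

    aucs: list[float] = []
    per_drug: dict[str, float] = {}
    skipped: list[str] = []
    all_pos: list[np.ndarray] = []
    all_neg: list[np.ndarray] = []
    for i in range(n):
        if degrees[i] == 0:
            continue
        if features.missing[i] or feature_similarity.degenerate[i]:
            warnings.warn(
                f"drug {ids[i]!r}: features missing/degenerate; skipped in de novo validation",
                stacklevel=2,
            )
            skipped.append(ids[i])
            continue
        train = Y.values.copy()
        train[i, :] = 0.0
        train[:, i] = 0.0
        train_m = InteractionMatrix(train, Y.drug_index, binary=Y.binary)
        scores = ddigip_predict(
            train_m, features, params, feature_similarity=feature_similarity
        ).values
        others = np.arange(n) != i
        pos = scores[i, others & (Y.values[i] == 1)]
        neg = scores[i, others & (Y.values[i] == 0)]
        auc = auc_rank(pos, neg)
        per_drug[ids[i]] = auc
        aucs.append(auc)
        all_pos.append(pos)
        all_neg.append(neg)

    if not aucs:
        raise InvalidParameterError("no drug eligible for de novo validation")
    pooled = auc_rank(np.concatenate(all_pos), np.concatenate(all_neg))
    mean, sd = _summarise(aucs)
    return EvalReport(
        protocol="denovo",
        auc_per_fold=aucs,
        auc_mean=mean,
        auc_sd=sd,
        params=params.to_dict(),
        pooled_auc=pooled,
        auc_per_drug=per_drug,
        skipped_drugs=skipped,
    )


def grid_search_k(
    Y: InteractionMatrix,
    features: FeatureMatrix,
    params: DdigipParams,
    k_values: Sequence[int],
) -> tuple[dict[int, float], int]:
    """De novo pooled AUC for each K; returns (curve, best K).

    Duplicate K values are collapsed; ties on AUC resolve to the smaller K.
    """
    if len(k_values) == 0:
        raise InvalidParameterError("k_values must be non-empty")
    feature_similarity = pearson_similarity(features)
    curve: dict[int, float] = {}
    for k in sorted(set(int(k) for k in k_values)):
        p = DdigipParams(
            sigma=params.sigma,
            gamma_prime=params.gamma_prime,
            k_neighbors=k,
            knn_enabled=True,
        )
        report = denovo_validate(Y, features, p, feature_similarity=feature_similarity)
        curve[k] = float(report.pooled_auc)
    best_k = max(curve, key=lambda k: (curve[k], -k))
    return curve, best_k
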