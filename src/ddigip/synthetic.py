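"""Synthetic DDI networks with group structure and informative features.

The generator plants the statistical structure the predictor exploits:
drugs belong to latent groups, pairs whose groups are *compatible* interact
with high probability ``p_in`` against a low background ``p_out``, and each
drug's binary feature vector is a noisy copy of its group prototype.  Drugs
in the same group therefore share interaction partners (the GIP kernel's
signal) and have correlated features (the cold-start KNN's signal), so the
latent truth lets tests assert both recovery and, with ``flip_prob=0.5``,
the absence of signal.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict

import numpy as np

from .data import DrugIndex, FeatureMatrix, InteractionMatrix, atomic_write_text
from .errors import InvalidParameterError

__all__ = ["SynthConfig", "GroundTruth", "generate", "holdout_new_drug", "write_truth"]


@dataclass(frozen=True)
class SynthConfig:
    """Generator settings.

    Defaults give 120 drugs in 6 groups; compatible pairs interact with
    probability 0.35 against a 0.02 background; 300 feature bits with
    prototype density 0.2 and 5% per-bit noise.
    """

    n_drugs: int = 120
    n_groups: int = 6
    p_in: float = 0.35
    p_out: float = 0.02
    n_features: int = 300
    proto_density: float = 0.2
    flip_prob: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 <= self.p_out <= self.p_in <= 1):
            raise InvalidParameterError("require 0 <= p_out <= p_in <= 1")
        if not (0 <= self.flip_prob <= 0.5):
            raise InvalidParameterError("flip_prob must lie in [0, 0.5]")
        if not (1 <= self.n_groups <= self.n_drugs):
            raise InvalidParameterError("require 1 <= n_groups <= n_drugs")
        if self.n_features < 2:
            raise InvalidParameterError("n_features must be >= 2")
        if not (0 <= self.proto_density <= 1):
            raise InvalidParameterError("proto_density must lie in [0, 1]")

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass(frozen=True)
class GroundTruth:
    """Latent structure behind a generated dataset."""

    groups: tuple[int, ...]  # group id per drug, in drug-index order
    compatible: tuple[tuple[int, int], ...]  # unordered compatible group pairs (g1 <= g2)

    def is_compatible(self, g1: int, g2: int) -> bool:
        a, b = min(g1, g2), max(g1, g2)
        return (a, b) in set(self.compatible)

    def to_dict(self) -> dict:
        return {"groups": list(self.groups), "compatible": [list(p) for p in self.compatible]}


def generate(config: SynthConfig) -> tuple[InteractionMatrix, FeatureMatrix, GroundTruth]:
    """Draw one synthetic dataset: interactions, features, latent truth.

    Drugs get uniform group labels; every group is compatible with itself
    and one randomly chosen partner group; unordered pairs interact with
    probability ``p_in`` when their groups are compatible, else ``p_out``;
    features are the group prototype with independent per-bit flips.
    """
    rng = np.random.default_rng(config.seed)
    n, g = config.n_drugs, config.n_groups
    width = max(3, len(str(n - 1)))
    index = DrugIndex.from_ids(f"D{i:0{width}d}" for i in range(n))

    groups = rng.integers(0, g, size=n)

    comp = np.eye(g, dtype=bool)
    for grp in range(g):
        if g > 1:
            partner = int(rng.choice([x for x in range(g) if x != grp]))
            comp[grp, partner] = comp[partner, grp] = True

    probs = np.where(comp[groups[:, None], groups[None, :]], config.p_in, config.p_out)
    upper = np.triu(rng.random((n, n)) < probs, k=1)
    y = (upper | upper.T).astype(float)

    prototypes = (rng.random((g, config.n_features)) < config.proto_density).astype(float)
    flips = rng.random((n, config.n_features)) < config.flip_prob
    feats = np.abs(prototypes[groups] - flips.astype(float))

    pairs = tuple(
        (i, j) for i in range(g) for j in range(i, g) if comp[i, j]
    )
    truth = GroundTruth(groups=tuple(int(x) for x in groups), compatible=pairs)
    return (
        InteractionMatrix(y, index, binary=True),
        FeatureMatrix(feats, index),
        truth,
    )


def holdout_new_drug(
    Y: InteractionMatrix, drug: str
) -> tuple[InteractionMatrix, list[tuple[str, str]]]:
    """Zero one drug's row/column; return the copy and the removed pairs."""
    i = Y.drug_index.index(drug)
    partners = np.flatnonzero(Y.values[i] != 0)
    if partners.size == 0:
        raise InvalidParameterError(f"drug {drug!r} has no known interactions to hold out")
    held = [tuple(sorted((drug, Y.drug_index.ids[j]))) for j in partners]
    values = Y.values.copy()
    values[i, :] = 0.0
    values[:, i] = 0.0
    return InteractionMatrix(values, Y.drug_index, binary=Y.binary), held


def write_truth(truth: GroundTruth, config: SynthConfig, path: str) -> None:
    payload = {"config": config.to_dict(), "truth": truth.to_dict()}
    atomic_write_text(path, json.dumps(payload, indent=2, sort_keys=True) + "\n")
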