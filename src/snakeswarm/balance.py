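"""SMOTE-ENN class rebalancing on encoded (all-numeric) feature matrices.

Phase 1 (SMOTE) oversamples every minority class up to the majority count by
interpolating between a class member and one of its k nearest same-class
neighbours: ``x_new = x + gap * (nn - x)`` with ``gap ~ U(0, 1)``.  Phase 2
(ENN, edited nearest neighbours) then removes — from all classes — every
sample whose label disagrees with the strict majority label of its k nearest
neighbours.  Distances are Euclidean on the standardized, one-hot-encoded
matrix, so balancing runs after the column transform.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.neighbors import NearestNeighbors

from ._rng import substream
from .prep import TabularDataset

__all__ = ["smote_oversample", "enn_clean", "smoteenn_balance"]


def smote_oversample(
    train: TabularDataset, k_smote: int = 5, seed: int = 0
) -> TabularDataset:
    """Oversample every minority class to the majority count.

    Each synthetic row's parents (base row index, neighbour row index, gap)
    are recorded in ``provenance['smote_parents']`` for auditability.
    """
    rng = substream(seed, "smote")
    X = train.X.to_numpy(dtype=float)
    y = train.y.to_numpy()
    counts = train.y.value_counts()
    majority = int(counts.max())

    new_rows: list[np.ndarray] = []
    new_labels: list = []
    parents: list[tuple] = []
    for cls, count in counts.items():
        need = majority - int(count)
        if need == 0:
            continue
        if count < 2:
            raise ValueError(f"too-few-samples: class {cls!r} has {count} member(s)")
        cls_idx = np.flatnonzero(y == cls)
        k = min(k_smote, len(cls_idx) - 1)
        nn = NearestNeighbors(n_neighbors=k + 1).fit(X[cls_idx])
        neigh = nn.kneighbors(X[cls_idx], return_distance=False)[:, 1:]  # drop self
        base = rng.integers(len(cls_idx), size=need)
        pick = rng.integers(k, size=need)
        gaps = rng.random(need)
        for b, p, g in zip(base, pick, gaps):
            j = neigh[b, p]
            new_rows.append(X[cls_idx[b]] + g * (X[cls_idx[j]] - X[cls_idx[b]]))
            new_labels.append(cls)
            parents.append((int(cls_idx[b]), int(cls_idx[j]), float(g)))

    if new_rows:
        X_out = np.vstack([X, np.asarray(new_rows)])
        y_out = np.concatenate([y, np.asarray(new_labels, dtype=y.dtype)])
    else:
        X_out, y_out = X, y
    prov = dict(train.provenance)
    prov["smote_parents"] = parents
    prov["counts_before_smote"] = {k: int(v) for k, v in counts.items()}
    return TabularDataset(
        pd.DataFrame(X_out, columns=train.feature_names),
        pd.Series(y_out, name=train.y.name),
        list(train.schema),
        prov,
    )


def enn_clean(train: TabularDataset, k_enn: int = 3) -> TabularDataset:
    """Remove samples whose label disagrees with the strict majority label of
    their k nearest neighbours (self excluded); ties keep the sample.
    All removals are decided simultaneously on the full set."""
    X = train.X.to_numpy(dtype=float)
    y = train.y.to_numpy()
    nn = NearestNeighbors(n_neighbors=k_enn + 1).fit(X)
    neigh = nn.kneighbors(X, return_distance=False)[:, 1:]
    keep = np.ones(len(y), dtype=bool)
    for i in range(len(y)):
        labels, votes = np.unique(y[neigh[i]], return_counts=True)
        top = votes.max()
        winners = labels[votes == top]
        if len(winners) == 1 and winners[0] != y[i]:
            keep[i] = False
    prov = dict(train.provenance)
    prov["enn_removed"] = int((~keep).sum())
    return TabularDataset(
        train.X.loc[keep].reset_index(drop=True),
        train.y.loc[keep].reset_index(drop=True),
        list(train.schema),
        prov,
    )


def smoteenn_balance(
    train: TabularDataset, k_smote: int = 5, k_enn: int = 3, seed: int = 0
) -> TabularDataset:
    """SMOTE to class parity, then ENN cleaning; per-class before/after counts
    are recorded in provenance."""
    before = train.y.value_counts().to_dict()
    out = enn_clean(smote_oversample(train, k_smote=k_smote, seed=seed), k_enn=k_enn)
    out.provenance["counts_before_balance"] = {k: int(v) for k, v in before.items()}
    out.provenance["counts_after_balance"] = {
        k: int(v) for k, v in out.y.value_counts().items()
    }
    return out
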