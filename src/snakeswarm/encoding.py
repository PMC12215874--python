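"""Mapping between optimizer positions and (feature mask, hyperparameters).

The wrapper search runs in a single raw box: one dimension per candidate
feature (raw bounds (0, 1), thresholded at 0.5 into a mask bit) plus the
classifier's hyperparameter dimensions (raw bounds (1, 100), mapped affinely
— or log-affinely — into each parameter's native range).  An all-zero mask
is repaired by switching on the feature with the largest raw value.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .swarm import BoundsSpec

__all__ = ["DimensionSpec", "SolutionEncoding", "build_space", "space_bounds", "decode",
           "HYPERPARAM_SPACES"]

KINDS = ("mask", "integer", "continuous", "log_continuous")


@dataclass(frozen=True)
class DimensionSpec:
    name: str
    kind: str
    raw_bounds: tuple[float, float] = (1.0, 100.0)
    native_bounds: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        if self.kind not in KINDS:
            raise ValueError(f"unknown dimension kind {self.kind!r}")
        if self.kind == "mask":
            object.__setattr__(self, "raw_bounds", (0.0, 1.0))
        elif self.native_bounds is None:
            raise ValueError(f"{self.name}: non-mask dims need native bounds")


@dataclass(frozen=True)
class SolutionEncoding:
    feature_mask: tuple[int, ...]
    hyperparams: dict
    n_selected: int

    def key(self) -> tuple:
        return (self.feature_mask, tuple(sorted(self.hyperparams.items())))


# Native hyperparameter ranges per wrapper model.  The raw search box for
# every non-mask dimension is (1, 100); integer parameters map affinely and
# continuous SVM parameters map on a log10 scale.  KNN's vote weighting is a
# mask-style bit (>= 0.5 -> distance weighting).
HYPERPARAM_SPACES: dict[str, list[DimensionSpec]] = {
    "rf": [
        DimensionSpec("n_estimators", "integer", native_bounds=(1, 100)),
        DimensionSpec("max_depth", "integer", native_bounds=(1, 100)),
    ],
    "dt": [
        DimensionSpec("max_depth", "integer", native_bounds=(1, 100)),
        DimensionSpec("min_samples_split", "integer", native_bounds=(2, 100)),
    ],
    "svm": [
        DimensionSpec("C", "log_continuous", native_bounds=(1e-2, 1e3)),
        DimensionSpec("gamma", "log_continuous", native_bounds=(1e-4, 1e1)),
    ],
    "knn": [
        DimensionSpec("n_neighbors", "integer", native_bounds=(1, 100)),
        DimensionSpec("distance_weighting", "mask"),
    ],
}


def build_space(feature_names: list[str], model_id: str) -> list[DimensionSpec]:
    """One mask dimension per feature followed by the model's hyperparameter
    dimensions."""
    if model_id not in HYPERPARAM_SPACES:
        raise ValueError(f"unknown model {model_id!r}")
    dims = [DimensionSpec(f"mask:{name}", "mask") for name in feature_names]
    return dims + HYPERPARAM_SPACES[model_id]


def space_bounds(space: list[DimensionSpec]) -> BoundsSpec:
    lo = np.array([d.raw_bounds[0] for d in space])
    hi = np.array([d.raw_bounds[1] for d in space])
    return BoundsSpec(lo, hi)


def _decode_native(dim: DimensionSpec, raw: float) -> float | int:
    rlo, rhi = dim.raw_bounds
    frac = (raw - rlo) / (rhi - rlo)
    nlo, nhi = dim.native_bounds
    if dim.kind == "integer":
        value = int(np.floor(nlo + frac * (nhi - nlo) + 0.5))  # round half up
        return int(np.clip(value, nlo, nhi))
    if dim.kind == "continuous":
        return float(nlo + frac * (nhi - nlo))
    # log_continuous
    llo, lhi = np.log10(nlo), np.log10(nhi)
    return float(10.0 ** (llo + frac * (lhi - llo)))


def decode(position: np.ndarray, space: list[DimensionSpec]) -> SolutionEncoding:
    """Decode a raw position into a repaired feature mask and native
    hyperparameter values."""
    position = np.asarray(position, dtype=float)
    if position.size != len(space):
        raise ValueError(
            f"invalid-position: length {position.size} != space size {len(space)}"
        )
    mask_idx = [i for i, d in enumerate(space) if d.kind == "mask" and d.name.startswith("mask:")]
    bits = {i: int(position[i] >= 0.5) for i in mask_idx}
    if mask_idx and not any(bits.values()):
        best = max(mask_idx, key=lambda i: position[i])
        bits[best] = 1
    hyperparams: dict = {}
    for i, d in enumerate(space):
        if i in bits:
            continue
        if d.kind == "mask":  # mask-style hyperparameter bit (e.g. KNN weighting)
            hyperparams[d.name] = int(position[i] >= 0.5)
        else:
            hyperparams[d.name] = _decode_native(d, position[i])
    mask = tuple(bits[i] for i in mask_idx)
    return SolutionEncoding(
        feature_mask=mask, hyperparams=hyperparams, n_selected=int(sum(mask))
    )
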