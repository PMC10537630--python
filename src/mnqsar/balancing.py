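"""Class-imbalance handling: class weighting and SMOTE oversampling.

Both micronucleus endpoints are imbalanced (roughly 70/30 positive in
vitro, 32/68 in vivo), so classifiers are trained either with
inverse-frequency class weights or after synthetic minority
oversampling. SMOTE is implemented here from its definition: each
synthetic sample is a uniform interpolation between a minority sample
and one of its k Euclidean nearest minority neighbors. Resampling is
always applied inside a training fold, never before splitting.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.neighbors import NearestNeighbors


@dataclass
class BalancingConfig:
    """How to counter class imbalance during training.

    method: 'none', 'class_weight' or 'smote'. smote_k: neighbor count
    for interpolation (clamped to minority size - 1). target_ratio:
    minority/majority ratio after resampling (1.0 = full balance).
    """

    method: str = "none"
    smote_k: int = 5
    target_ratio: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.method not in ("none", "class_weight", "smote"):
            raise ValueError(f"unknown balancing method {self.method!r}")
        if self.smote_k < 1:
            raise ValueError("smote_k must be >= 1")
        if not 0 < self.target_ratio <= 1:
            raise ValueError("target_ratio must be in (0, 1]")


def class_weights(labels: np.ndarray) -> dict[int, float]:
    """Inverse-frequency weights w_c = n / (2 * n_c).

    The weighted mass of each class is equal: w_0*n_0 == w_1*n_1.
    The data itself is untouched; weights are consumed by the learner.
    """
    y = np.asarray(labels).astype(int)
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2:
        raise ValueError("labels must contain both classes")
    n = len(y)
    return {int(c): n / (2 * int(k)) for c, k in zip(classes, counts)}


def smote_resample(
    X: np.ndarray, y: np.ndarray, cfg: BalancingConfig | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Oversample the minority class by SMOTE interpolation.

    Appends synthetic minority rows x_new = x_i + u * (x_nn - x_i) with
    u ~ U[0, 1] and x_nn one of the k nearest minority neighbors of
    x_i, until minority/majority reaches ``cfg.target_ratio`` (rounded
    to the nearest integer count). Original rows are preserved verbatim
    and majority rows are never touched. Deterministic for a fixed seed.
    """
    cfg = cfg or BalancingConfig(method="smote")
    X = np.asarray(X, dtype=float)
    y = np.asarray(y).astype(int)
    if X.ndim != 2 or len(X) != len(y):
        raise ValueError("X must be 2-D and aligned with y")
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) != 2:
        raise ValueError("SMOTE requires exactly two classes")

    minority = int(classes[np.argmin(counts)])
    n_min = int(counts.min())
    n_maj = int(counts.max())
    n_target = int(round(cfg.target_ratio * n_maj))
    n_synth = n_target - n_min
    if n_synth <= 0:
        return X.copy(), y.copy()
    if n_min < 2:
        raise ValueError("SMOTE needs at least 2 minority samples")

    Xmin = X[y == minority]
    k = min(cfg.smote_k, n_min - 1)
    nn = NearestNeighbors(n_neighbors=k + 1).fit(Xmin)
    # first neighbor is the point itself
    neighbor_idx = nn.kneighbors(Xmin, return_distance=False)[:, 1:]

    rng = np.random.default_rng(cfg.seed)
    base = rng.integers(0, n_min, size=n_synth)
    pick = rng.integers(0, k, size=n_synth)
    u = rng.random(n_synth)
    x_i = Xmin[base]
    x_nn = Xmin[neighbor_idx[base, pick]]
    synth = x_i + u[:, None] * (x_nn - x_i)

    X_out = np.vstack([X, synth])
    y_out = np.concatenate([y, np.full(n_synth, minority, dtype=y.dtype)])
    return X_out, y_out
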