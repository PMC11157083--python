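"""Two-class random-forest pixel classifier over a fixed convolutional bank.

The model is deliberately small — 100 trees of depth 2 — so that it can be
trained from a few hundred sparsely annotated voxels and serialized to a
portable JSON document.  Prediction never requires scikit-learn: the fitted
trees are exported to plain arrays and evaluated directly, so a stored model
round-trips losslessly and behaves identically across library versions.

Feature bank
------------
Filters are named members of a fixed vocabulary, each paired with a sigma:

==========================  ====================================================
``original``                the (preprocessed) image itself, sigma ignored
``gaussian``                Gaussian blur, standard deviation sigma
``difference_of_gaussian``  ``G(sigma) - G(2*sigma)``
``laplace_of_gaussian_box`` 6-neighbour discrete Laplacian of ``G(sigma)``
``sobel_of_gaussian``       Sobel gradient magnitude of ``G(sigma)``
``median_box``              median over a box of half-width sigma
``mean_box``                mean over a box of half-width sigma
``tophat_box``              white top-hat over a box of half-width sigma
==========================  ====================================================
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence
import warnings

import numpy as np
from scipy import ndimage
from sklearn.ensemble import RandomForestClassifier

from .preprocess import ImageStack3D

BACKGROUND, SIGNAL = 0, 1

FORMAT_VERSION = 1
N_TREES = 100
MAX_DEPTH = 2

FilterSpec = tuple[str, float]

#: production bank: raw image plus the three most efficient filters at sigma 1
DEFAULT_FEATURE_BANK: tuple[FilterSpec, ...] = (
    ("original", 0),
    ("gaussian", 1),
    ("difference_of_gaussian", 1),
    ("laplace_of_gaussian_box", 1),
)

#: every named filter at sigma 1 and 2, plus the raw image
FULL_FEATURE_BANK: tuple[FilterSpec, ...] = (("original", 0),) + tuple(
    (name, sigma)
    for name in (
        "gaussian",
        "difference_of_gaussian",
        "laplace_of_gaussian_box",
        "sobel_of_gaussian",
        "median_box",
        "mean_box",
        "tophat_box",
    )
    for sigma in (1, 2)
)


def _box_size(sigma: float) -> int:
    return 2 * int(round(sigma)) + 1


def _apply_filter(voxels: np.ndarray, name: str, sigma: float) -> np.ndarray:
    if name == "original":
        return voxels.copy()
    if name == "gaussian":
        return ndimage.gaussian_filter(voxels, sigma=sigma)
    if name == "difference_of_gaussian":
        return ndimage.gaussian_filter(voxels, sigma=sigma) - ndimage.gaussian_filter(
            voxels, sigma=2 * sigma
        )
    if name == "laplace_of_gaussian_box":
        return ndimage.laplace(ndimage.gaussian_filter(voxels, sigma=sigma))
    if name == "sobel_of_gaussian":
        g = ndimage.gaussian_filter(voxels, sigma=sigma)
        return np.sqrt(sum(ndimage.sobel(g, axis=ax) ** 2 for ax in range(3)))
    if name == "median_box":
        return ndimage.median_filter(voxels, size=_box_size(sigma))
    if name == "mean_box":
        return ndimage.uniform_filter(voxels, size=_box_size(sigma))
    if name == "tophat_box":
        return ndimage.white_tophat(voxels, size=_box_size(sigma))
    raise ValueError(f"unknown filter name {name!r}")


def compute_features(
    stack: ImageStack3D, bank: Sequence[FilterSpec] = DEFAULT_FEATURE_BANK
) -> np.ndarray:
    """One feature volume per bank entry, stacked as ``(n_features, z, y, x)``."""
    if not bank:
        raise ValueError("feature bank must not be empty")
    return np.stack([_apply_filter(stack.voxels, name, sigma) for name, sigma in bank])


@dataclass
class SparseAnnotation:
    """Voxel coordinates with class labels for one training image."""

    coords: np.ndarray  # (n, 3) int, (z, y, x)
    labels: np.ndarray  # (n,) in {BACKGROUND, SIGNAL}
    image_id: str = ""

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=np.intp)
        self.labels = np.asarray(self.labels, dtype=np.intp)
        if self.coords.ndim != 2 or self.coords.shape[1] != 3:
            raise ValueError("coords must be an (n, 3) array of (z, y, x)")
        if self.labels.shape != (len(self.coords),):
            raise ValueError("labels must align with coords")
        if not np.isin(self.labels, [BACKGROUND, SIGNAL]).all():
            raise ValueError("labels must be 0 (background) or 1 (signal)")

    def validate_bounds(self, shape: tuple[int, int, int]) -> None:
        if np.any(self.coords < 0) or np.any(self.coords >= np.asarray(shape)):
            raise ValueError(f"annotation coordinates outside image bounds {shape}")

    def deduplicated(self) -> "SparseAnnotation":
        _, idx = np.unique(self.coords, axis=0, return_index=True)
        if len(idx) < len(self.coords):
            warnings.warn(
                f"{len(self.coords) - len(idx)} duplicate annotation coordinates "
                f"dropped for image {self.image_id!r}",
                stacklevel=2,
            )
        idx = np.sort(idx)
        return SparseAnnotation(
            coords=self.coords[idx], labels=self.labels[idx], image_id=self.image_id
        )


@dataclass
class ForestModel:
    """Portable depth-2 random forest: per-tree split arrays plus metadata.

    Tree arrays follow the scikit-learn convention: ``left/right`` are child
    node indices (-1 at leaves), ``feature/threshold`` define the split
    ``x[feature] <= threshold`` (left branch), ``votes`` holds the per-node
    training class counts ``[background, signal]``.
    """

    trees: list[dict]
    bank: tuple[FilterSpec, ...]
    seed: int
    image_ids: list[str] = field(default_factory=list)
    format_version: int = FORMAT_VERSION

    @property
    def n_features(self) -> int:
        return len(self.bank)

    def tree_votes(self, features: np.ndarray) -> np.ndarray:
        """Count per-sample signal votes over all trees.

        ``features`` is ``(n_samples, n_features)``; a tree votes for the
        majority class of the leaf a sample lands in, ties go to background.
        """
        if features.ndim != 2 or features.shape[1] != self.n_features:
            raise ValueError(
                f"feature bank mismatch: model expects {self.n_features} features, "
                f"got array of shape {features.shape}"
            )
        n = features.shape[0]
        signal_votes = np.zeros(n, dtype=np.int32)
        for tree in self.trees:
            leaf_class = np.asarray(tree["votes"])[:, SIGNAL] > np.asarray(tree["votes"])[:, BACKGROUND]
            node = np.zeros(n, dtype=np.intp)
            left = np.asarray(tree["left"])
            right = np.asarray(tree["right"])
            feat = np.asarray(tree["feature"])
            thr = np.asarray(tree["threshold"])
            active = left[node] != -1
            while active.any():
                idx = np.nonzero(active)[0]
                cur = node[idx]
                goes_left = features[idx, feat[cur]] <= thr[cur]
                node[idx] = np.where(goes_left, left[cur], right[cur])
                active = left[node] != -1
            signal_votes += leaf_class[node]
        return signal_votes

    def classify(self, features: np.ndarray) -> np.ndarray:
        """Majority vote over trees; a tie is resolved to background."""
        return (self.tree_votes(features) * 2 > len(self.trees)).astype(np.uint8)

    # -- serialization ------------------------------------------------------

    def to_json(self) -> str:
        doc = {
            "format_version": self.format_version,
            "n_trees": len(self.trees),
            "max_depth": MAX_DEPTH,
            "seed": self.seed,
            "bank": [[name, sigma] for name, sigma in self.bank],
            "image_ids": self.image_ids,
            "trees": [
                {
                    "feature": [int(v) for v in t["feature"]],
                    "threshold": [float(v) for v in t["threshold"]],
                    "left": [int(v) for v in t["left"]],
                    "right": [int(v) for v in t["right"]],
                    "votes": [[int(a), int(b)] for a, b in t["votes"]],
                }
                for t in self.trees
            ],
        }
        return json.dumps(doc, indent=1)

    @classmethod
    def from_json(cls, text: str) -> "ForestModel":
        doc = json.loads(text)
        if doc.get("format_version") != FORMAT_VERSION:
            raise ValueError(f"unsupported model format version {doc.get('format_version')}")
        return cls(
            trees=doc["trees"],
            bank=tuple((name, sigma) for name, sigma in doc["bank"]),
            seed=int(doc["seed"]),
            image_ids=list(doc.get("image_ids", [])),
        )

    def save(self, path: str | Path) -> None:
        Path(path).write_text(self.to_json())

    @classmethod
    def load(cls, path: str | Path) -> "ForestModel":
        return cls.from_json(Path(path).read_text())


def _export_tree(estimator) -> dict:
    t = estimator.tree_
    return {
        "feature": t.feature.tolist(),
        "threshold": t.threshold.tolist(),
        "left": t.children_left.tolist(),
        "right": t.children_right.tolist(),
        "votes": _node_counts(t),
    }


def _node_counts(t) -> list[list[int]]:
    # sklearn >= 1.3 stores per-node class *fractions* in value; recover
    # counts via weighted_n_node_samples so tie-breaking is exact
    frac = t.value[:, 0, :]
    n = t.weighted_n_node_samples
    counts = np.rint(frac * n[:, None]).astype(np.int64)
    return counts.tolist()


def train(
    annotations: Sequence[SparseAnnotation],
    stacks: Sequence[ImageStack3D],
    bank: Sequence[FilterSpec] = DEFAULT_FEATURE_BANK,
    seed: int = 0,
) -> ForestModel:
    """Fit the forest on annotated voxels of preprocessed stacks.

    Requires at least one annotated image and both classes present overall.
    Duplicate annotation coordinates are deduplicated with a warning.
    """
    if len(annotations) == 0:
        raise ValueError("at least one annotated image is required")
    if len(annotations) != len(stacks):
        raise ValueError("annotations and stacks must align")
    bank = tuple((name, float(sigma)) for name, sigma in bank)

    xs, ys = [], []
    image_ids = []
    for ann, stack in zip(annotations, stacks):
        ann.validate_bounds(stack.shape)
        ann = ann.deduplicated()
        feats = compute_features(stack, bank)
        z, y, x = ann.coords.T
        xs.append(feats[:, z, y, x].T)
        ys.append(ann.labels)
        image_ids.append(ann.image_id)
    X = np.concatenate(xs)
    y = np.concatenate(ys)
    if len(np.unique(y)) < 2:
        raise ValueError("annotations must contain both classes")

    forest = RandomForestClassifier(
        n_estimators=N_TREES, max_depth=MAX_DEPTH, random_state=seed
    )
    forest.fit(X, y)
    if not np.array_equal(forest.classes_, [BACKGROUND, SIGNAL]):
        raise AssertionError("unexpected class ordering")
    trees = [_export_tree(est) for est in forest.estimators_]
    return ForestModel(trees=trees, bank=bank, seed=seed, image_ids=image_ids)


def predict(model: ForestModel, stack: ImageStack3D) -> np.ndarray:
    """Binary signal mask for a stack preprocessed like the training data."""
    feats = compute_features(stack, model.bank)
    if feats.shape[0] != model.n_features:
        raise ValueError("feature bank mismatch between model and stack features")
    flat = feats.reshape(model.n_features, -1).T
    return model.classify(flat).reshape(stack.shape).astype(bool)
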