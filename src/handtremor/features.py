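"""Feature extraction: modified PHOG, shape descriptors, deep embeddings.

The pyramid histogram of oriented gradients (PHOG) concatenates per-cell
orientation histograms over grids of 2^l x 2^l cells, l = 0..L.  The
*modified* variant used here first augments both derivative maps with a
scalar "improved entropy" IE computed from the gradient maps themselves: the
horizontal and vertical gradient entropies are compared and the larger one
(or their mean, when they are equal within tolerance) is added uniformly to
U_X and U_Y before orientation/magnitude binning.  The improved entropy is an
evidential (Dempster-Shafer flavoured) reweighting of Shannon entropy
computed over a K-bin histogram of gradient magnitudes whose bins act as
singleton focal elements.

Shape descriptors (area, perimeter, convex hull, contour-approximation
epsilon) come from the largest ink contour; deep embeddings come from
randomly-initialized (seeded) VGG16 / ResNet-50 forward passes in
:mod:`handtremor.backbones`.  The fused vector is ``Ff = [PHOG | shape |
deep]`` with a recorded segment layout and train-set standardization.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from shapely.geometry import Polygon
from skimage import measure
from skimage.filters import threshold_otsu

from . import backbones

__all__ = [
    "GradientField",
    "EntropyPair",
    "PhogConfig",
    "ShapeFeatures",
    "DeepFeatureConfig",
    "FeatureLayout",
    "FusedFeatures",
    "compute_gradients",
    "shannon_entropy",
    "improved_entropy",
    "entropy_from_masses",
    "modified_gradients",
    "phog",
    "phog_length",
    "shape_features",
    "deep_features",
    "fuse",
    "FeatureStandardizer",
]

K_X = np.array([[-1.0, 0.0, 1.0]])
K_Y = K_X.T


@dataclass(frozen=True)
class GradientField:
    """Signed derivative maps with orientation and magnitude."""

    u_x: np.ndarray
    u_y: np.ndarray
    u_o: np.ndarray  # arctan(U_Y/U_X) in (-pi/2, pi/2], 0 where both vanish
    u_g: np.ndarray  # sqrt(U_X^2 + U_Y^2)


@dataclass(frozen=True)
class EntropyPair:
    e_x: float
    e_y: float
    threshold: float  # mean of the two entropies
    selected: float  # the IE value injected into the gradients


@dataclass(frozen=True)
class PhogConfig:
    levels: int = 2
    bins: int = 8
    angle_mode: str = "unsigned"  # [0, 180) - classic PHOG edge convention
    norm: str = "l1"  # "l1" (sums to 1), "l2", or "none" (raw magnitude mass)

    def __post_init__(self) -> None:
        if self.levels < 0 or self.bins < 2:
            raise ValueError("levels must be >= 0 and bins >= 2")
        if self.angle_mode not in ("unsigned", "signed"):
            raise ValueError("angle_mode must be 'unsigned' or 'signed'")


@dataclass(frozen=True)
class ShapeFeatures:
    area: float
    perimeter: float
    hull_area: float
    hull_vertices: int
    epsilon: float

    def as_vector(self) -> np.ndarray:
        return np.array(
            [self.area, self.perimeter, self.hull_area, self.hull_vertices, self.epsilon]
        )


@dataclass(frozen=True)
class DeepFeatureConfig:
    backbones: tuple[str, ...] = ("vgg16",)
    input_size: int = 64
    weights_mode: str = "random-seeded"  # or "pretrained-file"
    weights_path: str | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        for name in self.backbones:
            if name not in ("vgg16", "resnet50"):
                raise ValueError(f"unknown backbone {name!r}")
        if self.weights_mode not in ("random-seeded", "pretrained-file"):
            raise ValueError("weights_mode must be 'random-seeded' or 'pretrained-file'")


# ---------------------------------------------------------------------------
# gradients and entropies


def compute_gradients(image: np.ndarray) -> GradientField:
    """Correlate with K_X = [-1 0 1] and its transpose (reflect padding)."""
    img = np.asarray(image, dtype=np.float64)
    if img.ndim != 2 or min(img.shape) < 3:
        raise ValueError("image must be 2-D and at least 3x3")
    u_x = ndimage.correlate(img, K_X, mode="reflect")
    u_y = ndimage.correlate(img, K_Y, mode="reflect")
    return GradientField(u_x, u_y, _orientation(u_x, u_y), np.hypot(u_x, u_y))


def _orientation(u_x: np.ndarray, u_y: np.ndarray) -> np.ndarray:
    """arctan(U_Y/U_X) with the 0/0 case defined as 0."""
    with np.errstate(divide="ignore", invalid="ignore"):
        u_o = np.arctan(u_y / u_x)
    u_o = np.where(u_x == 0, np.sign(u_y) * np.pi / 2, u_o)
    return np.where((u_x == 0) & (u_y == 0), 0.0, u_o)


def shannon_entropy(probabilities: np.ndarray, base: float = 2.0) -> float:
    """``-sum p log_b p`` with ``0 log 0 := 0``; renormalizes near-unit sums."""
    p = np.asarray(probabilities, dtype=np.float64)
    if (p < 0).any():
        raise ValueError("probabilities must be non-negative")
    total = p.sum()
    if not np.isclose(total, 1.0, atol=1e-6):
        raise ValueError(f"probabilities sum to {total}, not 1")
    p = p / total
    nz = p[p > 0]
    return float(-(nz * np.log(nz) / np.log(base)).sum())


def _magnitude_histogram(gradient_map: np.ndarray, bins: int) -> np.ndarray:
    """Bin probabilities of |gradient| values: the singleton mass function."""
    mags = np.abs(np.asarray(gradient_map, dtype=np.float64)).ravel()
    hist, _ = np.histogram(mags, bins=bins)
    total = hist.sum()
    return hist / total if total > 0 else hist.astype(np.float64)


def improved_entropy(
    gradient_map: np.ndarray, bins: int = 8, eps: float = 1e-12, base: float = 2.0
) -> float:
    """Evidential entropy of a gradient map (finite, clamped to >= 0).

    The frame of discernment is a ``bins``-bin histogram of gradient
    magnitudes; each bin is a singleton focal element with mass a(M) equal to
    its probability, so |M| = 1 and ``2^|M| - 1 = 1``.  Writing ``d =
    a log_2 a`` (stabilized at magnitude ``eps``), the value is::

        [ -sum_M a * log2( (a + 1) / |d| ) ]  /
        [  sum_M ( a log2 a  +  sigmoid(log2 a) ) ]

    Zero-mass bins contribute nothing; an all-zero gradient map returns 0.
    Any histogram-bin permutation leaves the value unchanged.
    """
    if np.allclose(np.abs(gradient_map), 0.0):
        return 0.0
    masses = _magnitude_histogram(gradient_map, bins)
    return entropy_from_masses(masses, eps)


def entropy_from_masses(masses: np.ndarray, eps: float = 1e-12) -> float:
    """Evidential entropy of a singleton mass function (see improved_entropy)."""
    masses = np.asarray(masses, dtype=np.float64)
    nz = masses[masses > 0]
    if nz.size == 0:
        return 0.0
    log2 = np.log2(nz)
    d = nz * log2  # inner denominator P log_b P
    d_safe = np.maximum(np.abs(d), eps)
    numerator = -(nz * np.log2((nz + 1.0) / d_safe)).sum()
    # the second numerator sum is a(M) log2(2^|M| - 1) = a log2(1) = 0 for singletons
    denominator = (nz * log2 + 1.0 / (1.0 + np.exp(-log2))).sum()
    if abs(denominator) < eps:
        denominator = eps
    return float(max(numerator / denominator, 0.0))


def entropy_pair(field: GradientField, bins: int = 8, tol: float = 1e-6) -> EntropyPair:
    """Compare the improved entropies of U_X and U_Y and pick the IE scalar.

    The larger entropy is selected when the two differ by more than ``tol``
    (the gradient direction with more information is enhanced); when they are
    within tolerance - edge information evenly distributed - their mean is
    used.
    """
    e_x = improved_entropy(field.u_x, bins)
    e_y = improved_entropy(field.u_y, bins)
    threshold = (e_x + e_y) / 2.0
    selected = max(e_x, e_y) if abs(e_x - e_y) > tol else threshold
    return EntropyPair(e_x, e_y, threshold, selected)


def modified_gradients(image: np.ndarray, bins: int = 8) -> GradientField:
    """Gradients with the scalar IE added to both derivative maps."""
    plain = compute_gradients(image)
    ie = entropy_pair(plain, bins).selected
    u_x = plain.u_x + ie
    u_y = plain.u_y + ie
    return GradientField(u_x, u_y, _orientation(u_x, u_y), np.hypot(u_x, u_y))


# ---------------------------------------------------------------------------
# PHOG


def phog_length(levels: int, bins: int) -> int:
    return bins * sum(4**level for level in range(levels + 1))


def phog(field: GradientField, config: PhogConfig | None = None) -> np.ndarray:
    """Pyramid of orientation histograms weighted by gradient magnitude.

    Level l partitions the image into 2^l x 2^l cells; each cell accumulates
    U_G mass into ``bins`` orientation bins of U_O.  Levels are concatenated
    coarse-to-fine and the whole vector normalized (L1 by default, so it sums
    to 1 when any gradient mass is present).
    """
    config = config or PhogConfig()
    h, w = field.u_g.shape
    if min(h, w) < 2**config.levels:
        raise ValueError(
            f"pyramid level {config.levels} needs image >= {2 ** config.levels} px per side"
        )
    if config.angle_mode == "unsigned":
        angles = np.mod(np.arctan2(field.u_y, field.u_x), np.pi)
        span = np.pi
    else:
        angles = np.mod(np.arctan2(field.u_y, field.u_x), 2 * np.pi)
        span = 2 * np.pi
    bin_idx = np.minimum((angles / span * config.bins).astype(int), config.bins - 1)
    chunks: list[np.ndarray] = []
    for level in range(config.levels + 1):
        n = 2**level
        row_edges = np.linspace(0, h, n + 1, dtype=int)
        col_edges = np.linspace(0, w, n + 1, dtype=int)
        for r0, r1 in zip(row_edges[:-1], row_edges[1:]):
            for c0, c1 in zip(col_edges[:-1], col_edges[1:]):
                cell_hist = np.bincount(
                    bin_idx[r0:r1, c0:c1].ravel(),
                    weights=field.u_g[r0:r1, c0:c1].ravel(),
                    minlength=config.bins,
                )
                chunks.append(cell_hist)
    vector = np.concatenate(chunks)
    if config.norm == "none":
        pass
    elif config.norm == "l1":
        total = vector.sum()
        if total > 0:
            vector = vector / total
    else:
        norm = np.linalg.norm(vector)
        if norm > 0:
            vector = vector / norm
    return vector


# ---------------------------------------------------------------------------
# shape features


class BlankImageError(ValueError):
    pass


def shape_features(
    image: np.ndarray,
    binarize_threshold: float | None = None,
    epsilon_fraction: float = 0.01,
) -> ShapeFeatures:
    """Geometry of the largest ink contour.

    Ink (dark strokes on light paper) is foregrounded by thresholding the
    inverted image - Otsu by default.  The largest closed contour (marching
    squares at level 0.5 on the padded mask) is measured as a polygon: area,
    perimeter, convex-hull area and vertex count, and the contour
    approximation tolerance ``epsilon = epsilon_fraction * perimeter``.
    """
    img = np.asarray(image, dtype=np.float64)
    inverted = img.max() - img
    if binarize_threshold is None:
        if np.allclose(inverted, inverted.ravel()[0]):
            raise BlankImageError("image is constant; no threshold separates ink")
        binarize_threshold = float(threshold_otsu(inverted))
    mask = inverted > binarize_threshold
    if not mask.any():
        raise BlankImageError(
            f"no foreground at binarize_threshold={binarize_threshold:.3f}"
        )
    padded = np.pad(mask.astype(float), 1)
    contours = measure.find_contours(padded, 0.5)
    best: Polygon | None = None
    for contour in contours:
        if len(contour) < 4:
            continue
        poly = Polygon(contour)
        if not poly.is_valid:
            poly = poly.buffer(0)
        if poly.is_empty:
            continue
        if best is None or poly.area > best.area:
            best = poly
    if best is None:
        raise BlankImageError(
            f"no closed contour found at binarize_threshold={binarize_threshold:.3f}"
        )
    hull = best.convex_hull
    perimeter = float(best.length)
    hull_vertices = (
        len(hull.exterior.coords) - 1 if hull.geom_type == "Polygon" else len(hull.coords)
    )
    return ShapeFeatures(
        area=float(best.area),
        perimeter=perimeter,
        hull_area=float(hull.area),
        hull_vertices=int(hull_vertices),
        epsilon=epsilon_fraction * perimeter,
    )


# ---------------------------------------------------------------------------
# deep features


def deep_features(image: np.ndarray, config: DeepFeatureConfig | None = None) -> np.ndarray:
    """Backbone embedding(s) truncated at global average pooling.

    VGG16 gives 512 values, ResNet-50 gives 2048; with both enabled the
    embeddings are concatenated in the order listed in the config.
    """
    config = config or DeepFeatureConfig()
    parts = [
        backbones.get_backbone(name, config).embed(image) for name in config.backbones
    ]
    return np.concatenate(parts)


def deep_feature_length(config: DeepFeatureConfig) -> int:
    return sum({"vgg16": 512, "resnet50": 2048}[name] for name in config.backbones)


# ---------------------------------------------------------------------------
# fusion


@dataclass(frozen=True)
class FeatureLayout:
    """Segment names, offsets and (optional) standardization statistics."""

    names: tuple[str, ...]
    offsets: tuple[int, ...]  # len == len(names) + 1
    mean: np.ndarray | None = None
    std: np.ndarray | None = None

    def segment(self, vector: np.ndarray, name: str) -> np.ndarray:
        i = self.names.index(name)
        return vector[self.offsets[i] : self.offsets[i + 1]]


@dataclass(frozen=True)
class FusedFeatures:
    vector: np.ndarray
    layout: FeatureLayout


def fuse(
    phog_vec: np.ndarray,
    shape: ShapeFeatures | np.ndarray,
    deep: np.ndarray,
    layout: FeatureLayout | None = None,
) -> FusedFeatures:
    """Concatenate [phog | shape | deep]; standardize if the layout has stats."""
    shape_vec = shape.as_vector() if isinstance(shape, ShapeFeatures) else np.asarray(shape)
    segments = {"phog": np.asarray(phog_vec), "shape": shape_vec, "deep": np.asarray(deep)}
    for name, seg in segments.items():
        if not np.isfinite(seg).all():
            raise ValueError(f"non-finite values in segment {name!r}")
    vector = np.concatenate(list(segments.values()))
    if layout is None:
        sizes = [seg.size for seg in segments.values()]
        offsets = tuple(np.concatenate([[0], np.cumsum(sizes)]).tolist())
        layout = FeatureLayout(tuple(segments), offsets)
    else:
        if vector.size != layout.offsets[-1]:
            raise ValueError("vector length does not match layout")
        if layout.mean is not None:
            vector = (vector - layout.mean) / layout.std
    return FusedFeatures(vector, layout)


class FeatureStandardizer:
    """Per-dimension train-set standardization recorded into the layout."""

    def __init__(self) -> None:
        self.layout: FeatureLayout | None = None

    def fit(self, matrix: np.ndarray, layout: FeatureLayout) -> "FeatureStandardizer":
        mean = matrix.mean(axis=0)
        std = matrix.std(axis=0)
        std = np.where(std < 1e-12, 1.0, std)
        self.layout = FeatureLayout(layout.names, layout.offsets, mean, std)
        return self

    def transform(self, matrix: np.ndarray) -> np.ndarray:
        if self.layout is None or self.layout.mean is None:
            raise RuntimeError("standardizer not fitted")
        return (matrix - self.layout.mean) / self.layout.std
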