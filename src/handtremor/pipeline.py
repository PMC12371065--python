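"""End-to-end detection: preprocess, extract, train both branches, fuse.

For each manifest image the pipeline applies the modified Wiener filter,
extracts the modified-PHOG / shape / deep segments into the fused vector Ff,
standardizes by train-set statistics, reshapes Ff to a square map and trains
the GhostNet and Improved-LinkNet branches independently with cross-entropy.
At inference the two per-class probability vectors are averaged (mean-score
fusion); the argmax is the detection: healthy or patient.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import imageio.v3 as iio
import numpy as np

from . import features as ft
from . import filters, metrics, nn
from .data_io import DatasetManifest
from .networks import GhostNet, GhostNetSpec, ImprovedLinkNet, LinkNetSpec, vector_to_map

__all__ = [
    "TrainConfig",
    "FeatureConfig",
    "FeatureExtractor",
    "fuse_scores",
    "train_hybrid",
    "HybridModel",
    "evaluate",
    "predictions_from_scores",
]


@dataclass(frozen=True)
class FeatureConfig:
    wiener: filters.WienerConfig = field(default_factory=filters.WienerConfig)
    phog: ft.PhogConfig = field(default_factory=ft.PhogConfig)
    deep: ft.DeepFeatureConfig = field(default_factory=ft.DeepFeatureConfig)
    phog_bins_entropy: int = 8


@dataclass(frozen=True)
class TrainConfig:
    epochs: int = 20
    batch_size: int = 16
    learning_rate: float = 1e-3
    seed: int = 0
    fusion: str = "probabilities"  # or "logits"

    def __post_init__(self) -> None:
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")


def _load_gray(path: str) -> np.ndarray:
    img = np.asarray(iio.imread(path), dtype=np.float64)
    if img.ndim == 3:
        img = img[..., :3].mean(axis=2)
    return img


class FeatureExtractor:
    """Manifest -> fused feature matrix, with train-set standardization."""

    def __init__(self, config: FeatureConfig | None = None):
        self.config = config or FeatureConfig()
        self.standardizer = ft.FeatureStandardizer()
        self.layout: ft.FeatureLayout | None = None

    def _one(self, path: str) -> np.ndarray:
        cfg = self.config
        image = filters.modified_wiener(_load_gray(path), cfg.wiener)
        grads = ft.modified_gradients(image, cfg.phog_bins_entropy)
        phog_vec = ft.phog(grads, cfg.phog)
        shape = ft.shape_features(image)
        deep = ft.deep_features(image, cfg.deep)
        fused = ft.fuse(phog_vec, shape, deep)
        self.layout = self.layout or fused.layout
        return fused.vector

    def raw_matrix(self, manifest: DatasetManifest) -> np.ndarray:
        return np.stack([self._one(rec.path) for rec in manifest])

    def fit_transform(self, manifest: DatasetManifest) -> np.ndarray:
        raw = self.raw_matrix(manifest)
        assert self.layout is not None
        self.standardizer.fit(raw, self.layout)
        return self.standardizer.transform(raw)

    def transform(self, manifest: DatasetManifest) -> np.ndarray:
        return self.standardizer.transform(self.raw_matrix(manifest))


def _to_maps(matrix: np.ndarray) -> np.ndarray:
    return np.stack([vector_to_map(v) for v in matrix])[:, None]  # N,1,S,S


def _labels_to_int(labels: np.ndarray) -> np.ndarray:
    return np.asarray([1 if lab == metrics.POSITIVE else 0 for lab in labels])


def fuse_scores(iln: np.ndarray, gnet: np.ndarray) -> np.ndarray:
    """Mean-score fusion of the two branches' per-class probabilities."""
    iln = np.asarray(iln, dtype=np.float64)
    gnet = np.asarray(gnet, dtype=np.float64)
    if iln.shape != gnet.shape:
        raise ValueError(f"score shapes differ: {iln.shape} vs {gnet.shape}")
    return (iln + gnet) / 2.0


def predictions_from_scores(scores: np.ndarray) -> list[str]:
    """Argmax over (healthy, patient) probability columns."""
    return [metrics.LABELS[i] for i in np.argmax(scores, axis=1)]


class HybridModel:
    """Trained Improved-LinkNet + GhostNet pair operating on feature maps."""

    def __init__(self, iln: ImprovedLinkNet, gnet: GhostNet, fusion: str = "probabilities"):
        self.iln = iln
        self.gnet = gnet
        self.fusion = fusion

    def branch_scores(self, maps: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        self.iln.eval()
        self.gnet.eval()
        x = nn.Tensor(maps)
        if self.fusion == "logits":
            return self.iln.logits(x).data, self.gnet.logits(x).data
        return self.iln(x), self.gnet(x)

    def scores(self, maps: np.ndarray) -> np.ndarray:
        iln_s, gnet_s = self.branch_scores(maps)
        fused = fuse_scores(iln_s, gnet_s)
        if self.fusion == "logits":
            fused = nn.softmax(fused)
        return fused

    def save(self, directory: str | Path) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        np.savez(directory / "iln.npz", **self.iln.state_arrays())
        np.savez(directory / "gnet.npz", **self.gnet.state_arrays())
        meta = {
            "fusion": self.fusion,
            "iln_seed": self.iln.spec.seed,
            "gnet_seed": self.gnet.spec.seed,
        }
        (directory / "model.json").write_text(json.dumps(meta))

    @classmethod
    def load(cls, directory: str | Path) -> "HybridModel":
        directory = Path(directory)
        meta = json.loads((directory / "model.json").read_text())
        iln = ImprovedLinkNet(LinkNetSpec(seed=meta["iln_seed"]))
        gnet = GhostNet(GhostNetSpec(seed=meta["gnet_seed"]))
        iln.load_state_arrays(dict(np.load(directory / "iln.npz")))
        gnet.load_state_arrays(dict(np.load(directory / "gnet.npz")))
        return cls(iln, gnet, meta["fusion"])


def _train_branch(
    model, maps: np.ndarray, y: np.ndarray, config: TrainConfig, rng: np.random.Generator
) -> list[float]:
    model.train()
    opt = nn.Adam(model.parameters(), lr=config.learning_rate)
    losses = []
    n = len(maps)
    for _epoch in range(config.epochs):
        order = rng.permutation(n)
        epoch_loss = 0.0
        for start in range(0, n, config.batch_size):
            idx = order[start : start + config.batch_size]
            if len(idx) < 2:
                continue  # batch statistics need >= 2 samples
            batch = nn.Tensor(maps[idx])
            loss = nn.cross_entropy(model.logits(batch), y[idx])
            if not np.isfinite(loss.data):
                raise RuntimeError("training diverged: non-finite loss")
            opt.zero_grad()
            loss.backward()
            opt.step()
            epoch_loss += float(loss.data) * len(idx)
        losses.append(epoch_loss / n)
    model.eval()
    return losses


def train_hybrid(
    train_matrix: np.ndarray,
    train_labels: np.ndarray,
    config: TrainConfig | None = None,
    linknet_spec: LinkNetSpec | None = None,
    ghostnet_spec: GhostNetSpec | None = None,
) -> tuple[HybridModel, dict[str, list[float]]]:
    """Train both branches independently on standardized fused features.

    Returns the hybrid model plus per-epoch mean training losses for each
    branch.  Fully reproducible from ``config.seed``.
    """
    config = config or TrainConfig()
    y = _labels_to_int(np.asarray(train_labels))
    if len(set(y.tolist())) < 2:
        raise ValueError("training needs both classes present")
    maps = _to_maps(train_matrix)
    iln = ImprovedLinkNet(linknet_spec or LinkNetSpec(seed=config.seed))
    gnet = GhostNet(ghostnet_spec or GhostNetSpec(seed=config.seed))
    rng_iln = np.random.default_rng(np.random.SeedSequence([config.seed, 11]))
    rng_gnet = np.random.default_rng(np.random.SeedSequence([config.seed, 12]))
    log = {
        "improved_linknet": _train_branch(iln, maps, y, config, rng_iln),
        "ghostnet": _train_branch(gnet, maps, y, config, rng_gnet),
    }
    return HybridModel(iln, gnet, config.fusion), log


def evaluate(
    model: HybridModel, test_matrix: np.ndarray, test_labels: np.ndarray
) -> dict:
    """Confusion matrix, metric report and ROC for the fused detector.

    The returned dict mirrors the reporting layout: keys ``accuracy`` ...
    ``fdr``, ``auc`` and ``confusion {tp, fp, fn, tn}``, plus per-branch
    accuracies under ``branches``.
    """
    if len(test_matrix) == 0:
        raise ValueError("empty test set")
    labels = list(test_labels)
    maps = _to_maps(test_matrix)
    iln_s, gnet_s = model.branch_scores(maps)
    fused = fuse_scores(iln_s, gnet_s)
    if model.fusion == "logits":
        fused = nn.softmax(fused)
        iln_s, gnet_s = nn.softmax(iln_s), nn.softmax(gnet_s)
    preds = predictions_from_scores(fused)
    cm = metrics.confusion(preds, labels)
    report = metrics.metrics(cm)
    curve = metrics.roc(fused[:, 1], labels)

    def _branch_acc(scores: np.ndarray) -> float:
        branch_cm = metrics.confusion(predictions_from_scores(scores), labels)
        return metrics.metrics(branch_cm).accuracy

    out = report.to_dict()
    out["auc"] = curve.auc
    out["confusion"] = {"tp": cm.tp, "fp": cm.fp, "fn": cm.fn, "tn": cm.tn}
    out["branches"] = {
        "improved_linknet_accuracy": _branch_acc(iln_s),
        "ghostnet_accuracy": _branch_acc(gnet_s),
    }
    return out


def write_report(report: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(report, indent=2))
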