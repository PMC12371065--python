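"""Forward-only VGG16 / ResNet-50 embedding extractors in numpy.

The detection pipeline consumes fixed deep embeddings - the backbones are
feature extractors truncated at global average pooling, never trained here.
Weights are He-normal draws from a configured seed by default, which keeps
the whole toolkit runnable offline and deterministic; trained weights can be
supplied as an ``.npz`` file (``weights_mode='pretrained-file'``), and a
missing file is an error rather than a silent fallback to random weights.

ResNet's normalization layers are realized as per-channel instance
normalization (spatial mean/variance of the sample at hand), which keeps
activation scales bounded through 50 layers regardless of the weight draw.
Computation is float32 and the conv loops are ``einsum`` over sliding
windows, so a 64x64 input embeds in well under a second per image.
"""

from __future__ import annotations

from functools import lru_cache

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = ["get_backbone", "VGG16", "ResNet50"]

_VGG_CFG = [64, 64, "M", 128, 128, "M", 256, 256, 256, "M", 512, 512, 512, "M", 512, 512, 512, "M"]
# stage definitions: (n_blocks, bottleneck width, stride of first block)
_RESNET_STAGES = [(3, 64, 1), (4, 128, 2), (6, 256, 2), (3, 512, 2)]
_EXPANSION = 4


def _conv(x: np.ndarray, w: np.ndarray, stride: int = 1, pad: int | None = None) -> np.ndarray:
    kh, kw = w.shape[2], w.shape[3]
    if pad is None:
        pad = kh // 2
    xp = np.pad(x, ((0, 0), (pad, pad), (pad, pad)))
    win = sliding_window_view(xp, (kh, kw), axis=(1, 2))[:, ::stride, ::stride]
    return np.einsum("chwij,kcij->khw", win, w, optimize=True)


def _relu(x: np.ndarray) -> np.ndarray:
    return np.maximum(x, 0.0, out=x)


def _maxpool2(x: np.ndarray) -> np.ndarray:
    c, h, w = x.shape
    h2, w2 = h - h % 2, w - w % 2
    return x[:, :h2, :w2].reshape(c, h2 // 2, 2, w2 // 2, 2).max(axis=(2, 4))


def _instance_norm(x: np.ndarray, eps: float = 1e-5) -> np.ndarray:
    mean = x.mean(axis=(1, 2), keepdims=True)
    var = x.var(axis=(1, 2), keepdims=True)
    return (x - mean) / np.sqrt(var + eps)


class _Backbone:
    name: str
    embedding_length: int

    def __init__(self, config) -> None:
        self.input_size = config.input_size
        if config.weights_mode == "pretrained-file":
            if config.weights_path is None:
                raise FileNotFoundError("pretrained-file mode requires weights_path")
            try:
                arrays = np.load(config.weights_path)
            except OSError as exc:
                raise FileNotFoundError(
                    f"cannot read backbone weights file {config.weights_path!r}"
                ) from exc
            self.weights = [np.asarray(arrays[k], dtype=np.float32) for k in arrays.files]
        else:
            rng = np.random.default_rng(np.random.SeedSequence([config.seed, self._tag]))
            self.weights = [
                (rng.normal(0.0, np.sqrt(2.0 / (s[1] * s[2] * s[3])), size=s)).astype(
                    np.float32
                )
                for s in self._weight_shapes()
            ]

    def _prepare(self, image: np.ndarray) -> np.ndarray:
        """Grayscale [0,255] -> (3, S, S) float32 in [0,1], bilinear resize."""
        img = np.asarray(image, dtype=np.float32)
        if img.ndim == 3:
            img = img.mean(axis=2)
        s = self.input_size
        if img.shape != (s, s):
            from skimage.transform import resize

            img = resize(img, (s, s), preserve_range=True, anti_aliasing=True).astype(
                np.float32
            )
        img = img / 255.0
        return np.repeat(img[None], 3, axis=0)

    def embed(self, image: np.ndarray) -> np.ndarray:
        maps = self._forward(self._prepare(image))
        return maps.mean(axis=(1, 2)).astype(np.float64)  # global average pooling


class VGG16(_Backbone):
    """13 convolutional 3x3 layers in five max-pooled blocks, GAP -> 512."""

    name = "vgg16"
    embedding_length = 512
    _tag = 16

    def _weight_shapes(self):
        shapes = []
        in_ch = 3
        for item in _VGG_CFG:
            if item == "M":
                continue
            shapes.append((item, in_ch, 3, 3))
            in_ch = item
        return shapes

    def _forward(self, x: np.ndarray) -> np.ndarray:
        wi = 0
        for item in _VGG_CFG:
            if item == "M":
                x = _maxpool2(x)
            else:
                x = _relu(_conv(x, self.weights[wi]))
                wi += 1
        return x


class ResNet50(_Backbone):
    """Bottleneck residual stages [3, 4, 6, 3], GAP -> 2048."""

    name = "resnet50"
    embedding_length = 2048
    _tag = 50

    def _weight_shapes(self):
        shapes = [(64, 3, 7, 7)]  # stem
        in_ch = 64
        for n_blocks, width, _stride in _RESNET_STAGES:
            out_ch = width * _EXPANSION
            for b in range(n_blocks):
                shapes.append((width, in_ch, 1, 1))
                shapes.append((width, width, 3, 3))
                shapes.append((out_ch, width, 1, 1))
                if b == 0:
                    shapes.append((out_ch, in_ch, 1, 1))  # projection shortcut
                in_ch = out_ch
        return shapes

    def _forward(self, x: np.ndarray) -> np.ndarray:
        wi = 0
        x = _relu(_instance_norm(_conv(x, self.weights[wi], stride=2, pad=3)))
        wi += 1
        x = _maxpool2(x)
        for n_blocks, _width, stride in _RESNET_STAGES:
            for b in range(n_blocks):
                s = stride if b == 0 else 1
                identity = x
                y = _relu(_instance_norm(_conv(x, self.weights[wi], stride=s, pad=0)))
                y = _relu(_instance_norm(_conv(y, self.weights[wi + 1], stride=1)))
                y = _instance_norm(_conv(y, self.weights[wi + 2], stride=1, pad=0))
                wi += 3
                if b == 0:
                    identity = _instance_norm(
                        _conv(x, self.weights[wi], stride=s, pad=0)
                    )
                    wi += 1
                x = _relu(y + identity)
        return x


@lru_cache(maxsize=8)
def _cached_backbone(name, input_size, weights_mode, weights_path, seed):
    from .features import DeepFeatureConfig

    config = DeepFeatureConfig(
        backbones=(name,),
        input_size=input_size,
        weights_mode=weights_mode,
        weights_path=weights_path,
        seed=seed,
    )
    return {"vgg16": VGG16, "resnet50": ResNet50}[name](config)


def get_backbone(name: str, config) -> _Backbone:
    """Backbone instance for a config; instances are cached by parameters."""
    return _cached_backbone(
        name, config.input_size, config.weights_mode, config.weights_path, config.seed
    )
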