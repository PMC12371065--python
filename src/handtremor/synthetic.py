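"""Synthetic spiral and meander drawings with a parametric tremor model.

Parkinsonian drawings differ from healthy ones mainly through tremor
(oscillatory deviation from the intended trace) and micrographia (progressive
shrinking of the stroke).  This module renders Archimedean spirals
``r(theta) = a + b*theta`` and square-wave meanders, perturbs them with a
sinusoidal tremor plus a random walk, optionally shrinks the trace turn by
turn, rasterizes to 8-bit grayscale, and can inject Gaussian and impulse
noise.  It exists so that every downstream stage (filtering, features,
classifiers) is testable without the external HandPD archives.

All randomness descends from a single integer seed through
``numpy.random.SeedSequence`` spawning, so individual drawings are
reproducible independently of generation order.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import imageio.v3 as iio
import numpy as np
from scipy import ndimage
from skimage.draw import disk

from .data_io import DatasetManifest, SampleRecord

__all__ = [
    "DrawingSpec",
    "TremorModel",
    "NoiseSpec",
    "generate_path",
    "render",
    "inject_noise",
    "generate_dataset",
    "mean_radial_deviation",
]


@dataclass(frozen=True)
class DrawingSpec:
    """Geometry of the pen trace to draw.

    For spirals the polar radius is ``r(theta) = a + b*theta``; when ``b`` is
    None it is chosen so the full trace fits the canvas with a small margin.
    Meanders are square waves of ``segment_count`` alternating
    horizontal/vertical strokes whose vertical extent shrinks along the path.
    """

    pattern: str = "spiral"
    image_size: int = 96
    turns: float = 3.0
    segment_count: int = 9
    stroke_width: float = 2.0
    a: float = 0.0
    b: float | None = None
    points_per_turn: int = 720

    def __post_init__(self) -> None:
        if self.pattern not in ("spiral", "meander"):
            raise ValueError("pattern must be 'spiral' or 'meander'")
        if self.image_size < 64:
            raise ValueError("image_size must be >= 64")

    @property
    def spiral_b(self) -> float:
        if self.b is not None:
            return self.b
        margin = 0.12 * self.image_size
        return (self.image_size / 2.0 - margin - self.a) / (self.turns * 2 * np.pi)


@dataclass(frozen=True)
class TremorModel:
    """Radial perturbation of the trace.

    ``amplitude`` (px) scales a sinusoid completing ``frequency`` cycles per
    turn of the trace; ``jitter_sd`` adds a seeded random walk (per-step
    standard deviation, px); ``micrographia_decay`` in (0, 1] multiplies the
    base radius by ``decay**(theta / 2pi)`` - a value of 1 means no shrink.
    """

    amplitude: float = 0.0
    frequency: float = 12.0
    phase: float = 0.0
    jitter_sd: float = 0.0
    micrographia_decay: float = 1.0

    def __post_init__(self) -> None:
        if self.amplitude < 0:
            raise ValueError("amplitude must be >= 0")
        if not 0.0 < self.micrographia_decay <= 1.0:
            raise ValueError("micrographia_decay must lie in (0, 1]")


#: default class conditions: healthy low tremor, patient strong tremor with shrink
HEALTHY_TREMOR = TremorModel(amplitude=1.0, frequency=12.0, jitter_sd=0.05)
PATIENT_TREMOR = TremorModel(
    amplitude=6.0, frequency=12.0, jitter_sd=0.15, micrographia_decay=0.93
)


@dataclass(frozen=True)
class NoiseSpec:
    gaussian_sd: float = 0.0
    impulse_density: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.gaussian_sd < 0 or not 0.0 <= self.impulse_density <= 1.0:
            raise ValueError("invalid noise parameters")


def _tremor_offsets(
    tremor: TremorModel, t_turns: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """Perturbation at each sample: sinusoid in 'cycles per turn' + random walk."""
    wave = tremor.amplitude * np.sin(2 * np.pi * tremor.frequency * t_turns + tremor.phase)
    if tremor.jitter_sd > 0:
        walk = np.cumsum(rng.normal(0.0, tremor.jitter_sd, size=t_turns.shape))
    else:
        walk = 0.0
    return wave + walk


def _spiral_path(
    spec: DrawingSpec, tremor: TremorModel, rng: np.random.Generator
) -> np.ndarray:
    n = max(int(spec.points_per_turn * spec.turns), 2)
    theta = np.linspace(0.0, spec.turns * 2 * np.pi, n)
    t_turns = theta / (2 * np.pi)
    base_r = (spec.a + spec.spiral_b * theta) * tremor.micrographia_decay**t_turns
    r = base_r + _tremor_offsets(tremor, t_turns, rng)
    cx = cy = spec.image_size / 2.0
    return np.column_stack([cy + r * np.sin(theta), cx + r * np.cos(theta)])


def _meander_skeleton(spec: DrawingSpec) -> np.ndarray:
    """Vertices of a square-wave path spanning the canvas width."""
    margin = 0.12 * spec.image_size
    width = spec.image_size - 2 * margin
    n_seg = max(int(spec.segment_count), 1)
    xs = np.linspace(margin, margin + width, n_seg + 1)
    half = width / 2.0
    cy = spec.image_size / 2.0
    pts = []
    for i, x in enumerate(xs):
        # vertical extent decreases along the path (micrographia-like layout)
        extent = half * (1.0 - 0.5 * i / max(n_seg, 1))
        y_top, y_bot = cy - extent, cy + extent
        if i % 2 == 0:
            pts.extend([(y_top, x), (y_bot, x)])
        else:
            pts.extend([(y_bot, x), (y_top, x)])
    return np.asarray(pts, dtype=float)


def _resample_polyline(vertices: np.ndarray, n: int) -> tuple[np.ndarray, np.ndarray]:
    """Evenly resample a polyline; returns points and unit normals."""
    seg = np.diff(vertices, axis=0)
    seg_len = np.hypot(seg[:, 0], seg[:, 1])
    s = np.concatenate([[0.0], np.cumsum(seg_len)])
    total = s[-1]
    u = np.linspace(0.0, total, n)
    y = np.interp(u, s, vertices[:, 0])
    x = np.interp(u, s, vertices[:, 1])
    pts = np.column_stack([y, x])
    d = np.gradient(pts, axis=0)
    norm = np.hypot(d[:, 0], d[:, 1])
    norm[norm == 0] = 1.0
    tangent = d / norm[:, None]
    normals = np.column_stack([-tangent[:, 1], tangent[:, 0]])
    return pts, normals


def _meander_path(
    spec: DrawingSpec, tremor: TremorModel, rng: np.random.Generator
) -> np.ndarray:
    vertices = _meander_skeleton(spec)
    n = max(int(spec.points_per_turn * spec.segment_count / 3), 2)
    pts, normals = _resample_polyline(vertices, n)
    # treat one square-wave period (2 segments) as one "turn"
    t_turns = np.linspace(0.0, spec.segment_count / 2.0, n)
    offsets = _tremor_offsets(tremor, t_turns, rng)
    scale = tremor.micrographia_decay ** t_turns
    centre = np.array([spec.image_size / 2.0, spec.image_size / 2.0])
    pts = centre + (pts - centre) * scale[:, None]
    return pts + normals * offsets[:, None]


def generate_path(
    spec: DrawingSpec, tremor: TremorModel, seed: int | np.random.SeedSequence = 0
) -> np.ndarray:
    """Ordered (row, col) points of the perturbed trace.

    With zero amplitude, zero jitter and decay 1 the points lie exactly on the
    ideal curve; identical seeds give identical paths.
    """
    rng = np.random.default_rng(seed)
    if spec.pattern == "spiral":
        return _spiral_path(spec, tremor, rng)
    return _meander_path(spec, tremor, rng)


def render(path: np.ndarray, spec: DrawingSpec) -> np.ndarray:
    """Rasterize a path as a dark stroke on white, values in [0, 255].

    The stroke is drawn by stamping anti-aliased disks of radius
    ``stroke_width / 2`` along the (densely sampled) path; points outside the
    canvas are clipped with a warning.
    """
    if len(path) == 0:
        raise ValueError("cannot render an empty path")
    size = spec.image_size
    canvas = np.zeros((size, size), dtype=np.float64)  # ink density
    pts = np.asarray(path, dtype=float)
    if (pts < -0.5).any() or (pts > size - 0.5).any():
        import warnings

        warnings.warn("path extends outside the canvas; clipping", stacklevel=2)
        pts = np.clip(pts, 0.0, size - 1.0)
    radius = max(spec.stroke_width / 2.0, 0.6)
    core = np.zeros(canvas.shape, dtype=bool)
    for y, x in pts:
        rr, cc = disk((y, x), radius, shape=canvas.shape)
        core[rr, cc] = True
    # soft 1-px halo around the core for a light anti-aliased edge
    halo = ndimage.binary_dilation(core, structure=np.ones((3, 3))) & ~core
    canvas[core] = 1.0
    canvas[halo] = 0.45
    return np.clip(255.0 * (1.0 - canvas), 0.0, 255.0)


def inject_noise(image: np.ndarray, noise: NoiseSpec) -> np.ndarray:
    """Add seeded Gaussian noise, then flip a fraction of pixels to 0/255."""
    rng = np.random.default_rng(noise.seed)
    out = np.asarray(image, dtype=np.float64).copy()
    if noise.gaussian_sd > 0:
        out += rng.normal(0.0, noise.gaussian_sd, size=out.shape)
    if noise.impulse_density > 0:
        mask = rng.random(out.shape) < noise.impulse_density
        out[mask] = np.where(rng.random(out.shape) < 0.5, 0.0, 255.0)[mask]
    return np.clip(out, 0.0, 255.0)


def mean_radial_deviation(
    spec: DrawingSpec, tremor: TremorModel, seed: int | np.random.SeedSequence = 0
) -> float:
    """Mean |perturbed - ideal| distance along the trace, in pixels.

    Computed analytically from the path model (not the raster); used as the
    single-feature logistic baseline against which the full pipeline is
    compared.
    """
    ideal = generate_path(spec, TremorModel(), 0)
    actual = generate_path(spec, tremor, seed)
    n = min(len(ideal), len(actual))
    return float(np.mean(np.hypot(*(actual[:n] - ideal[:n]).T)))


def generate_dataset(
    out_dir: str | Path,
    n_per_class: int = 50,
    healthy_tremor: TremorModel = HEALTHY_TREMOR,
    patient_tremor: TremorModel = PATIENT_TREMOR,
    specs: tuple[DrawingSpec, ...] = (
        DrawingSpec(pattern="spiral"),
        DrawingSpec(pattern="meander"),
    ),
    seed: int = 0,
    noise: NoiseSpec | None = None,
) -> tuple[DatasetManifest, dict[str, float]]:
    """Write a balanced labelled synthetic dataset to ``out_dir``.

    Returns the manifest plus a per-image mean-radial-deviation statistic
    (keyed by image path).  Drawings cycle through ``specs``; each image gets
    an independent seed spawned from ``seed``.
    """
    if n_per_class <= 0:
        raise ValueError("n_per_class must be positive")
    if patient_tremor.amplitude <= healthy_tremor.amplitude:
        raise ValueError("patient tremor amplitude must exceed healthy amplitude")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    root_ss = np.random.SeedSequence(seed)
    records: list[SampleRecord] = []
    deviations: dict[str, float] = {}
    for label, tremor in (("healthy", healthy_tremor), ("patient", patient_tremor)):
        cls_dir = out_dir / label
        cls_dir.mkdir(exist_ok=True)
        for i in range(n_per_class):
            spec = specs[i % len(specs)]
            ss = root_ss.spawn(1)[0]
            path_pts = generate_path(spec, tremor, ss)
            image = render(path_pts, spec)
            if noise is not None:
                child = np.random.default_rng(ss).integers(2**31 - 1)
                image = inject_noise(
                    image,
                    NoiseSpec(noise.gaussian_sd, noise.impulse_density, int(child)),
                )
            exam_id = i + (0 if label == "healthy" else n_per_class)
            fname = cls_dir / f"{exam_id}-1_{spec.pattern}.png"
            iio.imwrite(fname, image.astype(np.uint8))
            records.append(
                SampleRecord(
                    exam_id=exam_id,
                    image_id=1,
                    pattern=spec.pattern,
                    label=label,
                    path=str(fname),
                )
            )
            deviations[str(fname)] = mean_radial_deviation(spec, tremor, ss)
    manifest = DatasetManifest(records)
    manifest.write_csv(out_dir / "manifest.csv")
    return manifest, deviations
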