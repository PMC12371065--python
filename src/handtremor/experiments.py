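"""Canned study procedures: filter comparison and the scaled-down detection run.

These functions bundle the pipeline stages into the two experiments the
package uses to characterize itself: a denoiser comparison (mean PSNR/SSIM of
the modified Wiener filter against the conventional Wiener filter and the
noisy input over a batch of synthetic drawings) and the end-to-end
scaled-down detection experiment (balanced synthetic dataset, feature
extraction, independent training of both classifier branches, mean-score
fusion, held-out evaluation, plus a one-feature logistic baseline on mean
radial deviation).
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
from sklearn.linear_model import LogisticRegression

from . import filters, pipeline, synthetic
from .data_io import DatasetManifest, SplitSpec, split

__all__ = ["filter_comparison", "scaled_down_detection"]


def filter_comparison(
    n_images: int = 100,
    gaussian_sd: float = 15.0,
    seed: int = 0,
    image_size: int = 96,
) -> dict[str, float]:
    """Mean PSNR/SSIM of each denoiser over synthetic noisy drawings.

    Each drawing alternates spiral/meander and healthy/patient tremor; noise
    is Gaussian with the given standard deviation.  Returns mean PSNR (dB)
    and SSIM for the noisy input, the conventional Wiener filter and the
    modified Wiener filter against the clean renders.
    """
    root_ss = np.random.SeedSequence(seed)
    sums: dict[str, list[float]] = {
        "psnr_noisy": [], "psnr_conventional": [], "psnr_modified": [],
        "ssim_noisy": [], "ssim_conventional": [], "ssim_modified": [],
    }
    for i in range(n_images):
        ss = root_ss.spawn(1)[0]
        spec = synthetic.DrawingSpec(
            pattern="spiral" if i % 2 == 0 else "meander", image_size=image_size
        )
        tremor = synthetic.PATIENT_TREMOR if i % 4 < 2 else synthetic.HEALTHY_TREMOR
        clean = synthetic.render(synthetic.generate_path(spec, tremor, ss), spec)
        noise_seed = int(np.random.default_rng(ss.spawn(1)[0]).integers(2**31 - 1))
        noisy = synthetic.inject_noise(
            clean, synthetic.NoiseSpec(gaussian_sd=gaussian_sd, seed=noise_seed)
        )
        conv = filters.conventional_wiener(noisy)
        mod = filters.modified_wiener(noisy)
        for name, img in (("noisy", noisy), ("conventional", conv), ("modified", mod)):
            sums[f"psnr_{name}"].append(filters.psnr(clean, img))
            sums[f"ssim_{name}"].append(filters.ssim(clean, img))
    return {k: float(np.mean(v)) for k, v in sums.items()}


def scaled_down_detection(
    work_dir: str | Path,
    n_per_class: int = 200,
    epochs: int = 20,
    train_fraction: float = 0.8,
    seed: int = 0,
) -> dict:
    """End-to-end synthetic detection experiment at desk scale.

    Generates ``2 * n_per_class`` drawings at the default class effect sizes,
    splits stratified, extracts fused features (modified Wiener -> modified
    PHOG + shape + deep), trains both branches, and reports the fused
    held-out metrics together with the per-branch accuracies and the
    mean-radial-deviation logistic baseline.
    """
    work_dir = Path(work_dir)
    manifest, deviations = synthetic.generate_dataset(
        work_dir / "data", n_per_class=n_per_class, seed=seed
    )
    train_man, test_man = split(
        manifest, SplitSpec(train_fraction=train_fraction, seed=seed)
    )
    extractor = pipeline.FeatureExtractor()
    x_train = extractor.fit_transform(train_man)
    x_test = extractor.transform(test_man)
    config = pipeline.TrainConfig(epochs=epochs, seed=seed)
    model, log = pipeline.train_hybrid(x_train, train_man.labels(), config)
    report = pipeline.evaluate(model, x_test, test_man.labels())
    report["training_log"] = log
    report["n_train"] = len(train_man)
    report["n_test"] = len(test_man)
    report["baseline_accuracy"] = _deviation_baseline(
        train_man, test_man, deviations
    )
    return report


def _deviation_baseline(
    train_man: DatasetManifest, test_man: DatasetManifest, deviations: dict[str, float]
) -> float:
    """Accuracy of a logistic fit on the mean-radial-deviation statistic."""
    def xy(man):
        x = np.array([deviations[r.path] for r in man])[:, None]
        y = np.array([r.label == "patient" for r in man], dtype=int)
        return x, y

    x_train, y_train = xy(train_man)
    x_test, y_test = xy(test_man)
    model = LogisticRegression().fit(x_train, y_train)
    return float(model.score(x_test, y_test))
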