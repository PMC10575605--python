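"""Image-quality metrics and display conventions for reconstructed maps.

RMSE measures the quantitative pixelwise difference between a reconstruction
and its model; SSIM (structural similarity, Gaussian sliding window) measures
the perceptual/structural agreement.  Metrics are always computed on the raw
maps; :func:`clip_for_display` is a figure-only convention (0 to 1.5x the model
maximum) and never feeds back into the metrics.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from skimage.metrics import structural_similarity

__all__ = ["MetricsReport", "rmse", "ssim", "clip_for_display", "evaluate_maps"]

#: SSIM parameters used throughout (recorded in every report): 7x7 Gaussian
#: window with sigma 1.5 and the standard stabilization constants, data range
#: set by the model maximum.
SSIM_PARAMS = {"win_size": 7, "gaussian_weights": True, "sigma": 1.5,
               "use_sample_covariance": False, "K1": 0.01, "K2": 0.03}


def rmse(image, model) -> float:
    """Root of the mean squared pixel difference (NaNs excluded pairwise)."""
    image = np.asarray(image, float)
    model = np.asarray(model, float)
    if image.shape != model.shape:
        raise ValueError(f"shape mismatch {image.shape} vs {model.shape}")
    d = image - model
    return float(np.sqrt(np.nanmean(d * d)))


def ssim(image, model, data_range: float | None = None) -> float:
    """Structural similarity of ``image`` against the ``model`` reference."""
    image = np.asarray(image, float)
    model = np.asarray(model, float)
    if image.shape != model.shape:
        raise ValueError(f"shape mismatch {image.shape} vs {model.shape}")
    if data_range is None:
        data_range = float(model.max() - min(model.min(), 0.0))
        if data_range <= 0:
            raise ValueError("degenerate model: cannot infer data range")
    return float(structural_similarity(model, image, data_range=data_range,
                                       **SSIM_PARAMS))


def clip_for_display(image, model) -> np.ndarray:
    """Clip to [0, 1.5 * max(model)] for figures (not for metrics)."""
    model = np.asarray(model, float)
    peak = float(model.max())
    if peak <= 0:
        raise ValueError("degenerate model: nonpositive maximum")
    return np.clip(np.asarray(image, float), 0.0, 1.5 * peak)


@dataclass
class MetricsReport:
    """Per-quantity RMSE/SSIM with full provenance of the comparison."""

    per_quantity: dict = field(default_factory=dict)  # name -> {"rmse", "ssim"}
    clip_range: dict = field(default_factory=dict)
    provenance: dict = field(default_factory=dict)  # lambda, beta, delta_d, N...
    ssim_params: dict = field(default_factory=lambda: dict(SSIM_PARAMS))

    def to_json(self, path) -> None:
        import json

        with open(path, "w") as fh:
            json.dump(
                {"per_quantity": self.per_quantity, "clip_range": self.clip_range,
                 "provenance": self.provenance, "ssim_params": self.ssim_params},
                fh, indent=2,
            )

    def to_csv(self, path) -> None:
        import csv

        with open(path, "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["quantity", "rmse", "ssim"])
            for name, vals in self.per_quantity.items():
                w.writerow([name, vals["rmse"], vals["ssim"]])


def evaluate_maps(result, models: dict, provenance: dict | None = None,
                  mask=None) -> MetricsReport:
    """RMSE/SSIM of every reconstructed map against its ground-truth model.

    ``models`` maps quantity names ("mu_plus", "mu_e", "n_normalized", ...) to
    model arrays; ``mask`` optionally restricts the comparison (masked-out
    pixels are replaced by the model value, i.e. contribute zero error).
    """
    report = MetricsReport(provenance=provenance or {})
    for name, model in models.items():
        img = getattr(result, name, None)
        if img is None:
            continue
        img = np.asarray(img, float)
        if mask is not None:
            img = np.where(mask, img, model)
        img = np.where(np.isfinite(img), img, np.asarray(model, float))
        report.per_quantity[name] = {
            "rmse": rmse(img, model),
            "ssim": ssim(img, model),
        }
        report.clip_range[name] = [0.0, 1.5 * float(np.max(model))]
    return report
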