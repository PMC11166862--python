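"""Conventional and effective CNR assembly.

Conventional CNR divides the signal-background HU difference by the pixel
SD of the background — blind to noise texture and edge blur. The effective
CNR replaces both pieces with their perception-oriented counterparts:

    effective CNR = |C0 * sharpness index| / sigma_Apparent,

i.e. the fitted contrast penalized by edge blur, divided by the
texture-aware apparent noise. :func:`analyze` runs the full chain
(apparent noise on a noise ROI, radial profile extraction and edge-model
fit on a signal image) and assembles a :class:`CNRReport`.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from typing import Any

import numpy as np

from .apparent_noise import (
    ApparentNoiseResult,
    SquareROI,
    fit_apparent_noise,
    noise_curve,
)
from .edge_profile import RadialConfig, estimate_center, extract_radial_profile
from .grid import ImageGrid
from .sde_model import SDEFit, fit_edge_model, sharpness_index

__all__ = [
    "CNRReport",
    "StageError",
    "roi_stats",
    "conventional_cnr",
    "effective_cnr",
    "analyze",
]


class StageError(RuntimeError):
    """An analysis stage failed; ``stage`` names the failing component."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


@dataclass
class CNRReport:
    """All components of a conventional + effective CNR analysis."""

    p_signal: float
    p_background: float
    noise_sd: float
    conventional_cnr: float
    sigma_apparent: float
    c0: float
    sharpness_index: float
    effective_contrast: float
    effective_cnr: float
    provenance: dict[str, Any] = field(default_factory=dict)

    def to_dict(self) -> dict[str, Any]:
        return asdict(self)

    def to_json(self, path=None, indent: int = 1) -> str:
        text = json.dumps(self.to_dict(), indent=indent)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text


def roi_stats(image: ImageGrid | np.ndarray, roi: SquareROI) -> tuple[float, float]:
    """Sample mean and sample SD (n-1 denominator) of the ROI pixels."""
    pixels = roi.extract(image)
    return float(pixels.mean()), float(pixels.std(ddof=1))


def conventional_cnr(p_signal: float, p_background: float, noise_sd: float) -> float:
    """(P_signal - P_background) / Noise SD; signed."""
    if noise_sd <= 0:
        raise ValueError(f"noise_sd must be > 0, got {noise_sd}")
    return (p_signal - p_background) / noise_sd


def effective_cnr(effective_contrast: float, sigma_apparent: float) -> float:
    """|effective contrast| / sigma_Apparent; non-negative by construction."""
    if sigma_apparent <= 0:
        raise ValueError(f"sigma_apparent must be > 0, got {sigma_apparent}")
    return abs(effective_contrast) / sigma_apparent


def _config_hash(payload: dict[str, Any]) -> str:
    blob = json.dumps(payload, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


def analyze(
    noise_image: ImageGrid | np.ndarray,
    signal_image: ImageGrid | np.ndarray,
    noise_roi: SquareROI | None = None,
    center: tuple[float, float] | None = None,
    radial_config: RadialConfig = RadialConfig(),
    signal_roi: SquareROI | None = None,
    hu_threshold: float | None = None,
) -> CNRReport:
    """Run the full effective-CNR analysis and assemble a report.

    Parameters
    ----------
    noise_image
        Uniform-region image for noise measurement (may be the signal image
        itself if it has a large uniform background).
    signal_image
        Image containing the circular signal insert.
    noise_roi
        Square ROI for noise; defaults to a 40x40 ROI at the noise-image
        center.
    center
        Sub-pixel signal center; estimated from ``signal_image`` via the
        weighted centroid when omitted.
    radial_config
        Ray-casting configuration for the edge profile.
    signal_roi
        ROI for the conventional P_signal; defaults to a small square
        (half the insert transition-free core is unknown here, so a
        10x10 ROI at the signal center is used).
    hu_threshold
        Threshold for center estimation; defaults to midway between the
        signal image's median (background-dominated) and maximum.
    """
    noise_pixels = noise_image.pixels if isinstance(noise_image, ImageGrid) else np.asarray(noise_image, dtype=float)
    if noise_roi is None:
        noise_roi = SquareROI.centered(noise_pixels)

    # --- noise branch ---
    try:
        p_background, noise_sd = roi_stats(noise_pixels, noise_roi)
        curve = noise_curve(noise_roi.extract(noise_pixels))
        apparent: ApparentNoiseResult = fit_apparent_noise(curve)
    except Exception as exc:
        raise StageError("apparent_noise", str(exc)) from exc

    # --- signal branch ---
    signal_pixels = signal_image.pixels if isinstance(signal_image, ImageGrid) else np.asarray(signal_image, dtype=float)
    try:
        if center is None:
            if hu_threshold is None:
                hu_threshold = float(
                    (np.median(signal_pixels) + signal_pixels.max()) / 2
                )
            center = estimate_center(signal_pixels, hu_threshold)
        profile = extract_radial_profile(signal_pixels, center, radial_config)
    except StageError:
        raise
    except Exception as exc:
        raise StageError("edge_profile", str(exc)) from exc

    try:
        fit: SDEFit = fit_edge_model(profile)
        sharp = sharpness_index(fit.params)
    except Exception as exc:
        raise StageError("sde_edge_model", str(exc)) from exc

    if signal_roi is None:
        signal_roi = SquareROI(center, side=10)
    try:
        p_signal, _ = roi_stats(signal_pixels, signal_roi)
    except Exception as exc:
        raise StageError("cnr_pipeline", str(exc)) from exc

    eff_contrast = fit.params.c0 * sharp.sharpness_index
    report = CNRReport(
        p_signal=p_signal,
        p_background=p_background,
        noise_sd=noise_sd,
        conventional_cnr=conventional_cnr(p_signal, p_background, noise_sd),
        sigma_apparent=apparent.sigma_apparent,
        c0=fit.params.c0,
        sharpness_index=sharp.sharpness_index,
        effective_contrast=eff_contrast,
        effective_cnr=effective_cnr(eff_contrast, apparent.sigma_apparent),
        provenance={
            "noise_source": getattr(noise_image, "source_id", ""),
            "signal_source": getattr(signal_image, "source_id", ""),
            "center": [float(center[0]), float(center[1])],
            "fit_converged": fit.converged,
            "fit_rmse_hu": fit.rmse_hu,
            "free_slope": apparent.free_slope,
            "config_hash": _config_hash(
                {
                    "noise_roi": asdict(noise_roi),
                    "radial": asdict(radial_config),
                    "signal_roi": asdict(signal_roi),
                }
            ),
        },
    )
    return report
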