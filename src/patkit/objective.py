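"""Composite training loss (MAE + Fourier-MAE) and image-quality metrics.

The network is trained with

    L = k1 * L_MAE + k2 * L_FMAE,        k1 = 1,  k2 = 0.001

where ``L_MAE`` is the mean absolute pixel difference between ground truth
``Yg`` and prediction ``Yp``, and ``L_FMAE`` is the mean (over frequency
bins) of the complex modulus of the difference of their unnormalized 2D
discrete Fourier transforms.  The Fourier term penalizes the structured,
directional streak artifacts of sparse-view reconstructions, which
concentrate in frequency space; its small weight keeps the pixel-wise MAE
the primary objective.

Evaluation mirrors the cross-validated comparison of restored images:
pixelwise Pearson correlation (PCC), SSIM (7-pixel window, data range 1),
PSNR (data range 1, capped at 100 dB for identical images) and MAE,
reported as mean +/- std over a test set.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from skimage.metrics import structural_similarity

__all__ = [
    "LossWeights",
    "MetricsReport",
    "mae_loss",
    "fmae_loss",
    "composite_loss",
    "mae_grad",
    "fmae_grad",
    "composite_grad",
    "pcc",
    "psnr",
    "evaluate",
    "PSNR_CAP_DB",
]

#: PSNR reported for identical images instead of infinity, dB
PSNR_CAP_DB = 100.0


@dataclass(frozen=True)
class LossWeights:
    k1: float = 1.0
    k2: float = 0.001

    def __post_init__(self) -> None:
        if self.k1 < 0 or self.k2 < 0:
            raise ValueError("loss weights must be non-negative")


def _check_shapes(yg: np.ndarray, yp: np.ndarray) -> None:
    if yg.shape != yp.shape:
        raise ValueError(f"shape mismatch: {yg.shape} vs {yp.shape}")


def mae_loss(yg: np.ndarray, yp: np.ndarray) -> float:
    """Mean absolute pixel difference."""
    _check_shapes(yg, yp)
    return float(np.mean(np.abs(yg - yp)))


def fmae_loss(yg: np.ndarray, yp: np.ndarray) -> float:
    """Mean absolute difference of unnormalized 2D DFTs (complex modulus)."""
    _check_shapes(yg, yp)
    return float(np.mean(np.abs(np.fft.fft2(yg) - np.fft.fft2(yp))))


def composite_loss(yg: np.ndarray, yp: np.ndarray, weights: LossWeights = LossWeights()) -> float:
    return weights.k1 * mae_loss(yg, yp) + weights.k2 * fmae_loss(yg, yp)


def mae_grad(yg: np.ndarray, yp: np.ndarray) -> np.ndarray:
    """Gradient of :func:`mae_loss` with respect to the prediction."""
    _check_shapes(yg, yp)
    return np.sign(yp - yg) / yg.size


def fmae_grad(yg: np.ndarray, yp: np.ndarray) -> np.ndarray:
    """Gradient of :func:`fmae_loss` with respect to the prediction.

    With D = F(Yg) - F(Yp), d|D|/dYp back-propagates through the linear DFT:
    the gradient is -Re{ F(conj(D)/|D|) } / N, with zero contribution from
    bins where the spectra already agree.
    """
    _check_shapes(yg, yp)
    d = np.fft.fft2(yg) - np.fft.fft2(yp)
    mag = np.abs(d)
    u = np.zeros_like(d)
    nz = mag > 0
    u[nz] = np.conj(d[nz]) / mag[nz]
    return -np.real(np.fft.fft2(u)) / yg.size


def composite_grad(
    yg: np.ndarray, yp: np.ndarray, weights: LossWeights = LossWeights()
) -> np.ndarray:
    g = weights.k1 * mae_grad(yg, yp)
    if weights.k2 != 0.0:
        g = g + weights.k2 * fmae_grad(yg, yp)
    return g


def pcc(yg: np.ndarray, yp: np.ndarray) -> float:
    """Pixelwise Pearson correlation coefficient; NaN for constant images."""
    _check_shapes(yg, yp)
    a = yg.ravel().astype(np.float64)
    b = yp.ravel().astype(np.float64)
    if a.std() == 0.0 or b.std() == 0.0:
        return float("nan")
    return float(np.corrcoef(a, b)[0, 1])


def psnr(yg: np.ndarray, yp: np.ndarray, data_range: float = 1.0) -> float:
    """Peak signal-to-noise ratio in dB, capped at :data:`PSNR_CAP_DB`."""
    _check_shapes(yg, yp)
    mse = float(np.mean((yg.astype(np.float64) - yp.astype(np.float64)) ** 2))
    if mse == 0.0:
        return PSNR_CAP_DB
    return min(PSNR_CAP_DB, 10.0 * np.log10(data_range**2 / mse))


@dataclass
class MetricsReport:
    """Mean +/- std of PCC / SSIM / PSNR / MAE over a set of image pairs."""

    pcc_mean: float
    pcc_std: float
    ssim_mean: float
    ssim_std: float
    psnr_mean: float
    psnr_std: float
    mae_mean: float
    mae_std: float
    n: int
    n_pcc_excluded: int = 0
    per_image: dict = field(default_factory=dict, repr=False)

    def row(self, label: str) -> str:
        return (
            f"{label}\t{self.pcc_mean:.2f} ± {self.pcc_std:.2f}"
            f"\t{self.psnr_mean:.2f} ± {self.psnr_std:.2f}"
            f"\t{self.ssim_mean:.2f} ± {self.ssim_std:.2f}"
            f"\t{self.mae_mean:.3f} ± {self.mae_std:.3f}"
        )

    def to_dict(self) -> dict:
        return {
            k: getattr(self, k)
            for k in (
                "pcc_mean", "pcc_std", "ssim_mean", "ssim_std",
                "psnr_mean", "psnr_std", "mae_mean", "mae_std",
                "n", "n_pcc_excluded",
            )
        }


def evaluate(yg_set: np.ndarray, yp_set: np.ndarray) -> MetricsReport:
    """Per-image metrics over paired sets of [0, 1]-normalized images.

    Images with undefined correlation (constant ground truth or prediction)
    are excluded from the PCC mean with a warning; all other metrics still
    include them.
    """
    yg_set = np.asarray(yg_set, dtype=np.float64)
    yp_set = np.asarray(yp_set, dtype=np.float64)
    if yg_set.shape != yp_set.shape or yg_set.ndim != 3:
        raise ValueError("expect paired image stacks of shape (n, H, W)")
    pccs, ssims, psnrs, maes = [], [], [], []
    for yg, yp in zip(yg_set, yp_set):
        pccs.append(pcc(yg, yp))
        ssims.append(structural_similarity(yg, yp, data_range=1.0, win_size=7))
        psnrs.append(psnr(yg, yp))
        maes.append(mae_loss(yg, yp))
    pccs = np.array(pccs)
    bad = np.isnan(pccs)
    if bad.any():
        warnings.warn(f"{int(bad.sum())} image(s) had undefined PCC and were excluded")
    good = pccs[~bad]
    return MetricsReport(
        pcc_mean=float(good.mean()) if good.size else float("nan"),
        pcc_std=float(good.std()) if good.size else float("nan"),
        ssim_mean=float(np.mean(ssims)),
        ssim_std=float(np.std(ssims)),
        psnr_mean=float(np.mean(psnrs)),
        psnr_std=float(np.std(psnrs)),
        mae_mean=float(np.mean(maes)),
        mae_std=float(np.std(maes)),
        n=len(yg_set),
        n_pcc_excluded=int(bad.sum()),
        per_image={"pcc": pccs, "ssim": np.array(ssims), "psnr": np.array(psnrs), "mae": np.array(maes)},
    )
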