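"""Two-term task-based loss with Gaussian domain conversion and total variation.

The loss blends two objectives through the anatomical weight masks: a sharp
term that keeps the output faithful to the routine-dose sharp-kernel target
in bone/air, and a smooth term that compares a Gaussian-blurred copy of the
output (the "domain conversion" C(z, sigma)) with the routine-dose
smooth-kernel target inside the brain, plus a small per-pixel total-variation
penalty:

    L_sharp  = alpha * mean( D_sharp * (z - x_sharp)^2 )
    L_smooth = beta  * mean( D_smooth * [ (C(z, sigma) - x_smooth)^2 + gamma * TV(z) ] )

Both terms are means of per-pixel weighted squared differences (the weighted
L2 norm realized with standard MSE scaling so alpha/beta transfer across
patch sizes). Blurring the output before the smooth comparison lets z stay
sharper than the smooth target while matching its low-frequency content; TV
is weighted by D_smooth so smoothness is never demanded in bone. The weight
masks are treated as constants (no gradient flows through thresholding).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .masks import WeightMask

__all__ = ["LossParams", "LossBreakdown", "gaussian_convolve",
           "total_variation_map", "task_loss"]

#: default pixel spacing (250 mm field of view on a 512 grid)
DEFAULT_SPACING_MM = 250.0 / 512.0


@dataclass
class LossParams:
    """Scalars of the task-based loss.

    alpha / beta weight the sharp and smooth terms, gamma the TV penalty
    inside the smooth term, sigma_mm the domain-conversion blur width
    (converted to pixels via the pixel spacing).
    """

    alpha: float = 0.5
    beta: float = 7.0
    gamma: float = 1e-5
    sigma_mm: float = 0.47
    spacing_mm: float = DEFAULT_SPACING_MM

    def __post_init__(self) -> None:
        if self.alpha < 0 or self.beta < 0 or self.gamma < 0:
            raise ValueError("alpha, beta, gamma must be non-negative")
        if self.sigma_mm <= 0 or self.spacing_mm <= 0:
            raise ValueError("sigma and spacing must be positive")


@dataclass
class LossBreakdown:
    total: float
    l_sharp: float
    l_smooth: float
    smooth_fidelity: float
    smooth_tv: float

    def __post_init__(self) -> None:
        for v in (self.total, self.l_sharp, self.l_smooth,
                  self.smooth_fidelity, self.smooth_tv):
            if v < 0:
                raise ValueError("loss terms must be non-negative")
        if not math.isclose(self.total, self.l_sharp + self.l_smooth,
                            rel_tol=1e-9, abs_tol=1e-12):
            raise ValueError("total must equal l_sharp + l_smooth")


def _gauss_kernel_1d(sigma_px: float) -> np.ndarray:
    radius = max(1, int(math.ceil(3.0 * sigma_px)))
    x = np.arange(-radius, radius + 1, dtype=np.float64)
    k = np.exp(-0.5 * (x / sigma_px) ** 2)
    return k / k.sum()


def gaussian_convolve(image: np.ndarray, sigma_mm: float, spacing_mm: float) -> np.ndarray:
    """Separable, unit-sum, mean-preserving Gaussian blur.

    sigma is given in mm and converted to pixels through the spacing. The
    boundary is periodic, which makes the operator exactly self-adjoint — the
    backward pass of the loss reuses this same function.
    """
    if sigma_mm <= 0 or spacing_mm <= 0:
        raise ValueError("sigma and spacing must be positive")
    image = np.asarray(image)
    if not np.issubdtype(image.dtype, np.floating):
        image = image.astype(np.float64)
    k = _gauss_kernel_1d(sigma_mm / spacing_mm).astype(image.dtype)
    out = ndimage.correlate1d(image, k, axis=-2, mode="wrap")
    return ndimage.correlate1d(out, k, axis=-1, mode="wrap")


def total_variation_map(image: np.ndarray) -> np.ndarray:
    """Anisotropic per-pixel total variation |dz/dx| + |dz/dy|.

    Forward differences, zero beyond the last row/column; returned as a map
    so it can be weighted pixel-wise. The last two axes are spatial; leading
    axes (e.g. a batch) pass through.
    """
    z = np.asarray(image)
    if not np.issubdtype(z.dtype, np.floating):
        z = z.astype(np.float64)
    if z.ndim < 2 or z.shape[-2] < 2 or z.shape[-1] < 2:
        raise ValueError("TV needs at least a 2x2 image")
    tv = np.zeros_like(z)
    tv[..., :, :-1] += np.abs(z[..., :, 1:] - z[..., :, :-1])
    tv[..., :-1, :] += np.abs(z[..., 1:, :] - z[..., :-1, :])
    return tv


def _tv_backward(weight: np.ndarray, z: np.ndarray) -> np.ndarray:
    """Gradient of sum(weight * total_variation_map(z)) with respect to z."""
    g = np.zeros_like(z)
    sx = np.sign(z[..., :, 1:] - z[..., :, :-1]) * weight[..., :, :-1]
    g[..., :, 1:] += sx
    g[..., :, :-1] -= sx
    sy = np.sign(z[..., 1:, :] - z[..., :-1, :]) * weight[..., :-1, :]
    g[..., 1:, :] += sy
    g[..., :-1, :] -= sy
    return g


def task_loss(z, x_sharp, x_smooth, mask: WeightMask, params: LossParams,
              return_grad: bool = False):
    """Evaluate the task-based loss (optionally with its gradient in z).

    Returns a :class:`LossBreakdown`, or ``(breakdown, grad)`` when
    ``return_grad`` is set. The masks are constants of the computation.
    """
    dtype = np.result_type(np.asarray(z).dtype, np.asarray(x_sharp).dtype, np.float32)
    z = np.asarray(z, dtype=dtype)
    x_sharp = np.asarray(x_sharp, dtype=dtype)
    x_smooth = np.asarray(x_smooth, dtype=dtype)
    if not (z.shape == x_sharp.shape == x_smooth.shape == mask.d_sharp.shape):
        raise ValueError("z, targets and mask must share one shape")
    for name, arr in (("z", z), ("x_sharp", x_sharp), ("x_smooth", x_smooth)):
        if not np.all(np.isfinite(arr)):
            raise ValueError(f"{name} contains non-finite values")

    n = z.size
    r_sharp = z - x_sharp
    l_sharp = params.alpha * float(np.mean(mask.d_sharp * r_sharp**2))

    cz = gaussian_convolve(z, params.sigma_mm, params.spacing_mm)
    r_smooth = cz - x_smooth
    fidelity = params.beta * float(np.mean(mask.d_smooth * r_smooth**2))
    tv_term = params.beta * params.gamma * float(np.mean(mask.d_smooth * total_variation_map(z)))
    l_smooth = fidelity + tv_term

    breakdown = LossBreakdown(total=l_sharp + l_smooth, l_sharp=l_sharp,
                              l_smooth=l_smooth, smooth_fidelity=fidelity,
                              smooth_tv=tv_term)
    if not return_grad:
        return breakdown

    grad = (2.0 * params.alpha / n) * mask.d_sharp * r_sharp
    grad += gaussian_convolve((2.0 * params.beta / n) * mask.d_smooth * r_smooth,
                              params.sigma_mm, params.spacing_mm)
    grad += (params.beta * params.gamma / n) * _tv_backward(mask.d_smooth, z)
    return breakdown, grad
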