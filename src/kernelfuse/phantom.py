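"""Synthetic head-CT phantom and multi-kernel series simulation.

This module generates everything the rest of the pipeline needs without any
clinical data: a noise-free anthropomorphic head section (skull with cortical
tables and trabecular diploe, gray/white matter, CSF ventricles, vitreous
bodies, an optional fracture gap and hyperdense lesion), and simulated
reconstructions of it for a smooth and a sharp kernel at routine and reduced
dose, with kernel-shaped correlated noise calibrated to stated HU magnitudes.

The noise model is image-domain: white Gaussian noise shaped by a
kernel-specific spatial filter and scaled so that the standard deviation in a
uniform region matches the kernel's calibrated magnitude at the requested
dose. Smooth and sharp series of the same acquisition can share the same
white-noise realization, which reproduces the positive inter-kernel noise
correlation of series reconstructed from common projection data. Thin-slice
stacks carry AR(1) through-plane noise correlation (overlapping slice
sensitivity profiles), calibrated so that a 5 mm slab average of routine-dose
smooth slices reaches its own stated magnitude.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict, replace

import numpy as np
from scipy import ndimage, optimize

from .image import CTImage

__all__ = [
    "PhantomSpec",
    "KernelSpec",
    "TrainingExample",
    "smooth_kernel",
    "sharp_kernel",
    "make_phantom",
    "simulate_series",
    "simulate_stack",
    "make_thick_reference",
    "slab_weights",
    "interslice_rho_for_slab",
    "make_dataset",
    "load_dataset",
]

# ---------------------------------------------------------------------------
# Specs


@dataclass
class PhantomSpec:
    """Geometry and tissue HU assignments for the synthetic head section.

    All geometric quantities are in mm in a coordinate frame centred on the
    reconstruction grid; the head long axis runs along y with the face toward
    negative y.
    """

    grid: int = 512
    fov_mm: float = 250.0

    # tissue HU assignments
    hu_air: float = -1000.0
    hu_scalp: float = 50.0
    hu_cortical: float = 1200.0
    hu_trabecular_mean: float = 400.0
    hu_trabecular_amp: float = 150.0   # std of the smooth diploe texture field
    hu_csf: float = 8.0
    hu_wm: float = 25.0
    hu_gm: float = 38.0
    hu_vitreous: float = 10.0
    # sub-pixel gap contents partial-volume with bone: hypodense vs bone but
    # above the brain HU band even after sharp-kernel undershoot
    hu_fracture_gap: float = 150.0
    hu_lesion: float = 60.0

    # head geometry (semi-axes / thicknesses, mm)
    center_mm: tuple[float, float] = (0.0, 0.0)        # (y, x) offset
    scalp_axes: tuple[float, float] = (95.0, 78.0)     # (y, x) semi-axes
    skull_outer_axes: tuple[float, float] = (89.0, 72.0)
    outer_table_mm: float = 2.5
    diploe_mm: float = 5.0
    inner_table_mm: float = 2.5
    csf_margin_mm: float = 2.0
    gm_ribbon_mm: float = 6.0

    # internal structures: centres are (y, x) mm
    thalamus_centers: tuple = ((18.0, -13.0), (18.0, 13.0))
    thalamus_axes: tuple[float, float] = (12.0, 9.0)
    ventricle_centers: tuple = ((-5.0, -10.0), (-5.0, 10.0))
    ventricle_axes: tuple[float, float] = (14.0, 4.0)
    eye_centers: tuple = ((-86.0, -31.0), (-86.0, 31.0))
    eye_radius_mm: float = 12.0

    # lesions / defects
    fracture: bool = True
    fracture_angle_deg: float = 65.0   # direction of the radial gap, from +x toward +y
    fracture_width_mm: float = 0.7
    lesion: bool = True
    lesion_center: tuple[float, float] = (25.0, -20.0)
    lesion_radius_mm: float = 4.0

    def __post_init__(self) -> None:
        if self.grid < 32:
            raise ValueError("grid too small for the head geometry")
        if self.fov_mm <= 0:
            raise ValueError("field of view must be positive")
        if self.hu_gm <= self.hu_wm:
            raise ValueError("gray-matter HU must exceed white-matter HU")
        if self.hu_cortical <= 80:
            raise ValueError("cortical bone HU must exceed the 80 HU mask bound")
        for hu in (self.hu_air, self.hu_scalp, self.hu_cortical, self.hu_csf,
                   self.hu_wm, self.hu_gm, self.hu_vitreous):
            if not (-1024 <= hu <= 3000):
                raise ValueError(f"HU assignment {hu} outside [-1024, 3000]")
        if math.pi * self.eye_radius_mm**2 < 240.0:
            raise ValueError("vitreous region must offer >= 2.4 cm^2 for the noise ROI")
        half = self.fov_mm / 2.0
        cy, cx = self.center_mm
        if (abs(cy) + self.scalp_axes[0] > half + 1e-9
                or abs(cx) + self.scalp_axes[1] > half + 1e-9):
            raise ValueError("head geometry does not fit inside the field of view")

    @property
    def spacing(self) -> float:
        return self.fov_mm / self.grid

    def jittered(self, rng: np.random.Generator) -> "PhantomSpec":
        """Per-slice anatomy variation: global scale, shift and defect pose."""
        s = rng.uniform(0.92, 1.04)
        dy, dx = rng.uniform(-4.0, 4.0, size=2)
        scale2 = lambda t: (t[0] * s, t[1] * s)
        shift = lambda t: (t[0] * s + dy, t[1] * s + dx)
        return replace(
            self,
            center_mm=(self.center_mm[0] + dy, self.center_mm[1] + dx),
            scalp_axes=scale2(self.scalp_axes),
            skull_outer_axes=scale2(self.skull_outer_axes),
            thalamus_centers=tuple(shift(c) for c in self.thalamus_centers),
            thalamus_axes=scale2(self.thalamus_axes),
            ventricle_centers=tuple(shift(c) for c in self.ventricle_centers),
            ventricle_axes=scale2(self.ventricle_axes),
            eye_centers=tuple(shift(c) for c in self.eye_centers),
            fracture_angle_deg=float(rng.uniform(30.0, 150.0)),
            lesion_center=shift(self.lesion_center),
        )


@dataclass
class KernelSpec:
    """Point-spread and noise model for one reconstruction-kernel class.

    ``noise_hu`` maps dose fraction -> HU standard deviation in a uniform
    calibration region; routine dose (1.0) and the reduced dose used for
    training inputs are calibrated independently because measured low-dose /
    routine-dose noise ratios deviate from pure 1/sqrt(dose) scaling. Doses in
    between follow a power law through the two calibration points.
    """

    name: str
    psf_sigma_mm: float
    boost_gain: float = 0.0        # unsharp high-boost gain (edge overshoot)
    boost_sigma_mm: float = 0.9
    noise_lowpass_mm: float = 0.5  # shaping filter scale for the noise field
    noise_highpass_frac: float = 0.0
    noise_hu: dict = field(default_factory=dict)  # {dose: HU std}

    def __post_init__(self) -> None:
        if self.name not in ("smooth", "sharp"):
            raise ValueError(f"kernel class must be 'smooth' or 'sharp', got {self.name!r}")
        if self.psf_sigma_mm <= 0:
            raise ValueError("PSF width must be positive")
        doses = sorted(self.noise_hu)
        if any(d <= 0 or d > 1 for d in doses):
            raise ValueError("calibration doses must lie in (0, 1]")
        if len(doses) == 2:
            lo, hi = doses
            if self.noise_hu[lo] < self.noise_hu[hi]:
                raise ValueError("low-dose noise magnitude must be >= routine-dose magnitude")

    def noise_hu_at(self, dose: float) -> float:
        """Calibrated HU std at a dose fraction (power-law between points)."""
        if not (0 < dose <= 1):
            raise ValueError(f"dose fraction must be in (0, 1], got {dose}")
        doses = sorted(self.noise_hu)
        if not doses:
            return 0.0
        for d in doses:
            if math.isclose(dose, d, rel_tol=1e-9):
                return float(self.noise_hu[d])
        if len(doses) == 1:
            # single calibration point: fall back to 1/sqrt(dose)
            d0 = doses[0]
            return float(self.noise_hu[d0] * math.sqrt(d0 / dose))
        d_lo, d_hi = doses[0], doses[-1]
        s_lo, s_hi = self.noise_hu[d_lo], self.noise_hu[d_hi]
        if s_hi <= 0 or s_lo <= 0:
            return 0.0
        expo = math.log(s_lo / s_hi) / math.log(d_lo / d_hi)
        return float(s_hi * (dose / d_hi) ** expo)


def smooth_kernel() -> KernelSpec:
    """Smooth (brain) kernel: wide PSF, low-pass noise, low magnitudes."""
    return KernelSpec(
        name="smooth",
        psf_sigma_mm=1.0,
        noise_lowpass_mm=0.55,
        noise_hu={1.0: 6.0, 0.25: 12.8},
    )


def sharp_kernel() -> KernelSpec:
    """Sharp (bone) kernel: narrow PSF with high-boost overshoot, high-pass noise."""
    return KernelSpec(
        name="sharp",
        psf_sigma_mm=0.3,
        boost_gain=0.8,
        boost_sigma_mm=0.9,
        noise_lowpass_mm=0.55,
        noise_highpass_frac=0.7,
        noise_hu={1.0: 34.5, 0.25: 80.1},
    )


def validate_kernel_pair(smooth: KernelSpec, sharp: KernelSpec) -> None:
    """The sharp kernel must be the noisier one at matched dose."""
    if sharp.noise_hu_at(1.0) <= smooth.noise_hu_at(1.0):
        raise ValueError("sharp-kernel routine-dose noise must exceed the smooth kernel's")


@dataclass
class TrainingExample:
    """Aligned five-image bundle for one slice position."""

    smooth_ld: CTImage
    sharp_ld: CTImage
    smooth_rd: CTImage
    sharp_rd: CTImage
    truth: CTImage
    spec: PhantomSpec

    def __post_init__(self) -> None:
        shapes = {im.shape for im in self.images()}
        spacings = {im.spacing for im in self.images()}
        if len(shapes) != 1 or len(spacings) != 1:
            raise ValueError("all images of an example must share grid and spacing")

    def images(self) -> tuple[CTImage, ...]:
        return (self.smooth_ld, self.sharp_ld, self.smooth_rd, self.sharp_rd, self.truth)


# ---------------------------------------------------------------------------
# Phantom painting


def _ellipse(yy, xx, center, axes):
    cy, cx = center
    ay, ax = axes
    return ((yy - cy) / ay) ** 2 + ((xx - cx) / ax) ** 2 <= 1.0


def make_phantom(spec: PhantomSpec, seed: int = 0) -> CTImage:
    """Noise-free ground-truth HU image of one head section.

    Deterministic per (spec, seed); the seed drives only the trabecular
    texture field.
    """
    n = spec.grid
    sp = spec.spacing
    coords = (np.arange(n) - (n - 1) / 2.0) * sp
    yy, xx = np.meshgrid(coords, coords, indexing="ij")
    cy, cx = spec.center_mm

    img = np.full((n, n), spec.hu_air, dtype=np.float64)

    # scalp and skull layers (successively shrinking ellipses)
    shrink = lambda axes, t: (axes[0] - t, axes[1] - t)
    skull_outer = spec.skull_outer_axes
    t1 = spec.outer_table_mm
    t2 = t1 + spec.diploe_mm
    t3 = t2 + spec.inner_table_mm
    if min(shrink(skull_outer, t3)) <= spec.csf_margin_mm + spec.gm_ribbon_mm:
        raise ValueError("skull geometry leaves no room for the brain")

    img[_ellipse(yy, xx, (cy, cx), spec.scalp_axes)] = spec.hu_scalp
    img[_ellipse(yy, xx, (cy, cx), skull_outer)] = spec.hu_cortical

    diploe = _ellipse(yy, xx, (cy, cx), shrink(skull_outer, t1)) & ~_ellipse(
        yy, xx, (cy, cx), shrink(skull_outer, t2))
    rng = np.random.default_rng(seed)
    texture = ndimage.gaussian_filter(rng.standard_normal((n, n)), 2.0 / sp, mode="wrap")
    texture *= spec.hu_trabecular_amp / max(texture.std(), 1e-12)
    np.clip(texture, -spec.hu_trabecular_amp, spec.hu_trabecular_amp, out=texture)
    img[diploe] = spec.hu_trabecular_mean + texture[diploe]

    inner_table = _ellipse(yy, xx, (cy, cx), shrink(skull_outer, t2)) & ~_ellipse(
        yy, xx, (cy, cx), shrink(skull_outer, t3))
    img[inner_table] = spec.hu_cortical

    # intracranial contents
    skull_inner = shrink(skull_outer, t3)
    img[_ellipse(yy, xx, (cy, cx), skull_inner)] = spec.hu_csf
    brain_axes = shrink(skull_inner, spec.csf_margin_mm)
    img[_ellipse(yy, xx, (cy, cx), brain_axes)] = spec.hu_gm
    wm_axes = shrink(brain_axes, spec.gm_ribbon_mm)
    img[_ellipse(yy, xx, (cy, cx), wm_axes)] = spec.hu_wm
    for c in spec.thalamus_centers:
        img[_ellipse(yy, xx, c, spec.thalamus_axes)] = spec.hu_gm
    for c in spec.ventricle_centers:
        img[_ellipse(yy, xx, c, spec.ventricle_axes)] = spec.hu_csf
    if spec.lesion:
        img[_ellipse(yy, xx, spec.lesion_center,
                     (spec.lesion_radius_mm, spec.lesion_radius_mm))] = spec.hu_lesion

    # sub-millimetre hypodense gap through the skull (suture/fracture)
    if spec.fracture:
        phi = math.radians(spec.fracture_angle_deg)
        uy, ux = math.sin(phi), math.cos(phi)
        ry, rx = yy - cy, xx - cx
        along = ry * uy + rx * ux
        perp = np.abs(-ry * ux + rx * uy)
        in_skull = _ellipse(yy, xx, (cy, cx), skull_outer) & ~_ellipse(
            yy, xx, (cy, cx), skull_inner)
        gap = (perp <= spec.fracture_width_mm / 2.0) & (along > 0) & in_skull
        img[gap] = spec.hu_fracture_gap

    # vitreous bodies (painted last; uniform region hosting the noise ROI)
    for c in spec.eye_centers:
        img[_ellipse(yy, xx, c, (spec.eye_radius_mm, spec.eye_radius_mm))] = spec.hu_vitreous

    return CTImage(img, spacing=sp, thickness=0.75, kernel=None,
                   dose=1.0, provenance="ground-truth")


# ---------------------------------------------------------------------------
# Kernel PSF + noise shaping


def _apply_psf(pixels: np.ndarray, kernel: KernelSpec, spacing: float) -> np.ndarray:
    base = ndimage.gaussian_filter(pixels, kernel.psf_sigma_mm / spacing, mode="nearest")
    if kernel.boost_gain > 0:
        wide = ndimage.gaussian_filter(pixels, kernel.boost_sigma_mm / spacing, mode="nearest")
        return (1.0 + kernel.boost_gain) * base - kernel.boost_gain * wide
    return base


def _shape_noise(white: np.ndarray, kernel: KernelSpec, spacing: float) -> np.ndarray:
    low = ndimage.gaussian_filter(white, kernel.noise_lowpass_mm / spacing, mode="wrap")
    if kernel.noise_highpass_frac > 0:
        return white - kernel.noise_highpass_frac * low
    return low


_GAIN_CACHE: dict = {}


def _noise_gain(kernel: KernelSpec, spacing: float) -> float:
    """Std of a unit-white field after the kernel's shaping filter (discrete l2 norm)."""
    key = (kernel.noise_lowpass_mm, kernel.noise_highpass_frac, round(spacing, 9))
    if key not in _GAIN_CACHE:
        m = 129
        delta = np.zeros((m, m))
        delta[m // 2, m // 2] = 1.0
        h = _shape_noise(delta, kernel, spacing)
        _GAIN_CACHE[key] = float(np.sqrt(np.sum(h**2)))
    return _GAIN_CACHE[key]


def simulate_series(
    truth: CTImage,
    kernel: KernelSpec,
    dose_fraction: float,
    seed: int | None = None,
    shared_noise: np.ndarray | None = None,
) -> CTImage:
    """One reconstructed series: PSF-convolved truth plus calibrated shaped noise.

    ``shared_noise`` is an optional white-noise base realization; passing the
    same base to the smooth and the sharp simulation yields correlated noise
    fields, as in series reconstructed from the same projections.
    """
    if not (0 < dose_fraction <= 1):
        raise ValueError(f"dose fraction must be in (0, 1], got {dose_fraction}")
    blurred = _apply_psf(truth.pixels, kernel, truth.spacing)
    sigma = kernel.noise_hu_at(dose_fraction)
    if sigma > 0:
        if shared_noise is None:
            shared_noise = np.random.default_rng(seed).standard_normal(truth.shape)
        elif shared_noise.shape != truth.shape:
            raise ValueError("shared noise realization must match the image grid")
        shaped = _shape_noise(shared_noise, kernel, truth.spacing)
        blurred = blurred + (sigma / _noise_gain(kernel, truth.spacing)) * shaped
    return CTImage(blurred, spacing=truth.spacing, thickness=truth.thickness,
                   kernel=kernel.name, dose=dose_fraction, provenance="simulated")


# ---------------------------------------------------------------------------
# Thin-slice stacks and slab averaging


def slab_weights(n_thin: int, thin_mm: float, target_mm: float) -> np.ndarray:
    """Normalized averaging weights for a slab of ``target_mm`` from thin slices.

    A non-integer span uses fractional weights on the two terminal slices so
    the weights always sum to 1 (e.g. 5 mm from 0.75 mm slices spans 6 2/3
    slices, realized as 7 slices with end weights 5/6 of a slice each before
    normalization).
    """
    if target_mm < thin_mm:
        raise ValueError("target thickness must be >= thin-slice thickness")
    k = target_mm / thin_mm
    m = int(math.floor(k + 1e-9))
    if m < 1:
        m = 1
    if abs(k - m) < 1e-9:
        w = np.ones(m) if m > 1 else np.array([1.0])
    else:
        w = np.ones(m + 1)
        w[0] = w[-1] = (k - (m - 1)) / 2.0
    if n_thin < len(w):
        raise ValueError(f"stack of {n_thin} slices too short for a {target_mm} mm slab")
    return w / w.sum()


def interslice_rho_for_slab(
    thin_mm: float = 0.75,
    target_mm: float = 5.0,
    thin_sigma: float = 6.0,
    slab_sigma: float = 3.2,
) -> float:
    """AR(1) through-plane noise correlation reproducing a calibrated slab std.

    Solves sum_ij w_i w_j rho^|i-j| = (slab_sigma/thin_sigma)^2 for rho, where
    w are the slab averaging weights. Models the overlap of slice sensitivity
    profiles of adjacent thin reconstructions.
    """
    w = slab_weights(64, thin_mm, target_mm)
    target = (slab_sigma / thin_sigma) ** 2
    idx = np.arange(len(w))
    lag = np.abs(idx[:, None] - idx[None, :])

    def f(rho):
        return float(w @ (rho ** lag) @ w) - target

    if f(0.0) >= 0:
        return 0.0
    return float(optimize.brentq(f, 0.0, 0.999999))


def simulate_stack(
    truth: CTImage,
    kernel: KernelSpec,
    dose_fraction: float,
    n_slices: int,
    seed: int | None = None,
    rho: float | None = None,
) -> list[CTImage]:
    """Stack of thin slices over the same anatomy with AR(1) correlated noise.

    ``rho`` defaults to the correlation that calibrates the 5 mm smooth-RD
    slab reference (see :func:`interslice_rho_for_slab`).
    """
    if n_slices < 1:
        raise ValueError("need at least one slice")
    if rho is None:
        rho = interslice_rho_for_slab()
    rng = np.random.default_rng(seed)
    base = rng.standard_normal(truth.shape)
    out = []
    for _ in range(n_slices):
        out.append(simulate_series(truth, kernel, dose_fraction, shared_noise=base))
        base = rho * base + math.sqrt(1.0 - rho**2) * rng.standard_normal(truth.shape)
    return out


def make_thick_reference(stack: list[CTImage], target_thickness_mm: float) -> CTImage:
    """Slab-average contiguous thin slices into one thick reference slice."""
    if not stack:
        raise ValueError("empty stack")
    thin = stack[0].thickness
    if any(abs(im.thickness - thin) > 1e-9 for im in stack):
        raise ValueError("stack slices must share a uniform thin thickness")
    if any(im.shape != stack[0].shape for im in stack):
        raise ValueError("stack slices must be aligned on one grid")
    w = slab_weights(len(stack), thin, target_thickness_mm)
    start = (len(stack) - len(w)) // 2
    pix = sum(wi * stack[start + i].pixels for i, wi in enumerate(w))
    ref = stack[0]
    return CTImage(pix, spacing=ref.spacing, thickness=target_thickness_mm,
                   kernel=ref.kernel, dose=ref.dose, provenance=ref.provenance)


# ---------------------------------------------------------------------------
# Dataset assembly


def make_dataset(
    spec: PhantomSpec,
    kernels: tuple[KernelSpec, KernelSpec] | None = None,
    n_slices: int = 10,
    seed: int = 0,
    low_dose: float = 0.25,
    out_dir=None,
) -> tuple[list[TrainingExample], dict]:
    """Seeded collection of training examples plus a reproducibility manifest.

    Each slice gets independently jittered anatomy. Within a slice, the smooth
    and sharp series of the same dose share a white-noise base (correlated
    noise); the LD and RD acquisitions use independent bases. The manifest
    records everything needed to regenerate the dataset bit-exactly with
    :func:`load_dataset`.
    """
    if n_slices < 1:
        raise ValueError("n_slices must be >= 1")
    if kernels is None:
        kernels = (smooth_kernel(), sharp_kernel())
    ksmooth, ksharp = kernels
    validate_kernel_pair(ksmooth, ksharp)

    root = np.random.SeedSequence(seed)
    examples = []
    slice_entries = []
    for i, child in enumerate(root.spawn(n_slices)):
        rng = np.random.default_rng(child)
        anat_seed = int(rng.integers(2**31))
        sl_spec = spec.jittered(rng)
        truth = make_phantom(sl_spec, seed=anat_seed)
        base_rd = rng.standard_normal(truth.shape)
        base_ld = rng.standard_normal(truth.shape)
        ex = TrainingExample(
            smooth_ld=simulate_series(truth, ksmooth, low_dose, shared_noise=base_ld),
            sharp_ld=simulate_series(truth, ksharp, low_dose, shared_noise=base_ld),
            smooth_rd=simulate_series(truth, ksmooth, 1.0, shared_noise=base_rd),
            sharp_rd=simulate_series(truth, ksharp, 1.0, shared_noise=base_rd),
            truth=truth,
            spec=sl_spec,
        )
        examples.append(ex)
        slice_entries.append({"index": i, "anat_seed": anat_seed})

    manifest = {
        "seed": int(seed),
        "n_slices": int(n_slices),
        "low_dose": float(low_dose),
        "spec": asdict(spec),
        "kernels": {"smooth": asdict(ksmooth), "sharp": asdict(ksharp)},
        "slices": slice_entries,
        "files": [],
    }

    if out_dir is not None:
        from . import io as kio
        import json
        from pathlib import Path

        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        names = ("smooth_ld", "sharp_ld", "smooth_rd", "sharp_rd", "truth")
        for i, ex in enumerate(examples):
            for name, im in zip(names, ex.images()):
                path = out / f"slice{i:03d}_{name}.nii.gz"
                kio.write_series(im, path)
                manifest["files"].append(path.name)
        with open(out / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=1)
    return examples, manifest


def _spec_from_dict(d: dict) -> PhantomSpec:
    d = dict(d)
    for key in ("center_mm", "scalp_axes", "skull_outer_axes", "thalamus_axes",
                "ventricle_axes", "lesion_center"):
        d[key] = tuple(d[key])
    for key in ("thalamus_centers", "ventricle_centers", "eye_centers"):
        d[key] = tuple(tuple(c) for c in d[key])
    return PhantomSpec(**d)


def _kernel_from_dict(d: dict) -> KernelSpec:
    d = dict(d)
    # JSON round-trips stringify the dose keys
    d["noise_hu"] = {float(k): float(v) for k, v in d["noise_hu"].items()}
    return KernelSpec(**d)


def load_dataset(manifest: dict) -> tuple[list[TrainingExample], dict]:
    """Regenerate a dataset from its manifest (bit-exact, seed-driven)."""
    spec = _spec_from_dict(manifest["spec"])
    kernels = (_kernel_from_dict(manifest["kernels"]["smooth"]),
               _kernel_from_dict(manifest["kernels"]["sharp"]))
    return make_dataset(spec, kernels, n_slices=manifest["n_slices"],
                        seed=manifest["seed"], low_dose=manifest["low_dose"])
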