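"""Residual U-Net kernel-synthesis model with CT window preprocessing.

The network consumes the smooth- and sharp-kernel low-dose slices of one
acquisition and emits a single HU image. A fixed preprocessing layer maps
each of the two HU inputs through three clinical display windows
((HU - level) / width, no clipping) and concatenates the results into six
feature channels; all HU normalization lives here, the convolutional body
never rescales HU. The body is a shallow U-Net (two 2x downsamplings) whose
second convolution at every level carries an identity skip (residual block).
The final 3x3 convolution is zero-initialized and its output, scaled by a
fixed HU gain, is subtracted pixel-wise from an anchor input (the smooth-LD
channel by default), so an untrained model reproduces its anchor exactly and
training learns a correction image.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np

from .image import CTImage
from .masks import WeightMask
from .nn import Conv1x1, Conv3x3, ReLU, AvgPool2, Upsample2

__all__ = ["WindowSetting", "ModelConfig", "default_windows", "window_normalize",
           "preprocess", "KernelSynthesisNet", "build_model", "infer",
           "compose_output", "save_checkpoint", "load_checkpoint"]


@dataclass
class WindowSetting:
    """Clinical display window: name, level and width in HU."""

    name: str
    level: float
    width: float

    def __post_init__(self) -> None:
        if self.width <= 0:
            raise ValueError("window width must be positive")


def default_windows() -> tuple[WindowSetting, WindowSetting, WindowSetting]:
    """Soft-tissue 400/40, brain 80/40 and bone 2800/600 windows (width/level)."""
    return (WindowSetting("soft-tissue", level=40.0, width=400.0),
            WindowSetting("brain", level=40.0, width=80.0),
            WindowSetting("bone", level=600.0, width=2800.0))


@dataclass
class ModelConfig:
    """Architecture hyperparameters.

    ``filters`` are the channel counts of the three resolution levels.
    ``anchor`` selects the residual subtraction baseline: the smooth-LD
    input (default: it starts low-noise, so short training schedules refine
    the brain signal instead of first unlearning sharp-kernel noise), the
    sharp-LD input, or their mean. ``output_scale`` is the fixed HU
    magnitude of a unit network output, which keeps the zero-initialized
    last layer's weights at order one during training.
    """

    filters: tuple[int, int, int] = (16, 32, 64)
    windows: tuple[WindowSetting, WindowSetting, WindowSetting] = field(
        default_factory=default_windows)
    anchor: str = "smooth"
    output_scale: float = 100.0

    def __post_init__(self) -> None:
        if len(self.filters) != 3 or any(f < 1 for f in self.filters):
            raise ValueError("filters must be three positive channel counts")
        if len(self.windows) != 3:
            raise ValueError("exactly three window settings are expected")
        if self.anchor not in ("sharp", "smooth", "mean"):
            raise ValueError("anchor must be 'sharp', 'smooth' or 'mean'")
        if self.output_scale <= 0:
            raise ValueError("output_scale must be positive")


def window_normalize(image: np.ndarray, w: WindowSetting) -> np.ndarray:
    """(HU - level) / width, without clipping."""
    return (np.asarray(image, dtype=np.float32) - w.level) / w.width


def preprocess(smooth_ld: np.ndarray, sharp_ld: np.ndarray,
               windows=None) -> np.ndarray:
    """Window-normalized 6-channel feature stack.

    Channel order is fixed: the smooth input under each window in order, then
    the sharp input under each window. Accepts (H, W) or (B, H, W) arrays and
    returns channels-last (B, H, W, 6).
    """
    windows = windows or default_windows()
    s = np.asarray(smooth_ld, dtype=np.float32)
    q = np.asarray(sharp_ld, dtype=np.float32)
    if s.shape != q.shape:
        raise ValueError("smooth and sharp inputs must share one shape")
    if s.ndim == 2:
        s, q = s[None], q[None]
    chans = [window_normalize(s, w) for w in windows]
    chans += [window_normalize(q, w) for w in windows]
    return np.stack(chans, axis=-1)


class KernelSynthesisNet:
    """Fully convolutional residual U-Net mapping two HU inputs to one HU output.

    Trains on small patches, infers on full-size grids; spatial dimensions
    must be multiples of 4 (two pooling stages).
    """

    def __init__(self, cfg: ModelConfig, seed: int = 0):
        self.cfg = cfg
        #: computation dtype; float64 is available for numerical verification
        self.dtype = np.float32
        rng = np.random.default_rng(seed)
        f1, f2, f3 = cfg.filters
        conv = lambda ci, co: (Conv3x3(ci, co, rng), ReLU())
        self.enc0a = conv(6, f1)
        self.enc0b = conv(f1, f1)          # residual
        self.pool1 = AvgPool2()
        self.enc1a = conv(f1, f2)
        self.enc1b = conv(f2, f2)          # residual
        self.pool2 = AvgPool2()
        self.bota = conv(f2, f3)
        self.botb = conv(f3, f3)           # residual
        self.up1 = Upsample2()
        self.dec1a = (Conv1x1(f3 + f2, f2, rng), ReLU())   # skip fusion
        self.dec1b = conv(f2, f2)          # residual
        self.up2 = Upsample2()
        self.dec2a = (Conv1x1(f2 + f1, f1, rng), ReLU())   # skip fusion
        self.dec2b = conv(f1, f1)          # residual
        self.head = Conv3x3(f1, 1, zero_init=True)
        self._pairs = [self.enc0a, self.enc0b, self.enc1a, self.enc1b,
                       self.bota, self.botb, self.dec1a, self.dec1b,
                       self.dec2a, self.dec2b]

    # -- plumbing -----------------------------------------------------------

    def parameters(self):
        out = []
        for c, _ in self._pairs:
            out += c.parameters()
        out += self.head.parameters()
        return out

    @staticmethod
    def _block(pair, x, train, residual):
        conv, act = pair
        y = act.forward(conv.forward(x, train), train)
        return y + x if residual else y

    @staticmethod
    def _block_back(pair, dy, residual):
        conv, act = pair
        dx = conv.backward(act.backward(dy))
        return dx + dy if residual else dx

    def _anchor(self, smooth_hu: np.ndarray, sharp_hu: np.ndarray) -> np.ndarray:
        if self.cfg.anchor == "sharp":
            return sharp_hu
        if self.cfg.anchor == "smooth":
            return smooth_hu
        return 0.5 * (smooth_hu + sharp_hu)

    # -- forward / backward -------------------------------------------------

    def forward(self, smooth_hu: np.ndarray, sharp_hu: np.ndarray,
                train: bool = False) -> np.ndarray:
        """HU output for (B, H, W) (or (H, W)) HU input pairs."""
        squeeze = np.asarray(smooth_hu).ndim == 2
        x = preprocess(smooth_hu, sharp_hu, self.cfg.windows).astype(self.dtype, copy=False)
        if x.shape[1] % 4 or x.shape[2] % 4:
            raise ValueError("spatial dimensions must be multiples of 4")
        e0 = self._block(self.enc0b, self._block(self.enc0a, x, train, False), train, True)
        e1 = self._block(self.enc1b,
                         self._block(self.enc1a, self.pool1.forward(e0, train), train, False),
                         train, True)
        bt = self._block(self.botb,
                         self._block(self.bota, self.pool2.forward(e1, train), train, False),
                         train, True)
        u1 = np.concatenate([self.up1.forward(bt, train), e1], axis=-1)
        d1 = self._block(self.dec1b, self._block(self.dec1a, u1, train, False), train, True)
        u2 = np.concatenate([self.up2.forward(d1, train), e0], axis=-1)
        d2 = self._block(self.dec2b, self._block(self.dec2a, u2, train, False), train, True)
        corr = self.head.forward(d2, train)[..., 0]
        anchor = self._anchor(np.asarray(smooth_hu, dtype=self.dtype),
                              np.asarray(sharp_hu, dtype=self.dtype))
        z = anchor - self.dtype(self.cfg.output_scale) * corr
        self._split = (self.cfg.filters[2], self.cfg.filters[1])
        return z[0] if squeeze else z

    def backward(self, dz: np.ndarray) -> None:
        """Accumulate parameter gradients from dLoss/dz of the last forward."""
        if dz.ndim == 2:
            dz = dz[None]
        dcorr = (-self.cfg.output_scale * dz).astype(self.dtype)[..., None]
        d2 = self.head.backward(dcorr)
        du2 = self._block_back(self.dec2a, self._block_back(self.dec2b, d2, True), False)
        f3, f2 = self._split
        dd1 = self.up2.backward(np.ascontiguousarray(du2[..., :f2]))
        de0 = du2[..., f2:]
        du1 = self._block_back(self.dec1a, self._block_back(self.dec1b, dd1, True), False)
        dbt = self.up1.backward(np.ascontiguousarray(du1[..., :f3]))
        de1 = du1[..., f3:]
        dp2 = self._block_back(self.bota, self._block_back(self.botb, dbt, True), False)
        de1 = de1 + self.pool2.backward(dp2)
        dp1 = self._block_back(self.enc1a, self._block_back(self.enc1b, de1, True), False)
        de0 = de0 + self.pool1.backward(dp1)
        self._block_back(self.enc0a, self._block_back(self.enc0b, de0, True), False)

    def state_dict(self) -> list[np.ndarray]:
        return [p.copy() for p, _ in self.parameters()]

    def load_state(self, state: list[np.ndarray]) -> None:
        for (p, _), s in zip(self.parameters(), state):
            p[...] = s


def build_model(cfg: ModelConfig | None = None, seed: int = 0) -> KernelSynthesisNet:
    """Seeded construction of the kernel-synthesis network."""
    return KernelSynthesisNet(cfg or ModelConfig(), seed=seed)


def infer(model: KernelSynthesisNet, smooth_ld: CTImage, sharp_ld: CTImage) -> CTImage:
    """Run the model on one aligned slice pair; returns the HU output z."""
    if smooth_ld.shape != sharp_ld.shape or smooth_ld.spacing != sharp_ld.spacing:
        raise ValueError("smooth and sharp inputs must be aligned")
    z = model.forward(smooth_ld.pixels, sharp_ld.pixels, train=False)
    return smooth_ld.with_pixels(z, kernel=None, provenance="model-output")


def compose_output(z: CTImage, sharp_input: CTImage, mask: WeightMask) -> CTImage:
    """Bone-region composition: D_sharp * sharp input + D_smooth * z.

    Replaces saturated bone regions with the sharp input kernel and blends
    across the transition where the model output is progressively added.
    """
    if z.shape != sharp_input.shape or z.shape != mask.d_sharp.shape:
        raise ValueError("z, sharp input and mask must share one shape")
    pix = mask.d_sharp * sharp_input.pixels + mask.d_smooth * z.pixels
    return z.with_pixels(pix, provenance="model-output")


# ---------------------------------------------------------------------------
# Checkpoints


def save_checkpoint(model: KernelSynthesisNet, path) -> None:
    """Single-file checkpoint embedding the model configuration."""
    cfg = asdict(model.cfg)
    cfg["windows"] = [asdict(w) for w in model.cfg.windows]
    arrays = {f"param_{i}": p for i, (p, _) in enumerate(model.parameters())}
    np.savez(path, config=json.dumps(cfg), **arrays)


def load_checkpoint(path) -> KernelSynthesisNet:
    with np.load(path, allow_pickle=False) as data:
        cfg_d = json.loads(str(data["config"]))
        cfg_d["windows"] = tuple(WindowSetting(**w) for w in cfg_d["windows"])
        cfg_d["filters"] = tuple(cfg_d["filters"])
        model = KernelSynthesisNet(ModelConfig(**cfg_d), seed=0)
        state = [data[f"param_{i}"] for i in range(len(model.parameters()))]
    model.load_state(state)
    return model
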