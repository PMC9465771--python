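"""3D U-Net for skull stripping, implemented directly on NumPy arrays.

The architecture contract: an encoder of ``levels`` resolutions, each with
``convs_per_level`` 3x3x3 convolutions followed by leaky-ReLU (slope 0.2),
max-pooling x2 between levels; a mirrored decoder with nearest-neighbor x2
upsampling and concatenation skip connections at matched resolution; and a
task head — a single-feature convolution with linear activation for SDT
regression, or a two-feature convolution with voxel-wise softmax for
probabilistic brain / non-brain segmentation.

Forward and backward passes are written out explicitly (convolutions as 27
shifted-view matrix products), which keeps the package free of deep
learning framework dependencies and is fast enough for the small grids
used in training experiments here.  Checkpoints serialize to ``.npz``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["UNetSpec", "UNet", "build_unet", "parameter_count",
           "save_checkpoint", "load_checkpoint"]

_OFFSETS = [(dz, dy, dx) for dz in range(3) for dy in range(3) for dx in range(3)]

# Gradients far below the useful scale are flushed to zero: subnormal
# float32 values otherwise force the CPU onto its slow denormal path,
# inflating backward-pass time several-fold on converged networks.
_GRAD_FLUSH = np.float32(1e-30)


def _flush_subnormals(a: np.ndarray) -> np.ndarray:
    np.copyto(a, 0.0, where=np.abs(a) < _GRAD_FLUSH)
    return a


def _default_filters(levels: int, base: int = 16, cap: int = 256):
    return [min(base * 2 ** i, cap) for i in range(levels)]


@dataclass(frozen=True)
class UNetSpec:
    """Architecture hyperparameters of the skull-stripping U-Net."""

    levels: int = 7
    convs_per_level: int = 2
    leaky_slope: float = 0.2
    encoder_filters: tuple = None  # type: ignore[assignment]
    decoder_filters: tuple = None  # type: ignore[assignment]
    head_mode: str = "sdt"
    input_shape: tuple = (256, 256, 256)

    def __post_init__(self):
        if self.levels < 1:
            raise ValueError("levels must be >= 1")
        if self.convs_per_level < 1:
            raise ValueError("convs_per_level must be >= 1")
        if self.head_mode not in ("sdt", "dice"):
            raise ValueError("head_mode must be 'sdt' or 'dice'")
        enc = self.encoder_filters or tuple(_default_filters(self.levels))
        if len(enc) != self.levels or any(f < 1 for f in enc):
            raise ValueError("encoder_filters must list one positive count per level")
        dec = self.decoder_filters or tuple(reversed(enc[:-1]))
        if len(dec) != self.levels - 1 or any(f < 1 for f in dec):
            raise ValueError("decoder_filters must list levels-1 positive counts")
        stride = 2 ** (self.levels - 1)
        shape = tuple(int(s) for s in self.input_shape)
        if any(s % stride != 0 for s in shape):
            raise ValueError(
                f"input shape {shape} must be divisible by 2^(levels-1) = {stride}"
            )
        object.__setattr__(self, "encoder_filters", tuple(enc))
        object.__setattr__(self, "decoder_filters", tuple(dec))
        object.__setattr__(self, "input_shape", shape)

    @property
    def out_channels(self) -> int:
        return 1 if self.head_mode == "sdt" else 2

    def bottleneck_shape(self) -> tuple:
        f = 2 ** (self.levels - 1)
        return tuple(s // f for s in self.input_shape)

    def conv_plan(self):
        """Yield (name, in_channels, out_channels) for every convolution."""
        c_in = 1
        enc = self.encoder_filters
        for lvl in range(self.levels):
            for j in range(self.convs_per_level):
                yield f"enc{lvl}_conv{j}", c_in, enc[lvl]
                c_in = enc[lvl]
        for i, lvl in enumerate(reversed(range(self.levels - 1))):
            c_in = c_in + enc[lvl]  # concat skip
            for j in range(self.convs_per_level):
                yield f"dec{lvl}_conv{j}", c_in, self.decoder_filters[i]
                c_in = self.decoder_filters[i]
        yield "head", c_in, self.out_channels


def parameter_count(spec: UNetSpec) -> int:
    """Total trainable parameter count implied by a spec (27 weights + 1 bias
    per output filter per input channel)."""
    total = 0
    for _, c_in, c_out in spec.conv_plan():
        total += c_out * c_in * 27 + c_out
    return total


def _conv_forward(x, W, b):
    """Same-padded 3x3x3 convolution; x is (C, D, H, Wd) float32."""
    c_out = W.shape[0]
    D, H, Wd = x.shape[1:]
    xp = np.pad(x, ((0, 0), (1, 1), (1, 1), (1, 1)))
    n = D * H * Wd
    out = np.zeros((c_out, n), dtype=x.dtype)
    for k, (dz, dy, dx) in enumerate(_OFFSETS):
        view = xp[:, dz:dz + D, dy:dy + H, dx:dx + Wd].reshape(x.shape[0], n)
        out += W[:, :, dz, dy, dx] @ view
    out += b[:, None]
    return out.reshape(c_out, D, H, Wd), xp


def _conv_backward(gout, xp, W):
    c_out, D, H, Wd = gout.shape
    c_in = xp.shape[0]
    n = D * H * Wd
    g = gout.reshape(c_out, n)
    gW = np.zeros_like(W)
    gxp = np.zeros_like(xp)
    for k, (dz, dy, dx) in enumerate(_OFFSETS):
        view = xp[:, dz:dz + D, dy:dy + H, dx:dx + Wd].reshape(c_in, n)
        gW[:, :, dz, dy, dx] = g @ view.T
        gxp[:, dz:dz + D, dy:dy + H, dx:dx + Wd] += (
            W[:, :, dz, dy, dx].T @ g
        ).reshape(c_in, D, H, Wd)
    gb = g.sum(axis=1)
    return gxp[:, 1:-1, 1:-1, 1:-1], gW, gb


def _pool_forward(x):
    c, D, H, W = x.shape
    r = x.reshape(c, D // 2, 2, H // 2, 2, W // 2, 2)
    r = r.transpose(0, 1, 3, 5, 2, 4, 6).reshape(c, D // 2, H // 2, W // 2, 8)
    arg = r.argmax(axis=-1)
    out = np.take_along_axis(r, arg[..., None], axis=-1)[..., 0]
    return out, arg


def _pool_backward(gout, arg, in_shape):
    c, D, H, W = in_shape
    g = np.zeros((c, D // 2, H // 2, W // 2, 8), dtype=gout.dtype)
    np.put_along_axis(g, arg[..., None], gout[..., None], axis=-1)
    g = g.reshape(c, D // 2, H // 2, W // 2, 2, 2, 2)
    g = g.transpose(0, 1, 4, 2, 5, 3, 6).reshape(c, D, H, W)
    return g


def _upsample(x):
    return x.repeat(2, axis=1).repeat(2, axis=2).repeat(2, axis=3)


def _upsample_backward(g):
    c, D, H, W = g.shape
    return g.reshape(c, D // 2, 2, H // 2, 2, W // 2, 2).sum(axis=(2, 4, 6))


class UNet:
    """A parameterized skull-stripping U-Net (see module docstring)."""

    def __init__(self, spec: UNetSpec, seed: int = 0):
        self.spec = spec
        self.params: dict[str, np.ndarray] = {}
        rng = np.random.default_rng(seed)
        for name, c_in, c_out in spec.conv_plan():
            fan_in = c_in * 27
            w = rng.normal(0.0, np.sqrt(2.0 / fan_in), size=(c_out, c_in, 3, 3, 3))
            self.params[f"{name}.w"] = w.astype(np.float32)
            self.params[f"{name}.b"] = np.zeros(c_out, dtype=np.float32)
        self._cache = None

    # -- forward -----------------------------------------------------------
    def _lrelu(self, x):
        a = self.spec.leaky_slope
        return np.where(x > 0, x, a * x)

    def _conv_block(self, name, x, cache):
        W = self.params[f"{name}.w"]
        b = self.params[f"{name}.b"]
        pre, xp = _conv_forward(x, W, b)
        out = self._lrelu(pre)
        if cache is not None:
            cache.append((name, xp, pre))
        return out

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        """Run the network on a conformed image.

        ``x`` must match the spec's input shape, with intensities expected
        in [0, 1].  Returns the predicted SDT (D, H, W) in sdt mode, or
        per-voxel class probabilities (2, D, H, W) in dice mode.
        """
        spec = self.spec
        if x.shape != spec.input_shape:
            raise ValueError(f"input shape {x.shape} != {spec.input_shape}")
        x = np.asarray(x, dtype=np.float32)[None]
        cache = [] if train else None
        skips = []
        pool_args = []
        for lvl in range(spec.levels):
            for j in range(spec.convs_per_level):
                x = self._conv_block(f"enc{lvl}_conv{j}", x, cache)
            if lvl < spec.levels - 1:
                skips.append(x)
                x, arg = _pool_forward(x)
                pool_args.append((arg, None))
        for lvl in reversed(range(spec.levels - 1)):
            x = _upsample(x)
            skip = skips[lvl]
            x = np.concatenate([x, skip], axis=0)
            for j in range(spec.convs_per_level):
                x = self._conv_block(f"dec{lvl}_conv{j}", x, cache)
        W = self.params["head.w"]
        b = self.params["head.b"]
        out, xp = _conv_forward(x, W, b)
        if train:
            cache.append(("head", xp, None))
        if spec.head_mode == "sdt":
            result = out[0]
            if train:
                self._cache = (cache, skips, pool_args, None)
            return result.astype(np.float64) if not train else result
        # softmax over channels
        m = out.max(axis=0, keepdims=True)
        e = np.exp(out - m)
        probs = e / e.sum(axis=0, keepdims=True)
        if train:
            self._cache = (cache, skips, pool_args, probs)
        return probs if train else probs.astype(np.float64)

    # -- backward ----------------------------------------------------------
    def backward(self, gout: np.ndarray) -> dict:
        """Backpropagate a loss gradient through the last training forward.

        ``gout`` is dL/d(output): dL/d(SDT) in sdt mode, dL/d(probabilities)
        in dice mode (the softmax Jacobian is applied internally).  Returns
        a gradient dict keyed like :attr:`params`.
        """
        if self._cache is None:
            raise RuntimeError("backward requires a preceding forward(train=True)")
        cache, skips, pool_args, probs = self._cache
        spec = self.spec
        grads = {k: np.zeros_like(v) for k, v in self.params.items()}

        if spec.head_mode == "sdt":
            g = np.asarray(gout, dtype=np.float32)[None]
        else:
            gp = np.asarray(gout, dtype=np.float32)
            g = probs * (gp - (gp * probs).sum(axis=0, keepdims=True))

        cache = list(cache)
        a = spec.leaky_slope

        def pop_conv(g, with_act=True):
            name, xp, pre = cache.pop()
            if with_act:
                g = g * np.where(pre > 0, 1.0, a).astype(np.float32)
            _flush_subnormals(g)
            gx, gW, gb = _conv_backward(g, xp, self.params[f"{name}.w"])
            grads[f"{name}.w"] += gW
            grads[f"{name}.b"] += gb
            return _flush_subnormals(gx)

        g = pop_conv(g, with_act=False)  # head (linear)
        skip_grads = {}
        for lvl in range(spec.levels - 1):
            for j in range(spec.convs_per_level):
                g = pop_conv(g)
            n_up = g.shape[0] - skips[lvl].shape[0]
            g_skip = g[n_up:]
            skip_grads[lvl] = g_skip
            g = _upsample_backward(g[:n_up])
        for lvl in reversed(range(spec.levels)):
            if lvl < spec.levels - 1:
                arg, _ = pool_args[lvl]
                g = _pool_backward(g, arg, skips[lvl].shape)
                g = g + skip_grads[lvl]
            for j in range(spec.convs_per_level):
                g = pop_conv(g)
        self._cache = None
        return grads


def build_unet(spec: UNetSpec, seed: int = 0) -> UNet:
    """Instantiate a U-Net with He-initialized weights."""
    return UNet(spec, seed=seed)


def save_checkpoint(path, net: UNet, extra: dict | None = None):
    meta = dict(
        levels=net.spec.levels,
        convs_per_level=net.spec.convs_per_level,
        leaky_slope=net.spec.leaky_slope,
        encoder_filters=list(net.spec.encoder_filters),
        decoder_filters=list(net.spec.decoder_filters),
        head_mode=net.spec.head_mode,
        input_shape=list(net.spec.input_shape),
    )
    if extra:
        meta.update(extra)
    arrays = {f"param/{k}": v for k, v in net.params.items()}
    np.savez(path, __meta__=np.array(repr(meta)), **arrays)


def load_checkpoint(path) -> UNet:
    import ast

    data = np.load(path, allow_pickle=False)
    meta = ast.literal_eval(str(data["__meta__"]))
    spec = UNetSpec(
        levels=int(meta["levels"]),
        convs_per_level=int(meta["convs_per_level"]),
        leaky_slope=float(meta["leaky_slope"]),
        encoder_filters=tuple(meta["encoder_filters"]),
        decoder_filters=tuple(meta["decoder_filters"]),
        head_mode=meta["head_mode"],
        input_shape=tuple(meta["input_shape"]),
    )
    net = UNet(spec)
    for key in data.files:
        if key.startswith("param/"):
            net.params[key[len("param/"):]] = data[key]
    return net
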