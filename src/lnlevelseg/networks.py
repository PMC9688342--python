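"""Network architectures: residual 3D patch-UNet and 2.5D multi-view classifier.

Both networks are built from declarative specs.  The UNet maps a cubic
intensity patch to a per-voxel softmax over M classes (M = 6 for the direct
multi-class configuration, M = 2 for the foreground stage of the sequential
configuration).  The multi-view (MV) network classifies a single query voxel
from 3 context-pyramid scales x 3 orthogonal 2D views; with 32 in-plane
samples at 1.25 mm spacing and voxel strides 1/2/4, the scales span 4, 8 and
16 cm around the query voxel (M = 6 standalone, M = 5 when restricted to
UNet foreground).

Batch normalization follows every convolution, before the ReLU; dropout is
active only during training.  Weights use Glorot-uniform initialization from
a caller-provided seed, so two builds from the same seed are identical.
"""

from __future__ import annotations

import dataclasses
import json
import os

import numpy as np

from . import nn
from .volume_io import Volume

__all__ = [
    "UNetSpec", "MVSpec", "UNet3D", "MVNet", "build_unet", "build_mv",
    "extract_views", "extract_views_batch", "save_model", "load_model",
]


@dataclasses.dataclass(frozen=True)
class UNetSpec:
    patch_size: int = 64
    depth: int = 4                # encoder levels including the bottleneck
    base_filters: int = 16
    n_classes: int = 6
    dropout_p: float = 0.1

    def __post_init__(self):
        if self.n_classes < 2:
            raise ValueError("n_classes must be >= 2")
        if self.patch_size % (2 ** (self.depth - 1)) != 0:
            raise ValueError("patch_size must be divisible by 2^(depth-1)")


@dataclasses.dataclass(frozen=True)
class MVSpec:
    n_scales: int = 3
    in_plane_samples: int = 32
    strides: tuple[int, ...] = (1, 2, 4)
    filters: tuple[int, ...] = (16, 32, 64)
    fusion_units: int = 128
    n_classes: int = 6
    dropout_p: float = 0.1

    def __post_init__(self):
        if len(self.strides) != self.n_scales:
            raise ValueError("one stride per scale required")
        if self.in_plane_samples % (2 ** len(self.filters)) != 0:
            raise ValueError("in_plane_samples must survive the pooling stack")

    def span_mm(self, scale: int, spacing: float = 1.25) -> float:
        """Physical in-plane span of one view at a pyramid scale."""
        return self.in_plane_samples * self.strides[scale] * spacing


class _ResBlock3D(nn.Layer):
    """conv-BN-ReLU, conv-BN, identity/projection shortcut, ReLU."""

    def __init__(self, c_in: int, c_out: int, rng: np.random.Generator,
                 input_grad: bool = True):
        self.input_grad = input_grad
        self.conv1 = nn.Conv(c_in, c_out, 3, 3, rng, input_grad=input_grad)
        self.bn1 = nn.BatchNorm(c_out)
        self.relu1 = nn.ReLU()
        self.conv2 = nn.Conv(c_out, c_out, 3, 3, rng)
        self.bn2 = nn.BatchNorm(c_out)
        if c_in != c_out:
            self.proj = nn.Conv(c_in, c_out, 1, 3, rng, input_grad=input_grad)
            self.proj_bn = nn.BatchNorm(c_out)
        else:
            self.proj = None
        self.relu_out = nn.ReLU()

    def params(self):
        out = (self.conv1.params() + self.bn1.params() + self.conv2.params()
               + self.bn2.params())
        if self.proj is not None:
            out += self.proj.params() + self.proj_bn.params()
        return out

    def forward(self, x, train=False):
        h = self.relu1.forward(self.bn1.forward(self.conv1.forward(x, train), train), train)
        h = self.bn2.forward(self.conv2.forward(h, train), train)
        s = x if self.proj is None else self.proj_bn.forward(
            self.proj.forward(x, train), train)
        return self.relu_out.forward(h + s, train)

    def backward(self, gy):
        g = self.relu_out.backward(gy)
        # g feeds both the conv chain and the shortcut; BatchNorm.backward
        # consumes its input, so the chain gets its own copy
        if not hasattr(self, "_gbuf") or self._gbuf.shape != g.shape:
            self._gbuf = np.empty_like(g)
        np.copyto(self._gbuf, g)
        gh = self.conv1.backward(self.bn1.backward(self.relu1.backward(
            self.conv2.backward(self.bn2.backward(self._gbuf)))))
        if self.proj is None:
            gs = g
        else:
            gs = self.proj.backward(self.proj_bn.backward(g))
        if not self.input_grad:
            return None
        return gh + gs


class UNet3D:
    """Residual patch-UNet with per-voxel softmax output."""

    def __init__(self, spec: UNetSpec, seed: int = 0):
        self.spec = spec
        self.best_metric: float | None = None
        rng = np.random.default_rng(seed)
        self._drop_rng = np.random.default_rng(np.random.SeedSequence([seed, 1]))
        f = [spec.base_filters * 2 ** i for i in range(spec.depth)]
        self.enc = []
        c_in = 1
        for i in range(spec.depth - 1):
            self.enc.append(_ResBlock3D(c_in, f[i], rng, input_grad=i > 0))
            c_in = f[i]
        self._pools = [nn.MaxPool(3) for _ in self.enc]
        self.bottom = _ResBlock3D(c_in, f[-1], rng)
        self.dropout = nn.Dropout(spec.dropout_p, self._drop_rng)
        self.up = nn.Upsample3D()
        self.dec_compress = []
        self.dec = []
        for i in reversed(range(spec.depth - 1)):
            self.dec_compress.append(nn.Conv(f[i] + f[i + 1], f[i], 1, 3, rng))
            self.dec.append(_ResBlock3D(f[i], f[i], rng))
        self.head = nn.Conv(f[0], spec.n_classes, 1, 3, rng, bias=True)
        self.softmax = nn.Softmax()

    def params(self):
        out = []
        for b in self.enc:
            out += b.params()
        out += self.bottom.params()
        for c, b in zip(self.dec_compress, self.dec):
            out += c.params() + b.params()
        out += self.head.params()
        return out

    def forward(self, x, train=False):
        """x: (N, P, P, P) or (N, P, P, P, 1) -> (N, P, P, P, M) probabilities."""
        if x.ndim == 4:
            x = x[..., None]
        x = np.ascontiguousarray(x, np.float32)
        skips = []
        for blk, pool in zip(self.enc, self._pools):
            x = blk.forward(x, train)
            skips.append(x)
            x = pool.forward(x, train)
        x = self.bottom.forward(x, train)
        x = self.dropout.forward(x, train)
        for c, blk, skip in zip(self.dec_compress, self.dec, reversed(skips)):
            x = self.up.forward(x, train)
            x = np.concatenate([skip, x], axis=-1)
            x = blk.forward(c.forward(x, train), train)
        logits = self.head.forward(x, train)
        return self.softmax.forward(logits, train)

    def backward(self, gprob):
        g = self.softmax.backward(gprob.astype(np.float32))
        g = self.head.backward(g)
        gskips = []
        for c, blk in zip(reversed(self.dec_compress), reversed(self.dec)):
            g = c.backward(blk.backward(g))
            # channel split: [skip (f_i), upsampled (f_{i+1} = 2 f_i)]
            f_i = g.shape[-1] // 3
            gskips.append(g[..., :f_i])
            g = self.up.backward(np.ascontiguousarray(g[..., f_i:]))
        g = self.dropout.backward(g)
        g = self.bottom.backward(g)
        for i in reversed(range(len(self.enc))):
            g = self._pools[i].backward(g)
            gs = gskips[len(self.enc) - 1 - i]
            g = self.enc[i].backward(g + gs)
        return g

    def predict_proba(self, patches: np.ndarray) -> np.ndarray:
        return self.forward(patches, train=False)


def _branch(rng, filters, c_in=1):
    layers = []
    c = c_in
    for i, f in enumerate(filters):
        layers += [nn.Conv(c, f, 3, 2, rng, input_grad=i > 0),
                   nn.BatchNorm(f), nn.ReLU(), nn.MaxPool(2)]
        c = f
    layers.append(nn.Flatten())
    return nn.Sequential(layers)


class MVNet:
    """Multi-scale, multi-view voxel classifier (2.5D)."""

    def __init__(self, spec: MVSpec, seed: int = 0):
        self.spec = spec
        self.best_metric: float | None = None
        rng = np.random.default_rng(seed)
        self._drop_rng = np.random.default_rng(np.random.SeedSequence([seed, 1]))
        # independent weights per (scale, view) branch
        self.branches = [[_branch(rng, spec.filters) for _ in range(3)]
                         for _ in range(spec.n_scales)]
        side = spec.in_plane_samples // (2 ** len(spec.filters))
        feat = spec.filters[-1] * side * side
        self._feat = feat
        self.fusion = nn.Dense(3 * spec.n_scales * feat, spec.fusion_units, rng)
        self.fusion_relu = nn.ReLU()
        self.dropout = nn.Dropout(spec.dropout_p, self._drop_rng)
        self.head = nn.Dense(spec.fusion_units, spec.n_classes, rng)
        self.softmax = nn.Softmax()

    def params(self):
        out = []
        for scale in self.branches:
            for b in scale:
                out += b.params()
        out += self.fusion.params() + self.head.params()
        return out

    def forward(self, views: np.ndarray, train=False) -> np.ndarray:
        """views: (N, n_scales, 3, S, S) -> (N, M) class probabilities."""
        feats = []
        for s, scale in enumerate(self.branches):
            for v, branch in enumerate(scale):
                x = np.ascontiguousarray(views[:, s, v, :, :, None], np.float32)
                feats.append(branch.forward(x, train))
        h = np.concatenate(feats, axis=1)
        h = self.fusion_relu.forward(self.fusion.forward(h, train), train)
        h = self.dropout.forward(h, train)
        return self.softmax.forward(self.head.forward(h, train), train)

    def backward(self, gprob):
        g = self.softmax.backward(gprob.astype(np.float32))
        g = self.head.backward(g)
        g = self.dropout.backward(g)
        g = self.fusion.backward(self.fusion_relu.backward(g))
        k = 0
        for scale in self.branches:
            for branch in scale:
                branch.backward(np.ascontiguousarray(
                    g[:, k * self._feat:(k + 1) * self._feat]))
                k += 1

    def predict_proba(self, views: np.ndarray) -> np.ndarray:
        return self.forward(views, train=False)


def build_unet(spec: UNetSpec, seed: int = 0) -> UNet3D:
    return UNet3D(spec, seed)


def build_mv(spec: MVSpec, seed: int = 0) -> MVNet:
    return MVNet(spec, seed)


def extract_views_batch(data: np.ndarray, centers: np.ndarray,
                        spec: MVSpec) -> np.ndarray:
    """Extract view sets for many query voxels at once.

    data: 3D (normalized) intensity grid; centers: (K, 3) voxel indices.
    Returns (K, n_scales, 3, S, S) with edge-replication at the borders.
    """
    centers = np.atleast_2d(np.asarray(centers, int))
    k = centers.shape[0]
    s_len = spec.in_plane_samples
    out = np.empty((k, spec.n_scales, 3, s_len, s_len), np.float32)
    half = s_len // 2
    base = np.arange(s_len) - half
    shape = data.shape
    for s in range(spec.n_scales):
        off = base * spec.strides[s]
        ix = np.clip(centers[:, 0, None] + off, 0, shape[0] - 1)
        iy = np.clip(centers[:, 1, None] + off, 0, shape[1] - 1)
        iz = np.clip(centers[:, 2, None] + off, 0, shape[2] - 1)
        cx = np.clip(centers[:, 0], 0, shape[0] - 1)
        cy = np.clip(centers[:, 1], 0, shape[1] - 1)
        cz = np.clip(centers[:, 2], 0, shape[2] - 1)
        # axial: (x, y) at fixed z
        out[:, s, 0] = data[ix[:, :, None], iy[:, None, :], cz[:, None, None]]
        # sagittal: (y, z) at fixed x
        out[:, s, 1] = data[cx[:, None, None], iy[:, :, None], iz[:, None, :]]
        # coronal: (x, z) at fixed y
        out[:, s, 2] = data[ix[:, :, None], cy[:, None, None], iz[:, None, :]]
    return out


def extract_views(vol: Volume | np.ndarray, voxel, spec: MVSpec) -> np.ndarray:
    """View set (n_scales, 3, S, S) for one query voxel."""
    data = vol.data if isinstance(vol, Volume) else np.asarray(vol)
    voxel = tuple(int(v) for v in voxel)
    if not all(0 <= voxel[a] < data.shape[a] for a in range(3)):
        raise ValueError(f"voxel {voxel} outside volume {data.shape}")
    return extract_views_batch(data, np.asarray([voxel]), spec)[0]


# -- checkpoints ---------------------------------------------------------

def save_model(model: UNet3D | MVNet, path: str | os.PathLike) -> str:
    spec = model.spec
    meta = {
        "kind": "unet" if isinstance(model, UNet3D) else "mv",
        "spec": dataclasses.asdict(spec),
        "best_metric": model.best_metric,
    }
    arrays = {f"p{i}": p.value for i, p in enumerate(model.params())}
    np.savez(os.fspath(path), meta=json.dumps(meta), **arrays)
    return os.fspath(path)


def load_model(path: str | os.PathLike) -> UNet3D | MVNet:
    with np.load(os.fspath(path), allow_pickle=False) as f:
        meta = json.loads(str(f["meta"]))
        spec_d = meta["spec"]
        for key in ("strides", "filters", "shape"):
            if key in spec_d and isinstance(spec_d[key], list):
                spec_d[key] = tuple(spec_d[key])
        if meta["kind"] == "unet":
            model = UNet3D(UNetSpec(**spec_d))
        else:
            model = MVNet(MVSpec(**spec_d))
        for i, p in enumerate(model.params()):
            p.value[...] = f[f"p{i}"]
    model.best_metric = meta["best_metric"]
    return model
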