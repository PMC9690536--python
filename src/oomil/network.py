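"""The instance-scoring CNN: Conv(5x5,10) -> ReLU -> MaxPool(2) ->
Conv(3x3,20) -> ReLU -> flatten -> FC(500) -> ReLU -> head.

Two interchangeable heads: a 1-neuron scalar head for ordinal scoring
(default) and a 3-neuron softmax head for the cross-entropy baseline.
Forward and backward passes are written directly in numpy (channels-last,
im2col convolutions); closed-form shape and parameter-count calculators
double as independent oracles for the implementation.

With the default spec the derived feature-map sides are 220 (conv1),
110 (pool) and 108 (conv2), and the per-layer parameter counts are
260, 1820, 116,640,500 and 501 (ordinal head).
"""

from __future__ import annotations


import json
from dataclasses import dataclass, asdict
from typing import Dict, Optional, Tuple

import numpy as np

__all__ = [
    "NetworkSpec",
    "OrdinalCNN",
    "layer_output_side",
    "layer_param_count",
    "build_network",
    "forward_bag",
]

_HEADS = ("ordinal_scalar", "softmax3")
_INIT_MODES = ("standard", "zero")


def layer_output_side(in_side: int, kernel: int, stride: int = 1, pad: int = 0) -> int:
    """Spatial output side of a conv/pool layer: floor((n + 2p - k)/s) + 1."""
    if stride < 1:
        raise ValueError("stride must be >= 1")
    if kernel > in_side + 2 * pad:
        raise ValueError(f"kernel {kernel} larger than padded input {in_side + 2 * pad}")
    return (in_side + 2 * pad - kernel) // stride + 1


def layer_param_count(layer) -> int:
    """Trainable parameter count for a layer descriptor (bias included).

    Descriptors: ``("conv", kernel, in_channels, out_channels)``,
    ``("fc", in_units, out_units)``, or any of ``("input",)``, ``("relu",)``,
    ``("maxpool",)`` / ``("pool",)`` which hold no parameters.
    """
    kind = layer[0]
    if kind == "conv":
        _, k, cin, cout = layer
        if min(k, cin, cout) <= 0:
            raise ValueError("conv dimensions must be positive")
        return k * k * cin * cout + cout
    if kind == "fc":
        _, nin, nout = layer
        if min(nin, nout) <= 0:
            raise ValueError("fc dimensions must be positive")
        return nin * nout + nout
    if kind in ("input", "relu", "maxpool", "pool"):
        return 0
    raise ValueError(f"unknown layer kind {kind!r}")


@dataclass
class NetworkSpec:
    input_side: int = 224
    conv1_filters: int = 10
    conv1_kernel: int = 5
    pool_kernel: int = 2
    pool_stride: int = 2
    conv2_filters: int = 20
    conv2_kernel: int = 3
    fc1_units: int = 500
    head: str = "ordinal_scalar"
    init_mode: str = "standard"

    def validate(self) -> None:
        if self.head not in _HEADS:
            raise ValueError(f"head must be one of {_HEADS}")
        if self.init_mode not in _INIT_MODES:
            raise ValueError(f"init_mode must be one of {_INIT_MODES}")
        if self.pool_kernel != self.pool_stride:
            raise ValueError("only non-overlapping pooling (kernel == stride) is supported")
        side = layer_output_side(self.input_side, self.conv1_kernel)
        if side % self.pool_stride != 0:
            raise ValueError("conv1 output side must be divisible by the pool stride")
        layer_output_side(side // self.pool_stride, self.conv2_kernel)

    @property
    def out_dim(self) -> int:
        return 1 if self.head == "ordinal_scalar" else 3

    def sides(self) -> Tuple[int, int, int]:
        """(conv1 out, pool out, conv2 out) spatial sides."""
        s1 = layer_output_side(self.input_side, self.conv1_kernel)
        sp = s1 // self.pool_stride
        s2 = layer_output_side(sp, self.conv2_kernel)
        return s1, sp, s2

    @property
    def flat_dim(self) -> int:
        return self.sides()[2] ** 2 * self.conv2_filters


# ---------------------------------------------------------------------------
# conv / pool primitives (channels-last, stride 1, no padding)


def _conv_forward(x: np.ndarray, w: np.ndarray, b: np.ndarray, want_cols: bool = False):
    n, h, wd, cin = x.shape
    kh, kw, _, cout = w.shape
    ho, wo = h - kh + 1, wd - kw + 1
    cols = np.empty((n, ho, wo, kh * kw * cin), dtype=np.float32)
    k = 0
    for di in range(kh):
        for dj in range(kw):
            cols[..., k * cin : (k + 1) * cin] = x[:, di : di + ho, dj : dj + wo, :]
            k += 1
    out = cols.reshape(-1, kh * kw * cin) @ w.reshape(-1, cout)
    out += b
    out = out.reshape(n, ho, wo, cout)
    return (out, cols) if want_cols else (out, None)


def _conv_backward(cols: np.ndarray, w: np.ndarray, dout: np.ndarray, in_shape, need_dx: bool):
    n, ho, wo, cout = dout.shape
    kh, kw, cin, _ = w.shape
    dflat = dout.reshape(-1, cout)
    dw = (cols.reshape(-1, kh * kw * cin).T @ dflat).reshape(w.shape)
    db = dflat.sum(axis=0)
    dx = None
    if need_dx:
        dcols = (dflat @ w.reshape(-1, cout).T).reshape(n, ho, wo, kh * kw * cin)
        dx = np.zeros(in_shape, dtype=np.float32)
        k = 0
        for di in range(kh):
            for dj in range(kw):
                dx[:, di : di + ho, dj : dj + wo, :] += dcols[..., k * cin : (k + 1) * cin]
                k += 1
    return dw, db, dx


def _pool_forward(x: np.ndarray, m: int, want_idx: bool = False):
    n, h, w, c = x.shape
    ho, wo = h // m, w // m
    xt = x.reshape(n, ho, m, wo, m, c).transpose(0, 1, 3, 5, 2, 4).reshape(n, ho, wo, c, m * m)
    if not want_idx:
        return xt.max(axis=-1), None
    idx = xt.argmax(axis=-1)
    out = np.take_along_axis(xt, idx[..., None], axis=-1)[..., 0]
    return out, idx


def _pool_backward(idx: np.ndarray, dout: np.ndarray, m: int, in_shape):
    n, ho, wo, c = dout.shape
    dxt = np.zeros((n, ho, wo, c, m * m), dtype=np.float32)
    np.put_along_axis(dxt, idx[..., None], dout[..., None], axis=-1)
    return (
        dxt.reshape(n, ho, wo, c, m, m).transpose(0, 1, 4, 2, 5, 3).reshape(in_shape)
    )


def _softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


class OrdinalCNN:
    """The scoring network.  Parameters live in ``self.params`` (float32)."""

    def __init__(self, spec: NetworkSpec, params: Dict[str, np.ndarray]):
        spec.validate()
        self.spec = spec
        self.params = params
        expected = {k: v for k, v in self._param_shapes(spec).items()}
        for name, shape in expected.items():
            if name not in params or params[name].shape != shape:
                raise ValueError(f"parameter {name!r} missing or mis-shaped (want {shape})")

    # -- construction -------------------------------------------------------

    @staticmethod
    def _param_shapes(spec: NetworkSpec) -> Dict[str, tuple]:
        return {
            "conv1_w": (spec.conv1_kernel, spec.conv1_kernel, 1, spec.conv1_filters),
            "conv1_b": (spec.conv1_filters,),
            "conv2_w": (spec.conv2_kernel, spec.conv2_kernel, spec.conv1_filters, spec.conv2_filters),
            "conv2_b": (spec.conv2_filters,),
            "fc1_w": (spec.flat_dim, spec.fc1_units),
            "fc1_b": (spec.fc1_units,),
            "head_w": (spec.fc1_units, spec.out_dim),
            "head_b": (spec.out_dim,),
        }

    @classmethod
    def build(cls, spec: NetworkSpec, seed: int = 0) -> "OrdinalCNN":
        spec.validate()
        rng = np.random.default_rng(seed)
        params = {}
        for name, shape in cls._param_shapes(spec).items():
            if name.endswith("_b") or spec.init_mode == "zero":
                params[name] = np.zeros(shape, dtype=np.float32)
            else:
                if name.startswith("conv"):
                    fan_in = shape[0] * shape[1] * shape[2]
                else:
                    fan_in = shape[0]
                std = np.float32(np.sqrt(2.0 / fan_in))
                params[name] = rng.standard_normal(size=shape, dtype=np.float32) * std
        return cls(spec, params)

    # -- introspection ------------------------------------------------------

    def layer_table(self):
        """Per-layer (name, output_side_or_units, parameter_count) rows."""
        s1, sp, s2 = self.spec.sides()
        p = self.params
        return [
            ("Input", self.spec.input_side, 0),
            ("Conv1", s1, p["conv1_w"].size + p["conv1_b"].size),
            ("Relu", s1, 0),
            ("MaxPool", sp, 0),
            ("Conv2", s2, p["conv2_w"].size + p["conv2_b"].size),
            ("Relu", s2, 0),
            ("FC1", self.spec.fc1_units, p["fc1_w"].size + p["fc1_b"].size),
            ("FC2", self.spec.out_dim, p["head_w"].size + p["head_b"].size),
        ]

    def param_count(self) -> int:
        return int(sum(v.size for v in self.params.values()))

    # -- forward / backward -------------------------------------------------

    def _check_input(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=np.float32)
        if x.ndim == 2:
            x = x[None]
        side = self.spec.input_side
        if x.ndim != 3 or x.shape[1:] != (side, side):
            raise ValueError(f"expected (n, {side}, {side}) input, got {x.shape}")
        return x

    def forward(self, x: np.ndarray, want_cache: bool = False, chunk: int = 16):
        """Map instances ``(n, side, side)`` to head outputs.

        Ordinal head: scalar scores ``(n,)``.  Softmax head: probability
        rows ``(n, 3)``.  With ``want_cache=True`` the intermediates needed
        by :meth:`backward` are kept (use small batches).
        """
        x = self._check_input(x)
        if not want_cache and x.shape[0] > chunk:
            return np.concatenate(
                [self.forward(x[i : i + chunk]) for i in range(0, x.shape[0], chunk)], axis=0
            )
        p = self.params
        x0 = x[..., None]  # NHWC with C=1
        z1, cols1 = _conv_forward(x0, p["conv1_w"], p["conv1_b"], want_cols=want_cache)
        mask1 = z1 > 0
        a1 = z1 * mask1
        pool, idx = _pool_forward(a1, self.spec.pool_stride, want_idx=want_cache)
        z2, cols2 = _conv_forward(pool, p["conv2_w"], p["conv2_b"], want_cols=want_cache)
        mask2 = z2 > 0
        a2 = z2 * mask2
        flat = a2.reshape(a2.shape[0], -1)
        zf = flat @ p["fc1_w"] + p["fc1_b"]
        maskf = zf > 0
        af = zf * maskf
        preact = af @ p["head_w"] + p["head_b"]
        if want_cache:
            self._cache = {
                "x0_shape": x0.shape,
                "cols1": cols1,
                "mask1": mask1,
                "idx": idx,
                "a1_shape": a1.shape,
                "pool_shape": pool.shape,
                "cols2": cols2,
                "mask2": mask2,
                "flat": flat,
                "maskf": maskf,
                "af": af,
                "preact": preact,
            }
        if self.spec.head == "ordinal_scalar":
            return preact[:, 0]
        return _softmax(preact)

    def backward(self, d_preact: np.ndarray) -> Dict[str, np.ndarray]:
        """Gradients of a scalar objective w.r.t. all parameters.

        ``d_preact`` is the gradient w.r.t. the head pre-activation,
        shape ``(n, out_dim)``.  Requires a preceding ``forward(...,
        want_cache=True)`` on the same inputs.
        """
        c = self._cache
        p = self.params
        d_preact = np.asarray(d_preact, dtype=np.float32)
        grads = {}
        grads["head_w"] = c["af"].T @ d_preact
        grads["head_b"] = d_preact.sum(axis=0)
        daf = d_preact @ p["head_w"].T
        dzf = daf * c["maskf"]
        grads["fc1_w"] = c["flat"].T @ dzf
        grads["fc1_b"] = dzf.sum(axis=0)
        dflat = dzf @ p["fc1_w"].T
        da2 = dflat.reshape(c["mask2"].shape)
        dz2 = da2 * c["mask2"]
        dw2, db2, dpool = _conv_backward(
            c["cols2"], p["conv2_w"], dz2, c["pool_shape"], need_dx=True
        )
        grads["conv2_w"], grads["conv2_b"] = dw2, db2
        da1 = _pool_backward(c["idx"], dpool, self.spec.pool_stride, c["a1_shape"])
        dz1 = da1 * c["mask1"]
        dw1, db1, _ = _conv_backward(c["cols1"], p["conv1_w"], dz1, c["x0_shape"], need_dx=False)
        grads["conv1_w"], grads["conv1_b"] = dw1, db1
        return grads

    def __call__(self, x: np.ndarray):
        return self.forward(x)

    # -- persistence --------------------------------------------------------

    def save(self, path) -> None:
        """Single-archive checkpoint: parameter arrays + the spec as JSON."""
        meta = np.frombuffer(json.dumps(asdict(self.spec)).encode(), dtype=np.uint8)
        np.savez(path, __spec_json__=meta, **self.params)

    @classmethod
    def load(cls, path) -> "OrdinalCNN":
        with np.load(path) as data:
            spec = NetworkSpec(**json.loads(bytes(data["__spec_json__"]).decode()))
            params = {k: data[k] for k in data.files if k != "__spec_json__"}
        return cls(spec, params)


def save_checkpoint(path, net: OrdinalCNN, cuts=None) -> None:
    """Checkpoint = parameter arrays + spec JSON (+ cutpoints if given)."""
    meta = np.frombuffer(json.dumps(asdict(net.spec)).encode(), dtype=np.uint8)
    extra = {}
    if cuts is not None:
        extra["__cutpoints__"] = np.array([cuts.b1, cuts.delta], dtype=np.float64)
    np.savez(path, __spec_json__=meta, **extra, **net.params)


def load_checkpoint(path):
    """Inverse of :func:`save_checkpoint`; returns ``(net, cuts_or_None)``."""
    from .losses import OrdinalCutpoints

    with np.load(path) as data:
        spec = NetworkSpec(**json.loads(bytes(data["__spec_json__"]).decode()))
        params = {k: data[k] for k in data.files if not k.startswith("__")}
        cuts = None
        if "__cutpoints__" in data.files:
            b1, delta = data["__cutpoints__"]
            cuts = OrdinalCutpoints(b1=float(b1), delta=float(delta))
    return OrdinalCNN(spec, params), cuts


def build_network(spec: Optional[NetworkSpec] = None, seed: int = 0) -> OrdinalCNN:
    """Construct the scoring network from a spec (default: the full stack)."""
    return OrdinalCNN.build(spec or NetworkSpec(), seed=seed)


def forward_bag(net: OrdinalCNN, bag) -> np.ndarray:
    """Score every instance of a bag, order-preserving."""
    x = np.stack([inst.pixels for inst in bag.instances])
    return net.forward(x)
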