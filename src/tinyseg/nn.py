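"""A small numpy execution engine for the architecture specs.

The engine interprets a :class:`~tinyseg.archspec.ModelSpec` directly:
parameters live in a plain ``{layer_name: {array_name: ndarray}}`` tree,
the forward pass walks the layer DAG, and ``backward`` replays it in
reverse to produce gradients of the same tree shape.  Everything runs in
float32, NHWC layout, on the CPU.

Conventions
-----------
* Dense convolutions store ``kernel`` with shape (kh, kw, Cin, Cout) and
  an optional ``bias`` (Cout,).  All convolutions are "same"-padded,
  stride 1, odd kernels.
* Separable convolutions store ``depthwise`` (kh, kw, Cin) — depth
  multiplier fixed at 1 — plus ``pointwise`` (Cin, Cout) and ``bias``.
* Batch norm stores ``gamma``, ``beta`` (trainable) and
  ``moving_mean``, ``moving_var`` (updated with momentum 0.9 during
  training, used at inference).
* 2x2 stride-2 max pooling records, for every output position and
  channel, which of the four pooled inputs was the maximum; unpooling
  scatters values back to those positions.  When the unpooled tensor
  carries ``m`` times the channels of the recorded indices, channel
  ``c`` reuses the indices of channel ``c mod Cidx``.
* ``pixel_shuffle`` maps channel ``(dr*r + dc)*Cout + co`` of input
  position (i, j) to output position (i*r+dr, j*r+dc), channel ``co``.
"""

from __future__ import annotations

from functools import lru_cache

import numpy as np

from .archspec import LayerSpec, ModelSpec

__all__ = ["init_params", "check_params", "forward", "backward", "predict"]

_BN_EPS = 1e-5
_BN_MOMENTUM = 0.9


class ShapeMismatchError(ValueError):
    """Weights do not match the architecture; names the offending layer."""


# ---------------------------------------------------------------------------
# parameter initialisation


def init_params(spec: ModelSpec, rng: np.random.Generator | int | None = 0) -> dict:
    """Glorot-uniform weights (zero biases, unit-variance BN) for a spec."""
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)

    def glorot(shape, fan_in, fan_out):
        limit = np.sqrt(6.0 / (fan_in + fan_out))
        return rng.uniform(-limit, limit, size=shape).astype(np.float32)

    params: dict[str, dict[str, np.ndarray]] = {}
    for layer in spec.layers:
        if layer.kind == "conv2d":
            kh, kw = layer.kernel
            cin, cout = layer.channels_in, layer.channels_out
            p = {"kernel": glorot((kh, kw, cin, cout), kh * kw * cin, kh * kw * cout)}
            if layer.has_bias:
                p["bias"] = np.zeros(cout, np.float32)
            params[layer.name] = p
        elif layer.kind == "separable_conv2d":
            kh, kw = layer.kernel
            cin, cout = layer.channels_in, layer.channels_out
            p = {
                "depthwise": glorot((kh, kw, cin), kh * kw, kh * kw),
                "pointwise": glorot((cin, cout), cin, cout),
            }
            if layer.has_bias:
                p["bias"] = np.zeros(cout, np.float32)
            params[layer.name] = p
        elif layer.kind == "batchnorm":
            c = layer.channels_out
            params[layer.name] = {
                "gamma": np.ones(c, np.float32),
                "beta": np.zeros(c, np.float32),
                "moving_mean": np.zeros(c, np.float32),
                "moving_var": np.ones(c, np.float32),
            }
    return params


def _expected_shapes(layer: LayerSpec) -> dict[str, tuple]:
    if layer.kind == "conv2d":
        kh, kw = layer.kernel
        shapes = {"kernel": (kh, kw, layer.channels_in, layer.channels_out)}
        if layer.has_bias:
            shapes["bias"] = (layer.channels_out,)
        return shapes
    if layer.kind == "separable_conv2d":
        kh, kw = layer.kernel
        shapes = {
            "depthwise": (kh, kw, layer.channels_in),
            "pointwise": (layer.channels_in, layer.channels_out),
        }
        if layer.has_bias:
            shapes["bias"] = (layer.channels_out,)
        return shapes
    if layer.kind == "batchnorm":
        c = (layer.channels_out,)
        return {"gamma": c, "beta": c, "moving_mean": c, "moving_var": c}
    return {}


def check_params(spec: ModelSpec, params: dict) -> None:
    """Raise :class:`ShapeMismatchError` naming the first offending layer."""
    for layer in spec.layers:
        expected = _expected_shapes(layer)
        if not expected:
            continue
        have = params.get(layer.name)
        if have is None:
            raise ShapeMismatchError(f"layer {layer.name!r}: weights missing")
        for key, shape in expected.items():
            arr = have.get(key)
            if arr is None or tuple(arr.shape) != shape:
                got = None if arr is None else tuple(arr.shape)
                raise ShapeMismatchError(
                    f"layer {layer.name!r}: array {key!r} has shape {got}, "
                    f"expected {shape}"
                )


# ---------------------------------------------------------------------------
# layer primitives (forward + vector-Jacobian products)


def _pad(x, ph, pw):
    if ph == 0 and pw == 0:
        return x
    return np.pad(x, ((0, 0), (ph, ph), (pw, pw), (0, 0)))


def conv2d_forward(x, kernel, bias=None):
    kh, kw = kernel.shape[:2]
    ph, pw = (kh - 1) // 2, (kw - 1) // 2
    n, h, w, _ = x.shape
    if kh == kw == 1:
        y = x @ kernel[0, 0]
    else:
        xp = _pad(x, ph, pw)
        y = np.zeros((n, h, w, kernel.shape[3]), x.dtype)
        for i in range(kh):
            for j in range(kw):
                y += xp[:, i : i + h, j : j + w, :] @ kernel[i, j]
    if bias is not None:
        y += bias
    return y


def conv2d_backward(x, kernel, g):
    kh, kw = kernel.shape[:2]
    ph, pw = (kh - 1) // 2, (kw - 1) // 2
    n, h, w, _ = x.shape
    dk = np.empty_like(kernel)
    if kh == kw == 1:
        dk[0, 0] = np.tensordot(x, g, axes=([0, 1, 2], [0, 1, 2]))
        dx = g @ kernel[0, 0].T
    else:
        xp = _pad(x, ph, pw)
        dxp = np.zeros_like(xp)
        for i in range(kh):
            for j in range(kw):
                xs = xp[:, i : i + h, j : j + w, :]
                dk[i, j] = np.tensordot(xs, g, axes=([0, 1, 2], [0, 1, 2]))
                dxp[:, i : i + h, j : j + w, :] += g @ kernel[i, j].T
        dx = dxp[:, ph : ph + h, pw : pw + w, :]
    db = g.sum(axis=(0, 1, 2))
    return dx, dk, db


def depthwise_forward(x, kernel):
    kh, kw = kernel.shape[:2]
    ph, pw = (kh - 1) // 2, (kw - 1) // 2
    n, h, w, c = x.shape
    xp = _pad(x, ph, pw)
    y = np.zeros_like(x)
    for i in range(kh):
        for j in range(kw):
            y += xp[:, i : i + h, j : j + w, :] * kernel[i, j]
    return y


def depthwise_backward(x, kernel, g):
    kh, kw = kernel.shape[:2]
    ph, pw = (kh - 1) // 2, (kw - 1) // 2
    n, h, w, c = x.shape
    xp = _pad(x, ph, pw)
    dk = np.empty_like(kernel)
    dxp = np.zeros_like(xp)
    for i in range(kh):
        for j in range(kw):
            xs = xp[:, i : i + h, j : j + w, :]
            dk[i, j] = np.einsum("nhwc,nhwc->c", xs, g)
            dxp[:, i : i + h, j : j + w, :] += g * kernel[i, j]
    return dxp[:, ph : ph + h, pw : pw + w, :], dk


def maxpool_forward(x):
    n, h, w, c = x.shape
    xr = (
        x.reshape(n, h // 2, 2, w // 2, 2, c)
        .transpose(0, 1, 3, 5, 2, 4)
        .reshape(n, h // 2, w // 2, c, 4)
    )
    idx = xr.argmax(axis=-1).astype(np.int8)
    y = np.take_along_axis(xr, idx[..., None].astype(np.intp), -1)[..., 0]
    return y, idx


def maxpool_backward(g, idx, in_shape):
    n, h, w, c = in_shape
    z = np.zeros((n, h // 2, w // 2, c, 4), g.dtype)
    np.put_along_axis(z, idx[..., None].astype(np.intp), g[..., None], -1)
    return (
        z.reshape(n, h // 2, w // 2, c, 2, 2)
        .transpose(0, 1, 4, 2, 5, 3)
        .reshape(n, h, w, c)
    )


def _broadcast_indices(idx, channels):
    cidx = idx.shape[-1]
    if channels == cidx:
        return idx
    if channels % cidx:
        raise ValueError(
            f"cannot broadcast {cidx} index channels to {channels} data channels"
        )
    return np.tile(idx, (1, 1, 1, channels // cidx))


def unpool_forward(x, idx):
    n, h, w, c = x.shape
    idx = _broadcast_indices(idx, c)
    z = np.zeros((n, h, w, c, 4), x.dtype)
    np.put_along_axis(z, idx[..., None].astype(np.intp), x[..., None], -1)
    return (
        z.reshape(n, h, w, c, 2, 2).transpose(0, 1, 4, 2, 5, 3).reshape(n, 2 * h, 2 * w, c)
    )


def unpool_backward(g, idx, channels):
    n, h2, w2, c = g.shape
    idx = _broadcast_indices(idx, channels)
    gr = (
        g.reshape(n, h2 // 2, 2, w2 // 2, 2, c)
        .transpose(0, 1, 3, 5, 2, 4)
        .reshape(n, h2 // 2, w2 // 2, c, 4)
    )
    return np.take_along_axis(gr, idx[..., None].astype(np.intp), -1)[..., 0]


@lru_cache(maxsize=None)
def _bilinear_matrix(size: int, factor: int) -> np.ndarray:
    """Row-stochastic (size*factor, size) linear upsampling operator.

    Output sample i is taken at source coordinate (i + 0.5)/factor - 0.5
    (half-pixel-centre convention), linearly interpolated and clamped at
    the borders.
    """
    out = size * factor
    u = np.zeros((out, size), np.float32)
    for i in range(out):
        src = (i + 0.5) / factor - 0.5
        i0 = int(np.floor(src))
        t = src - i0
        a = min(max(i0, 0), size - 1)
        b = min(max(i0 + 1, 0), size - 1)
        u[i, a] += 1.0 - t
        u[i, b] += t
    return u


def upsample_bilinear_forward(x, factor):
    n, h, w, c = x.shape
    uh = _bilinear_matrix(h, factor)
    uw = _bilinear_matrix(w, factor)
    y = np.tensordot(uh, x, axes=(1, 1)).transpose(1, 0, 2, 3)
    y = np.tensordot(uw, y, axes=(1, 2)).transpose(1, 2, 0, 3)
    return np.ascontiguousarray(y, dtype=x.dtype)


def upsample_bilinear_backward(g, in_hw, factor):
    h, w = in_hw
    uh = _bilinear_matrix(h, factor)
    uw = _bilinear_matrix(w, factor)
    y = np.tensordot(uh.T, g, axes=(1, 1)).transpose(1, 0, 2, 3)
    y = np.tensordot(uw.T, y, axes=(1, 2)).transpose(1, 2, 0, 3)
    return np.ascontiguousarray(y, dtype=g.dtype)


def pixel_shuffle_forward(x, r):
    n, h, w, c = x.shape
    co = c // (r * r)
    return (
        x.reshape(n, h, w, r, r, co)
        .transpose(0, 1, 3, 2, 4, 5)
        .reshape(n, h * r, w * r, co)
    )


def pixel_shuffle_backward(g, r):
    n, hr, wr, co = g.shape
    h, w = hr // r, wr // r
    return (
        g.reshape(n, h, r, w, r, co)
        .transpose(0, 1, 3, 2, 4, 5)
        .reshape(n, h, w, co * r * r)
    )


def softmax_channels(x):
    z = x - x.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


# ---------------------------------------------------------------------------
# graph execution


def forward(
    spec: ModelSpec,
    params: dict,
    x: np.ndarray,
    *,
    training: bool = False,
    keep_cache: bool = False,
    stop_before: str | None = None,
):
    """Run the network.

    Returns ``(output, cache)``; ``cache`` is ``None`` unless
    ``keep_cache``.  With ``training`` batch norm uses batch statistics
    (and updates its moving statistics in place).  ``stop_before`` halts
    execution just before the named layer (used to train against logits
    with a fused softmax/cross-entropy).
    """
    if x.dtype != np.float64:
        x = np.ascontiguousarray(x, dtype=np.float32)
    values: dict[str, np.ndarray] = {"__input__": x}
    cache: dict[str, tuple] = {"__order__": []} if keep_cache else None
    prev = "__input__"
    out = x
    for layer in spec.layers:
        if layer.name == stop_before:
            break
        ins = layer.inputs or (prev,)
        a = values[ins[0]]
        kind = layer.kind
        p = params.get(layer.name, {})
        if kind == "conv2d":
            out = conv2d_forward(a, p["kernel"], p.get("bias"))
            entry = (ins, (a,))
        elif kind == "separable_conv2d":
            mid = depthwise_forward(a, p["depthwise"])
            out = conv2d_forward(mid, p["pointwise"][None, None], p.get("bias"))
            entry = (ins, (a, mid))
        elif kind == "batchnorm":
            if training:
                mu = a.mean(axis=(0, 1, 2))
                var = a.var(axis=(0, 1, 2))
                p["moving_mean"] *= _BN_MOMENTUM
                p["moving_mean"] += (1 - _BN_MOMENTUM) * mu
                p["moving_var"] *= _BN_MOMENTUM
                p["moving_var"] += (1 - _BN_MOMENTUM) * var
            else:
                mu, var = p["moving_mean"], p["moving_var"]
            invstd = 1.0 / np.sqrt(var + _BN_EPS)
            xhat = (a - mu) * invstd
            out = p["gamma"] * xhat + p["beta"]
            entry = (ins, (xhat, invstd, training))
        elif kind == "relu":
            out = np.maximum(a, 0.0)
            entry = (ins, (out,))
        elif kind in ("maxpool", "maxpool_with_indices"):
            out, idx = maxpool_forward(a)
            entry = (ins, (idx, a.shape))
        elif kind == "unpool_with_indices":
            idx = cache[ins[1]][1][0] if cache is not None else values[ins[1] + "/idx"]
            out = unpool_forward(a, idx)
            entry = (ins, (idx, a.shape[-1]))
        elif kind == "upsample_bilinear":
            out = upsample_bilinear_forward(a, layer.factor)
            entry = (ins, (a.shape[1:3],))
        elif kind == "pixel_shuffle":
            out = pixel_shuffle_forward(a, layer.factor)
            entry = (ins, ())
        elif kind == "add":
            out = a + values[ins[1]]
            entry = (ins, ())
        elif kind == "softmax":
            out = softmax_channels(a)
            entry = (ins, (out,))
        else:  # pragma: no cover - kinds not emitted by the builders
            raise NotImplementedError(f"layer kind {kind!r} ({layer.name})")
        values[layer.name] = out
        if cache is not None:
            cache[layer.name] = entry
            cache["__order__"].append(layer)
        elif kind == "maxpool_with_indices":
            values[layer.name + "/idx"] = idx
        prev = layer.name
    return out, cache


def backward(spec: ModelSpec, params: dict, cache: dict, grad_out: np.ndarray):
    """Gradients of every trainable array, given d(loss)/d(last output)."""
    order = cache["__order__"]
    grads: dict[str, dict[str, np.ndarray]] = {}
    gvals: dict[str, np.ndarray] = {order[-1].name: grad_out}
    for layer in reversed(order):
        g = gvals.pop(layer.name, None)
        if g is None:
            continue
        ins, saved = cache[layer.name]
        kind = layer.kind
        p = params.get(layer.name, {})

        def send(name, value):
            if name in gvals:
                gvals[name] = gvals[name] + value
            else:
                gvals[name] = value

        if kind == "conv2d":
            (a,) = saved
            dx, dk, db = conv2d_backward(a, p["kernel"], g)
            grads[layer.name] = {"kernel": dk}
            if "bias" in p:
                grads[layer.name]["bias"] = db
            send(ins[0], dx)
        elif kind == "separable_conv2d":
            a, mid = saved
            dmid, dpw, db = conv2d_backward(mid, p["pointwise"][None, None], g)
            dx, ddw = depthwise_backward(a, p["depthwise"], dmid)
            grads[layer.name] = {"depthwise": ddw, "pointwise": dpw[0, 0]}
            if "bias" in p:
                grads[layer.name]["bias"] = db
            send(ins[0], dx)
        elif kind == "batchnorm":
            xhat, invstd, was_training = saved
            dgamma = np.einsum("nhwc,nhwc->c", g, xhat)
            dbeta = g.sum(axis=(0, 1, 2))
            grads[layer.name] = {"gamma": dgamma, "beta": dbeta}
            if was_training:
                m = g.shape[0] * g.shape[1] * g.shape[2]
                dx = (p["gamma"] * invstd) * (g - dbeta / m - xhat * (dgamma / m))
            else:
                dx = g * (p["gamma"] * invstd)
            send(ins[0], dx)
        elif kind == "relu":
            (out,) = saved
            send(ins[0], g * (out > 0))
        elif kind in ("maxpool", "maxpool_with_indices"):
            idx, in_shape = saved
            send(ins[0], maxpool_backward(g, idx, in_shape))
        elif kind == "unpool_with_indices":
            idx, channels = saved
            send(ins[0], unpool_backward(g, idx, channels))
        elif kind == "upsample_bilinear":
            (in_hw,) = saved
            send(ins[0], upsample_bilinear_backward(g, in_hw, layer.factor))
        elif kind == "pixel_shuffle":
            send(ins[0], pixel_shuffle_backward(g, layer.factor))
        elif kind == "add":
            send(ins[0], g)
            send(ins[1], g)
        elif kind == "softmax":
            (out,) = saved
            dot = (g * out).sum(axis=-1, keepdims=True)
            send(ins[0], out * (g - dot))
    return grads


def predict(spec: ModelSpec, params: dict, image: np.ndarray) -> np.ndarray:
    """Per-pixel class probabilities for one image or a batch.

    ``image`` is (H, W, 3) or (N, H, W, 3), values in [0, 1].  Returns
    the matching (..., H, W, C) probability tensor; ``argmax`` over the
    last axis gives the label map.
    """
    check_params(spec, params)
    image = np.asarray(image, dtype=np.float32)
    single = image.ndim == 3
    if single:
        image = image[None]
    h, w, _ = spec.input_shape
    if image.shape[1:] != (h, w, 3):
        raise ValueError(
            f"expected input of shape (N, {h}, {w}, 3), got {image.shape}"
        )
    probs, _ = forward(spec, params, image, training=False)
    return probs[0] if single else probs
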