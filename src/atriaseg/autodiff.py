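"""A small reverse-mode automatic differentiation core on NumPy arrays.

Supports exactly the operations the segmentation network needs: broadcasted
elementwise arithmetic, sigmoid/ReLU/tanh, reductions, concatenation, axis
permutation, slicing along an axis, stride-1 'same'-padded dilated 2D
convolution, and batch normalization. Gradients are accumulated by a
topological sweep over the recorded computation graph.

float32 is the working precision for training; float64 inputs are preserved,
which the equation-level unit tests rely on.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Tensor", "add", "mul", "sub", "div", "neg", "sigmoid", "relu", "tanh",
    "tsum", "tmean", "concat", "permute", "reshape", "narrow", "conv2d",
    "batch_norm2d",
]


def _as_float(data):
    arr = np.asarray(data)
    if arr.dtype not in (np.float32, np.float64):
        arr = arr.astype(np.float32)
    return arr


class Tensor:
    """A node in the computation graph wrapping a NumPy array."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False):
        self.data = _as_float(data)
        self.grad = None
        self.requires_grad = bool(requires_grad)
        self._parents: tuple = ()
        self._backward = None

    # -- factory used by ops ------------------------------------------------
    @classmethod
    def _from_op(cls, data, parents, backward):
        out = cls(data)
        if any(p.requires_grad for p in parents):
            out.requires_grad = True
            out._parents = tuple(parents)
            out._backward = backward
        return out

    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def zero_grad(self):
        self.grad = None

    def detach(self) -> "Tensor":
        return Tensor(self.data.copy(), requires_grad=False)

    def backward(self, grad=None):
        """Accumulate gradients of this (scalar unless grad given) output."""
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without grad requires a scalar output")
            grad = np.ones_like(self.data)
        # topological order (iterative to cope with deep LSTM graphs)
        topo: list[Tensor] = []
        visited: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in visited:
                continue
            visited.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                if p.requires_grad and id(p) not in visited:
                    stack.append((p, False))
        self.grad = np.asarray(grad, dtype=self.data.dtype)
        adopted: set[int] = set()
        for node in reversed(topo):
            if node._backward is None or node.grad is None:
                continue
            for parent, pgrad in zip(node._parents, node._backward(node.grad)):
                if not parent.requires_grad or pgrad is None:
                    continue
                pgrad = pgrad.astype(parent.data.dtype, copy=False)
                if parent.grad is None:
                    # adopt freshly owned arrays, each at most once (a later
                    # in-place accumulation must never alias another parent's
                    # gradient); copy views, broadcasts and pool-backed
                    # scratch buffers, which later ops may reuse
                    if (
                        pgrad.flags.owndata
                        and pgrad.flags.writeable
                        and id(pgrad) not in _SCRATCH_IDS
                        and id(pgrad) not in adopted
                    ):
                        parent.grad = pgrad
                        adopted.add(id(pgrad))
                    else:
                        parent.grad = pgrad.copy()
                else:
                    parent.grad += pgrad

    # -- operator sugar -----------------------------------------------------
    def __add__(self, other):
        return add(self, other)

    __radd__ = __add__

    def __mul__(self, other):
        return mul(self, other)

    __rmul__ = __mul__

    def __sub__(self, other):
        return sub(self, other)

    def __rsub__(self, other):
        return sub(other, self)

    def __neg__(self):
        return neg(self)

    def __truediv__(self, other):
        return div(self, other)

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"


def _wrap(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def _wrap2(a, b) -> tuple[Tensor, Tensor]:
    """Wrap the operands of a binary op; a bare Python/NumPy scalar adopts
    the tensor operand's dtype so constants never promote float32 graphs."""
    if isinstance(a, Tensor) and not isinstance(b, Tensor):
        b = Tensor(np.asarray(b, dtype=a.data.dtype))
    elif isinstance(b, Tensor) and not isinstance(a, Tensor):
        a = Tensor(np.asarray(a, dtype=b.data.dtype))
    return _wrap(a), _wrap(b)


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Reduce `grad` back to `shape` after NumPy broadcasting."""
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for i, s in enumerate(shape):
        if s == 1 and grad.shape[i] != 1:
            grad = grad.sum(axis=i, keepdims=True)
    return grad


# ---------------------------------------------------------------------------
# Elementwise ops
# ---------------------------------------------------------------------------

def add(a, b) -> Tensor:
    a, b = _wrap2(a, b)
    return Tensor._from_op(
        a.data + b.data,
        (a, b),
        lambda g: (_unbroadcast(g, a.data.shape), _unbroadcast(g, b.data.shape)),
    )


def sub(a, b) -> Tensor:
    a, b = _wrap2(a, b)
    return Tensor._from_op(
        a.data - b.data,
        (a, b),
        lambda g: (_unbroadcast(g, a.data.shape), _unbroadcast(-g, b.data.shape)),
    )


def neg(a) -> Tensor:
    a = _wrap(a)
    return Tensor._from_op(-a.data, (a,), lambda g: (-g,))


def mul(a, b) -> Tensor:
    a, b = _wrap2(a, b)
    return Tensor._from_op(
        a.data * b.data,
        (a, b),
        lambda g: (
            _unbroadcast(g * b.data, a.data.shape),
            _unbroadcast(g * a.data, b.data.shape),
        ),
    )


def div(a, b) -> Tensor:
    a, b = _wrap2(a, b)
    out = a.data / b.data
    return Tensor._from_op(
        out,
        (a, b),
        lambda g: (
            _unbroadcast(g / b.data, a.data.shape),
            _unbroadcast(-g * out / b.data, b.data.shape),
        ),
    )


def sigmoid(x) -> Tensor:
    from scipy.special import expit

    x = _wrap(x)
    s = expit(x.data)
    return Tensor._from_op(s, (x,), lambda g: (g * s * (1.0 - s),))


def relu(x) -> Tensor:
    x = _wrap(x)
    mask = x.data > 0
    return Tensor._from_op(x.data * mask, (x,), lambda g: (g * mask,))


def tanh(x) -> Tensor:
    x = _wrap(x)
    t = np.tanh(x.data)
    return Tensor._from_op(t, (x,), lambda g: (g * (1.0 - t * t),))


# ---------------------------------------------------------------------------
# Reductions and reshapes
# ---------------------------------------------------------------------------

def tsum(x) -> Tensor:
    x = _wrap(x)
    return Tensor._from_op(
        np.asarray(x.data.sum()), (x,), lambda g: (np.broadcast_to(g, x.data.shape),)
    )


def tmean(x) -> Tensor:
    x = _wrap(x)
    n = x.data.size
    return Tensor._from_op(
        np.asarray(x.data.mean()),
        (x,),
        lambda g: (np.broadcast_to(g / n, x.data.shape),),
    )


def concat(tensors, axis: int = 0) -> Tensor:
    tensors = [_wrap(t) for t in tensors]
    sizes = [t.data.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def backward(g):
        return tuple(np.split(g, splits, axis=axis))

    return Tensor._from_op(
        np.concatenate([t.data for t in tensors], axis=axis), tensors, backward
    )


def permute(x, axes) -> Tensor:
    x = _wrap(x)
    inv = np.argsort(axes)
    return Tensor._from_op(
        np.transpose(x.data, axes), (x,), lambda g: (np.transpose(g, inv),)
    )


def reshape(x, shape) -> Tensor:
    x = _wrap(x)
    return Tensor._from_op(
        x.data.reshape(shape), (x,), lambda g: (g.reshape(x.data.shape),)
    )


def narrow(x, axis: int, start: int, length: int) -> Tensor:
    """Contiguous slice of `length` entries along `axis`."""
    x = _wrap(x)
    idx = [slice(None)] * x.data.ndim
    idx[axis] = slice(start, start + length)
    idx = tuple(idx)

    def backward(g):
        # scratch-backed: the caller accumulates this immediately, so the
        # buffer may be reused by the next narrow's backward
        full = _scratch("narrowgrad", x.data.shape, x.data.dtype)
        full[:] = 0.0
        full[idx] = g
        return (full,)

    return Tensor._from_op(x.data[idx], (x,), backward)


# ---------------------------------------------------------------------------
# Convolution
# ---------------------------------------------------------------------------

# Scratch-buffer pool for convolution work arrays. The same (shape, dtype)
# temporaries recur thousands of times per training run; reusing them keeps
# the allocator from cycling multi-megabyte mmap'd blocks, which otherwise
# dominates runtime with page faults. Buffers are consumed immediately by
# the matmul that follows, never retained in the graph.
_SCRATCH: dict[tuple, np.ndarray] = {}
_SCRATCH_IDS: set[int] = set()
_SCRATCH_CAP = 48  # distinct buffers kept before the pool is cleared


def _scratch(tag: str, shape: tuple, dtype) -> np.ndarray:
    key = (tag, shape, np.dtype(dtype).str)
    buf = _SCRATCH.get(key)
    if buf is None:
        if len(_SCRATCH) >= _SCRATCH_CAP:
            _SCRATCH.clear()
            _SCRATCH_IDS.clear()
        buf = np.empty(shape, dtype)
        _SCRATCH[key] = buf
        _SCRATCH_IDS.add(id(buf))
    return buf


def _pad_into(x, p):
    if p == 0:
        return x
    n, c, h, w = x.shape
    xp = _scratch("pad", (n, c, h + 2 * p, w + 2 * p), x.dtype)
    xp[:] = 0.0
    xp[:, :, p : p + h, p : p + w] = x
    return xp


def _im2col(x, k, dilation):
    """Unfold (N, C, H, W) into columns (N, C*k*k, H*W) for a stride-1
    'same'-padded dilated kernel; column order matches w.reshape(Cout, -1)."""
    n, c, h, w = x.shape
    if k == 1:  # a 1x1 kernel needs no unfolding at all
        return x.reshape(n, c, h * w)
    p = dilation * (k - 1) // 2
    xp = _pad_into(x, p)
    cols = _scratch("cols", (n, c, k * k, h, w), x.dtype)
    j = 0
    for a in range(k):
        for b in range(k):
            cols[:, :, j] = xp[:, :, a * dilation : a * dilation + h,
                               b * dilation : b * dilation + w]
            j += 1
    return cols.reshape(n, c * k * k, h * w)


def _conv_forward(x, w, dilation):
    """Stride-1 'same' dilated 2D cross-correlation: im2col + batched matmul.

    x: (N, Cin, H, W); w: (Cout, Cin, k, k); output (N, Cout, H, W), an
    owned array (so gradient accumulation can adopt it without a copy).
    """
    n, _, h, wd = x.shape
    cout, _, k, _ = w.shape
    cols = _im2col(x, k, dilation)
    out = np.empty((n, cout, h, wd), dtype=x.dtype)
    np.matmul(w.reshape(1, cout, -1), cols, out=out.reshape(n, cout, h * wd))
    return out


def conv2d(x, w, b=None, dilation: int = 1) -> Tensor:
    """2D convolution layer op: stride 1, zero 'same' padding, odd kernel.

    Padding is ``dilation * (k - 1) / 2`` per side, so the spatial size is
    unchanged at every dilation rate.
    """
    x, w = _wrap(x), _wrap(w)
    k = w.data.shape[2]
    if k % 2 != 1 or w.data.shape[3] != k:
        raise ValueError("conv2d requires square odd kernels")
    if x.data.shape[1] != w.data.shape[1]:
        raise ValueError(
            f"channel mismatch: input has {x.data.shape[1]}, kernel expects {w.data.shape[1]}"
        )
    out = _conv_forward(x.data, w.data, dilation)
    parents = [x, w]
    if b is not None:
        b = _wrap(b)
        out = out + b.data[None, :, None, None]
        parents.append(b)

    n, cin, h, wd = x.data.shape
    cout = w.data.shape[0]

    def backward(g):
        gx = gw = None
        if x.requires_grad:
            # grad wrt input: correlate g with flipped, channel-swapped w
            w_flip = w.data[:, :, ::-1, ::-1].transpose(1, 0, 2, 3)
            gx = _conv_forward(g, np.ascontiguousarray(w_flip), dilation)
        if w.requires_grad:
            # grad wrt weights: columns of x contracted with g over batch/space
            cols = _im2col(x.data, k, dilation)  # (N, Cin*k*k, H*W)
            g_r = g.reshape(n, cout, h * wd)
            gw = np.matmul(g_r, cols.transpose(0, 2, 1)).sum(axis=0).reshape(w.data.shape)
        grads = [gx, gw]
        if b is not None:
            grads.append(g.sum(axis=(0, 2, 3)))
        return tuple(grads)

    return Tensor._from_op(out, parents, backward)


# ---------------------------------------------------------------------------
# Batch normalization
# ---------------------------------------------------------------------------

def batch_norm2d(
    x,
    gamma,
    beta,
    running_mean: np.ndarray,
    running_var: np.ndarray,
    mode: str = "train",
    momentum: float = 0.1,
    eps: float = 1e-5,
) -> Tensor:
    """Per-channel batch normalization over an (N, C, H, W) map.

    ``train`` uses batch statistics and updates the running averages in
    place; ``eval`` uses the running averages; ``identity`` passes the input
    through unchanged (gamma = 1, beta = 0, unit variance) for unit tests.
    """
    x = _wrap(x)
    if mode == "identity":
        return Tensor._from_op(x.data.copy(), (x,), lambda g: (g,))
    gamma, beta = _wrap(gamma), _wrap(beta)
    if mode == "train":
        mu = x.data.mean(axis=(0, 2, 3))
        var = x.data.var(axis=(0, 2, 3))
        running_mean *= 1.0 - momentum
        running_mean += momentum * mu
        running_var *= 1.0 - momentum
        running_var += momentum * var
    elif mode == "eval":
        mu, var = running_mean, running_var
    else:
        raise ValueError(f"unknown batch-norm mode {mode!r}")
    inv_std = 1.0 / np.sqrt(var + eps)
    xhat = (x.data - mu[None, :, None, None]) * inv_std[None, :, None, None]
    out = gamma.data[None, :, None, None] * xhat + beta.data[None, :, None, None]

    def backward(g):
        dgamma = np.einsum("nchw,nchw->c", g, xhat, optimize=True)
        dbeta = g.sum(axis=(0, 2, 3))
        scale = (gamma.data * inv_std)[None, :, None, None]
        if mode == "eval":
            return g * scale, dgamma, dbeta
        # dx = scale * (g - mean(g) - xhat * mean(g * xhat)), per channel;
        # built with one scratch temp to keep allocations flat
        m = g.shape[0] * g.shape[2] * g.shape[3]
        dx = np.subtract(g, (dbeta / m)[None, :, None, None])
        tmp = _scratch("bnbwd", xhat.shape, xhat.dtype)
        np.multiply(xhat, (dgamma / m)[None, :, None, None], out=tmp)
        dx -= tmp
        dx *= scale
        return dx, dgamma, dbeta

    return Tensor._from_op(out, (x, gamma, beta), backward)
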