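"""Minimal CPU neural-network kernels for the counting FCNN.

Single-sample (batch size 1) 2-D convolutional layers with same padding,
spatial batch normalization, ReLU, channel concatenation and an Adam
optimizer, all in float32 numpy.  Convolutions are lowered to matrix
multiplication via im2col (``sliding_window_view`` + reshape), so the hot
loop runs in BLAS; the input gradient of a same-padded cross-correlation
is computed as another same-padded cross-correlation with the spatially
flipped, channel-transposed kernel, which keeps the backward pass in BLAS
as well.

Tensors are ``(channels, height, width)``.  Layers cache what their
backward pass needs; ``backward`` returns the input gradient and stores
parameter gradients on the layer.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

_F32 = np.float32


def _conv_same(x: np.ndarray, weight: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Same-padded cross-correlation.

    x: (Cin, H, W), weight: (Cout, Cin, kh, kw) with kh, kw odd.
    Returns (out (Cout, H, W), cols (H*W, Cin*kh*kw)) — cols are kept for
    the weight gradient.
    """
    cin, H, W = x.shape
    cout, _, kh, kw = weight.shape
    ph, pw = kh // 2, kw // 2
    xp = np.pad(x, ((0, 0), (ph, ph), (pw, pw)))
    win = sliding_window_view(xp, (kh, kw), axis=(1, 2))  # (Cin, H, W, kh, kw)
    cols = np.ascontiguousarray(win.transpose(1, 2, 0, 3, 4)).reshape(H * W, cin * kh * kw)
    out = cols @ weight.reshape(cout, -1).T
    return out.reshape(H, W, cout).transpose(2, 0, 1), cols


_FFT_MIN_KERNEL = 7  # below this, im2col+gemm beats FFT on our sizes


class Conv2d:
    """Same-padded convolution with bias; odd kernel sizes only.

    Three execution paths, all numerically equivalent: 1x1 kernels reduce
    to a channel matmul, small kernels go through im2col + gemm, and large
    kernels (>= 7) run in the Fourier domain, where the forward pass, the
    input gradient and the weight gradient are each one batched FFT
    product (FFT sizes are padded to fast lengths, and circular wraparound
    is avoided by construction).
    """

    def __init__(
        self,
        in_channels: int,
        out_channels: int,
        kernel_size: int,
        rng: np.random.Generator,
    ) -> None:
        if kernel_size % 2 == 0:
            raise ValueError("kernel_size must be odd for same padding")
        self.in_channels = in_channels
        self.out_channels = out_channels
        self.kernel_size = kernel_size
        fan_in = in_channels * kernel_size * kernel_size
        fan_out = out_channels * kernel_size * kernel_size
        limit = np.sqrt(6.0 / (fan_in + fan_out))  # Glorot uniform
        self.weight = rng.uniform(
            -limit, limit, (out_channels, in_channels, kernel_size, kernel_size)
        ).astype(_F32)
        self.bias = np.zeros(out_channels, dtype=_F32)
        self.d_weight = np.zeros_like(self.weight)
        self.d_bias = np.zeros_like(self.bias)
        self._cache: tuple | None = None
        self._fft_ctx: dict | None = None

    # -- plain paths --------------------------------------------------------
    def _forward_1x1(self, x: np.ndarray) -> np.ndarray:
        cin, H, W = x.shape
        out = self.weight.reshape(self.out_channels, cin) @ x.reshape(cin, H * W)
        return out.reshape(self.out_channels, H, W)

    def _backward_1x1(self, d_out: np.ndarray) -> np.ndarray:
        x = self._cache[0]
        cin, H, W = x.shape
        dy = d_out.reshape(self.out_channels, H * W)
        self.d_weight[...] = (dy @ x.reshape(cin, H * W).T).reshape(self.weight.shape)
        dx = self.weight.reshape(self.out_channels, cin).T @ dy
        return dx.reshape(cin, H, W)

    def _backward_im2col(self, d_out: np.ndarray) -> np.ndarray:
        cols = self._cache[0]
        dy = d_out.reshape(self.out_channels, -1)
        self.d_weight[...] = (dy @ cols).reshape(self.weight.shape)
        flipped = np.ascontiguousarray(
            self.weight.transpose(1, 0, 2, 3)[:, :, ::-1, ::-1]
        )
        dx, _ = _conv_same(np.ascontiguousarray(d_out), flipped)
        return dx

    # -- FFT path -----------------------------------------------------------
    def _fft_setup(self, H: int, W: int) -> dict:
        from scipy.fft import next_fast_len

        k = self.kernel_size
        s0 = next_fast_len(H + k - 1, real=True)
        s1 = next_fast_len(W + k - 1, real=True)
        # phase ramps: multiplying an rfft2 by exp(-2*pi*i*kappa*d/S)
        # shifts the signal by d samples
        f0 = np.fft.fftfreq(s0)[:, None]
        f1 = np.fft.rfftfreq(s1)[None, :]
        pad_phase = np.exp(-2j * np.pi * (f0 * (k // 2) + f1 * (k // 2))).astype(np.complex64)
        flip_phase = np.exp(-2j * np.pi * (f0 * (k - 1) + f1 * (k - 1))).astype(np.complex64)
        return {"H": H, "W": W, "shape": (s0, s1), "pad_phase": pad_phase, "flip_phase": flip_phase}

    def _forward_fft(self, x: np.ndarray, train: bool) -> np.ndarray:
        from scipy.fft import irfft2, rfft2

        cin, H, W = x.shape
        if self._fft_ctx is None or (self._fft_ctx["H"], self._fft_ctx["W"]) != (H, W):
            self._fft_ctx = self._fft_setup(H, W)
        ctx = self._fft_ctx
        s = ctx["shape"]
        p = self.kernel_size // 2
        fx = rfft2(x, s=s)
        # FFT of the spatially flipped kernel: cross-correlation becomes a
        # plain product
        fwf = rfft2(self.weight[:, :, ::-1, ::-1], s=s)
        fy = np.einsum("cij,ocij->oij", fx, fwf)
        y = irfft2(fy, s=s)[:, p : p + H, p : p + W]
        if train:
            self._cache = (fx, fwf)
        return np.ascontiguousarray(y, dtype=_F32)

    def _backward_fft(self, d_out: np.ndarray) -> np.ndarray:
        from scipy.fft import irfft2, rfft2

        fx, fwf = self._cache
        ctx = self._fft_ctx
        s = ctx["shape"]
        H, W = ctx["H"], ctx["W"]
        k = self.kernel_size
        p = k // 2
        fdy = rfft2(d_out, s=s)
        # weight gradient: correlation of the zero-padded input with d_out,
        # evaluated at the k x k kernel lags.  FFT(x padded by p) is
        # FFT(x) times a phase ramp.
        fxp = fx * ctx["pad_phase"]
        g = np.einsum("cij,oij->ocij", fxp, np.conj(fdy))
        self.d_weight[...] = irfft2(g, s=s)[:, :, :k, :k]
        self.d_bias[...] = d_out.sum(axis=(1, 2))
        # input gradient: convolution of d_out with the unflipped kernel,
        # channels transposed; FFT(w) recovered from FFT(flip(w)) by
        # conjugation and a phase ramp
        fw = np.conj(fwf) * ctx["flip_phase"]
        fdx = np.einsum("oij,ocij->cij", fdy, fw)
        dx = irfft2(fdx, s=s)[:, p : p + H, p : p + W]
        self._cache = None
        return np.ascontiguousarray(dx, dtype=_F32)

    # -- public interface ---------------------------------------------------
    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        if self.kernel_size == 1:
            out = self._forward_1x1(x)
            self._cache = (x,) if train else None
        elif self.kernel_size >= _FFT_MIN_KERNEL:
            out = self._forward_fft(x, train)
        else:
            out, cols = _conv_same(x, self.weight)
            self._cache = (cols,) if train else None
        return out + self.bias[:, None, None]

    def backward(self, d_out: np.ndarray) -> np.ndarray:
        if self.kernel_size >= _FFT_MIN_KERNEL and self.kernel_size > 1:
            return self._backward_fft(d_out)
        self.d_bias[...] = d_out.sum(axis=(1, 2))
        if self.kernel_size == 1:
            dx = self._backward_1x1(d_out)
        else:
            dx = self._backward_im2col(d_out)
        self._cache = None
        return dx

    def parameters(self) -> list[tuple[np.ndarray, np.ndarray]]:
        return [(self.weight, self.d_weight), (self.bias, self.d_bias)]


class BatchNorm:
    """Per-channel normalization over the spatial axes (batch of one).

    With ``running_stats=True`` (classic batch norm) inference normalizes
    by exponentially averaged training statistics.  With
    ``running_stats=False`` inference uses the current image's own
    statistics — identical to the training-time behaviour of batch norm at
    batch size 1 — which makes every frame's normalization self-contained
    and robust to global intensity shifts between frames.
    """

    def __init__(
        self,
        channels: int,
        momentum: float = 0.1,
        eps: float = 1e-5,
        running_stats: bool = True,
    ) -> None:
        self.running_stats = running_stats
        # frozen: normalize by the stored running statistics even during
        # training, and stop updating them — used for fine-tuning phases
        # where training must optimize the exact inference-time function
        self.frozen = False
        self.gamma = np.ones(channels, dtype=_F32)
        self.beta = np.zeros(channels, dtype=_F32)
        self.d_gamma = np.zeros_like(self.gamma)
        self.d_beta = np.zeros_like(self.beta)
        self.running_mean = np.zeros(channels, dtype=_F32)
        self.running_var = np.ones(channels, dtype=_F32)
        self.momentum = momentum
        self.eps = eps
        self._cache: tuple | None = None

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        if self.frozen:
            mean, var = self.running_mean, self.running_var
        elif train or not self.running_stats:
            mean = x.mean(axis=(1, 2))
            var = x.var(axis=(1, 2))
            if train and self.running_stats:
                self.running_mean += self.momentum * (mean - self.running_mean)
                self.running_var += self.momentum * (var - self.running_var)
        else:
            mean, var = self.running_mean, self.running_var
        inv_std = 1.0 / np.sqrt(var + self.eps)
        x_hat = (x - mean[:, None, None]) * inv_std[:, None, None]
        if train:
            self._cache = (x_hat, inv_std)
        return self.gamma[:, None, None] * x_hat + self.beta[:, None, None]

    def backward(self, d_out: np.ndarray) -> np.ndarray:
        x_hat, inv_std = self._cache
        self._cache = None
        self.d_gamma[...] = (d_out * x_hat).sum(axis=(1, 2))
        self.d_beta[...] = d_out.sum(axis=(1, 2))
        d_xhat = d_out * self.gamma[:, None, None]
        if self.frozen:
            # mean/var are constants here: the backward is a plain affine
            return d_xhat * inv_std[:, None, None]
        # standard batch-norm backward, reduced over the spatial axes
        term = (
            d_xhat
            - d_xhat.mean(axis=(1, 2))[:, None, None]
            - x_hat * (d_xhat * x_hat).mean(axis=(1, 2))[:, None, None]
        )
        return term * inv_std[:, None, None]

    def parameters(self) -> list[tuple[np.ndarray, np.ndarray]]:
        return [(self.gamma, self.d_gamma), (self.beta, self.d_beta)]


class ReLU:
    def __init__(self) -> None:
        self._mask: np.ndarray | None = None

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        mask = x > 0
        self._mask = mask if train else None
        return np.where(mask, x, 0.0).astype(_F32, copy=False)

    def backward(self, d_out: np.ndarray) -> np.ndarray:
        out = d_out * self._mask
        self._mask = None
        return out

    def parameters(self) -> list:
        return []


class ConvUnit:
    """Conv -> (BatchNorm) -> (ReLU), the basic block of the network."""

    def __init__(
        self,
        in_channels: int,
        out_channels: int,
        kernel_size: int,
        rng: np.random.Generator,
        batch_norm: bool = True,
        activation: bool = True,
        bn_running_stats: bool = True,
    ) -> None:
        self.conv = Conv2d(in_channels, out_channels, kernel_size, rng)
        self.bn = (
            BatchNorm(out_channels, running_stats=bn_running_stats)
            if batch_norm
            else None
        )
        self.relu = ReLU() if activation else None

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        x = self.conv.forward(x, train)
        if self.bn is not None:
            x = self.bn.forward(x, train)
        if self.relu is not None:
            x = self.relu.forward(x, train)
        return x

    def backward(self, d_out: np.ndarray) -> np.ndarray:
        if self.relu is not None:
            d_out = self.relu.backward(d_out)
        if self.bn is not None:
            d_out = self.bn.backward(d_out)
        return self.conv.backward(d_out)

    def parameters(self) -> list[tuple[np.ndarray, np.ndarray]]:
        out = self.conv.parameters()
        if self.bn is not None:
            out += self.bn.parameters()
        return out


class InceptionBlock:
    """Parallel 1x1 and 3x3 conv units, concatenated channel-wise."""

    def __init__(
        self,
        in_channels: int,
        branch_channels: int,
        rng: np.random.Generator,
        batch_norm: bool = True,
        bn_running_stats: bool = True,
    ) -> None:
        self.branch1 = ConvUnit(
            in_channels, branch_channels, 1, rng, batch_norm,
            bn_running_stats=bn_running_stats,
        )
        self.branch3 = ConvUnit(
            in_channels, branch_channels, 3, rng, batch_norm,
            bn_running_stats=bn_running_stats,
        )
        self.out_channels = 2 * branch_channels

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        return np.concatenate(
            [self.branch1.forward(x, train), self.branch3.forward(x, train)], axis=0
        )

    def backward(self, d_out: np.ndarray) -> np.ndarray:
        half = self.out_channels // 2
        return self.branch1.backward(d_out[:half]) + self.branch3.backward(d_out[half:])

    def parameters(self) -> list[tuple[np.ndarray, np.ndarray]]:
        return self.branch1.parameters() + self.branch3.parameters()


class Adam:
    """Adam with the usual bias correction (beta1=0.9, beta2=0.999)."""

    def __init__(
        self,
        params: list[tuple[np.ndarray, np.ndarray]],
        learning_rate: float = 1e-3,
        beta1: float = 0.9,
        beta2: float = 0.999,
        eps: float = 1e-8,
    ) -> None:
        self.lr = learning_rate
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.t = 0
        self.m = [np.zeros_like(p) for p, _ in params]
        self.v = [np.zeros_like(p) for p, _ in params]

    def step(self, params: list[tuple[np.ndarray, np.ndarray]]) -> None:
        self.t += 1
        b1t = 1.0 - self.beta1**self.t
        b2t = 1.0 - self.beta2**self.t
        for i, (p, g) in enumerate(params):
            self.m[i] += (1.0 - self.beta1) * (g - self.m[i])
            self.v[i] += (1.0 - self.beta2) * (g * g - self.v[i])
            p -= self.lr * (self.m[i] / b1t) / (np.sqrt(self.v[i] / b2t) + self.eps)


def l1_loss_grad(pred: np.ndarray, target: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean absolute error per pixel and its gradient w.r.t. pred."""
    diff = pred - target
    n = diff.size
    return float(np.abs(diff).mean()), (np.sign(diff) / n).astype(_F32)


def l2_loss_grad(pred: np.ndarray, target: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean squared error per pixel and its gradient w.r.t. pred."""
    diff = pred - target
    n = diff.size
    return float((diff * diff).mean()), (2.0 * diff / n).astype(_F32)


def clipped_l2_loss_grad(
    pred: np.ndarray, target: np.ndarray, leak: float = 0.1
) -> tuple[float, np.ndarray]:
    """MSE between the zero-clipped prediction and the target.

    Count inference sums ``max(pred, 0)``, so this loss trains the exact
    quantity that is measured: on zero-target regions the raw output is
    free to settle below zero, which silences the positive-noise floor
    that plain MSE leaves behind after clipping.  A small leak passes
    gradient through the clip where the target is positive but the raw
    output is still negative, so missed objects remain learnable.
    """
    clipped = np.maximum(pred, 0.0)
    diff = clipped - target
    n = diff.size
    slope = np.where(pred > 0, 1.0, leak).astype(_F32)
    return float((diff * diff).mean()), (2.0 * diff * slope / n).astype(_F32)
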