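"""State-space sequence operators: ZOH discretization, recurrent and
convolutional scans, the input-dependent selective scan (S6), and the
four-direction 2-D scan (SS2D).

A continuous linear state-space model

    h'(t) = A h(t) + B x(t),      y(t) = C h(t)

is discretized with a zero-order hold over a time scale ``delta``:

    A_bar = exp(delta * A)
    B_bar = (delta A)^{-1} (exp(delta A) - I) * delta B

after which the sequence can be processed either step-by-step (recurrent
form) or, for fixed parameters, by a causal convolution with the kernel
K = [C B_bar, C A_bar B_bar, ..., C A_bar^{M-1} B_bar].  The selective scan
makes ``delta``, ``B`` and ``C`` functions of the input at each step, which
the kernel form cannot represent; the network therefore always runs the
recurrence, and the kernel path is kept for verification.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import expm

from . import nn
from .autodiff import (
    Tensor,
    as_tensor,
    selective_scan_zoh,
)

__all__ = [
    "StateSpaceParams",
    "DiscreteStateSpace",
    "ScanSequence",
    "discretize_zoh",
    "recurrent_scan",
    "build_conv_kernel",
    "conv_scan",
    "S6",
    "selective_scan_s6",
    "ss2d_expand",
    "ss2d_merge",
]


# ---------------------------------------------------------------------------
# Plain (non-selective) SSM primitives on NumPy arrays
# ---------------------------------------------------------------------------


@dataclass
class StateSpaceParams:
    """Continuous-time SSM parameters (A, B, C) and time scale delta.

    A is N x N, B is N x 1, C is 1 x N; delta is a strictly positive scalar.
    """

    A: np.ndarray
    B: np.ndarray
    C: np.ndarray
    delta: float

    def __post_init__(self):
        self.A = np.atleast_2d(np.asarray(self.A, dtype=np.float64))
        self.B = np.asarray(self.B, dtype=np.float64).reshape(-1, 1)
        self.C = np.asarray(self.C, dtype=np.float64).reshape(1, -1)
        if self.A.shape[0] != self.A.shape[1]:
            raise ValueError(f"A must be square, got {self.A.shape}")
        n = self.A.shape[0]
        if self.B.shape != (n, 1):
            raise ValueError(f"B must have shape ({n}, 1), got {self.B.shape}")
        if self.C.shape != (1, n):
            raise ValueError(f"C must have shape (1, {n}), got {self.C.shape}")
        if not np.isscalar(self.delta) and np.ndim(self.delta) != 0:
            raise ValueError("delta must be a scalar")
        self.delta = float(self.delta)
        if not self.delta > 0:
            raise ValueError(f"delta must be strictly positive, got {self.delta}")
        if not (np.all(np.isfinite(self.A)) and np.all(np.isfinite(self.B))
                and np.all(np.isfinite(self.C))):
            raise ValueError("non-finite state-space parameters")


@dataclass
class DiscreteStateSpace:
    """ZOH-discretized transition matrix A_bar and input map B_bar."""

    A_bar: np.ndarray
    B_bar: np.ndarray


@dataclass
class ScanSequence:
    """Input/output sequences plus the full hidden-state trajectory."""

    x: np.ndarray
    h: np.ndarray
    y: np.ndarray
    K: np.ndarray | None = field(default=None)


def discretize_zoh(params: StateSpaceParams) -> DiscreteStateSpace:
    """Zero-order-hold discretization.

    B_bar is computed from the augmented matrix exponential

        exp([[dA, dB], [0, 0]]) = [[A_bar, B_bar], [0, I]]

    which equals the integral form exactly and stays finite when dA is
    singular, so B_bar -> delta*B as A -> 0.
    """
    n = params.A.shape[0]
    dA = params.delta * params.A
    dB = params.delta * params.B
    aug = np.zeros((n + 1, n + 1), dtype=np.float64)
    aug[:n, :n] = dA
    aug[:n, n:] = dB
    e = expm(aug)
    return DiscreteStateSpace(A_bar=e[:n, :n], B_bar=e[:n, n:])


def recurrent_scan(
    dss: DiscreteStateSpace,
    C: np.ndarray,
    x: np.ndarray,
    h0: np.ndarray | None = None,
) -> ScanSequence:
    """Run h_t = A_bar h_{t-1} + B_bar x_t, y_t = C h_t for t = 1..M."""
    x = np.asarray(x, dtype=np.float64).ravel()
    if x.size < 1:
        raise ValueError("input sequence must have length >= 1")
    if not np.all(np.isfinite(x)):
        raise ValueError("non-finite input sequence")
    A_bar = np.atleast_2d(dss.A_bar)
    B_bar = np.asarray(dss.B_bar, dtype=np.float64).reshape(-1, 1)
    C = np.asarray(C, dtype=np.float64).reshape(1, -1)
    n = A_bar.shape[0]
    h = np.zeros(n) if h0 is None else np.asarray(h0, dtype=np.float64).ravel().copy()
    if h.shape != (n,):
        raise ValueError("h0 dimension mismatch")
    M = x.size
    hs = np.empty((M, n))
    y = np.empty(M)
    for t in range(M):
        h = A_bar @ h + B_bar[:, 0] * x[t]
        hs[t] = h
        y[t] = float((C @ h).item())
    return ScanSequence(x=x, h=hs, y=y)


def build_conv_kernel(dss: DiscreteStateSpace, C: np.ndarray, M: int) -> np.ndarray:
    """Kernel K = [C B_bar, C A_bar B_bar, ..., C A_bar^{M-1} B_bar]."""
    if M < 1:
        raise ValueError("kernel length M must be >= 1")
    A_bar = np.atleast_2d(dss.A_bar)
    B_bar = np.asarray(dss.B_bar, dtype=np.float64).reshape(-1, 1)
    C = np.asarray(C, dtype=np.float64).reshape(1, -1)
    K = np.empty(M)
    v = B_bar[:, 0].copy()
    for m in range(M):
        K[m] = float((C @ v).item())
        v = A_bar @ v
    return K


def conv_scan(x: np.ndarray, K: np.ndarray) -> np.ndarray:
    """Causal convolution y_t = sum_j K_j x_{t-j} (output length == input length)."""
    x = np.asarray(x, dtype=np.float64).ravel()
    K = np.asarray(K, dtype=np.float64).ravel()
    if x.size != K.size:
        raise ValueError(f"kernel length {K.size} != sequence length {x.size}")
    return np.convolve(x, K)[: x.size]


# ---------------------------------------------------------------------------
# Selective scan (S6)
# ---------------------------------------------------------------------------


class S6(nn.Module):
    """Input-dependent (selective) state-space scan over a (B, L, C) sequence.

    Per channel the state matrix A is diagonal with learnable negative-real
    entries initialised to -(1..n_state).  The step size delta (per channel,
    softplus-positive), the input map B and the output map C (both per step,
    shared over channels) are linear projections of the input, so the
    recurrence is content-dependent.  Discretization is exact elementwise ZOH:
    a_bar = exp(delta*a), b_bar = phi(delta*a)*delta*b with phi(z)=(e^z-1)/z.
    """

    def __init__(self, channels: int, n_state: int, rng: np.random.Generator,
                 dt_init: float = 0.05):
        super().__init__()
        self.channels = channels
        self.n_state = n_state
        self.A = nn.Parameter(
            np.tile(-np.arange(1.0, n_state + 1.0), (channels, 1))
        )
        scale = 1.0 / np.sqrt(channels)
        self.W_dt = nn.Parameter(rng.normal(0.0, scale, size=(channels, channels)))
        # softplus(b_dt) == dt_init at zero input
        self.b_dt = nn.Parameter(np.full(channels, np.log(np.expm1(dt_init))))
        self.W_B = nn.Parameter(rng.normal(0.0, scale, size=(channels, n_state)))
        self.b_B = nn.Parameter(np.zeros(n_state))
        self.W_C = nn.Parameter(rng.normal(0.0, scale, size=(channels, n_state)))
        self.b_C = nn.Parameter(np.zeros(n_state))

    def forward(self, u: Tensor) -> Tensor:
        u = as_tensor(u)
        if u.ndim != 3 or u.shape[2] != self.channels:
            raise ValueError(
                f"expected (batch, length, {self.channels}) sequence, got {u.shape}"
            )
        dt = (u @ self.W_dt + self.b_dt).softplus()  # (B, L, C)
        Bm = u @ self.W_B + self.b_B                  # (B, L, N)
        Cm = u @ self.W_C + self.b_C                  # (B, L, N)
        return selective_scan_zoh(dt, self.A, Bm, Cm, u)


def selective_scan_s6(seq, proj: S6):
    """Apply the selective scan ``proj`` to a single (L, C) sequence.

    Convenience wrapper for the non-batched interface; returns a NumPy array
    when given one, otherwise a Tensor.
    """
    if isinstance(seq, Tensor):
        return proj(seq)
    seq = np.asarray(seq, dtype=np.float64)
    if not np.all(np.isfinite(seq)):
        raise ValueError("non-finite input sequence")
    out = proj(Tensor(seq[None]))
    return out.data[0]


# ---------------------------------------------------------------------------
# SS2D: four-direction expand / merge
# ---------------------------------------------------------------------------
# Direction conventions (fixed):
#   1: row-major, left->right then top->bottom
#   2: exact reversal of 1
#   3: column-major, top->bottom then left->right
#   4: exact reversal of 3


def _flatten(z, transpose_hw: bool):
    """Flatten trailing (H, W) of an array or Tensor, optionally transposed."""
    lead = z.shape[:-2]
    H, W = z.shape[-2], z.shape[-1]
    if transpose_hw:
        axes = tuple(range(len(lead))) + (len(lead) + 1, len(lead))
        z = z.transpose(axes) if isinstance(z, Tensor) else np.transpose(z, axes)
    return z.reshape(*lead, H * W)


def _flip_last(z):
    return z.flip(-1) if isinstance(z, Tensor) else np.flip(z, axis=-1)


def ss2d_expand(z):
    """Arrange a (..., C, H, W) feature map into four directional sequences.

    Returns a list of four (..., C, H*W) sequences, each a permutation of the
    source entries (per channel).
    """
    if z.shape[-1] * z.shape[-2] < 1 or z.ndim < 3:
        raise ValueError("feature map must be (..., C, H, W) with H*W >= 1")
    s1 = _flatten(z, transpose_hw=False)
    s2 = _flip_last(s1)
    s3 = _flatten(z, transpose_hw=True)
    s4 = _flip_last(s3)
    return [s1, s2, s3, s4]


def ss2d_merge(scanned, H: int, W: int):
    """Undo the four directional orderings and fuse by elementwise sum.

    ``scanned`` is a sequence of four (..., C, H*W) arrays/Tensors in the
    direction order of :func:`ss2d_expand`; output is (..., C, H, W).
    With an identity scan, merge(expand(z)) == 4*z exactly.
    """
    if len(scanned) != 4:
        raise ValueError("expected four directional sequences")
    maps = []
    for i, s in enumerate(scanned):
        if s.shape[-1] != H * W:
            raise ValueError(
                f"sequence {i + 1} has length {s.shape[-1]}, expected {H * W}"
            )
        if i in (1, 3):
            s = _flip_last(s)
        lead = s.shape[:-1]
        if i < 2:
            m = s.reshape(*lead, H, W)
        else:
            m = s.reshape(*lead, W, H)
            axes = tuple(range(len(lead))) + (len(lead) + 1, len(lead))
            m = m.transpose(axes) if isinstance(m, Tensor) else np.transpose(m, axes)
        maps.append(m)
    out = maps[0] + maps[1]
    out = out + maps[2]
    return out + maps[3]
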