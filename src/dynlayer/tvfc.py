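"""Instantaneous-phase time-varying functional connectivity (TVFC).

Each regional BOLD signal is mapped to an analytic signal via the Hilbert
transform; the instantaneous phase angle θ_{n,t} of region ``n`` at timepoint
``t`` then yields a per-timepoint connectivity layer

    TVFC[n, p, t] = cos(θ_{n,t} − θ_{p,t})

which is 1 for perfectly synchronized regions, 0 at 90° phase difference and
−1 in anti-phase.  Negative coherence values are clamped to zero before the
multilayer network is assembled, keeping only positive coupling.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.signal import hilbert

__all__ = [
    "TVFCStack",
    "instantaneous_phase",
    "phase_coherence",
    "clamp_negatives",
    "compute_tvfc",
]


@dataclass(frozen=True)
class TVFCStack:
    """Stack of per-timepoint symmetric N×N phase-coherence matrices.

    Attributes
    ----------
    data:
        Array of shape ``(T, N, N)``; ``data[t]`` is the connectivity layer at
        timepoint ``t``.  Layers are symmetric with a zero diagonal
        (self-connections are excluded).
    clamped:
        ``True`` once negative entries have been set to zero, i.e. entries lie
        in ``[0, 1]``; otherwise entries lie in ``[−1, 1]``.
    """

    data: np.ndarray
    clamped: bool = False

    @property
    def n_layers(self) -> int:
        return self.data.shape[0]

    @property
    def n_regions(self) -> int:
        return self.data.shape[1]

    def __post_init__(self) -> None:
        if self.data.ndim != 3 or self.data.shape[1] != self.data.shape[2]:
            raise ValueError("TVFC stack must have shape (T, N, N)")


def _validate_series(series: np.ndarray) -> np.ndarray:
    series = np.asarray(series, dtype=float)
    if series.ndim != 2:
        raise ValueError("time series must be a 2-D (T, N) matrix")
    if series.shape[0] < 8:
        raise ValueError(f"need at least 8 timepoints, got {series.shape[0]}")
    bad = ~np.isfinite(series)
    if bad.any():
        t, n = np.argwhere(bad)[0]
        raise ValueError(f"non-finite value at timepoint {t}, region {n}")
    return series


def instantaneous_phase(series: np.ndarray, *, permissive: bool = False) -> np.ndarray:
    """Instantaneous phase of every regional signal via the Hilbert transform.

    Parameters
    ----------
    series:
        ``(T, N)`` matrix, rows = timepoints, columns = regions.  Columns are
        demeaned internally: the analytic-signal phase is not meaningful in
        the presence of a DC offset.
    permissive:
        Constant (zero-variance) columns are degenerate — their analytic
        signal is identically zero and the phase is undefined.  By default
        they raise ``ValueError``; with ``permissive=True`` they are mapped to
        an all-zero phase column instead.

    Returns
    -------
    ``(T, N)`` array of phase angles in ``(−π, π]``.
    """
    series = _validate_series(series)
    centered = series - series.mean(axis=0, keepdims=True)
    constant = np.ptp(centered, axis=0) == 0
    if constant.any():
        if not permissive:
            cols = np.flatnonzero(constant)
            raise ValueError(
                f"constant signal in region(s) {cols.tolist()}: phase undefined "
                "(pass permissive=True to map them to zero phase)"
            )
        # avoid 0/0 inside the transform; phases overwritten below
        centered = centered.copy()
        centered[:, constant] = 1.0
    theta = np.angle(hilbert(centered, axis=0))
    if constant.any():
        theta[:, constant] = 0.0
    return theta


def phase_coherence(theta: np.ndarray) -> TVFCStack:
    """Build the unclamped TVFC stack, layer ``t`` entry ``(n, p)`` =
    ``cos(θ_{n,t} − θ_{p,t})``.

    Output layers are symmetric by construction and the diagonal is zeroed so
    self-loops never enter downstream degree sums.
    """
    theta = np.asarray(theta, dtype=float)
    if theta.ndim != 2:
        raise ValueError("phase matrix must be 2-D (T, N)")
    T, N = theta.shape
    diff = theta[:, :, None] - theta[:, None, :]
    stack = np.cos(diff)
    idx = np.arange(N)
    stack[:, idx, idx] = 0.0
    return TVFCStack(data=stack, clamped=False)


def clamp_negatives(stack: TVFCStack) -> TVFCStack:
    """Set negative coherence entries to zero (positive coupling only).

    Idempotent: clamping an already-clamped stack is a no-op.
    """
    if stack.clamped:
        return stack
    return replace(stack, data=np.maximum(stack.data, 0.0), clamped=True)


def compute_tvfc(series: np.ndarray, *, trim_edges: int = 0,
                 permissive: bool = False) -> TVFCStack:
    """Convenience path: series → phases → clamped coherence stack.

    ``trim_edges=k`` drops the first and last ``k`` layers, discarding Hilbert
    transform edge artifacts; the default keeps all ``T`` timepoints.
    """
    theta = instantaneous_phase(series, permissive=permissive)
    stack = clamp_negatives(phase_coherence(theta))
    if trim_edges:
        if trim_edges < 0 or 2 * trim_edges >= stack.n_layers:
            raise ValueError(f"trim_edges={trim_edges} leaves no layers")
        stack = replace(stack, data=stack.data[trim_edges:-trim_edges])
    return stack
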