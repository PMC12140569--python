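"""Temporal denoising of node time series.

Framewise displacement from the six rigid-body motion parameters, motion
scrubbing (volume censoring with back/forward neighbors), nuisance
regression against motion/CSF/WM regressors and their first-order
derivatives, and high-pass filtering by regression on a discrete-cosine
low-frequency basis. Censored volumes are dropped from every fit and every
downstream statistic — never interpolated.

The fixed stage order is scrub -> nuisance regression -> high-pass; each
:class:`TimeSeries` carries a provenance log of the steps applied to it.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import scipy.linalg

FD_ROTATION_RADIUS_MM = 50.0
DEFAULT_FD_THRESHOLD_MM = 0.5
DEFAULT_HIGHPASS_HZ = 0.008


@dataclass
class TimeSeries:
    """Node-by-volume BOLD matrix with a retention mask.

    Attributes
    ----------
    values : (n_nodes, n_volumes) float array
    tr : repetition time in seconds
    volume_mask : (n_volumes,) bool array, True = retained
    log : provenance of applied processing steps
    """

    values: np.ndarray
    tr: float
    volume_mask: np.ndarray = None
    log: list = field(default_factory=list)

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D nodes x volumes array")
        if self.tr <= 0:
            raise ValueError("tr must be positive")
        if self.volume_mask is None:
            self.volume_mask = np.ones(self.n_volumes, dtype=bool)
        self.volume_mask = np.asarray(self.volume_mask, dtype=bool)
        if self.volume_mask.shape != (self.n_volumes,):
            raise ValueError("volume_mask length must equal the number of volumes")

    @property
    def n_nodes(self) -> int:
        return self.values.shape[0]

    @property
    def n_volumes(self) -> int:
        return self.values.shape[1]

    @property
    def n_retained(self) -> int:
        return int(self.volume_mask.sum())

    def retained(self) -> np.ndarray:
        """values restricted to retained volumes, (n_nodes, n_retained)."""
        return self.values[:, self.volume_mask]


def framewise_displacement(motion: np.ndarray,
                           rotation_radius_mm: float = FD_ROTATION_RADIUS_MM) -> np.ndarray:
    """Per-volume framewise displacement in mm.

    ``motion`` is (n_volumes, 6): three translations in mm then three
    rotations in radians. FD(t) = sum |Delta translation| + radius * sum
    |Delta rotation| (rotations converted to arc length on a head-sized
    sphere); FD(0) = 0.
    """
    motion = np.asarray(motion, dtype=float)
    if motion.ndim != 2 or motion.shape[1] != 6:
        raise ValueError("motion must be (n_volumes, 6)")
    if motion.shape[0] < 2:
        raise ValueError("need at least 2 volumes")
    if not np.all(np.isfinite(motion)):
        raise ValueError("motion parameters contain non-finite values")
    diff = np.abs(np.diff(motion, axis=0))
    fd = diff[:, :3].sum(axis=1) + rotation_radius_mm * diff[:, 3:].sum(axis=1)
    return np.concatenate([[0.0], fd])


def scrub_mask(fd: np.ndarray, threshold_mm: float = DEFAULT_FD_THRESHOLD_MM,
               n_back: int = 1, n_forward: int = 2) -> np.ndarray:
    """Retention mask censoring high-motion volumes and their neighbors.

    Every volume with FD above threshold is excluded together with
    ``n_back`` preceding and ``n_forward`` following volumes (windows
    clipped at the series boundaries).
    """
    fd = np.asarray(fd, dtype=float)
    if not np.all(np.isfinite(fd)):
        raise ValueError("FD contains non-finite values")
    n = fd.size
    mask = np.ones(n, dtype=bool)
    for t in np.flatnonzero(fd > threshold_mm):
        mask[max(0, t - n_back): min(n, t + n_forward + 1)] = False
    return mask


def build_confound_matrix(motion: np.ndarray, csf: np.ndarray, wm: np.ndarray,
                          global_signal: np.ndarray | None = None) -> np.ndarray:
    """Stack nuisance regressors: motion(6) + CSF + WM, plus the backward-
    difference first derivative of each (leading element 0); optionally a
    global-signal column. 16 columns, 17 with the global signal."""
    motion = np.asarray(motion, dtype=float)
    cols = [motion] + [np.asarray(c, dtype=float).reshape(-1, 1) for c in (csf, wm)]
    base = np.hstack(cols)
    deriv = np.vstack([np.zeros((1, base.shape[1])), np.diff(base, axis=0)])
    out = np.hstack([base, deriv])
    if global_signal is not None:
        out = np.hstack([out, np.asarray(global_signal, dtype=float).reshape(-1, 1)])
    return out


def _drop_collinear(X: np.ndarray) -> np.ndarray:
    """Keep a maximal linearly independent column subset (QR with pivoting)."""
    rank = np.linalg.matrix_rank(X)
    if rank == X.shape[1]:
        return X
    _, _, piv = scipy.linalg.qr(X, mode="economic", pivoting=True)
    keep = np.sort(piv[:rank])
    warnings.warn(f"dropping {X.shape[1] - rank} collinear confound column(s)",
                  stacklevel=3)
    return X[:, keep]


def nuisance_regress(ts: TimeSeries, confounds: np.ndarray) -> TimeSeries:
    """OLS residuals of each node series on the confounds (+ intercept).

    Fitted on retained volumes only; residuals at censored volumes are set
    to 0 and stay masked out.
    """
    confounds = np.asarray(confounds, dtype=float)
    if confounds.shape[0] != ts.n_volumes:
        raise ValueError("confound rows must match the number of volumes")
    keep = ts.volume_mask
    X = np.column_stack([np.ones(keep.sum()), confounds[keep]])
    if keep.sum() < X.shape[1] + 2:
        raise ValueError("too few retained volumes for the confound model")
    X = _drop_collinear(X)
    Y = ts.values[:, keep].T                     # (n_ret, n_nodes)
    beta, *_ = np.linalg.lstsq(X, Y, rcond=None)
    resid = np.zeros_like(ts.values)
    resid[:, keep] = (Y - X @ beta).T
    return TimeSeries(resid, ts.tr, keep.copy(),
                      log=ts.log + [{"step": "nuisance_regress",
                                     "n_confounds": int(confounds.shape[1])}])


def dct_basis(n_volumes: int, tr: float, cutoff_hz: float) -> np.ndarray:
    """Discrete-cosine columns with frequency below ``cutoff_hz``.

    Component k of a length-N DCT basis has frequency k / (2 N TR); all
    components below the cutoff (excluding the constant) are returned,
    evaluated at every volume index.
    """
    order = int(np.floor(2.0 * n_volumes * tr * cutoff_hz))
    t = np.arange(n_volumes)
    cols = [np.cos(np.pi * k * (2 * t + 1) / (2.0 * n_volumes)) for k in range(1, order + 1)]
    return np.column_stack(cols) if cols else np.empty((n_volumes, 0))


def highpass_filter(ts: TimeSeries, cutoff_hz: float = DEFAULT_HIGHPASS_HZ) -> TimeSeries:
    """Remove fluctuations slower than ``cutoff_hz``.

    Regresses out (on retained volumes) a constant plus every discrete-
    cosine component with frequency below the cutoff. DCT regression stays
    well-behaved on censored series, unlike an IIR filter applied across
    gaps.
    """
    if cutoff_hz >= 0.5 / ts.tr:
        raise ValueError("cutoff at or above the Nyquist frequency")
    if ts.n_retained < 8:
        raise ValueError("need at least 8 retained volumes")
    keep = ts.volume_mask
    basis = dct_basis(ts.n_volumes, ts.tr, cutoff_hz)
    X = np.column_stack([np.ones(keep.sum()), basis[keep]])
    Y = ts.values[:, keep].T
    beta, *_ = np.linalg.lstsq(X, Y, rcond=None)
    out = np.zeros_like(ts.values)
    out[:, keep] = (Y - X @ beta).T
    return TimeSeries(out, ts.tr, keep.copy(),
                      log=ts.log + [{"step": "highpass", "cutoff_hz": cutoff_hz}])


def denoise(ts: TimeSeries, motion: np.ndarray, csf: np.ndarray, wm: np.ndarray,
            fd_threshold_mm: float = DEFAULT_FD_THRESHOLD_MM,
            n_back: int = 1, n_forward: int = 2,
            highpass_hz: float = DEFAULT_HIGHPASS_HZ) -> TimeSeries:
    """Full denoising pipeline: scrub -> nuisance regression -> high-pass."""
    fd = framewise_displacement(motion)
    mask = ts.volume_mask & scrub_mask(fd, fd_threshold_mm, n_back, n_forward)
    scrubbed = TimeSeries(ts.values, ts.tr, mask,
                          log=ts.log + [{"step": "scrub",
                                         "fd_threshold_mm": fd_threshold_mm,
                                         "n_back": n_back, "n_forward": n_forward,
                                         "n_censored": int((~mask).sum())}])
    conf = build_confound_matrix(motion, csf, wm)
    return highpass_filter(nuisance_regress(scrubbed, conf), highpass_hz)
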