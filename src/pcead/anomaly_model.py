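"""Normal error reference distribution (NERD) and Mahalanobis thresholding.

Phase 2 pools the per-pixel absolute reconstruction errors of held-out
normal slides into a single 3-variate Gaussian over the RGB error
channels (patches are not spatially registered, so a per-position model
is meaningless).  Phase 3 converts each pixel's error vector into a
Mahalanobis distance from that Gaussian and picks the cut-off tau as an
empirical quantile of distances on further held-out normal slides: a
pixel whose distance exceeds tau is called anomalous (tumor).

If errors really were Gaussian, squared distances would follow a
chi-squared law with 3 degrees of freedom, which gives a closed-form
check for the calibration (tau at q = 0.05 ~ sqrt of the chi2_3 0.95
quantile ~ 2.796).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

import numpy as np

from .wsi_tiling import Patch

__all__ = [
    "ErrorTensor", "NERD", "CutoffThreshold", "NerdAccumulator",
    "reconstruction_error", "fit_nerd", "mahalanobis_map",
    "calibrate_threshold", "binarize", "save_nerd", "load_nerd",
    "save_threshold", "load_threshold",
]


@dataclass
class ErrorTensor:
    """Per-pixel absolute reconstruction error, H x W x 3, with provenance."""

    errors: np.ndarray
    slide: str = ""
    origin: tuple[int, int] = (0, 0)

    def __post_init__(self):
        e = np.asarray(self.errors, dtype=np.float64)
        if e.ndim != 3 or e.shape[2] != 3:
            raise ValueError("error tensor must be H x W x 3")
        if (e < 0).any():
            raise ValueError("absolute errors must be non-negative")
        self.errors = e


@dataclass
class NERD:
    """3-variate Gaussian of normal-tissue reconstruction errors."""

    mean: np.ndarray
    cov: np.ndarray
    epsilon: float = 1e-6
    n: int = 0

    def __post_init__(self):
        self.mean = np.asarray(self.mean, dtype=np.float64).reshape(3)
        self.cov = np.asarray(self.cov, dtype=np.float64).reshape(3, 3)
        if not np.allclose(self.cov, self.cov.T, atol=1e-9):
            raise ValueError("covariance must be symmetric")
        if self.n < 2:
            raise ValueError("NERD requires n >= 2 samples")

    @property
    def regularized_cov(self) -> np.ndarray:
        return self.cov + self.epsilon * np.eye(3)

    def precision(self) -> np.ndarray:
        try:
            return np.linalg.inv(self.regularized_cov)
        except np.linalg.LinAlgError as exc:
            raise ValueError("regularized covariance is not invertible") from exc


@dataclass
class CutoffThreshold:
    """Mahalanobis cut-off tau calibrated at exceedance rate q."""

    tau: float
    q: float
    n: int

    def __post_init__(self):
        if self.tau < 0:
            raise ValueError("tau must be non-negative")
        if not 0 <= self.q < 1:
            raise ValueError("q must lie in [0, 1)")


def reconstruction_error(input_patch: Patch, recon: Patch) -> ErrorTensor:
    """Elementwise |input - reconstruction| per RGB channel."""
    if input_patch.image.shape != recon.image.shape:
        raise ValueError("input and reconstruction shapes differ")
    return ErrorTensor(errors=np.abs(input_patch.image - recon.image),
                       slide=input_patch.slide, origin=input_patch.origin)


class NerdAccumulator:
    """Streaming pooled moments so Phase 2 never holds all errors at once.

    Accumulates per-channel sums and the 3x3 sum of outer products; the
    pooled mean and (n-1)-denominator covariance fall out at the end.
    Order-independent and exactly equivalent to a batch fit.
    """

    def __init__(self, epsilon: float = 1e-6):
        self.epsilon = epsilon
        self.n = 0
        self.sum = np.zeros(3)
        self.sum_outer = np.zeros((3, 3))

    def add(self, err: ErrorTensor | np.ndarray) -> "NerdAccumulator":
        e = err.errors if isinstance(err, ErrorTensor) else np.asarray(err, dtype=np.float64)
        flat = e.reshape(-1, 3)
        self.n += flat.shape[0]
        self.sum += flat.sum(axis=0)
        self.sum_outer += flat.T @ flat
        return self

    def finalize(self) -> NERD:
        if self.n < 2:
            raise ValueError(f"need at least 2 pixels to fit NERD, got {self.n}")
        mu = self.sum / self.n
        cov = (self.sum_outer - self.n * np.outer(mu, mu)) / (self.n - 1)
        cov = (cov + cov.T) / 2.0            # kill round-off asymmetry
        return NERD(mean=mu, cov=cov, epsilon=self.epsilon, n=self.n)


def fit_nerd(errors: Iterable[ErrorTensor], epsilon: float = 1e-6) -> NERD:
    """Pool a stream of error tensors into the NERD Gaussian."""
    acc = NerdAccumulator(epsilon=epsilon)
    for err in errors:
        acc.add(err)
    return acc.finalize()


def mahalanobis_map(errors: ErrorTensor | np.ndarray, nerd: NERD) -> np.ndarray:
    """Per-pixel Mahalanobis distance sqrt((e-mu)^T (Sigma+eps I)^-1 (e-mu))."""
    prec = nerd.precision()
    e = errors.errors if isinstance(errors, ErrorTensor) else np.asarray(errors, float)
    d = e - nerd.mean
    d2 = np.einsum("hwi,ij,hwj->hw", d, prec, d)
    return np.sqrt(np.maximum(d2, 0.0))


def calibrate_threshold(normal_distances: Iterable[float], q: float = 0.05) -> CutoffThreshold:
    """Cut-off tau as the nearest-rank (1-q)-quantile of normal distances.

    With rank k = ceil((1-q) * n) over the pooled held-out normal pixel
    distances; q = 0 returns the maximum observed distance, so no
    calibration pixel exceeds tau.
    """
    if not 0 <= q < 1:
        raise ValueError("q must lie in [0, 1)")
    values = np.fromiter(_flatten(normal_distances), dtype=np.float64)
    if values.size == 0:
        raise ValueError("cannot calibrate on an empty distance stream")
    values.sort()
    if q == 0:
        tau = values[-1]
    else:
        k = int(np.ceil((1.0 - q) * values.size))
        tau = values[max(k, 1) - 1]
    return CutoffThreshold(tau=float(tau), q=q, n=int(values.size))


def _flatten(stream):
    for item in stream:
        arr = np.asarray(item, dtype=np.float64)
        if arr.ndim == 0:
            yield float(arr)
        else:
            yield from arr.ravel().tolist()


def binarize(dmap: np.ndarray, threshold: CutoffThreshold | float) -> np.ndarray:
    """Anomaly mask: True where distance is strictly higher than tau."""
    tau = threshold.tau if isinstance(threshold, CutoffThreshold) else float(threshold)
    return np.asarray(dmap) > tau


# -- JSON serialization ----------------------------------------------------

def save_nerd(nerd: NERD, path) -> None:
    Path(path).write_text(json.dumps({
        "mean": nerd.mean.tolist(),
        "cov": nerd.cov.tolist(),
        "epsilon": nerd.epsilon,
        "n": nerd.n,
    }, indent=1))


def load_nerd(path) -> NERD:
    d = json.loads(Path(path).read_text())
    return NERD(mean=np.array(d["mean"]), cov=np.array(d["cov"]),
                epsilon=d["epsilon"], n=d["n"])


def save_threshold(t: CutoffThreshold, path) -> None:
    Path(path).write_text(json.dumps({"tau": t.tau, "q": t.q, "n": t.n}, indent=1))


def load_threshold(path) -> CutoffThreshold:
    d = json.loads(Path(path).read_text())
    return CutoffThreshold(tau=d["tau"], q=d["q"], n=d["n"])
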