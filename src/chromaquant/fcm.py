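"""Fuzzy C-means clustering of nucleus pixel intensities.

The nucleus image is clustered in intensity space only, so the fit is
carried out on the 256-bin histogram: each distinct intensity is one
datum weighted by its pixel count.  This is algebraically identical to
running FCM on the individual pixels (the objective and both update
equations depend on the data only through the multiset of intensity
values) but is tractable even when the cluster count runs into the
hundreds, as it can under the histogram-peak rule below.

The number of clusters defaults to the intensity value at the peak of
the nucleus histogram (the mode of the stretched image), clamped to
``[c_min, c_max]``.  ``c_min`` defaults to 6 so that five distinct
sensitivity thresholds exist downstream.

The minimised objective is

    W_m = sum_i sum_j mu_ij^m * ||x_j - v_i||^2

subject to sum_i mu_ij = 1, with the classic alternating updates

    mu_ij = 1 / sum_k (||x_j - v_i||^2 / ||x_j - v_k||^2)^(1/(m-1))
    v_i   = sum_j mu_ij^m x_j / sum_j mu_ij^m

A datum coinciding exactly with one or more centroids receives crisp
membership split equally among the coinciding clusters.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "FCMConfig",
    "FCMResult",
    "histogram",
    "select_cluster_count",
    "fcm_fit",
    "label_image",
]


@dataclass
class FCMConfig:
    """Settings for the fuzzy C-means fit.

    m: fuzziness exponent (> 1); 2.0 is the standard choice.
    max_iter: iteration cap.
    tol: minimum objective improvement; iteration stops once the
        decrease of W_m falls below this.
    c_min / c_max: clamp range for the automatic cluster count.
    """

    m: float = 2.0
    max_iter: int = 100
    tol: float = 1e-5
    c_min: int = 6
    c_max: int = 255

    def __post_init__(self) -> None:
        if self.m <= 1:
            raise ValueError("fuzziness exponent m must be > 1")
        if self.max_iter < 1:
            raise ValueError("max_iter must be >= 1")
        if self.tol <= 0:
            raise ValueError("tol must be > 0")


@dataclass
class FCMResult:
    """Outcome of a histogram-weighted FCM fit.

    ``values`` holds the distinct intensities observed in the image (the
    weighted data); ``memberships`` is the corresponding
    ``len(values) x c`` table of membership degrees, each row summing
    to 1.  ``centroids`` are sorted ascending.  ``objective_trace``
    records W_m after every iteration and is non-increasing.
    """

    centroids: np.ndarray
    memberships: np.ndarray
    values: np.ndarray
    weights: np.ndarray
    objective_trace: list[float]
    m: float
    c_requested: int
    c_effective: int
    reduced: bool = False
    converged: bool = False
    n_iter: int = 0
    segmented: np.ndarray | None = field(default=None, repr=False)


def histogram(image: np.ndarray) -> np.ndarray:
    """256-bin intensity histogram; counts[v] = pixels at intensity v."""
    image = np.asarray(image)
    if np.any(image < 0) or np.any(image > 255):
        raise ValueError("intensities must lie in [0, 255]")
    return np.bincount(image.ravel().astype(np.int64), minlength=256)


def select_cluster_count(
    hist: np.ndarray, c_min: int = 6, c_max: int = 255
) -> int:
    """Cluster count from the histogram-peak rule.

    Returns the intensity value at which the histogram is maximal
    (lowest intensity on ties), clamped to ``[c_min, c_max]``.
    """
    hist = np.asarray(hist)
    if hist.sum() == 0:
        raise ValueError("empty histogram")
    peak = int(np.argmax(hist))  # argmax takes the lowest index on ties
    return int(min(max(peak, c_min), c_max))


def _memberships(
    values: np.ndarray, centroids: np.ndarray, m: float
) -> np.ndarray:
    """Membership update (rows = data, columns = clusters)."""
    d2 = (values[:, None] - centroids[None, :]) ** 2
    zero = d2 <= 0.0
    any_zero = zero.any(axis=1)
    dmin = d2.min(axis=1, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        w = (dmin / d2) ** (1.0 / (m - 1.0))
    u = w / w.sum(axis=1, keepdims=True)
    if any_zero.any():
        # exact coincidence: crisp membership, split among ties
        z = zero[any_zero].astype(np.float64)
        u[any_zero] = z / z.sum(axis=1, keepdims=True)
    return u


def fcm_fit(
    hist: np.ndarray, c: int, config: FCMConfig | None = None
) -> FCMResult:
    """Histogram-weighted fuzzy C-means fit with ``c`` clusters.

    Initial centroids are evenly spaced between the observed minimum
    and maximum intensity, which makes the fit fully deterministic.  If
    the image holds fewer distinct intensities than ``c``, the cluster
    count is reduced to that number and flagged via ``result.reduced``.
    """
    if config is None:
        config = FCMConfig()
    if c < 1:
        raise ValueError("cluster count must be >= 1")
    hist = np.asarray(hist, dtype=np.float64)
    present = np.nonzero(hist)[0]
    if present.size == 0:
        raise ValueError("empty histogram")
    values = present.astype(np.float64)
    weights = hist[present]

    c_requested = int(c)
    reduced = False
    if values.size < c:
        c = int(values.size)
        reduced = True

    centroids = np.linspace(values.min(), values.max(), c)
    m = config.m
    trace: list[float] = []
    converged = False
    n_iter = 0
    for n_iter in range(1, config.max_iter + 1):
        u = _memberships(values, centroids, m)
        um = (u**m) * weights[:, None]
        den = um.sum(axis=0)
        num = um.T @ values
        centroids = np.where(den > 0, num / np.where(den > 0, den, 1.0),
                             centroids)
        d2 = (values[:, None] - centroids[None, :]) ** 2
        obj = float(np.sum((u**m) * weights[:, None] * d2))
        trace.append(obj)
        if len(trace) >= 2 and abs(trace[-2] - trace[-1]) < config.tol:
            converged = True
            break

    order = np.argsort(centroids, kind="stable")
    centroids = centroids[order]
    u = _memberships(values, centroids, m)

    return FCMResult(
        centroids=centroids,
        memberships=u,
        values=values,
        weights=weights,
        objective_trace=trace,
        m=m,
        c_requested=c_requested,
        c_effective=int(c),
        reduced=reduced,
        converged=converged,
        n_iter=n_iter,
    )


def label_image(image: np.ndarray, result: FCMResult) -> np.ndarray:
    """Replace each pixel by the centroid intensity of its cluster.

    Every intensity is assigned to its maximum-membership cluster; on an
    exact membership tie the lower centroid wins (centroids are sorted,
    argmax returns the first).  Centroid intensities are rounded to the
    nearest integer in [0, 255].
    """
    levels = np.arange(256, dtype=np.float64)
    u = _memberships(levels, result.centroids, result.m)
    assign = np.argmax(u, axis=1)
    rounded = np.clip(np.round(result.centroids), 0, 255).astype(np.uint8)
    lut = rounded[assign]
    return lut[np.asarray(image).astype(np.int64)]
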