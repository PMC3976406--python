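"""Per-scan PCA-reduced spatial ICA with fixed sign and count conventions.

Each scan is decomposed independently (sessions are never concatenated).
Component maps are z-scored over the brain mask — a map value is then the
number of spatial standard deviations by which the component modulates that
voxel, i.e. the amplitude of its correlated fluctuations there. Conventions:
positive spatial skewness per map, components ordered by descending
explained variance, failures after a bounded number of seeded restarts.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats
from sklearn.decomposition import FastICA
from sklearn.exceptions import ConvergenceWarning

from .core import Scan

logger = logging.getLogger(__name__)

MAX_ICA_RESTARTS = 5


@dataclass
class ComponentSet:
    """K spatial z-score maps and time courses from one scan's ICA."""

    subject: str
    day: str | None
    timepoint: str | None
    maps: np.ndarray  # (K, V) spatial z-scores over the brain mask
    courses: np.ndarray | None  # (K, T); None for derived representatives
    variance_retained: float | None = None  # PCA diagnostic, fraction in [0,1]

    def __post_init__(self) -> None:
        self.maps = np.asarray(self.maps, dtype=float)
        if self.maps.ndim != 2:
            raise ValueError("maps must be K x V")
        if self.courses is not None:
            self.courses = np.asarray(self.courses, dtype=float)
            if self.courses.shape[0] != self.maps.shape[0]:
                raise ValueError("courses and maps disagree on K")
            if self.maps.shape[0] > self.courses.shape[1]:
                raise ValueError("K cannot exceed the number of time points")

    @property
    def k(self) -> int:
        return self.maps.shape[0]

    @property
    def condition(self) -> str | None:
        if self.day is None or self.timepoint is None:
            return None
        return f"{self.day}-{self.timepoint}"


def select_component_count(n_timepoints: int, divisor: int = 6) -> int:
    """Smallest component count that is at least 1/``divisor`` of T.

    The standard rule of thumb for resting-state decompositions: with 180
    volumes and the default divisor this gives 30 components.
    """
    if n_timepoints < divisor:
        raise ValueError(f"need at least {divisor} time points, got {n_timepoints}")
    return int(-(-n_timepoints // divisor))  # ceil division


def zscale_map(raw_map: np.ndarray, mask: np.ndarray | None = None) -> np.ndarray:
    """Scale a spatial map to z-scores over the (masked) voxel distribution."""
    raw_map = np.asarray(raw_map, dtype=float)
    values = raw_map if mask is None else raw_map[np.asarray(mask, dtype=bool)]
    sd = values.std()
    if sd == 0:
        raise ValueError("map has zero variance over the mask; cannot z-scale")
    return (raw_map - values.mean()) / sd


def _orient_and_order(maps: np.ndarray, courses: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Positive-skewness sign flip, then order by descending explained variance."""
    for k in range(maps.shape[0]):
        if stats.skew(maps[k]) < 0:
            maps[k] = -maps[k]
            courses[k] = -courses[k]
    # variance contributed by component k to the data: ||a_k||^2 * ||s_k||^2
    contrib = (courses**2).sum(axis=1) * (maps**2).sum(axis=1)
    order = np.argsort(-contrib, kind="stable")
    return maps[order], courses[order]


def decompose_scan(scan: Scan, k: int | None = None, seed: int = 0) -> ComponentSet:
    """PCA-reduced spatial ICA of one preprocessed scan.

    The T x V data matrix is modeled as mixtures (over time) of K spatially
    independent sources; FastICA is run on the voxels-as-samples orientation,
    so the unmixed sources are the spatial maps and the mixing matrix holds
    the component time courses. Non-convergence triggers up to
    ``MAX_ICA_RESTARTS`` seeded restarts before failing.
    """
    if k is None:
        k = select_component_count(scan.n_timepoints)
    if k > scan.n_timepoints:
        raise ValueError(f"K={k} exceeds T={scan.n_timepoints}")

    x = scan.data - scan.data.mean(axis=0)  # center each voxel's course
    # PCA retained-variance diagnostic for the K-dimensional reduction
    sv = np.linalg.svd(x, compute_uv=False)
    total = float((sv**2).sum())
    variance_retained = float((sv[:k] ** 2).sum() / total) if total > 0 else 0.0

    last_err: Exception | None = None
    for attempt in range(MAX_ICA_RESTARTS):
        rs = np.random.RandomState(
            int(np.random.SeedSequence([int(seed), attempt]).generate_state(1)[0] % (2**31))
        )
        # deflation extracts sources one at a time; unlike the parallel
        # update it converges even when trailing components are near-Gaussian
        ica = FastICA(n_components=k, whiten="unit-variance", algorithm="deflation",
                      max_iter=1000, tol=1e-4, random_state=rs)
        with warnings.catch_warnings(record=True) as caught:
            warnings.simplefilter("always", ConvergenceWarning)
            try:
                sources = ica.fit_transform(x.T)  # (V, K) spatial sources
            except Exception as err:  # pragma: no cover - rare numerical failure
                last_err = err
                continue
        if any(issubclass(w.category, ConvergenceWarning) for w in caught):
            last_err = RuntimeError(f"FastICA did not converge (attempt {attempt + 1})")
            logger.warning("ICA restart %d for %s %s: non-convergence",
                           attempt + 1, scan.subject, scan.condition)
            continue
        maps = sources.T.copy()  # (K, V)
        courses = ica.mixing_.T.copy()  # (K, T)
        # transfer each map's scale to its course, then z-score the map
        for j in range(k):
            mu, sd = maps[j].mean(), maps[j].std()
            if sd == 0:
                raise ValueError(f"ICA returned a constant map (component {j})")
            maps[j] = (maps[j] - mu) / sd
            courses[j] = courses[j] * sd
        maps, courses = _orient_and_order(maps, courses)
        logger.info("ICA %s %s: K=%d, variance retained %.4f",
                    scan.subject, scan.condition, k, variance_retained)
        return ComponentSet(
            subject=scan.subject, day=scan.day, timepoint=scan.timepoint,
            maps=maps, courses=courses, variance_retained=variance_retained,
        )
    raise RuntimeError(
        f"spatial ICA failed for {scan.subject} {scan.condition} after "
        f"{MAX_ICA_RESTARTS} seeded restarts: {last_err}"
    )
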