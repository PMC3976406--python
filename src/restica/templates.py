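"""Group RSN templates and best-fitting component selection.

Each group cluster yields a random-effects one-sample t-map (subjects as
random observations); thresholding it at P = 0.05 Bonferroni-corrected over
brain voxels (one-tailed, positive — network membership is positive
engagement) gives the RSN template mask. A subject's best-fitting component
for an RSN in a given scan is the one maximizing the goodness-of-fit score:
mean component z-score inside the template mask minus the mean outside.
Templates derive only from baseline scans; selection sees only the scan
under evaluation, so the later contrast is unbiased by construction.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .core import StatMap, VolumeGrid
from .decompose import ComponentSet
from .grouping import ComponentCluster, ComponentRef
from .preprocess import T_CAP

logger = logging.getLogger(__name__)


@dataclass
class TemplateRSN:
    """A thresholded group network template."""

    label: str
    tmap: np.ndarray  # (V,)
    df: int
    mask: np.ndarray  # (V,) boolean
    alpha: float
    correction: str = "bonferroni"
    usable: bool = True


def one_sample_tmap(values: np.ndarray) -> tuple[np.ndarray, bool]:
    """Per-voxel one-sample t across rows; zero-variance voxels capped.

    Returns the t-vector and whether any voxel hit the ±T_CAP cap (a voxel
    with zero spread and zero mean gets t = 0).
    """
    values = np.asarray(values, dtype=float)
    n = values.shape[0]
    mean = values.mean(axis=0)
    sd = values.std(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = mean / (sd / np.sqrt(n))
    degenerate = sd == 0
    capped = False
    if degenerate.any():
        t[degenerate] = np.sign(mean[degenerate]) * T_CAP
        capped = bool((mean[degenerate] != 0).any())
    return t, capped


def cluster_tmap(cluster: ComponentCluster, grid: VolumeGrid) -> StatMap:
    """Random-effects one-sample t-map of a cluster's member maps."""
    n = cluster.n_members
    if n < 3:
        raise ValueError(f"random-effects t-map needs >= 3 members, got {n}")
    t, capped = one_sample_tmap(cluster.member_maps)
    if capped:
        logger.warning("cluster %d: zero-variance voxels capped at ±%g", cluster.label, T_CAP)
    return StatMap(values=t, df=n - 1, grid=grid, tail="one", capped=capped)


def make_template_mask(
    tmap: StatMap, alpha: float = 0.05, n_tests: int | None = None, label: str = ""
) -> TemplateRSN:
    """Bonferroni-corrected one-tailed template mask from a cluster t-map."""
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    if n_tests is None:
        n_tests = tmap.grid.n_voxels
    threshold = stats.t.ppf(1.0 - alpha / n_tests, tmap.df)
    mask = tmap.values >= threshold
    usable = bool(mask.any())
    if not usable:
        logger.warning("template %r: no voxel survives P=%g Bonferroni over %d tests",
                       label, alpha, n_tests)
    return TemplateRSN(label=label, tmap=tmap.values.copy(), df=tmap.df,
                       mask=mask, alpha=alpha, usable=usable)


def goodness_of_fit(component_map: np.ndarray, mask: np.ndarray) -> float:
    """Template goodness of fit: mean z inside the mask minus mean outside."""
    component_map = np.asarray(component_map, dtype=float)
    mask = np.asarray(mask, dtype=bool)
    if component_map.shape != mask.shape:
        raise ValueError("map and mask must share the masked voxel order")
    n_in = int(mask.sum())
    if n_in == 0 or n_in == mask.size:
        raise ValueError("template mask must be nonempty and not cover every voxel")
    return float(component_map[mask].mean() - component_map[~mask].mean())


def select_best_fit(component_set: ComponentSet, template: TemplateRSN) -> tuple[ComponentRef, float]:
    """The component maximizing GOF against a template; ties -> lowest index."""
    if not template.usable:
        raise ValueError(f"template {template.label!r} is unusable (empty mask)")
    scores = np.array([goodness_of_fit(m, template.mask) for m in component_set.maps])
    best = int(np.argmax(scores))  # argmax returns the first (lowest) index on ties
    ref = ComponentRef(component_set.subject, component_set.day,
                       component_set.timepoint, best)
    logger.debug("best fit for %s %s vs %s: component %d (GOF %.3f)",
                 component_set.subject, component_set.condition, template.label,
                 best, scores[best])
    return ref, float(scores[best])


def build_templates(
    clusters: list[ComponentCluster], grid: VolumeGrid, alpha: float = 0.05
) -> list[TemplateRSN]:
    """Template masks for every group cluster (unusable ones flagged)."""
    templates = []
    for cluster in clusters:
        tmap = cluster_tmap(cluster, grid)
        templates.append(make_template_mask(tmap, alpha=alpha, label=f"cluster{cluster.label}"))
    return templates
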