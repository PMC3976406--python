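"""End-to-end study analysis: preprocess -> ICA -> group -> template -> infer.

Templates are built from baseline (T1) scans only; the combined exhaustion
contrast and the regional ANCOVA then run per selected network template.
Network labeling is by spatial match against user-supplied reference maps
(for synthetic studies, the generator's true network maps).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import ConfoundSet, Scan, StatMap, VolumeGrid
from .decompose import ComponentSet, decompose_scan, select_component_count
from .grouping import BASELINE_CONDITIONS, hierarchical_group, spatial_similarity
from .inference import (
    DEFAULT_CONTRAST,
    ContrastSpec,
    RegionCluster,
    ancova_scores,
    cluster_threshold_mc,
    contrast_tmap,
    estimate_smoothness,
    extract_clusters,
    network_adjusted_alpha,
    regional_scores,
)
from .preprocess import preprocess_scan
from .templates import TemplateRSN, build_templates, select_best_fit
from .behavior import pooled_exhaustion_table

logger = logging.getLogger(__name__)


@dataclass
class NetworkResult:
    """Inference results for one selected network template."""

    template: TemplateRSN
    best_fit_maps: dict[str, dict[str, np.ndarray]]  # subject -> condition -> z-map
    best_fit_table: pd.DataFrame
    contrast_map: StatMap
    fwhm_mm: float
    min_cluster_size: int
    clusters: list[RegionCluster]
    scores: list[pd.DataFrame] = field(default_factory=list)
    ancova: list[dict] = field(default_factory=list)


@dataclass
class StudyResult:
    component_sets: dict[tuple[str, str], ComponentSet]
    templates: list[TemplateRSN]
    networks: dict[str, NetworkResult]
    excluded_scans: list[tuple[str, str]]
    k: int
    adjusted_alpha: float


def match_templates(
    templates: list[TemplateRSN], reference_maps: np.ndarray, labels: list[str] | None = None
) -> dict[str, TemplateRSN]:
    """Label templates by best absolute spatial correlation to references.

    Greedy one-to-one matching in descending similarity; unusable templates
    are skipped. References are, e.g., generator truth maps (synthetic) or
    canonical network masks (real data).
    """
    reference_maps = np.atleast_2d(np.asarray(reference_maps, dtype=float))
    if labels is None:
        labels = [f"network{i}" for i in range(reference_maps.shape[0])]
    usable = [t for t in templates if t.usable]
    sims = np.array([[spatial_similarity(t.tmap, ref) for t in usable] for ref in reference_maps])
    out: dict[str, TemplateRSN] = {}
    taken: set[int] = set()
    for _ in range(min(len(labels), len(usable))):
        i, j = np.unravel_index(np.argmax(sims), sims.shape)
        out[labels[i]] = usable[j]
        taken.add(j)
        sims[i, :] = -1
        sims[:, j] = -1
    return out


def run_study(
    scans: list[Scan],
    confounds: dict[tuple[str, str], ConfoundSet],
    behavior: pd.DataFrame | None = None,
    reference_maps: np.ndarray | None = None,
    reference_labels: list[str] | None = None,
    k: int | None = None,
    hp_cycles: float = 2.0,
    motion_limit_mm: float = 4.0,
    template_alpha: float = 0.05,
    contrast: dict[str, float] | None = None,
    voxel_p: float = 0.01,
    cluster_alpha: float = 0.05,
    n_networks_tested: int | None = None,
    mc_iter: int = 500,
    fwhm_override_mm: float | None = None,
    seed: int = 0,
    score_scans: tuple[str, ...] = ("WD-T2", "WD-T3"),
) -> StudyResult:
    """Run the full repeated-measures ICA analysis on one study.

    When ``reference_maps`` is given, only the matching templates are carried
    into inference (and ``n_networks_tested`` defaults to their number);
    otherwise every usable template is tested.
    """
    grid = scans[0].grid
    spec = ContrastSpec(dict(contrast) if contrast else dict(DEFAULT_CONTRAST))

    # 1. preprocessing with motion exclusion
    clean: dict[tuple[str, str], Scan] = {}
    excluded: list[tuple[str, str]] = []
    for scan in scans:
        key = (scan.subject, scan.condition)
        out = preprocess_scan(scan, confounds[key], hp_cycles=hp_cycles,
                              motion_limit_mm=motion_limit_mm)
        if out is None:
            excluded.append(key)
        else:
            clean[key] = out
    if excluded:
        logger.warning("excluded %d scans by motion QC: %s", len(excluded), excluded)

    # 2. per-scan spatial ICA
    if k is None:
        k = select_component_count(scans[0].n_timepoints)
    component_sets: dict[tuple[str, str], ComponentSet] = {}
    for i, (key, scan) in enumerate(sorted(clean.items())):
        ica_seed = int(np.random.SeedSequence([int(seed), 17, i]).generate_state(1)[0] % (2**31))
        component_sets[key] = decompose_scan(scan, k=k, seed=ica_seed)

    # 3-4. baseline-only hierarchical grouping and template construction
    baseline_sets = [cs for (subj, cond), cs in component_sets.items()
                     if cond in BASELINE_CONDITIONS]
    clusters = hierarchical_group(baseline_sets)
    templates = build_templates(clusters, grid, alpha=template_alpha)

    if reference_maps is not None:
        selected = match_templates(templates, reference_maps, reference_labels)
    else:
        selected = {f"cluster{t.label}": t for t in templates if t.usable}
    n_tested = n_networks_tested if n_networks_tested is not None else max(len(selected), 1)
    adj_alpha = network_adjusted_alpha(cluster_alpha, n_tested)

    # behavioral exhaustion lookup for the regional ANCOVA
    exhaustion: dict[tuple[str, str], float] | None = None
    if behavior is not None:
        pooled = pooled_exhaustion_table(behavior)
        exhaustion = {
            (r.subject, f"{r.day}-{r.timepoint}"): float(r.exhaustion)
            for r in pooled.itertuples()
        }

    networks: dict[str, NetworkResult] = {}
    for name, template in selected.items():
        # 5. per-subject per-scan best-fit component selection
        best_maps: dict[str, dict[str, np.ndarray]] = {}
        fit_rows = []
        for (subj, cond), cs in component_sets.items():
            ref, gof = select_best_fit(cs, template)
            best_maps.setdefault(subj, {})[cond] = cs.maps[ref.index]
            fit_rows.append({"subject": subj, "scan": cond, "rsn": name,
                             "component": ref.index, "gof": gof})

        # 6. combined within-subject contrast + Monte-Carlo cluster threshold
        complete = {s: m for s, m in best_maps.items()
                    if all(c in m for c, w in spec.weights.items() if w != 0)}
        tmap = contrast_tmap(complete, spec, grid)
        fwhm = fwhm_override_mm if fwhm_override_mm is not None else \
            estimate_smoothness(tmap.values, grid)
        min_size = cluster_threshold_mc(grid, fwhm, voxel_p=voxel_p, alpha=adj_alpha,
                                        n_iter=mc_iter, seed=seed)
        regions = extract_clusters(tmap, voxel_p=voxel_p, min_size=min_size)

        # 7. regional scores and exhaustion ANCOVA for surviving clusters
        scores, ancovas = [], []
        for ri, region in enumerate(regions):
            tbl = regional_scores(best_maps, region, grid,
                                  behavior_exhaustion=exhaustion,
                                  scans=score_scans, rsn=name, region_label=f"region{ri}")
            scores.append(tbl)
            if exhaustion is not None and len(tbl):
                try:
                    ancovas.append(ancova_scores(tbl))
                except ValueError as err:
                    logger.warning("ANCOVA skipped for %s region %d: %s", name, ri, err)
                    ancovas.append({})
        networks[name] = NetworkResult(
            template=template, best_fit_maps=best_maps,
            best_fit_table=pd.DataFrame(fit_rows), contrast_map=tmap,
            fwhm_mm=float(fwhm), min_cluster_size=min_size, clusters=regions,
            scores=scores, ancova=ancovas,
        )

    return StudyResult(component_sets=component_sets, templates=templates,
                       networks=networks, excluded_scans=excluded, k=k,
                       adjusted_alpha=adj_alpha)


def dice(mask_a: np.ndarray, mask_b: np.ndarray) -> float:
    """Dice overlap of two boolean masks."""
    a = np.asarray(mask_a, dtype=bool)
    b = np.asarray(mask_b, dtype=bool)
    denom = a.sum() + b.sum()
    if denom == 0:
        return 0.0
    return float(2.0 * (a & b).sum() / denom)
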