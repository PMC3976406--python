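"""Voxelwise repeated-measures inference with Monte-Carlo cluster correction.

The within-subject design (day x time point) is tested through a single
combined linear contrast on each subject's best-fit component maps — by
default ``3*WD-T3 - WD-T1 - FD-T1 - FD-T3``, which isolates an effect
present only in the most exhausted scan. Because the contrast weights sum
to zero, subject-specific constant maps cancel and the contrast t-map is a
one-sample t on the per-subject contrast scores (exact for a single
within-subject contrast).

Voxelwise thresholding at p = 0.01 (two-tailed, since both enhancement and
suppression are of interest) is combined with a cluster-extent threshold
calibrated by Monte-Carlo simulation of smoothness-matched null Gaussian
fields; with N networks tested, the cluster level is alpha/N. Surviving
clusters are reported with intensity-weighted center of mass (mm), average
and peak t, and extension in mm^3. Regional mean z-scores feed an ANCOVA
with a scan factor, the VAS exhaustion covariate, and their interaction.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage, stats

from .core import StatMap, VolumeGrid
from .preprocess import T_CAP

logger = logging.getLogger(__name__)

FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))

#: The combined exhaustion contrast (weights sum to zero; WD-T2 never enters).
DEFAULT_CONTRAST = {"WD-T3": 3.0, "WD-T1": -1.0, "FD-T1": -1.0, "FD-T3": -1.0}

FACE_CONNECTIVITY = ndimage.generate_binary_structure(3, 1)


@dataclass(frozen=True)
class ContrastSpec:
    """Condition weights of a within-subject linear contrast."""

    weights: dict[str, float]

    def __post_init__(self) -> None:
        nonzero = [w for w in self.weights.values() if w != 0]
        if len(nonzero) < 2:
            raise ValueError("contrast needs at least 2 nonzero weights")
        if abs(sum(self.weights.values())) > 1e-12:
            raise ValueError(f"contrast weights must sum to 0, got {sum(self.weights.values())}")


@dataclass
class RegionCluster:
    """One surviving cluster of a thresholded contrast map."""

    voxel_indices: np.ndarray  # indices into the masked V-vector
    center_of_mass_mm: tuple[float, float, float]
    extension_mm3: float
    avg_t: float
    max_t: float  # signed value at the peak |t| voxel
    sign: str  # {"enhancement", "suppression"}

    @property
    def n_voxels(self) -> int:
        return int(self.voxel_indices.size)

    def region_mask(self, grid: VolumeGrid) -> np.ndarray:
        mask = np.zeros(grid.n_voxels, dtype=bool)
        mask[self.voxel_indices] = True
        return mask


def network_adjusted_alpha(alpha: float, n_networks: int) -> float:
    """Cluster-level alpha divided by the number of networks tested (5/N%)."""
    if n_networks < 1:
        raise ValueError("n_networks must be >= 1")
    return alpha / n_networks


def contrast_tmap(
    maps: dict[str, dict[str, np.ndarray]], spec: ContrastSpec, grid: VolumeGrid
) -> StatMap:
    """One-sample t over per-subject contrast scores ``c_s = sum_c w_c y_sc``.

    ``maps[subject][condition]`` are the subject's best-fit z-maps. Every
    subject must supply every condition with nonzero weight.
    """
    subjects = sorted(maps)
    if len(subjects) < 3:
        raise ValueError("contrast inference needs >= 3 subjects")
    needed = [c for c, w in spec.weights.items() if w != 0]
    scores = np.empty((len(subjects), grid.n_voxels))
    for i, s in enumerate(subjects):
        for cond in needed:
            if cond not in maps[s]:
                raise ValueError(f"subject {s} is missing condition {cond}")
        scores[i] = sum(spec.weights[c] * np.asarray(maps[s][c], dtype=float) for c in needed)
    n = len(subjects)
    # floor out floating-point residue of the zero-sum weights so that
    # identical condition maps give exactly t = 0
    scale = max(float(np.abs(np.asarray(list(m.values()))).max()) for m in maps.values())
    scores[np.abs(scores) < 1e-10 * max(scale, 1e-300)] = 0.0
    mean = scores.mean(axis=0)
    sd = scores.std(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = mean / (sd / np.sqrt(n))
    degenerate = sd == 0
    t[degenerate] = np.sign(mean[degenerate]) * T_CAP
    t = np.clip(t, -T_CAP, T_CAP)
    capped = bool((np.abs(t) == T_CAP).any())
    if capped:
        logger.warning("contrast map: zero-variance voxels capped at ±%g", T_CAP)
    return StatMap(values=t, df=n - 1, grid=grid, tail="two", capped=capped)


def estimate_smoothness(map_values: np.ndarray, grid: VolumeGrid) -> float:
    """Effective spatial FWHM (mm) from the variance of first differences.

    For a Gaussian random field, ``sigma = dx * sqrt(var(map) /
    (2 * var(diff)))`` per axis; the FWHM (2.3548 sigma) is averaged over
    axes. White noise yields ~1.18 voxels by construction.
    """
    vol = grid.to_volume(np.asarray(map_values, dtype=float), fill=np.nan)
    vol[~grid.brain_mask] = np.nan
    total_var = np.nanvar(vol)
    if total_var == 0:
        raise ValueError("constant map has no estimable smoothness")
    fwhms = []
    for axis in range(3):
        d = np.diff(vol, axis=axis)
        d = d[np.isfinite(d)]  # differences with both voxels in-mask
        if d.size < 2 or d.var() == 0:
            continue
        sigma_vox = np.sqrt(total_var / (2.0 * d.var()))
        fwhms.append(sigma_vox / FWHM_TO_SIGMA * grid.voxel_size_mm)
    if not fwhms:
        raise ValueError("not enough in-mask neighbors to estimate smoothness")
    return float(np.mean(fwhms))


def _max_cluster_size(binary: np.ndarray) -> int:
    labels, n = ndimage.label(binary, structure=FACE_CONNECTIVITY)
    if n == 0:
        return 0
    return int(np.bincount(labels.ravel())[1:].max())


def cluster_threshold_mc(
    grid: VolumeGrid,
    fwhm_mm: float,
    voxel_p: float = 0.01,
    alpha: float = 0.05,
    n_iter: int = 500,
    seed: int = 0,
    two_tailed: bool = True,
) -> int:
    """Minimum cluster size (voxels) controlling family-wise error at alpha.

    Simulates ``n_iter`` null Gaussian fields at the given smoothness inside
    the brain mask, thresholds at ``voxel_p`` (two-tailed by default), and
    records the maximum face-connected suprathreshold cluster size. Returns
    the smallest k such that fewer than ``alpha * n_iter`` iterations reach
    a cluster of size k.
    """
    if not 0 < voxel_p < 1 or not 0 < alpha < 1:
        raise ValueError("voxel_p and alpha must be in (0, 1)")
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 424242]))
    sigma_vox = fwhm_mm * FWHM_TO_SIGMA / grid.voxel_size_mm
    z_thr = stats.norm.ppf(1.0 - voxel_p / 2) if two_tailed else stats.norm.ppf(1.0 - voxel_p)
    mask = grid.brain_mask
    max_sizes = np.empty(n_iter, dtype=int)
    for i in range(n_iter):
        field = rng.standard_normal(grid.dims)
        if sigma_vox > 0:
            field = ndimage.gaussian_filter(field, sigma_vox)
        vals = field[mask]
        vals = (vals - vals.mean()) / vals.std()
        exceed = np.zeros(grid.dims, dtype=bool)
        exceed[mask] = np.abs(vals) > z_thr if two_tailed else vals > z_thr
        max_sizes[i] = _max_cluster_size(exceed)
    # P(max cluster >= k) < alpha for the returned k
    counts = np.bincount(max_sizes, minlength=2)
    exceed_prob = counts[::-1].cumsum()[::-1] / n_iter  # P(max >= k) for k=0..
    above = np.nonzero(exceed_prob < alpha)[0]
    k = int(above[0]) if above.size else int(max_sizes.max()) + 1
    k = max(k, 1)
    logger.info("MC cluster threshold: fwhm=%.2f mm, p=%g, alpha=%g, iter=%d -> %d voxels",
                fwhm_mm, voxel_p, alpha, n_iter, k)
    return k


def extract_clusters(tmap: StatMap, voxel_p: float = 0.01, min_size: int = 1) -> list[RegionCluster]:
    """Surviving face-connected clusters of a two-tailed thresholded t-map.

    Positive (enhancement) and negative (suppression) exceedances are
    clustered separately. Each cluster reports its |t|-weighted center of
    mass in mm, extension in mm^3, average t, and signed peak t.
    """
    if min_size < 1:
        raise ValueError("min_size must be >= 1")
    grid = tmap.grid
    t_thr = stats.t.ppf(1.0 - voxel_p / 2, tmap.df)
    tvol = grid.to_volume(tmap.values)
    flat_index = np.full(grid.dims, -1, dtype=int)
    flat_index[grid.brain_mask] = np.arange(grid.n_voxels)

    clusters: list[RegionCluster] = []
    for sign, name in ((1, "enhancement"), (-1, "suppression")):
        exceed = np.zeros(grid.dims, dtype=bool)
        exceed[grid.brain_mask] = sign * tmap.values > t_thr
        labels, n = ndimage.label(exceed, structure=FACE_CONNECTIVITY)
        for lab in range(1, n + 1):
            where = labels == lab
            size = int(where.sum())
            if size < min_size:
                continue
            coords = np.argwhere(where)
            weights = np.abs(tvol[where])
            com_vox = (coords * weights[:, None]).sum(axis=0) / weights.sum()
            com_mm = tuple(float(c * grid.voxel_size_mm) for c in com_vox)
            tvals = tvol[where]
            peak = tvals[np.argmax(np.abs(tvals))]
            clusters.append(RegionCluster(
                voxel_indices=flat_index[where],
                center_of_mass_mm=com_mm,
                extension_mm3=size * grid.voxel_volume_mm3,
                avg_t=float(tvals.mean()),
                max_t=float(peak),
                sign=name,
            ))
    clusters.sort(key=lambda c: -abs(c.max_t))
    return clusters


def cluster_report(clusters: list[RegionCluster], label: str = "") -> pd.DataFrame:
    """Tabular cluster summary: center of mass, avg/max t, extension mm^3."""
    rows = [{
        "region": label or f"cluster{i}",
        "sign": c.sign,
        "com_x_mm": c.center_of_mass_mm[0],
        "com_y_mm": c.center_of_mass_mm[1],
        "com_z_mm": c.center_of_mass_mm[2],
        "avg_t": c.avg_t,
        "max_t": c.max_t,
        "extension_mm3": c.extension_mm3,
        "n_voxels": c.n_voxels,
    } for i, c in enumerate(clusters)]
    return pd.DataFrame(rows)


def regional_scores(
    maps: dict[str, dict[str, np.ndarray]],
    region: RegionCluster,
    grid: VolumeGrid,
    behavior_exhaustion: dict[tuple[str, str], float] | None = None,
    scans: tuple[str, ...] = ("WD-T2", "WD-T3"),
    rsn: str = "",
    region_label: str = "",
) -> pd.DataFrame:
    """Mean best-fit z-score over a region, per subject x chosen scan.

    Pairs each score with the subject's VAS exhaustion for that scan when a
    behavior lookup is supplied — the input to :func:`ancova_scores`.
    """
    mask = region.region_mask(grid)
    if not mask.any():
        raise ValueError("empty region")
    rows = []
    for subject in sorted(maps):
        for cond in scans:
            if cond not in maps[subject]:
                continue
            score = float(np.asarray(maps[subject][cond])[mask].mean())
            row = {"subject": subject, "scan": cond, "rsn": rsn,
                   "region": region_label, "score": score}
            if behavior_exhaustion is not None:
                row["vas"] = behavior_exhaustion[(subject, cond)]
            rows.append(row)
    return pd.DataFrame(rows)


def _ols_rss(x: np.ndarray, y: np.ndarray) -> tuple[float, int]:
    """Residual sum of squares and residual df of an OLS fit."""
    beta, _, rank, _ = np.linalg.lstsq(x, y, rcond=None)
    resid = y - x @ beta
    return float(resid @ resid), y.size - int(rank)


def _partial_f(
    rss_reduced: float, rss_full: float, df_extra: int, df_resid: int, tiny: float = 0.0
) -> tuple[float, float]:
    """Nested-model F; sums of squares below ``tiny`` count as exact zero."""
    if df_resid <= 0 or df_extra <= 0:
        raise ValueError("not enough residual degrees of freedom")
    num = max(rss_reduced - rss_full, 0.0) / df_extra
    den = rss_full / df_resid
    if den <= max(tiny, 1e-300):
        return (float(np.inf), 0.0) if num > tiny else (0.0, 1.0)
    f = num / den
    return float(f), float(stats.f.sf(f, df_extra, df_resid))


def ancova_scores(table: pd.DataFrame) -> dict[str, float]:
    """ANCOVA of regional scores: scan factor, VAS covariate, interaction.

    Fits ``score ~ intercept + scan + vas + scan:vas`` by OLS and reports
    partial F-tests: the interaction against the additive model, and the
    covariate against the scan-only model (so its main effect is not
    absorbed by the interaction term). P-values are uncorrected.
    """
    for col in ("subject", "scan", "score", "vas"):
        if col not in table.columns:
            raise ValueError(f"score table is missing column {col!r}")
    scans = sorted(table["scan"].unique())
    if len(scans) < 2:
        raise ValueError("ANCOVA needs >= 2 scan levels")
    counts = table.groupby("scan").size()
    if (counts < 3).any():
        raise ValueError("ANCOVA needs >= 3 observations per scan level")

    y = table["score"].to_numpy(dtype=float)
    vas = table["vas"].to_numpy(dtype=float)
    n = y.size
    scan_dummies = np.column_stack([
        (table["scan"] == s).to_numpy(dtype=float) for s in scans[1:]
    ])
    intercept = np.ones((n, 1))
    x_scan = np.hstack([intercept, scan_dummies])
    x_add = np.hstack([x_scan, vas[:, None]])
    x_full = np.hstack([x_add, scan_dummies * vas[:, None]])

    if np.linalg.matrix_rank(x_full) < x_full.shape[1]:
        raise ValueError("collinear ANCOVA design (constant VAS within a scan level?)")

    rss_scan, _ = _ols_rss(x_scan, y)
    rss_add, _ = _ols_rss(x_add, y)
    rss_full, df_full = _ols_rss(x_full, y)
    k = len(scans) - 1
    tiny = 1e-12 * max(float(((y - y.mean()) ** 2).sum()), 1e-300)
    f_vas, p_vas = _partial_f(rss_scan, rss_add, 1, n - x_add.shape[1], tiny)
    f_int, p_int = _partial_f(rss_add, rss_full, k, df_full, tiny)
    return {
        "F_vas": f_vas, "p_vas": p_vas, "df_vas": (1, n - x_add.shape[1]),
        "F_interaction": f_int, "p_interaction": p_int, "df_interaction": (k, df_full),
    }
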