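"""Synthetic group resting-state fMRI studies with a recoverable ground truth.

The generator emulates the repeated-measures design of a two-day exhaustion
study: each subject contributes five scans (FD-T1, FD-T3 on a free day;
WD-T1, WD-T2, WD-T3 on a working day). A shared atlas of spatially smooth
network maps drives band-limited (0.01-0.1 Hz) fluctuations; a planted
effect multiplies one network's amplitude inside a sub-region for chosen
conditions only (gain > 1 = enhancement, gain < 1 = suppression). Scans also
carry polynomial drift, aliased cardiac/respiratory sinusoids, and white
Gaussian noise. Behavioral exhaustion scores are linearly coupled to the
planted modulation so the full pipeline, through the final ANCOVA, has a
known answer.

Everything is bit-exact reproducible from the top-level seed: per-scan
generators are spawned via ``numpy.random.SeedSequence([seed, subject_index,
condition_index])``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from .core import CONDITIONS, ConfoundSet, Scan, VolumeGrid, make_ellipsoid_mask

FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))  # sigma = FWHM * this

#: Default acquisition parameters (TR in seconds, volumes per scan).
DEFAULT_TR_S = 2.0
DEFAULT_N_VOL = 180
#: Resting-state network fluctuation band in Hz.
DEFAULT_BAND = (0.01, 0.1)
#: Generator noise/nuisance amplitudes relative to unit network amplitude.
DEFAULT_NOISE_SD = 0.5
DEFAULT_PHYSIO_AMP = 0.3
DEFAULT_DRIFT_AMP = 0.2
#: Between-subject variability: rigid map shift (voxels) and amplitude CV.
DEFAULT_SUBJECT_JITTER = 1.0
DEFAULT_AMP_JITTER = 0.1
#: Behavioral coupling: VAS points per unit of |gain - 1|, plus rating noise.
DEFAULT_VAS_BASELINE = 60.0
DEFAULT_VAS_SLOPE = 80.0
DEFAULT_VAS_NOISE_SD = 8.0


@dataclass
class NetworkAtlas:
    """N network maps on a common grid, with pairwise-disjoint core masks."""

    grid: VolumeGrid
    maps: np.ndarray  # (N, V) nonnegative weights, masked order
    core_masks: np.ndarray  # (N, V) boolean, pairwise disjoint

    def __post_init__(self) -> None:
        self.maps = np.asarray(self.maps, dtype=float)
        self.core_masks = np.asarray(self.core_masks, dtype=bool)
        if self.maps.ndim != 2 or self.maps.shape[0] < 2:
            raise ValueError("atlas needs >= 2 network maps")
        if self.maps.shape != self.core_masks.shape:
            raise ValueError("maps and core_masks shapes differ")
        if self.maps.shape[1] != self.grid.n_voxels:
            raise ValueError("atlas maps must be in masked voxel order")
        if (self.maps < 0).any():
            raise ValueError("map weights must be nonnegative")
        for k in range(self.n_networks):
            if (self.core_masks[k] & (self.maps[k] <= 0)).any():
                raise ValueError(f"core mask of network {k} leaves its map support")
        if (self.core_masks.sum(axis=0) > 1).any():
            raise ValueError("core masks overlap")

    @property
    def n_networks(self) -> int:
        return self.maps.shape[0]

    def support(self, k: int) -> np.ndarray:
        return self.maps[k] > 0


@dataclass
class EffectSpec:
    """A planted condition-dependent amplitude modulation in one sub-region.

    ``condition_gains`` maps condition labels (e.g. ``"WD-T3"``) to a
    multiplicative amplitude factor applied inside ``target_region`` only;
    unlisted conditions have gain 1.
    """

    target_network: int
    target_region: np.ndarray  # 3-D boolean volume on the atlas grid
    condition_gains: dict[str, float]

    def __post_init__(self) -> None:
        self.target_region = np.asarray(self.target_region, dtype=bool)
        for cond, g in self.condition_gains.items():
            if cond not in CONDITIONS:
                raise ValueError(f"unknown condition {cond!r}")
            if g <= 0:
                raise ValueError("gains must be positive")

    def gain(self, condition: str) -> float:
        return float(self.condition_gains.get(condition, 1.0))

    def region_vector(self, grid) -> np.ndarray:
        """Masked region vector; the region must lie inside the brain mask."""
        region = grid.from_volume(self.target_region)
        if self.target_region.sum() != region.sum():
            raise ValueError("target_region leaves the brain mask")
        if not region.any():
            raise ValueError("target_region is empty")
        return region

    def validate_against(self, atlas: NetworkAtlas) -> np.ndarray:
        """Check containment in the defining atlas's network support.

        Applies to the atlas the effect was specified on; per-subject
        jittered copies may shift their support off the region slightly.
        """
        if not 0 <= self.target_network < atlas.n_networks:
            raise ValueError(f"no network {self.target_network} in atlas")
        region = self.region_vector(atlas.grid)
        if (region & ~atlas.support(self.target_network)).any():
            raise ValueError("target_region leaves the network's map support")
        return region


@dataclass
class ScanTruth:
    """What one simulated scan actually contained."""

    condition: str
    seed: int
    amplitudes: np.ndarray  # (N,) base network amplitude in this scan
    regional_gains: np.ndarray  # (n_effects,) gain applied in each region
    courses: np.ndarray  # (N, T) network time courses as mixed


@dataclass
class GroundTruth:
    """Complete generator state: sufficient to rescore any recovery."""

    atlas: NetworkAtlas
    effects: list[EffectSpec]
    subject_ids: list[str]
    subject_shifts: np.ndarray  # (S, 3) voxel shifts applied to subject maps
    subject_amp_factors: np.ndarray  # (S, N)
    realizations: pd.DataFrame  # subject x condition x effect amplitudes
    vas_slope: float
    seed: int
    scan_truths: dict[tuple[str, str], ScanTruth] = field(default_factory=dict)

    @property
    def is_null(self) -> bool:
        return all(g == 1.0 for e in self.effects for g in e.condition_gains.values())

    def region_vector(self, effect_index: int) -> np.ndarray:
        return self.atlas.grid.from_volume(self.effects[effect_index].target_region)


def default_grid(dims: tuple[int, int, int] = (24, 24, 16), voxel_size_mm: float = 3.0) -> VolumeGrid:
    """An ellipsoidal brain mask on an isotropic grid (3 mm default)."""
    return VolumeGrid(dims=tuple(dims), voxel_size_mm=voxel_size_mm,
                      brain_mask=make_ellipsoid_mask(tuple(dims)))


def _sphere(dims: tuple[int, int, int], center: np.ndarray, radius: float) -> np.ndarray:
    grids = np.ogrid[[slice(0, d) for d in dims]]
    d2 = sum((g - c) ** 2 for g, c in zip(grids, center))
    return d2 <= radius**2


def make_atlas(
    grid: VolumeGrid,
    n_networks: int,
    fwhm_mm: float = 6.0,
    seed: int = 0,
    blob_radius_vox: float = 2.5,
    core_radius_vox: float = 1.5,
) -> NetworkAtlas:
    """Place ``n_networks`` Gaussian-smoothed blob networks with disjoint cores.

    Blob centers are rejection-sampled inside the brain mask so that every
    blob lies fully in-mask and core spheres never touch. With ``fwhm_mm=0``
    each map equals its 0/1 blob indicator exactly.
    """
    if n_networks < 2:
        raise ValueError("need at least 2 networks")
    if fwhm_mm < 0:
        raise ValueError("fwhm_mm must be >= 0")
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 11]))

    # candidate centers: voxels whose whole blob fits inside the mask
    erosion_iters = int(np.ceil(blob_radius_vox))
    interior = ndimage.binary_erosion(grid.brain_mask, iterations=erosion_iters)
    candidates = np.argwhere(interior)
    if candidates.shape[0] == 0:
        raise ValueError(
            f"grid {grid.dims} too small: no interior voxel can host a blob of "
            f"radius {blob_radius_vox} voxels inside the brain mask"
        )

    # cores are spheres of core_radius around the centers; a center spacing
    # of 2*core_radius + 1 guarantees disjoint cores (map supports may overlap)
    min_center_dist = 2.0 * core_radius_vox + 1.0
    centers: list[np.ndarray] = []
    for c in candidates[rng.permutation(candidates.shape[0])]:
        if all(np.linalg.norm(c - p) >= min_center_dist for p in centers):
            centers.append(c)
            if len(centers) == n_networks:
                break
    if len(centers) < n_networks:
        raise ValueError(
            f"could not place {n_networks} pairwise-disjoint network cores on grid "
            f"{grid.dims} (placed {len(centers)}; cores must be >= "
            f"{min_center_dist:.1f} voxels apart inside the brain mask)"
        )

    sigma_vox = fwhm_mm * FWHM_TO_SIGMA / grid.voxel_size_mm
    maps = np.empty((n_networks, grid.n_voxels))
    cores = np.empty((n_networks, grid.n_voxels), dtype=bool)
    for k, c in enumerate(centers):
        blob = _sphere(grid.dims, c, blob_radius_vox).astype(float)
        vol = ndimage.gaussian_filter(blob, sigma_vox) if sigma_vox > 0 else blob
        vol[~grid.brain_mask] = 0.0
        # smoothing leaves negligible but nonzero weight far away; clip to a
        # compact support so cores/targets stay meaningful sub-regions
        vol[vol < 1e-6 * vol.max()] = 0.0
        maps[k] = grid.from_volume(vol)
        cores[k] = grid.from_volume(_sphere(grid.dims, c, core_radius_vox) & grid.brain_mask)
    return NetworkAtlas(grid=grid, maps=maps, core_masks=cores)


def bandlimited_course(
    n_vol: int, tr_s: float, rng: np.random.Generator, band: tuple[float, float] = DEFAULT_BAND
) -> np.ndarray:
    """Unit-SD Gaussian time course band-passed (FFT brick wall) to ``band`` Hz."""
    white = rng.standard_normal(n_vol)
    spec = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(n_vol, d=tr_s)
    keep = (freqs >= band[0]) & (freqs <= band[1])
    if not keep.any():
        raise ValueError(f"no FFT bins inside band {band} Hz at T={n_vol}, TR={tr_s}s")
    spec[~keep] = 0.0
    course = np.fft.irfft(spec, n=n_vol)
    return course / course.std()


def _smooth_weight_map(grid: VolumeGrid, rng: np.random.Generator, sigma_vox: float = 1.5) -> np.ndarray:
    vol = ndimage.gaussian_filter(rng.standard_normal(grid.dims), sigma_vox)
    w = grid.from_volume(vol)
    return (w - w.mean()) / w.std()


def simulate_scan(
    atlas: NetworkAtlas,
    effects: list[EffectSpec],
    condition: str,
    tr_s: float = DEFAULT_TR_S,
    n_vol: int = DEFAULT_N_VOL,
    noise_sd: float = DEFAULT_NOISE_SD,
    seed: int = 0,
    subject: str = "sub00",
    amplitudes: np.ndarray | None = None,
    physio_amp: float = DEFAULT_PHYSIO_AMP,
    drift_amp: float = DEFAULT_DRIFT_AMP,
    band: tuple[float, float] = DEFAULT_BAND,
) -> tuple[Scan, ConfoundSet, ScanTruth]:
    """Simulate one scan: networks + drift + physio sinusoids + noise.

    The data model is ``sum_k a_k * g_k(v) * map_k(v) * s_k(t) + drift +
    physio + noise`` where ``g_k`` is the planted gain field (1 outside every
    target region) and ``s_k`` are unit-SD band-limited courses. The returned
    :class:`ConfoundSet` contains the cardiac/respiratory phases exactly as
    mixed, so order-2 RETROICOR regressors can remove the physio term.
    """
    if condition not in CONDITIONS:
        raise ValueError(f"condition {condition!r} not in design {CONDITIONS}")
    if n_vol < 32:
        raise ValueError("n_vol must be >= 32")
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    grid = atlas.grid
    n_net = atlas.n_networks
    if amplitudes is None:
        amplitudes = np.ones(n_net)
    amplitudes = np.asarray(amplitudes, dtype=float)

    rng = np.random.default_rng(np.random.SeedSequence(int(seed)))
    t_idx = np.arange(n_vol)

    # network signal with regionally confined gains; courses are mutually
    # orthogonalized (linear combinations stay band-limited) so a voxel's
    # temporal SD is exactly sqrt(sum_k (a_k g_k w_k)^2) at zero noise
    courses = np.stack([bandlimited_course(n_vol, tr_s, rng, band) for _ in range(n_net)])
    q, rmat = np.linalg.qr(courses.T)
    d = np.sign(np.diag(rmat))
    q = q * np.where(d == 0, 1.0, d)
    courses = (q * np.sqrt(n_vol)).T
    gain_fields = np.ones((n_net, grid.n_voxels))
    regional_gains = np.empty(len(effects))
    for i, eff in enumerate(effects):
        if not 0 <= eff.target_network < n_net:
            raise ValueError(f"no network {eff.target_network} in atlas")
        region = eff.region_vector(grid)
        g = eff.gain(condition)
        gain_fields[eff.target_network, region] *= g
        regional_gains[i] = g
    effective_maps = amplitudes[:, None] * gain_fields * atlas.maps
    data = courses.T @ effective_maps  # (T, V)

    # low-order polynomial drift with smooth spatial weights
    if drift_amp > 0:
        tt = 2.0 * t_idx / (n_vol - 1) - 1.0
        p1, p2 = tt, 1.5 * tt**2 - 0.5
        data += drift_amp * (
            np.outer(p1, _smooth_weight_map(grid, rng))
            + np.outer(p2, _smooth_weight_map(grid, rng))
        )

    # aliased physiological sinusoids, harmonics 1-2 of each phase
    cardiac_f = 1.0 + 0.05 * rng.standard_normal()
    resp_f = 0.3 + 0.02 * rng.standard_normal()
    cardiac_phase = 2.0 * np.pi * cardiac_f * t_idx * tr_s
    resp_phase = 2.0 * np.pi * resp_f * t_idx * tr_s
    if physio_amp > 0:
        for phase in (cardiac_phase, resp_phase):
            for m, amp in ((1, physio_amp), (2, 0.5 * physio_amp)):
                data += amp * np.outer(np.cos(m * phase), _smooth_weight_map(grid, rng))
                data += amp * np.outer(np.sin(m * phase), _smooth_weight_map(grid, rng))

    if noise_sd > 0:
        data += rng.normal(0.0, noise_sd, data.shape)

    # slow drifting motion traces, well under the 4 mm exclusion gate;
    # motion image artifacts are out of the generator's scope
    motion = np.cumsum(rng.normal(0.0, 0.01, (n_vol, 6)), axis=0)

    day, timepoint = condition.split("-")
    scan = Scan(subject=subject, day=day, timepoint=timepoint, tr_s=tr_s, data=data, grid=grid)
    confounds = ConfoundSet(motion=motion, cardiac_phase=cardiac_phase, resp_phase=resp_phase)
    truth = ScanTruth(
        condition=condition,
        seed=int(seed),
        amplitudes=amplitudes.copy(),
        regional_gains=regional_gains,
        courses=courses,
    )
    return scan, confounds, truth


def default_effects(
    atlas: NetworkAtlas,
    enhancement_gain: float = 1.5,
    suppression_gain: float = 0.6,
    intermediate_fraction: float = 0.5,
) -> list[EffectSpec]:
    """The canonical planted pattern: enhancement in network 0's core and
    suppression in network 1's core, expressed fully at WD-T3 and half-way
    (on the log-gain scale) at WD-T2; all other scans are unmodulated."""
    grid = atlas.grid

    def region_volume(k: int) -> np.ndarray:
        return grid.to_volume(atlas.core_masks[k].astype(float)) > 0.5

    def schedule(gain: float) -> dict[str, float]:
        mid = float(np.exp(intermediate_fraction * np.log(gain)))
        return {"WD-T2": mid, "WD-T3": float(gain)}

    return [
        EffectSpec(0, region_volume(0), schedule(enhancement_gain)),
        EffectSpec(1, region_volume(1), schedule(suppression_gain)),
    ]


def scan_seed(seed: int, subject_index: int, condition: str) -> int:
    """Deterministic per-scan seed; scans are reproducible independently."""
    ci = CONDITIONS.index(condition)
    ss = np.random.SeedSequence([int(seed), int(subject_index), ci])
    return int(ss.generate_state(1)[0] % (2**31))


def jitter_atlas(
    atlas: NetworkAtlas, shift_vox: np.ndarray
) -> NetworkAtlas:
    """Apply a small rigid translation (linear interpolation) to every map.

    Emulates residual misregistration between subjects; core masks stay at
    the group-level location, which is what recovery is scored against.
    """
    grid = atlas.grid
    maps = np.empty_like(atlas.maps)
    for k in range(atlas.n_networks):
        vol = grid.to_volume(atlas.maps[k])
        vol = ndimage.shift(vol, shift_vox, order=1, mode="constant", cval=0.0)
        vol[vol < 0] = 0.0
        vol[~grid.brain_mask] = 0.0
        maps[k] = grid.from_volume(vol)
    # after a sub-voxel shift the core may graze zero-weight voxels; keep the
    # core on the (slightly eroded) intersection with the shifted support
    cores = atlas.core_masks & (maps > 0)
    return NetworkAtlas(grid=grid, maps=maps, core_masks=cores)


def simulate_group_study(
    n_subjects: int = 8,
    grid: VolumeGrid | None = None,
    n_networks: int = 5,
    effects: list[EffectSpec] | None = None,
    atlas: NetworkAtlas | None = None,
    subject_jitter: float = DEFAULT_SUBJECT_JITTER,
    amp_jitter: float = DEFAULT_AMP_JITTER,
    tr_s: float = DEFAULT_TR_S,
    n_vol: int = DEFAULT_N_VOL,
    noise_sd: float = DEFAULT_NOISE_SD,
    fwhm_mm: float = 6.0,
    seed: int = 0,
    vas_baseline: float = DEFAULT_VAS_BASELINE,
    vas_slope: float = DEFAULT_VAS_SLOPE,
    vas_noise_sd: float = DEFAULT_VAS_NOISE_SD,
    physio_amp: float = DEFAULT_PHYSIO_AMP,
    drift_amp: float = DEFAULT_DRIFT_AMP,
) -> tuple[list[Scan], dict[tuple[str, str], ConfoundSet], pd.DataFrame, GroundTruth]:
    """Simulate an ``n_subjects x 5-scan`` study with planted effects.

    Returns the scans (one per subject x condition), their confound sets
    keyed by ``(subject, condition)``, a behavioral table with VAS ratings
    coupled to the planted modulation, and the full :class:`GroundTruth`.
    """
    if n_subjects < 3:
        raise ValueError("need at least 3 subjects")
    if atlas is None:
        if grid is None:
            grid = default_grid()
        atlas = make_atlas(grid, n_networks, fwhm_mm=fwhm_mm, seed=seed)
    else:
        grid = atlas.grid
    if effects is None:
        effects = default_effects(atlas)
    for eff in effects:
        eff.validate_against(atlas)

    subject_ids = [f"sub{i:02d}" for i in range(n_subjects)]
    shifts = np.empty((n_subjects, 3))
    amp_factors = np.empty((n_subjects, atlas.n_networks))
    scans: list[Scan] = []
    confounds: dict[tuple[str, str], ConfoundSet] = {}
    scan_truths: dict[tuple[str, str], ScanTruth] = {}
    rows = []

    for si, sid in enumerate(subject_ids):
        srng = np.random.default_rng(np.random.SeedSequence([int(seed), si, 101]))
        direction = srng.standard_normal(3)
        direction /= np.linalg.norm(direction)
        shifts[si] = subject_jitter * srng.uniform(0.5, 1.0) * direction
        amp_factors[si] = np.exp(amp_jitter * srng.standard_normal(atlas.n_networks))
        subj_atlas = jitter_atlas(atlas, shifts[si]) if subject_jitter > 0 else atlas

        for cond in CONDITIONS:
            s = scan_seed(seed, si, cond)
            scan, conf, truth = simulate_scan(
                subj_atlas, effects, cond, tr_s=tr_s, n_vol=n_vol, noise_sd=noise_sd,
                seed=s, subject=sid, amplitudes=amp_factors[si],
                physio_amp=physio_amp, drift_amp=drift_amp,
            )
            scans.append(scan)
            confounds[(sid, cond)] = conf
            scan_truths[(sid, cond)] = truth
            for ei, eff in enumerate(effects):
                rows.append({
                    "subject": sid, "condition": cond, "effect": ei,
                    "network": eff.target_network,
                    "base_amplitude": amp_factors[si, eff.target_network],
                    "regional_amplitude": amp_factors[si, eff.target_network]
                    * eff.gain(cond),
                })
    realizations = pd.DataFrame(rows)

    # behavioral coupling: exhaustion tracks the planted modulation strength
    behavior_rows = []
    brng = np.random.default_rng(np.random.SeedSequence([int(seed), 999]))
    baselines = vas_baseline + 10.0 * brng.standard_normal(n_subjects)
    for si, sid in enumerate(subject_ids):
        for cond in CONDITIONS:
            driver = float(np.mean([abs(e.gain(cond) - 1.0) for e in effects])) if effects else 0.0
            exhaustion = baselines[si] + vas_slope * driver
            tired = np.clip(exhaustion + brng.normal(0, vas_noise_sd), 0, 150)
            rested = np.clip(150 - exhaustion + brng.normal(0, vas_noise_sd), 0, 150)
            day, timepoint = cond.split("-")
            behavior_rows.append({
                "subject": sid, "day": day, "timepoint": timepoint,
                "tired_vas": float(tired), "rested_vas": float(rested),
            })
    behavior = pd.DataFrame(behavior_rows)

    truth = GroundTruth(
        atlas=atlas, effects=list(effects), subject_ids=subject_ids,
        subject_shifts=shifts, subject_amp_factors=amp_factors,
        realizations=realizations, vas_slope=vas_slope, seed=int(seed),
        scan_truths=scan_truths,
    )
    return scans, confounds, behavior, truth
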