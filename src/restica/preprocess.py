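"""Temporal high-pass filtering, nuisance regression, and motion QC.

The pipeline order is fixed: high-pass first, then confound regression
(``highpass_first=True`` flag on :func:`preprocess_scan` to flip it for
sensitivity analyses). Both steps are linear projections applied voxelwise.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .core import ConfoundSet, Scan

logger = logging.getLogger(__name__)

T_CAP = 1e6  # cap for zero-variance t statistics, shared across the package


def drift_basis(n_timepoints: int, cutoff_cycles: float) -> np.ndarray:
    """Low-frequency drift basis: constant plus cosine/sine pairs.

    Includes every whole-course harmonic k = 1..floor(cutoff_cycles), i.e.
    all discrete frequencies <= cutoff_cycles / (T * TR). A sampled cosine or
    sine at an integer number of cycles <= the cutoff lies exactly in the
    span, so "remove up to k cycles per time-course" is exact.
    """
    if cutoff_cycles < 0:
        raise ValueError("cutoff_cycles must be >= 0")
    t = np.arange(n_timepoints)
    cols = [np.ones(n_timepoints)]
    for k in range(1, int(np.floor(cutoff_cycles)) + 1):
        arg = 2.0 * np.pi * k * t / n_timepoints
        cols.append(np.cos(arg))
        cols.append(np.sin(arg))
    basis = np.column_stack(cols)
    if basis.shape[1] >= n_timepoints:
        raise ValueError(
            f"cutoff of {cutoff_cycles} cycles implies {basis.shape[1]} basis "
            f"functions for only {n_timepoints} time points"
        )
    return basis


def highpass(scan: Scan, cutoff_cycles: float = 2.0) -> Scan:
    """Project out drifts slower than ``cutoff_cycles`` per time-course.

    The default of 2 cycles per time-course matches standard resting-state
    preprocessing. Output voxel means are exactly zero (the constant is in
    the removed span), and the operation is an idempotent projection.
    """
    basis = drift_basis(scan.n_timepoints, cutoff_cycles)
    q, _ = np.linalg.qr(basis)
    residual = scan.data - q @ (q.T @ scan.data)
    return scan.replace_data(residual)


def build_physio_regressors(
    cardiac_phase: np.ndarray, resp_phase: np.ndarray, order: int = 2
) -> np.ndarray:
    """RETROICOR-style Fourier expansion of the physiological phases.

    Column order: cardiac cos(1x), sin(1x), ..., cos(order*x), sin(order*x),
    then the same block for respiration — ``4 * order`` columns for the two
    modalities at the default order 2.
    """
    if order < 1:
        raise ValueError("order must be >= 1")
    cardiac_phase = np.asarray(cardiac_phase, dtype=float)
    resp_phase = np.asarray(resp_phase, dtype=float)
    cols = []
    for phase in (cardiac_phase, resp_phase):
        for m in range(1, order + 1):
            cols.append(np.cos(m * phase))
            cols.append(np.sin(m * phase))
    return np.column_stack(cols)


def regress_confounds(scan: Scan, confounds: np.ndarray) -> Scan:
    """Voxelwise GLM residualization against ``[intercept | confounds]``.

    Residuals are orthogonal to every confound column; a rank-deficient
    design is rejected with the offending columns named.
    """
    confounds = np.atleast_2d(np.asarray(confounds, dtype=float))
    if confounds.shape[0] != scan.n_timepoints:
        raise ValueError("confound rows must match scan time points")
    if confounds.shape[1] >= scan.n_timepoints:
        raise ValueError("more confounds than time points")
    design = np.column_stack([np.ones(scan.n_timepoints), confounds])
    rank = np.linalg.matrix_rank(design)
    if rank < design.shape[1]:
        # identify columns that add no rank, scanning left to right
        bad = []
        kept = design[:, :1]
        for j in range(1, design.shape[1]):
            trial = np.column_stack([kept, design[:, j]])
            if np.linalg.matrix_rank(trial) == kept.shape[1]:
                bad.append(j - 1)  # confound column index (intercept excluded)
            else:
                kept = trial
        raise ValueError(f"confound design is rank-deficient; offending columns: {bad}")
    q, _ = np.linalg.qr(design)
    residual = scan.data - q @ (q.T @ scan.data)
    return scan.replace_data(residual)


@dataclass(frozen=True)
class MotionQC:
    verdict: str  # {"keep", "exclude"}
    max_translation_mm: float
    max_rotation_deg: float
    limit_mm: float

    def __bool__(self) -> bool:  # truthy == keep
        return self.verdict == "keep"


def motion_qc(motion: np.ndarray, limit_mm: float = 4.0) -> MotionQC:
    """Exclude a scan whose peak absolute translation exceeds ``limit_mm``.

    The comparison is strict (exactly 4.0 mm keeps the scan). Rotations are
    reported for the log but do not gate.
    """
    motion = np.atleast_2d(np.asarray(motion, dtype=float))
    if motion.shape[1] != 6:
        raise ValueError("motion must be T x 6 (3 translations mm, 3 rotations deg)")
    max_trans = float(np.abs(motion[:, :3]).max()) if motion.size else 0.0
    max_rot = float(np.abs(motion[:, 3:]).max()) if motion.size else 0.0
    verdict = "exclude" if max_trans > limit_mm else "keep"
    if verdict == "exclude":
        logger.warning("motion QC: excluding scan, max translation %.2f mm > %.1f mm",
                       max_trans, limit_mm)
    return MotionQC(verdict, max_trans, max_rot, float(limit_mm))


def preprocess_scan(
    scan: Scan,
    confounds: ConfoundSet,
    hp_cycles: float = 2.0,
    physio_order: int = 2,
    motion_limit_mm: float = 4.0,
    highpass_first: bool = True,
) -> Scan | None:
    """Full per-scan preprocessing: QC gate, high-pass, nuisance regression.

    Returns ``None`` when the scan fails the motion gate. The nuisance
    design stacks motion parameters and order-``physio_order`` RETROICOR
    regressors (plus any extra confound columns).
    """
    qc = motion_qc(confounds.motion, motion_limit_mm)
    if not qc:
        return None
    physio = build_physio_regressors(confounds.cardiac_phase, confounds.resp_phase, physio_order)
    blocks = [confounds.motion, physio]
    if confounds.extra is not None:
        blocks.append(confounds.extra)
    nuisance = np.column_stack(blocks)
    logger.info("preprocess %s %s: order = %s", scan.subject, scan.condition,
                "highpass->regress" if highpass_first else "regress->highpass")
    if highpass_first:
        return regress_confounds(highpass(scan, hp_cycles), nuisance)
    return highpass(regress_confounds(scan, nuisance), hp_cycles)
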