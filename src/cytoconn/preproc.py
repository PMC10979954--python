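"""Scan-level preprocessing: motion scrubbing, nuisance regression, filtering.

The pipeline mirrors a standard awake-mouse resting-state workflow: rigid-body
motion is summarised per volume as a scalar displacement, volumes above half a
voxel (0.125 mm) are censored together with their temporal neighbours, scans
keeping fewer than 90% of volumes are dropped, ROI signals are residualised
against nuisance regressors (WM-CSF signal plus the six rigid motion
parameters), band-pass filtered to 0.01-0.1 Hz, and finally correlated ROI
against ROI over the retained volumes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage, signal
from scipy.spatial.transform import Rotation

from .connectivity import ConnectivityMatrix

__all__ = [
    "ScanTimeSeries",
    "MotionTrace",
    "ScrubResult",
    "DEFAULT_RADII",
    "SCRUB_THRESHOLD_MM",
    "compute_motion_parameter",
    "scrub_volumes",
    "apply_scrub",
    "nuisance_regress",
    "spatial_smooth",
    "bandpass",
    "roi_correlation",
]

#: half an in-plane voxel (0.25 mm voxels): the volume-censoring threshold
SCRUB_THRESHOLD_MM = 0.125

#: effective head radii (mm) used to convert rotations to displacement; the
#: mouse brain is roughly a 5 mm sphere.  Configurable everywhere they appear.
DEFAULT_RADII = (5.0, 5.0, 5.0)


@dataclass
class ScanTimeSeries:
    """One EPI scan reduced to an ROI x time matrix.

    ``censor_mask`` is True for retained volumes.  ``tr`` is the repetition
    time in seconds (1.5 s in the acquisition this emulates).
    """

    data: np.ndarray
    roi_names: list[str]
    tr: float
    subject_id: str
    genotype: str
    age_months: float
    scan_id: str = "scan00"
    censor_mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.data = np.atleast_2d(np.asarray(self.data, dtype=float))
        if len(set(self.roi_names)) != len(self.roi_names):
            raise ValueError("roi_names must be unique")
        if len(self.roi_names) != self.data.shape[0]:
            raise ValueError("roi_names length must match the data row count")
        if self.tr <= 0:
            raise ValueError("tr must be positive")
        if self.censor_mask is None:
            self.censor_mask = np.ones(self.data.shape[1], dtype=bool)
        else:
            self.censor_mask = np.asarray(self.censor_mask, dtype=bool)
            if self.censor_mask.shape != (self.data.shape[1],):
                raise ValueError("censor_mask length must equal volume count")

    @property
    def n_rois(self) -> int:
        return self.data.shape[0]

    @property
    def n_volumes(self) -> int:
        return self.data.shape[1]

    def retained(self) -> np.ndarray:
        """Data restricted to retained volumes."""
        return self.data[:, self.censor_mask]

    def with_data(self, data: np.ndarray, censor_mask: np.ndarray | None = None
                  ) -> "ScanTimeSeries":
        return ScanTimeSeries(
            data=data, roi_names=list(self.roi_names), tr=self.tr,
            subject_id=self.subject_id, genotype=self.genotype,
            age_months=self.age_months, scan_id=self.scan_id,
            censor_mask=self.censor_mask.copy() if censor_mask is None
            else np.asarray(censor_mask, dtype=bool))


@dataclass
class MotionTrace:
    """Per-volume rigid-body motion relative to the reference volume.

    Translations are in mm, rotations (Euler angles th_x, th_y, th_z) in
    radians, and ``radii`` (r_x, r_y, r_z, mm) convert rotations into arc
    displacements.  The scalar per-volume displacement is

        |Tx| + |Ty| + |Tz| + |th_x| r_z + |th_y| r_z + |th_z| r_x

    i.e. the motion-parameter formula with absolute values on every term so
    the result is a non-negative displacement.
    """

    translations: np.ndarray
    rotations: np.ndarray
    radii: tuple[float, float, float] = DEFAULT_RADII
    spike_indices: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.translations = np.atleast_2d(np.asarray(self.translations, float))
        self.rotations = np.atleast_2d(np.asarray(self.rotations, float))
        if self.translations.shape != self.rotations.shape or \
                self.translations.shape[1] != 3:
            raise ValueError("translations and rotations must both be (n, 3)")

    @property
    def n_volumes(self) -> int:
        return self.translations.shape[0]

    @property
    def displacement(self) -> np.ndarray:
        rx, ry, rz = self.radii
        t = np.abs(self.translations).sum(axis=1)
        rot = np.abs(self.rotations)
        return t + rot[:, 0] * rz + rot[:, 1] * rz + rot[:, 2] * rx

    def to_affines(self) -> np.ndarray:
        """Rebuild per-volume 4x4 rigid transforms (intrinsic Z-Y-X Euler)."""
        n = self.n_volumes
        out = np.tile(np.eye(4), (n, 1, 1))
        for i in range(n):
            tx, ty, tz = self.rotations[i]
            out[i, :3, :3] = Rotation.from_euler("ZYX", [tz, ty, tx]).as_matrix()
            out[i, :3, 3] = self.translations[i]
        return out


@dataclass
class ScrubResult:
    """Outcome of motion censoring for one scan."""

    displacement: np.ndarray
    discarded: np.ndarray          # sorted indices of censored volumes
    retained_fraction: float
    scan_kept: bool
    threshold: float = SCRUB_THRESHOLD_MM

    @property
    def censor_mask(self) -> np.ndarray:
        mask = np.ones(len(self.displacement), dtype=bool)
        mask[self.discarded] = False
        return mask


def compute_motion_parameter(affines: np.ndarray,
                             radii: tuple[float, float, float] = DEFAULT_RADII,
                             rigid_tol: float = 1e-6) -> MotionTrace:
    """Back-compute Euler angles/translations from per-volume affines.

    Each transform is expressed relative to the first (reference) volume and
    must be rigid: the rotation block is checked for orthonormality within
    ``rigid_tol``.  Euler angles use the intrinsic Z-Y-X convention.
    """
    affines = np.asarray(affines, dtype=float)
    if affines.ndim != 3 or affines.shape[1:] != (4, 4):
        raise ValueError("affines must have shape (n, 4, 4)")
    ref = affines[0]
    ref_inv = np.linalg.inv(ref)
    translations = np.empty((len(affines), 3))
    rotations = np.empty((len(affines), 3))
    for i, aff in enumerate(affines):
        rel = ref_inv @ aff
        R = rel[:3, :3]
        if (np.max(np.abs(R @ R.T - np.eye(3))) > rigid_tol
                or abs(np.linalg.det(R) - 1.0) > rigid_tol):
            raise ValueError(f"transform {i} is not rigid within {rigid_tol}")
        tz, ty, tx = Rotation.from_matrix(R).as_euler("ZYX")
        rotations[i] = (tx, ty, tz)
        translations[i] = rel[:3, 3]
    return MotionTrace(translations, rotations, radii=radii)


def scrub_volumes(trace: MotionTrace,
                  threshold: float = SCRUB_THRESHOLD_MM) -> ScrubResult:
    """Censor volumes whose displacement exceeds ``threshold``.

    Each offending volume is discarded together with the volume before and the
    volume after it (clipped to the scan).  A scan is kept only if at least
    90% of its volumes survive.
    """
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    disp = trace.displacement
    n = len(disp)
    if n == 0:
        raise ValueError("empty motion trace")
    offenders = np.flatnonzero(disp > threshold)
    discarded: set[int] = set()
    for i in offenders:
        discarded.update(j for j in (i - 1, i, i + 1) if 0 <= j < n)
    discarded_arr = np.array(sorted(discarded), dtype=int)
    retained_fraction = 1.0 - len(discarded_arr) / n
    return ScrubResult(
        displacement=disp,
        discarded=discarded_arr,
        retained_fraction=retained_fraction,
        scan_kept=bool(retained_fraction >= 0.9),
        threshold=threshold,
    )


def apply_scrub(scan: ScanTimeSeries, scrub: ScrubResult) -> ScanTimeSeries:
    """Intersect the scan's censor mask with a scrub result."""
    if len(scrub.displacement) != scan.n_volumes:
        raise ValueError("scrub result length does not match scan")
    return scan.with_data(scan.data, scan.censor_mask & scrub.censor_mask)


def nuisance_regress(scan: ScanTimeSeries, regressors: np.ndarray,
                     add_intercept: bool = True) -> ScanTimeSeries:
    """OLS-residualise every ROI signal against the nuisance regressors.

    ``regressors`` has one row per *retained* volume (typically the WM-CSF
    mean signal plus the six rigid motion parameters); an intercept column is
    appended unless already present.  Residuals are computed over retained
    volumes only; censored positions are zero-filled (they are re-excluded
    downstream).  A rank-deficient design raises, naming the collinear
    columns.
    """
    keep = scan.censor_mask
    R = np.atleast_2d(np.asarray(regressors, dtype=float))
    if R.shape[0] != int(keep.sum()):
        raise ValueError(
            f"regressors have {R.shape[0]} rows but scan retains {int(keep.sum())} volumes")
    if add_intercept:
        R = np.column_stack([np.ones(R.shape[0]), R])
    rank = np.linalg.matrix_rank(R)
    if rank < R.shape[1]:
        # identify columns whose removal restores full rank
        bad = [j for j in range(R.shape[1])
               if np.linalg.matrix_rank(np.delete(R, j, axis=1)) == rank]
        raise ValueError(f"rank-deficient nuisance design; collinear columns {bad}")
    Y = scan.data[:, keep].T                      # volumes x rois
    beta, *_ = np.linalg.lstsq(R, Y, rcond=None)
    resid = Y - R @ beta
    out = np.zeros_like(scan.data)
    out[:, keep] = resid.T
    return scan.with_data(out)


def _gaussian_kernel_3x3(sigma: float) -> np.ndarray:
    ax = np.array([-1.0, 0.0, 1.0])
    g = np.exp(-(ax ** 2) / (2 * sigma ** 2))
    k = np.outer(g, g)
    return k / k.sum()


def spatial_smooth(volume_series: np.ndarray, sigma: float = 0.7,
                   mask: np.ndarray | None = None) -> np.ndarray:
    """In-plane 3x3 Gaussian smoothing of an (x, y, t) frame stack.

    The kernel is renormalised by the in-mask kernel mass so masked-out or
    out-of-image pixels do not drag values toward zero; a constant image is
    therefore exactly preserved.
    """
    vol = np.asarray(volume_series, dtype=float)
    if vol.ndim == 2:
        vol = vol[:, :, None]
    if vol.ndim != 3:
        raise ValueError("expected an (x, y, t) array")
    kern = _gaussian_kernel_3x3(sigma)
    m = np.ones(vol.shape[:2]) if mask is None else np.asarray(mask, dtype=float)
    mass = ndimage.convolve(m, kern, mode="constant", cval=0.0)
    out = np.empty_like(vol)
    for t in range(vol.shape[2]):
        num = ndimage.convolve(vol[:, :, t] * m, kern, mode="constant", cval=0.0)
        with np.errstate(invalid="ignore", divide="ignore"):
            frame = num / mass
        frame[m == 0] = vol[:, :, t][m == 0]
        out[:, :, t] = frame
    return out if volume_series.ndim == 3 else out[:, :, 0]


def bandpass(scan: ScanTimeSeries, lo: float = 0.01, hi: float = 0.1,
             order: int = 4) -> ScanTimeSeries:
    """Zero-phase Butterworth band-pass (default 0.01-0.1 Hz).

    Censored volumes are linearly interpolated before filtering (avoiding
    ringing at gaps) and remain censored afterwards, so they never enter the
    correlation step.  ``hi`` must stay below the Nyquist frequency
    ``1 / (2 tr)``.
    """
    fs = 1.0 / scan.tr
    nyq = fs / 2.0
    if not (0 < lo < hi):
        raise ValueError("need 0 < lo < hi")
    if hi >= nyq:
        raise ValueError(f"hi={hi} Hz is at/above Nyquist ({nyq:.3f} Hz)")
    keep = scan.censor_mask
    if keep.sum() < 2:
        raise ValueError("too few retained volumes to filter")
    t_all = np.arange(scan.n_volumes)
    data = scan.data.copy()
    if not keep.all():
        for i in range(scan.n_rois):
            data[i] = np.interp(t_all, t_all[keep], data[i, keep])
    sos = signal.butter(order, [lo, hi], btype="bandpass", fs=fs, output="sos")
    filtered = signal.sosfiltfilt(sos, data, axis=1)
    return scan.with_data(filtered)


def roi_correlation(scan: ScanTimeSeries, min_volumes: int = 30
                    ) -> ConnectivityMatrix:
    """Pairwise Pearson correlation over retained volumes.

    Zero-variance ROIs get NaN rows/columns (with a warning) rather than
    failing the scan; the diagonal is 1 for valid ROIs.
    """
    X = scan.retained()
    if X.shape[1] < min_volumes:
        raise ValueError(
            f"only {X.shape[1]} retained volumes; need >= {min_volumes}")
    sd = X.std(axis=1)
    degenerate = np.flatnonzero(sd == 0)
    if scan.n_rois == 1:
        r = np.ones((1, 1))
    else:
        with np.errstate(invalid="ignore", divide="ignore"):
            r = np.corrcoef(X)
    if degenerate.size:
        warnings.warn(
            f"zero-variance ROIs {[scan.roi_names[i] for i in degenerate]}; "
            "set to missing", RuntimeWarning, stacklevel=2)
        r[degenerate, :] = np.nan
        r[:, degenerate] = np.nan
    valid = np.setdiff1d(np.arange(scan.n_rois), degenerate)
    r[valid, valid] = 1.0
    r = np.clip(r, -1.0, 1.0)
    return ConnectivityMatrix(
        r, list(scan.roi_names),
        metadata={
            "subject": scan.subject_id,
            "genotype": scan.genotype,
            "age_months": scan.age_months,
            "scan_id": scan.scan_id,
            "retained_fraction": float(scan.censor_mask.mean()),
            "n_degenerate_rois": int(degenerate.size),
        },
    )
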