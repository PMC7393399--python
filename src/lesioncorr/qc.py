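"""Scan-quality and reliability statistics: SNR, CNR, ABC/2 lesion volume,
and the intraclass correlation coefficient (ICC) with an F-based CI.

SNR is the mean over sample SD of the intensities inside the white-matter
segmentation. CNR averages the WM-GM and GM-CSF contrasts, each contrast
being |mu_a - mu_b| / sqrt((sigma_a^2 + sigma_b^2) / 2) (pooled-SD form).
ABC/2 is the bedside volume estimate A*B*C/2 from the two largest
perpendicular in-slice diameters and the craniocaudal extent. The ICC is
the two-way, single-measurement form, either absolute agreement ICC(2,1)
(default) or consistency ICC(3,1).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

from .io_fs import VoxelVolume

__all__ = [
    "TissueMasks",
    "RaterMatrix",
    "snr",
    "cnr",
    "abc2",
    "abc2_from_mask",
    "icc",
    "ICCResult",
]


@dataclass
class TissueMasks:
    """Binary WM/GM/CSF masks aligned to one intensity grid."""

    wm: np.ndarray
    gm: np.ndarray
    csf: np.ndarray

    def __post_init__(self) -> None:
        self.wm = np.asarray(self.wm, dtype=bool)
        self.gm = np.asarray(self.gm, dtype=bool)
        self.csf = np.asarray(self.csf, dtype=bool)
        if not (self.wm.shape == self.gm.shape == self.csf.shape):
            raise ValueError("tissue masks must share one shape")


@dataclass
class RaterMatrix:
    """Lesion-volume measurements (ml), subjects x raters, no missing entries."""

    measurements: np.ndarray

    def __post_init__(self) -> None:
        m = np.asarray(self.measurements, dtype=np.float64)
        if m.ndim != 2:
            raise ValueError("measurements must be a 2-D subjects x raters array")
        if m.shape[0] < 2 or m.shape[1] < 2:
            raise ValueError(f"need >= 2 subjects and >= 2 raters, got shape {m.shape}")
        if np.any(~np.isfinite(m)):
            raise ValueError("missing/non-finite entries are not allowed")
        self.measurements = m

    @property
    def n_subjects(self) -> int:
        return self.measurements.shape[0]

    @property
    def n_raters(self) -> int:
        return self.measurements.shape[1]


def _masked(volume: VoxelVolume, mask: np.ndarray, what: str) -> np.ndarray:
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != volume.intensities.shape:
        raise ValueError(f"{what} mask shape {mask.shape} != volume shape {volume.intensities.shape}")
    vals = volume.intensities[mask]
    if vals.size == 0:
        raise ValueError(f"empty {what} mask")
    return vals


def snr(volume: VoxelVolume, wm_mask: np.ndarray) -> float:
    """Signal-to-noise ratio: mean / sample SD of intensities within WM."""
    vals = _masked(volume, wm_mask, "WM")
    sd = float(vals.std(ddof=1)) if vals.size > 1 else 0.0
    if sd == 0.0:
        raise ValueError("constant region: SD of WM intensities is zero")
    return float(vals.mean()) / sd


def _contrast(a: np.ndarray, b: np.ndarray) -> float:
    # pooled-SD contrast between two tissue classes
    va = float(a.var(ddof=1)) if a.size > 1 else 0.0
    vb = float(b.var(ddof=1)) if b.size > 1 else 0.0
    pooled = math.sqrt((va + vb) / 2.0)
    if pooled == 0.0:
        raise ValueError("constant region: pooled SD is zero")
    return abs(float(a.mean()) - float(b.mean())) / pooled


def cnr(volume: VoxelVolume, masks: TissueMasks) -> float:
    """Contrast-to-noise ratio: average of the WM-GM and GM-CSF contrasts."""
    wm = _masked(volume, masks.wm, "WM")
    gm = _masked(volume, masks.gm, "GM")
    csf = _masked(volume, masks.csf, "CSF")
    return 0.5 * (_contrast(wm, gm) + _contrast(gm, csf))


def abc2(a_mm: float, b_mm: float, c_mm: float) -> float:
    """ABC/2 lesion volume in ml from three diameters in mm: a*b*c/2000."""
    if a_mm <= 0 or b_mm <= 0 or c_mm <= 0:
        raise ValueError("ABC/2 diameters must be > 0")
    return a_mm * b_mm * c_mm / 2000.0


def abc2_from_mask(mask: np.ndarray, voxel_size: tuple[float, float, float]) -> float:
    """ABC/2 volume (ml) measured on a binary lesion mask.

    A is the longest in-plane diameter on the axial slice (last axis) with
    the largest lesion cross-section; B is the largest extent perpendicular
    to A's direction on that slice; C is the number of lesion-bearing slices
    times the slice thickness. Ties on slice size break to the lowest slice
    index. Diameters are measured between voxel centers.
    """
    mask = np.asarray(mask, dtype=bool)
    if mask.ndim != 3:
        raise ValueError("mask must be a 3-D grid")
    if not mask.any():
        raise ValueError("empty mask")
    dx, dy, dz = (float(v) for v in voxel_size)
    slice_counts = mask.sum(axis=(0, 1))
    k = int(np.argmax(slice_counts))  # argmax takes the first (lowest) maximal slice
    ii, jj = np.nonzero(mask[:, :, k])
    pts = np.column_stack([ii * dx, jj * dy])
    if pts.shape[0] == 1:
        a_len, b_len = dx, dy  # single voxel: one voxel footprint in each direction
    else:
        hull = pts
        if pts.shape[0] > 400:  # reduce to the convex hull before pairwise distances
            from scipy.spatial import ConvexHull

            try:
                hull = pts[ConvexHull(pts).vertices]
            except Exception:  # degenerate (collinear) point sets
                hull = pts
        d2 = np.sum((hull[:, None, :] - hull[None, :, :]) ** 2, axis=-1)
        i, j = np.unravel_index(int(np.argmax(d2)), d2.shape)
        a_vec = hull[j] - hull[i]
        a_len = float(np.linalg.norm(a_vec))
        if a_len == 0.0:
            a_len = max(dx, dy)
            b_len = min(dx, dy)
        else:
            perp = np.array([-a_vec[1], a_vec[0]]) / a_len
            proj = pts @ perp
            b_len = float(proj.max() - proj.min())
            if b_len == 0.0:  # collinear footprint: one voxel across
                b_len = min(dx, dy)
    c_len = float(np.count_nonzero(slice_counts)) * dz
    return abc2(a_len, b_len, c_len)


@dataclass
class ICCResult:
    """Point estimate with confidence interval and the form used."""

    estimate: float
    ci_low: float
    ci_high: float
    form: str
    confidence: float


def icc(matrix: RaterMatrix, confidence: float = 0.95, form: str = "agreement") -> ICCResult:
    """Two-way, single-measurement intraclass correlation coefficient.

    ``form="agreement"`` gives the two-way random-effects absolute-agreement
    ICC(2,1); ``form="consistency"`` the two-way mixed consistency ICC(3,1).
    The CI uses the standard F-based intervals (exact for consistency, the
    Satterthwaite-type approximation for agreement). The estimate is clipped
    to [-1, 1].
    """
    if form not in ("agreement", "consistency"):
        raise ValueError(f"form must be 'agreement' or 'consistency', got {form!r}")
    if not (0 < confidence < 1):
        raise ValueError("confidence must be in (0, 1)")
    y = matrix.measurements
    n, k = y.shape
    grand = y.mean()
    row_means = y.mean(axis=1)
    col_means = y.mean(axis=0)
    ss_rows = k * np.sum((row_means - grand) ** 2)
    ss_cols = n * np.sum((col_means - grand) ** 2)
    ss_tot = np.sum((y - grand) ** 2)
    ss_err = ss_tot - ss_rows - ss_cols
    msr = ss_rows / (n - 1)
    msc = ss_cols / (k - 1)
    mse = max(ss_err / ((n - 1) * (k - 1)), 0.0)
    alpha = 1.0 - confidence

    if form == "consistency":
        denom = msr + (k - 1) * mse
        est = (msr - mse) / denom if denom > 0 else 1.0
        if mse == 0.0:
            return ICCResult(1.0, 1.0, 1.0, form, confidence)
        fobs = msr / mse
        df1, df2 = n - 1, (n - 1) * (k - 1)
        fl = fobs / sps.f.ppf(1 - alpha / 2, df1, df2)
        fu = fobs * sps.f.ppf(1 - alpha / 2, df2, df1)
        lo = (fl - 1) / (fl + k - 1)
        hi = (fu - 1) / (fu + k - 1)
    else:
        denom = msr + (k - 1) * mse + k * (msc - mse) / n
        est = (msr - mse) / denom if denom > 0 else 1.0
        if mse == 0.0 and msc <= mse:
            return ICCResult(1.0, 1.0, 1.0, form, confidence)
        a = k * est / (n * (1 - est)) if est < 1 else np.inf
        b = 1 + k * est * (n - 1) / (n * (1 - est)) if est < 1 else np.inf
        if not np.isfinite(a) or not np.isfinite(b):
            lo = hi = 1.0
        else:
            num = (a * msc + b * mse) ** 2
            den = (a * msc) ** 2 / (k - 1) + (b * mse) ** 2 / ((n - 1) * (k - 1))
            v = num / den if den > 0 else (n - 1) * (k - 1)
            f_lo = sps.f.ppf(1 - alpha / 2, n - 1, v)
            f_hi = sps.f.ppf(1 - alpha / 2, v, n - 1)
            lo = n * (msr - f_lo * mse) / (
                f_lo * (k * msc + (k * n - k - n) * mse) + n * msr
            )
            hi = n * (f_hi * msr - mse) / (
                k * msc + (k * n - k - n) * mse + n * f_hi * msr
            )
    est = float(np.clip(est, -1.0, 1.0))
    lo = float(np.clip(lo, -1.0, est))
    hi = float(np.clip(hi, est, 1.0))
    return ICCResult(est, lo, hi, form, confidence)
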