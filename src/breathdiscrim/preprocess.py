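"""Chromatogram preprocessing: smoothing, baseline/bleed correction,
retention-time alignment, and peak detection/integration.

Reduces a set of raw breathograms to a samples x compounds feature matrix.
The chain is a standard, fully parameterized GC-MS stack:

1. ``smooth`` — Savitzky-Golay local-polynomial smoothing against rapid
   baseline fluctuations (noise);
2. ``correct_baseline`` — asymmetric least squares (iteratively reweighted
   Whittaker smoother) against column bleed and slow drift of the baseline;
3. ``align`` — segment-wise cross-correlation alignment against a reference
   trace, with shifts interpolated smoothly between segment centers, against
   chromatographic drift of retention times;
4. ``detect_and_integrate`` — prominence-based peak calling, boundaries at
   flanking minima, trapezoidal integration, and a cross-sample registry that
   matches peaks within a retention-time tolerance into shared compound IDs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.signal import savgol_filter, find_peaks
from scipy.sparse.linalg import spsolve

from .datatypes import Breathogram, FeatureMatrix

__all__ = ["smooth", "correct_baseline", "resample", "align",
           "detect_and_integrate", "preprocess_cohort", "PeakTable"]


def smooth(b: Breathogram, window: int = 11, polyorder: int = 3) -> Breathogram:
    """Savitzky-Golay smoothing; reproduces polynomials of degree <= polyorder.

    ``window`` must be odd and larger than ``polyorder``; ``window=1`` is the
    identity.
    """
    if window % 2 == 0:
        raise ValueError("window must be odd")
    if window > len(b.intensity):
        raise ValueError("window larger than the trace")
    if window == 1:
        return b.copy_with(b.intensity.copy())
    if window <= polyorder:
        raise ValueError("window must exceed polyorder")
    return b.copy_with(savgol_filter(b.intensity, window, polyorder))


def _asls_baseline(y: np.ndarray, asymmetry: float, stiffness: float,
                   max_iter: int) -> tuple[np.ndarray, bool]:
    """Asymmetric least-squares baseline (Whittaker smoother, 2nd-order penalty)."""
    n = len(y)
    D = sp.diags([1.0, -2.0, 1.0], [0, 1, 2], shape=(n - 2, n), format="csc")
    penalty = stiffness * (D.T @ D)
    w = np.ones(n)
    converged = False
    z = y
    for _ in range(max_iter):
        W = sp.diags(w, 0, format="csc")
        z = spsolve(W + penalty, w * y)
        w_new = np.where(y > z, asymmetry, 1.0 - asymmetry)
        if np.array_equal(w_new, w):
            converged = True
            break
        w = w_new
    return z, converged


def correct_baseline(b: Breathogram, asymmetry: float = 0.01,
                     stiffness: float = 1e7, max_iter: int = 20) -> Breathogram:
    """Subtract a slowly varying baseline (drift + column bleed), floor at 0.

    Points above the running baseline are down-weighted by ``asymmetry`` so
    the smoother tracks the valleys under the peaks.  Non-convergence within
    ``max_iter`` returns the last iterate with ``meta["baseline_converged"]``
    set to False.
    """
    if not 0 < asymmetry < 1:
        raise ValueError("asymmetry must lie in (0, 1)")
    if stiffness <= 0:
        raise ValueError("stiffness must be positive")
    baseline, converged = _asls_baseline(b.intensity, asymmetry, stiffness, max_iter)
    out = b.copy_with(np.maximum(b.intensity - baseline, 0.0))
    out.meta["baseline_converged"] = bool(converged)
    out.meta["baseline_fraction"] = float(
        np.trapezoid(baseline, b.rt) / max(np.trapezoid(b.intensity, b.rt), 1e-300))
    return out


def resample(b: Breathogram, rt_grid: np.ndarray) -> Breathogram:
    """Linear re-interpolation onto a common retention-time grid."""
    out = Breathogram(b.sample_id, rt_grid,
                      np.interp(rt_grid, b.rt, b.intensity), dict(b.meta))
    return out


def _segment_shift(y: np.ndarray, ref: np.ndarray, lo: int, hi: int,
                   max_shift: int) -> float:
    """Best integer shift s in [-max_shift, max_shift] (corrected = y[i - s])."""
    best_s, best_c = 0, -np.inf
    for s in range(-max_shift, max_shift + 1):
        # y indices feeding corrected[lo:hi], trimmed to the valid overlap
        off_lo = max(0, -(lo + s))
        off_hi = max(0, hi + s - len(y))
        seg = y[lo + s + off_lo: hi + s - off_hi]
        seg_ref = ref[lo + off_lo: hi - off_hi]
        if len(seg) < (hi - lo) // 2:
            continue
        denom = np.linalg.norm(seg) * np.linalg.norm(seg_ref)
        c = float(seg @ seg_ref) / denom if denom > 0 else 0.0
        if c > best_c + 1e-12:
            best_c, best_s = c, s
    return float(-best_s)


def align(samples: list[Breathogram], reference="median", segment_len: int = 500,
          max_shift: int = 20) -> tuple[list[Breathogram], pd.DataFrame]:
    """Segment-wise cross-correlation alignment onto a shared reference.

    Samples are first resampled onto the first sample's grid if grids differ.
    Per segment, the integer shift (in grid points, within ``max_shift``)
    maximizing the normalized cross-correlation with the reference is found;
    shifts are linearly interpolated between segment centers and applied by
    interpolation.  Returns the aligned traces and a QC table of per-segment
    shifts (a sample needing more than ``max_shift`` saturates at the bound,
    which shows up in the QC output as residual misalignment).
    """
    if not samples:
        raise ValueError("empty sample list")
    if max_shift >= segment_len:
        raise ValueError("max_shift must be smaller than segment_len")
    grid = samples[0].rt
    samples = [s if np.array_equal(s.rt, grid) else resample(s, grid) for s in samples]
    mat = np.stack([s.intensity for s in samples])
    if isinstance(reference, Breathogram):
        ref = resample(reference, grid).intensity
    elif reference == "median":
        ref = np.median(mat, axis=0)
    else:
        raise ValueError("reference must be a Breathogram or 'median'")

    n = len(grid)
    starts = np.arange(0, n, segment_len)
    centers = np.minimum(starts + segment_len // 2, n - 1)
    aligned, qc_rows = [], []
    idx = np.arange(n, dtype=float)
    for s in samples:
        shifts = np.array([_segment_shift(s.intensity, ref, lo,
                                          min(lo + segment_len, n), max_shift)
                           for lo in starts])
        shift_per_point = np.interp(idx, centers.astype(float), shifts)
        warped = np.interp(idx - shift_per_point, idx, s.intensity)
        out = s.copy_with(warped)
        out.meta["alignment_shifts"] = shifts
        aligned.append(out)
        qc_rows.append({"sample_id": s.sample_id,
                        **{f"seg{k}": sh for k, sh in enumerate(shifts)},
                        "max_abs_shift": float(np.max(np.abs(shifts)))})
    return aligned, pd.DataFrame(qc_rows)


@dataclass
class PeakTable:
    """Per-sample integrated peaks plus the cross-sample compound registry."""

    peaks: pd.DataFrame      # sample_id, apex_rt, left_rt, right_rt, area, compound
    registry: pd.DataFrame   # compound, apex_rt (cluster mean)


def _sample_peaks(b: Breathogram, min_prominence: float) -> list[dict]:
    y = b.intensity
    apex, _ = find_peaks(y, prominence=min_prominence)
    rows = []
    for k, a in enumerate(apex):
        left_bound = apex[k - 1] if k > 0 else 0
        right_bound = apex[k + 1] if k + 1 < len(apex) else len(y) - 1
        li = left_bound + int(np.argmin(y[left_bound:a + 1])) if a > left_bound else a
        ri = a + int(np.argmin(y[a:right_bound + 1])) if right_bound > a else a
        if li >= a or ri <= a:
            continue
        area = float(np.trapezoid(y[li:ri + 1], b.rt[li:ri + 1]))
        rows.append({"sample_id": b.sample_id, "apex_rt": float(b.rt[a]),
                     "left_rt": float(b.rt[li]), "right_rt": float(b.rt[ri]),
                     "area": max(area, 0.0)})
    return rows


def detect_and_integrate(samples: list[Breathogram], min_prominence: float,
                         match_tol: float,
                         min_fraction: float = 0.0) -> tuple[PeakTable, pd.DataFrame]:
    """Call and integrate peaks, then match them across samples by apex RT.

    All apexes within ``match_tol`` retention-time units (transitively, by
    gap-based clustering of the pooled apex positions) share one compound ID;
    a sample lacking a registry compound gets area 0.  ``min_fraction`` drops
    registry compounds detected in fewer than that fraction of samples
    (0 keeps everything).  Returns the peak table and the feature matrix
    (rows in input sample order).
    """
    rows = [r for b in samples for r in _sample_peaks(b, min_prominence)]
    sample_order = [b.sample_id for b in samples]
    if not rows:
        import warnings
        warnings.warn("no peaks detected in any sample")
        return (PeakTable(pd.DataFrame(columns=["sample_id", "apex_rt", "left_rt",
                                                "right_rt", "area", "compound"]),
                          pd.DataFrame(columns=["compound", "apex_rt"])),
                pd.DataFrame(index=pd.Index(sample_order, name="sample_id")))
    peaks = pd.DataFrame(rows).sort_values("apex_rt", kind="stable").reset_index(drop=True)
    rts = peaks["apex_rt"].to_numpy()
    cluster = np.concatenate([[0], np.cumsum(np.diff(rts) > match_tol)])
    peaks["cluster"] = cluster
    reg = peaks.groupby("cluster").agg(apex_rt=("apex_rt", "mean"),
                                       n_samples=("sample_id", "nunique")).reset_index()
    if min_fraction > 0:
        reg = reg[reg["n_samples"] >= min_fraction * len(samples)].reset_index(drop=True)
        peaks = peaks[peaks["cluster"].isin(reg["cluster"])]
    reg["compound"] = [f"C{k + 1:04d}" for k in range(len(reg))]
    peaks = peaks.merge(reg[["cluster", "compound"]], on="cluster").drop(columns="cluster")

    fm = (peaks.groupby(["sample_id", "compound"])["area"].sum().unstack(fill_value=0.0)
          .reindex(index=sample_order, columns=reg["compound"], fill_value=0.0))
    fm.index.name = "sample_id"
    return PeakTable(peaks, reg[["compound", "apex_rt"]]), fm


def preprocess_cohort(samples: list[Breathogram], window: int = 11, polyorder: int = 3,
                      asymmetry: float = 0.01, stiffness: float = 1e7,
                      baseline_max_iter: int = 20, segment_len: int = 500,
                      max_shift: int = 20, min_prominence: float = 0.01,
                      match_tol: float = 5.0, min_fraction: float = 0.0,
                      labels: pd.Series | None = None) -> tuple[FeatureMatrix, dict]:
    """Full chain: smooth -> baseline -> align -> detect/integrate.

    Returns a FeatureMatrix (class labels taken from ``labels`` or 'unknown'),
    a QC dict (alignment shifts, baseline fractions removed), and the PeakTable.
    """
    smoothed = [smooth(b, window, polyorder) for b in samples]
    corrected = [correct_baseline(b, asymmetry, stiffness, baseline_max_iter)
                 for b in smoothed]
    aligned, shift_qc = align(corrected, "median", segment_len, max_shift)
    table, fm_df = detect_and_integrate(aligned, min_prominence, match_tol,
                                        min_fraction)
    y = (labels.loc[fm_df.index] if labels is not None
         else pd.Series("unknown", index=fm_df.index))
    qc = {"alignment": shift_qc,
          "baseline_fraction": {b.sample_id: b.meta.get("baseline_fraction")
                                for b in corrected},
          "n_compounds": int(fm_df.shape[1])}
    return FeatureMatrix(fm_df, y), qc, table
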