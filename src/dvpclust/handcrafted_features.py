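"""Handcrafted pulse-morphology features.

Fourteen per-pulse features describing the shape of a normalized DVP:
notch/diastolic amplitude ratio, downslope areas and derivative moments,
amplitude skewness/kurtosis, second-derivative landmark amplitudes and
indices, rise time, peak count and an augmentation-index computability
flag.  Feature extraction is total on valid normalized pulses: missing
fiducial points (e.g., a notch-free class-4 wave) are encoded by sentinels,
never raised.

Fiducial detection follows common pulse-wave-analysis practice: systolic
peak = global maximum; maximum downslope = most negative first derivative
after the systolic peak; dicrotic notch = first local minimum of the pulse
thereafter (falling back to the most negative local minimum of the first
derivative when the notch does not develop into a true minimum); diastolic
peak = first local maximum after the notch.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.signal import find_peaks
from sklearn.preprocessing import StandardScaler

__all__ = [
    "FEATURE_NAMES",
    "DDR_SENTINEL",
    "FiducialSet",
    "detect_fiducials",
    "extract_features",
    "extract_feature_matrix",
    "fit_transform_features",
]

FEATURE_NAMES = [
    "DDR",
    "RDS",
    "DDM",
    "Skew",
    "P_b_2Dev_A",
    "P_b_2Dev_i",
    "P_a_2Dev_A",
    "P_a_2Dev_i",
    "S_P_Onde",
    "nbr_peaks",
    "log_RT",
    "log_Kurt",
    "AI_bin",
    "log_DDV",
]

#: DDR value reported when no diastolic point is detected.
DDR_SENTINEL = 1.1

#: default peak-counting prominence, in normalized amplitude units
PEAK_PROMINENCE = 0.02

_DDV_FLOOR = 1e-8


@dataclass(frozen=True)
class FiducialSet:
    """Landmark indices/amplitudes on the 100-sample normalized pulse grid.

    ``dicrotic_notch_idx`` and ``diastolic_peak_idx`` are ``None`` when no
    qualifying extremum exists (notch-free morphologies).
    """

    onset_idx: int
    systolic_peak_idx: int
    max_downslope_idx: int
    dicrotic_notch_idx: int | None
    diastolic_peak_idx: int | None
    sdppg_min1_idx: int
    sdppg_min1_amp: float
    sdppg_max_idx: int
    sdppg_max_amp: float


def _first_local_min(x: np.ndarray) -> int | None:
    idx, _ = find_peaks(-x)
    return int(idx[0]) if idx.size else None


def detect_fiducials(pulse: np.ndarray) -> FiducialSet:
    x = np.asarray(pulse, dtype=float)
    d1 = np.gradient(x)
    d2 = np.gradient(d1)

    sys_idx = int(np.argmax(x))
    onset_idx = int(np.argmin(x[: sys_idx + 1]))
    down_idx = sys_idx + int(np.argmin(d1[sys_idx:]))

    notch_idx: int | None = None
    rel = _first_local_min(x[down_idx:])
    if rel is not None:
        notch_idx = down_idx + rel
    else:
        # shoulder-type notch: the downslope decelerates then re-steepens,
        # leaving a local minimum in the first derivative
        cand, _ = find_peaks(-d1[down_idx + 1 :])
        if cand.size:
            notch_idx = down_idx + 1 + int(cand[np.argmin(d1[down_idx + 1 :][cand])])

    dia_idx: int | None = None
    if notch_idx is not None:
        cand, _ = find_peaks(x[notch_idx:])
        if cand.size:
            dia_idx = notch_idx + int(cand[0])

    min1 = _first_local_min(d2)
    sd_min1 = min1 if min1 is not None else int(np.argmin(d2))
    sd_max = int(np.argmax(d2))

    return FiducialSet(
        onset_idx=onset_idx,
        systolic_peak_idx=sys_idx,
        max_downslope_idx=down_idx,
        dicrotic_notch_idx=notch_idx,
        diastolic_peak_idx=dia_idx,
        sdppg_min1_idx=sd_min1,
        sdppg_min1_amp=float(d2[sd_min1]),
        sdppg_max_idx=sd_max,
        sdppg_max_amp=float(d2[sd_max]),
    )


def _ai_flag(x: np.ndarray, d1: np.ndarray, fid: FiducialSet) -> float:
    """1.0 iff a secondary systolic wave (pre-notch shoulder) is detectable.

    A reflected wave superposed on the systolic downslope produces a local
    maximum in the first derivative between the systolic peak and the notch
    (deceleration followed by re-acceleration).
    """
    end = fid.dicrotic_notch_idx if fid.dicrotic_notch_idx is not None else x.size - 1
    seg = d1[fid.systolic_peak_idx + 1 : end]
    if seg.size < 3:
        return 0.0
    prom = 0.05 * (d1.max() - d1.min())
    peaks, _ = find_peaks(seg, prominence=prom)
    return 1.0 if peaks.size else 0.0


def extract_features(
    pulse: np.ndarray, peak_prominence: float = PEAK_PROMINENCE
) -> np.ndarray:
    """The 14-entry feature vector of one normalized pulse (fixed order).

    Order and abbreviations follow :data:`FEATURE_NAMES`.  Logarithm guards:
    rise time floored at 1 sample; kurtosis taken as Pearson (excess + 3,
    always positive here); downslope derivative variance floored at 1e-8.
    """
    x = np.asarray(pulse, dtype=float)
    d1 = np.gradient(x)
    fid = detect_fiducials(x)

    if fid.diastolic_peak_idx is not None and fid.dicrotic_notch_idx is not None:
        ddr = x[fid.dicrotic_notch_idx] / max(x[fid.diastolic_peak_idx], 1e-12)
    else:
        ddr = DDR_SENTINEL

    rds = float(np.trapezoid(x[fid.max_downslope_idx :]))
    post_sys = d1[fid.systolic_peak_idx :]
    ddm = float(post_sys.mean()) if post_sys.size else 0.0
    skew = float(stats.skew(x))
    s_p_onde = float(np.trapezoid(x))
    peaks, _ = find_peaks(x, prominence=peak_prominence)
    n_interior = peaks.size
    # the systolic maximum itself may sit at the boundary of the window
    if fid.systolic_peak_idx not in peaks:
        n_interior += 1
    nbr_peaks = max(n_interior, 1)
    log_rt = float(np.log(max(fid.systolic_peak_idx - fid.onset_idx, 1)))
    kurt = stats.kurtosis(x, fisher=True) + 3.0
    log_kurt = float(np.log(kurt))
    ai_bin = _ai_flag(x, d1, fid)
    ddv = max(float(np.var(post_sys)) if post_sys.size else 0.0, _DDV_FLOOR)
    log_ddv = float(np.log(ddv))

    return np.array(
        [
            ddr,
            rds,
            ddm,
            skew,
            fid.sdppg_min1_amp,
            float(fid.sdppg_min1_idx),
            fid.sdppg_max_amp,
            float(fid.sdppg_max_idx),
            s_p_onde,
            float(nbr_peaks),
            log_rt,
            log_kurt,
            ai_bin,
            log_ddv,
        ]
    )


def extract_feature_matrix(
    pulses: np.ndarray, peak_prominence: float = PEAK_PROMINENCE
) -> pd.DataFrame:
    """Feature table for a pulse matrix, columns named per :data:`FEATURE_NAMES`."""
    rows = [extract_features(p, peak_prominence) for p in np.asarray(pulses, dtype=float)]
    return pd.DataFrame(rows, columns=FEATURE_NAMES)


def fit_transform_features(train, *others):
    """Column z-scoring with statistics estimated on the training set only.

    Returns ``(train_scaled, [other_scaled...], scaler)``.  A zero-variance
    training column is an error (it cannot be scaled to unit variance) and
    is reported by name.
    """
    train_arr = np.asarray(train, dtype=float)
    scaler = StandardScaler().fit(train_arr)
    zero = np.flatnonzero(scaler.var_ < 1e-24)
    if zero.size:
        names = [FEATURE_NAMES[i] if i < len(FEATURE_NAMES) else str(i) for i in zero]
        raise ValueError(f"zero-variance feature column(s): {', '.join(names)}")
    scaled_others = [scaler.transform(np.asarray(o, dtype=float)) for o in others]
    return scaler.transform(train_arr), scaled_others, scaler
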