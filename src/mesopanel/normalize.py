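"""Median signal normalization and calibrator-based inter-plate scaling.

Both corrections are purely multiplicative on the RFU scale.  Median
normalization aligns each sample's median ratio to a common per-analyte
reference; plate calibration scales each (plate, analyte) pair so that the
median of the plate's reference calibrator wells matches a pooled target.

Each transform is idempotent when re-applied with the reference it
returns; with a self-derived reference the second pass recomputes the
reference and is idempotent for calibration (plate calibrator medians all
equal the target afterwards) but only approximately so for normalization.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data import RfuMatrix

EXPECTED_CALIBRATORS_PER_PLATE = 8


@dataclass
class NormalizationResult:
    normalized: RfuMatrix
    sample_scale_factors: pd.Series  # per sample, strictly positive
    reference: pd.Series  # per analyte, strictly positive


@dataclass
class CalibrationResult:
    calibrated: RfuMatrix
    scale_factors: pd.DataFrame  # plates x analytes, strictly positive
    calibrator_reference: pd.Series


def median_normalize(
    matrix: RfuMatrix, reference: pd.Series | None = None
) -> NormalizationResult:
    """Align the median of each sample to a common per-analyte reference.

    The per-sample factor is ``f_s = median_a(reference_a / value_sa)``
    (median of ratios, invariant under per-analyte reweighting); every value
    in the row is multiplied by ``f_s``, so afterwards the per-sample median
    ratio to the reference is exactly 1.
    """
    v = matrix.values
    if reference is None:
        reference = v.median(axis=0)
    reference = reference.reindex(v.columns)
    if reference.isna().any() or (reference <= 0).any():
        raise ValueError("reference must be positive for every analyte")
    ratios = reference.to_numpy()[None, :] / v.to_numpy()
    factors = pd.Series(np.median(ratios, axis=1), index=v.index, name="scale_factor")
    normalized = RfuMatrix(v.mul(factors, axis=0), matrix.analyte_meta)
    return NormalizationResult(normalized, factors, reference)


def calibrate_plates(
    matrix: RfuMatrix,
    ann: pd.DataFrame,
    reference: pd.Series | None = None,
) -> CalibrationResult:
    """Multiplicative per-(plate, analyte) scaling from calibrator wells.

    ``g_pa = reference_a / median(calibrator wells of analyte a on plate p)``;
    every sample on plate p is multiplied by ``g_pa`` column-wise.  If no
    reference is supplied it is the per-analyte median of calibrator wells
    pooled over plates.
    """
    v = matrix.values
    ann = ann.set_index("sample_id", drop=False).loc[list(v.index)]
    is_cal = (ann["class_label"] == "CALIBRATOR").to_numpy()
    plates = ann["plate_id"].to_numpy()
    plate_names = sorted(set(plates))

    cal_medians = {}
    for p in plate_names:
        sel = is_cal & (plates == p)
        n_cal = int(sel.sum())
        if n_cal == 0:
            raise ValueError(f"plate {p!r} has no calibrator wells")
        if n_cal != EXPECTED_CALIBRATORS_PER_PLATE:
            warnings.warn(
                f"plate {p!r} has {n_cal} calibrator wells "
                f"(expected {EXPECTED_CALIBRATORS_PER_PLATE})",
                stacklevel=2,
            )
        cal_medians[p] = v.loc[sel].median(axis=0)
    cal_medians = pd.DataFrame(cal_medians).T  # plates x analytes

    if reference is None:
        reference = v.loc[is_cal].median(axis=0)
    reference = reference.reindex(v.columns)
    if reference.isna().any() or (reference <= 0).any():
        raise ValueError("calibrator reference must be positive for every analyte")

    factors = reference.to_numpy()[None, :] / cal_medians.to_numpy()
    factors = pd.DataFrame(factors, index=cal_medians.index, columns=v.columns)
    scaled = v.to_numpy() * factors.loc[plates].to_numpy()
    calibrated = RfuMatrix(
        pd.DataFrame(scaled, index=v.index, columns=v.columns), matrix.analyte_meta
    )
    return CalibrationResult(calibrated, factors, reference)
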