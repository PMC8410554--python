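"""Dilution-series calibration of dPCR assays: linearity, LOD and LOQ.

An assay is calibrated by spiking mutant template into wild-type
background at known allele fractions (e.g. 1%, 0.5%, 0.1%, 0.05%) and
regressing the observed MAF (the response) on the expected MAF by
ordinary least squares.  Detection limits follow the
standard-deviation-of-the-response/slope method of the ICH Q2(R1)
guideline, with the response SD taken as the standard error of the
regression intercept:

    LOD = 3.3 * sigma / S        LOQ = 10 * sigma / S

where S is the calibration slope and sigma the intercept's standard
error.  Both limits are in the same unit as the MAFs supplied.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy.stats import linregress

from .dpcr import DpcrCall

__all__ = [
    "DilutionSeries",
    "CalibrationResult",
    "LOD_MULTIPLIER",
    "LOQ_MULTIPLIER",
    "calibrate",
    "false_positive_screen",
]

LOD_MULTIPLIER = 3.3
LOQ_MULTIPLIER = 10.0


@dataclass(frozen=True)
class DilutionSeries:
    """Paired expected/observed MAF points for one assay.

    ``points`` holds (expected_maf, observed_maf, replicate) triples with
    MAFs as fractions; at least 3 distinct expected levels are required
    for detection-limit estimation.  ``input_ng`` records the cfDNA input
    the series was run at (detection limits are input-dependent).
    """

    assay: str
    points: tuple[tuple[float, float, int], ...]
    input_ng: float = 7.0

    def __post_init__(self):
        for exp, obs, _ in self.points:
            if not (0 <= exp <= 1 and 0 <= obs <= 1):
                raise ValueError("MAFs must be fractions in [0, 1]")

    @property
    def levels(self) -> tuple[float, ...]:
        return tuple(sorted({exp for exp, _, _ in self.points}))


@dataclass(frozen=True)
class CalibrationResult:
    assay: str
    slope: float
    intercept: float
    intercept_se: float
    pearson_r: float
    lod: float
    loq: float


class CalibrationError(ValueError):
    pass


def calibrate(series: DilutionSeries, *, aggregate_levels: bool = False
              ) -> CalibrationResult:
    """OLS of observed on expected MAF; LOD/LOQ from intercept SE and slope.

    With ``aggregate_levels`` replicates are averaged per expected level
    before regression; by default every point enters individually.
    Raises :class:`CalibrationError` for <3 distinct levels or a
    non-positive slope.
    """
    if len(series.levels) < 3:
        raise CalibrationError(
            f"need >= 3 distinct expected levels, got {len(series.levels)}")
    x = np.array([p[0] for p in series.points], dtype=float)
    y = np.array([p[1] for p in series.points], dtype=float)
    if aggregate_levels:
        levels = np.array(series.levels)
        y = np.array([y[x == lv].mean() for lv in levels])
        x = levels
    fit = linregress(x, y)
    if fit.slope <= 0:
        raise CalibrationError(f"non-positive calibration slope {fit.slope:g}")
    sigma = float(fit.intercept_stderr)
    return CalibrationResult(
        assay=series.assay,
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        intercept_se=sigma,
        pearson_r=float(fit.rvalue),
        lod=LOD_MULTIPLIER * sigma / fit.slope,
        loq=LOQ_MULTIPLIER * sigma / fit.slope,
    )


def false_positive_screen(wt_results: Iterable[DpcrCall]) -> int:
    """Count positive calls among chips run on wild-type-only material.

    A specific assay is expected to return zero; any positive is a
    false-positive signal of the assay/chemistry.
    """
    return sum(1 for call in wt_results if call.positive)
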