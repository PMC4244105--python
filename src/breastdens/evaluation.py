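"""Agreement statistics between two segmentations or volumetries.

Voxel-overlap metrics follow the delineation framework: with A the automatic
and M the manual (reference) segmentation on image domain Omega,

    DSC  = 2|A ∩ M| / (|A| + |M|)
    TPVF = |A ∩ M| / |M|                  (delineation sensitivity)
    FPVF = |A \\ M| / |Omega \\ M|
    TNVF = 1 - FPVF                       (delineation specificity)

Method agreement on scalar volumes uses Bland–Altman analysis: differences
``d_i = auto_i - manual_i`` plotted against averages ``a_i``, with mean bias,
SD of differences and classic limits ``bias ± 1.96 SD``.  When the bias
varies with the measured magnitude, regression-based limits are available:
the differences are regressed on the averages, the absolute residuals are
regressed on the averages, and the limits are

    D(a) ± 1.96 * sqrt(pi/2) * R(a),

where D and R are the two fitted lines (sqrt(pi/2) ≈ 1.2533 converts the
mean absolute residual to an SD under normality).

Note: delineation specificity is reported for completeness but is close to 1
whenever the background dwarfs any plausible oversegmentation, so it carries
little information; treat it as unreliable.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import pi, sqrt
from typing import Callable

import numpy as np
import statsmodels.api as sm

from .volume_io import BinaryMask

__all__ = [
    "AgreementStats",
    "BlandAltman",
    "RegressionFit",
    "agreement",
    "bland_altman",
    "regression_loa",
    "linear_regression",
]

SD_FROM_MAR = sqrt(pi / 2.0)  # mean absolute residual -> SD under normality


@dataclass(frozen=True)
class AgreementStats:
    """Voxel-overlap agreement between an automatic and a reference mask."""

    dsc: float
    sens: float  # TPVF
    spec: float  # TNVF
    fpvf: float
    specificity_reliable: bool = False  # near-1 by construction on large domains

    def to_dict(self) -> dict:
        return {
            "dsc": self.dsc,
            "sensitivity_tpvf": self.sens,
            "specificity_tnvf": self.spec,
            "fpvf": self.fpvf,
            "specificity_reliable": self.specificity_reliable,
        }


@dataclass(frozen=True)
class RegressionFit:
    """OLS fit y = intercept + slope * x with inference."""

    intercept: float
    slope: float
    p_values: tuple[float, float]
    conf_int: tuple[tuple[float, float], tuple[float, float]]  # ((lo,hi) intercept, (lo,hi) slope)
    r: float

    def predict(self, x: np.ndarray) -> np.ndarray:
        return self.intercept + self.slope * np.asarray(x, dtype=float)


@dataclass
class BlandAltman:
    """Bland–Altman agreement between two paired volume series."""

    points: np.ndarray  # (n, 2): average, difference (auto - manual)
    mean_bias: float
    sd_diff: float
    loa_low: float
    loa_high: float
    regression_line: RegressionFit | None = None  # differences on averages
    residual_line: RegressionFit | None = None  # |residuals| on averages
    regression_loa: tuple[Callable[[np.ndarray], np.ndarray], Callable[[np.ndarray], np.ndarray]] | None = None


def agreement(auto: BinaryMask, manual: BinaryMask) -> AgreementStats:
    """DSC, delineation sensitivity (TPVF) and specificity (TNVF) of A vs M."""
    if auto.shape != manual.shape:
        raise ValueError(f"mask shapes differ: {auto.shape} vs {manual.shape}")
    a = auto.data.astype(bool)
    m = manual.data.astype(bool)
    n_m = int(m.sum())
    n_a = int(a.sum())
    if n_m == 0:
        raise ValueError("reference mask is empty: DSC and sensitivity undefined")
    omega = m.size
    n_bg = omega - n_m
    if n_bg == 0:
        raise ValueError("reference mask covers the whole domain: specificity undefined")
    inter = int((a & m).sum())
    fp = n_a - inter
    fpvf = fp / n_bg
    return AgreementStats(
        dsc=2.0 * inter / (n_a + n_m),
        sens=inter / n_m,
        spec=1.0 - fpvf,
        fpvf=fpvf,
    )


def bland_altman(v_auto, v_manual) -> BlandAltman:
    """Classic Bland–Altman: points, mean bias, SD and 1.96-SD limits.

    The difference convention is automatic minus manual; SD uses the n-1
    denominator.
    """
    v1 = np.asarray(v_auto, dtype=float)
    v2 = np.asarray(v_manual, dtype=float)
    if v1.shape != v2.shape or v1.ndim != 1:
        raise ValueError("inputs must be equal-length 1D sequences")
    if v1.size < 2:
        raise ValueError("need at least 2 pairs")
    avg = (v1 + v2) / 2.0
    diff = v1 - v2
    bias = float(diff.mean())
    sd = float(diff.std(ddof=1))
    return BlandAltman(
        points=np.column_stack([avg, diff]),
        mean_bias=bias,
        sd_diff=sd,
        loa_low=bias - 1.96 * sd,
        loa_high=bias + 1.96 * sd,
    )


def linear_regression(x, y) -> RegressionFit:
    """Simple OLS with two-sided t-tests and 95% CIs (via statsmodels)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 3:
        raise ValueError("need at least 3 points")
    if np.ptp(x) == 0:
        raise np.linalg.LinAlgError("constant x: regression design is rank-deficient")
    model = sm.OLS(y, sm.add_constant(x)).fit()
    ci = model.conf_int(alpha=0.05)
    r = float(np.corrcoef(x, y)[0, 1]) if np.ptp(y) > 0 else 0.0
    return RegressionFit(
        intercept=float(model.params[0]),
        slope=float(model.params[1]),
        p_values=(float(model.pvalues[0]), float(model.pvalues[1])),
        conf_int=((float(ci[0, 0]), float(ci[0, 1])), (float(ci[1, 0]), float(ci[1, 1]))),
        r=r,
    )


def regression_loa(ba: BlandAltman) -> BlandAltman:
    """Attach regression-based limits of agreement to a Bland–Altman result.

    Fits the difference line D(a) by OLS, the absolute-residual line R(a),
    and sets ``limits(a) = D(a) ± 1.96 * sqrt(pi/2) * R(a)``.  The decision
    whether the slope is significant enough to prefer these over the classic
    limits is left to the caller.
    """
    avg = ba.points[:, 0]
    diff = ba.points[:, 1]
    if avg.size < 3:
        raise ValueError("need at least 3 pairs for regression-based limits")
    d_line = linear_regression(avg, diff)
    resid = np.abs(diff - d_line.predict(avg))
    r_line = linear_regression(avg, resid)
    lower = lambda a, d=d_line, r=r_line: d.predict(a) - 1.96 * SD_FROM_MAR * r.predict(a)
    upper = lambda a, d=d_line, r=r_line: d.predict(a) + 1.96 * SD_FROM_MAR * r.predict(a)
    ba.regression_line = d_line
    ba.residual_line = r_line
    ba.regression_loa = (lower, upper)
    return ba
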