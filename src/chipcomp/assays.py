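"""Bench assay math: qChIP percent-input and β-galactosidase Miller units.

The qPCR standard curve is a least-squares line Ct = slope·log10(q) +
intercept fitted to serially diluted chromatin input; an IP sample's Ct is
interpolated back to a quantity and expressed as percent of the total
chromatin, accounting for the input aliquot being a fraction (10% by
default) of the whole.

Miller units: U = (A420 × 1000) / (A660 × t × v), with t the incubation time
in minutes and v the culture volume in mL.
"""
from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy import stats

DEFAULT_INPUT_FRACTION = 0.10


@dataclass(frozen=True)
class QPCRStandardCurve:
    """Least-squares standard curve over (log10 quantity, Ct) points."""

    points: tuple[tuple[float, float], ...]  # (log10_quantity, ct)
    slope: float
    intercept: float
    r_squared: float
    input_fraction: float = DEFAULT_INPUT_FRACTION

    @property
    def efficiency(self) -> float:
        """Amplification efficiency implied by the slope: 10^(−1/slope) − 1
        (1.0 = perfect doubling per cycle).  Diagnostic only; quantities are
        interpolated from the curve directly."""
        return 10.0 ** (-1.0 / self.slope) - 1.0


def fit_standard_curve(
    points: Iterable[tuple[float, float]],
    input_fraction: float = DEFAULT_INPUT_FRACTION,
) -> QPCRStandardCurve:
    """Fit Ct = slope·log10(quantity) + intercept to (dilution_factor, Ct)
    pairs; quantity is the dilution factor in relative units."""
    pts = [(float(q), float(ct)) for q, ct in points]
    if len(pts) < 3:
        raise ValueError("standard curve needs >= 3 points")
    if not (0.0 < input_fraction <= 1.0):
        raise ValueError(f"input_fraction must be in (0, 1], got {input_fraction}")
    qs = np.array([q for q, _ in pts])
    if np.any(qs <= 0):
        raise ValueError("dilution factors must be > 0")
    if len(np.unique(qs)) < 3:
        raise ValueError("standard curve needs >= 3 distinct dilutions")
    x = np.log10(qs)
    y = np.array([ct for _, ct in pts])
    if np.ptp(x) == 0:
        raise ValueError("zero variance in log10 quantity")
    fit = stats.linregress(x, y)
    return QPCRStandardCurve(
        points=tuple(zip(x.tolist(), y.tolist())),
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r_squared=float(fit.rvalue) ** 2,
        input_fraction=input_fraction,
    )


def percent_input(ct_ip: float, curve: QPCRStandardCurve) -> float:
    """Percent of total chromatin recovered in the IP.

    The curve's quantity unit is the undiluted input aliquot; since that
    aliquot is ``input_fraction`` of the chromatin, the total-chromatin
    quantity is ``1 / input_fraction`` and
    ``% input = 100 · q_ip · input_fraction``.
    """
    if curve.slope >= 0:
        raise ValueError(
            f"invalid standard curve: slope must be < 0, got {curve.slope}"
        )
    q_ip = 10.0 ** ((ct_ip - curve.intercept) / curve.slope)
    return 100.0 * q_ip * curve.input_fraction


def ct_from_quantity(
    quantity,
    efficiency: float = 1.0,
    intercept: float = 20.0,
    sigma: float = 0.0,
    rng: np.random.Generator | None = None,
):
    """Forward qPCR model: Ct = intercept − log10(q)/log10(1+efficiency),
    with optional Gaussian Ct noise.  The inverse of the standard-curve
    interpolation, used for simulation-based checks."""
    if not (0.0 < efficiency <= 1.0):
        raise ValueError(f"efficiency must be in (0, 1], got {efficiency}")
    q = np.asarray(quantity, dtype=np.float64)
    if np.any(q <= 0):
        raise ValueError("quantities must be > 0")
    slope = -1.0 / math.log10(1.0 + efficiency)
    ct = intercept + slope * np.log10(q)
    if sigma > 0:
        if rng is None:
            raise ValueError("noise requested but no rng given")
        ct = ct + rng.normal(0.0, sigma, size=ct.shape)
    return ct if ct.ndim else float(ct)


def miller_units(a420: float, a660: float, t: float, v: float) -> float:
    """β-galactosidase activity: U = (A420 × 1000) / (A660 × t × v)."""
    for label, val in (("A420", a420), ("A660", a660), ("t", t), ("v", v)):
        if not (val > 0):
            raise ValueError(f"{label} must be > 0, got {val}")
    return (a420 * 1000.0) / (a660 * t * v)


def aggregate_replicates(values: Sequence[float]) -> tuple[float, float]:
    """Mean and standard error (sample SD / sqrt(n)) of replicate values."""
    arr = np.asarray(list(values), dtype=np.float64)
    if len(arr) < 2:
        raise ValueError("need >= 2 replicates to estimate a standard error")
    mean = float(np.mean(arr))
    se = float(np.std(arr, ddof=1) / math.sqrt(len(arr)))
    return mean, se
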