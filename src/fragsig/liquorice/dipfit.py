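"""Constrained three-Gaussian dip model and control-based signal detection.

The aggregated, bias-corrected coverage profile y(x) (x = bp offset from
the region midpoint) is modelled as an intercept plus three Gaussians of
different widths, all centered at x = 0:

    y(x) = c + sum_i A_i * exp(-x^2 / (2 sigma_i^2))

The sigma boxes reflect the three scales of regulatory architecture:
20-200 bp (transcription-factor footprints), 200-3000 bp
(enhancers/promoters), 3000-40000 bp (super-enhancer-scale domains).
Optimization is damped least squares (Levenberg-Marquardt via lmfit, which
enforces the boxes by parameter transformation).

Sign convention: a depletion yields negative amplitudes; the reported
dip_depth = -(A1+A2+A3) and aoc (area between the intercept and the fitted
curve) are positive for depletion, so "more tumor signal" is larger.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from lmfit import Parameters, minimize

DEFAULT_SIGMA_BOUNDS: tuple[tuple[float, float], ...] = (
    (20.0, 200.0),
    (200.0, 3_000.0),
    (3_000.0, 40_000.0),
)


def dip_model(
    x: np.ndarray, intercept: float, amplitudes: np.ndarray, sigmas: np.ndarray
) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    y = np.full(len(x), float(intercept))
    for a, s in zip(amplitudes, sigmas):
        y = y + a * np.exp(-(x ** 2) / (2.0 * s * s))
    return y


@dataclass
class DipModelFit:
    """Fitted intercept + three centered Gaussians, with dip metrics."""

    x: np.ndarray = field(repr=False)
    y: np.ndarray = field(repr=False)
    intercept: float
    amplitudes: np.ndarray   # A1 (narrow) .. A3 (wide); negative = depletion
    sigmas: np.ndarray
    sigma_bounds: tuple[tuple[float, float], ...]
    success: bool
    message: str = ""

    @property
    def fitted(self) -> np.ndarray:
        return dip_model(self.x, self.intercept, self.amplitudes, self.sigmas)

    @property
    def dip_depth(self) -> float:
        """-(A1 + A2 + A3); positive for depletion."""
        return float(-np.sum(self.amplitudes))

    @property
    def aoc(self) -> float:
        """Area between intercept and fitted curve (trapezoid over the
        binned domain); positive for depletion."""
        return float(np.trapezoid(self.intercept - self.fitted, self.x))

    @property
    def aoc_analytic(self) -> float:
        """-sum A_i sigma_i sqrt(2 pi): the closed-form area over an
        infinite domain."""
        return float(-np.sum(self.amplitudes * self.sigmas) * np.sqrt(2 * np.pi))

    @property
    def aoc_excluding_center(self) -> float:
        """AOC excluding x in [-sigma_G1, sigma_G1]."""
        s1 = self.sigmas[0]
        mask = np.abs(self.x) > s1
        if mask.sum() < 2:
            return 0.0
        resid = self.intercept - self.fitted
        left = self.x < -s1
        right = self.x > s1
        total = 0.0
        for side in (left, right):
            if side.sum() >= 2:
                total += float(np.trapezoid(resid[side], self.x[side]))
        return total

    @property
    def y_sum(self) -> float:
        """Sum of fitted y over all bins."""
        return float(np.sum(self.fitted))

    def metrics(self) -> dict[str, float]:
        return {
            "aoc": self.aoc,
            "aoc_analytic": self.aoc_analytic,
            "aoc_excluding_center": self.aoc_excluding_center,
            "y_sum": self.y_sum,
            "amplitude_g1": float(self.amplitudes[0]),
            "amplitude_g2": float(self.amplitudes[1]),
            "amplitude_g3": float(self.amplitudes[2]),
            "sigma_g1": float(self.sigmas[0]),
            "sigma_g2": float(self.sigmas[1]),
            "sigma_g3": float(self.sigmas[2]),
            "intercept": float(self.intercept),
            "dip_depth": self.dip_depth,
        }


def _residual(params: Parameters, x: np.ndarray, y: np.ndarray) -> np.ndarray:
    amplitudes = np.array([params[f"a{i}"].value for i in (1, 2, 3)])
    sigmas = np.array([params[f"s{i}"].value for i in (1, 2, 3)])
    return dip_model(x, params["c"].value, amplitudes, sigmas) - y


def fit_dip_model(
    x: np.ndarray,
    y: np.ndarray,
    sigma_bounds: tuple[tuple[float, float], ...] = DEFAULT_SIGMA_BOUNDS,
    fixed_sigmas: np.ndarray | None = None,
) -> DipModelFit:
    """Damped least-squares fit of the centered dip model.

    ``fixed_sigmas`` (from a cohort refit) pins the widths; otherwise each
    sigma is box-constrained to its component's bounds. Non-convergence is
    flagged on the returned fit, never silently replaced.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    if len(x) < 20:
        raise ValueError("profile must have >= 20 finite points")

    params = Parameters()
    params.add("c", value=float(np.median(y)))
    center = y[np.argmin(np.abs(x))]
    a0 = float(min(center - np.median(y), 0.0)) / 3.0 - 1e-4
    for i, (lo, hi) in enumerate(sigma_bounds, start=1):
        params.add(f"a{i}", value=a0)
        if fixed_sigmas is not None:
            params.add(f"s{i}", value=float(fixed_sigmas[i - 1]), vary=False)
        else:
            params.add(f"s{i}", value=float(np.sqrt(lo * hi)), min=lo, max=hi)

    result = minimize(_residual, params, args=(x, y), method="leastsq")
    p = result.params
    return DipModelFit(
        x=x,
        y=y,
        intercept=float(p["c"].value),
        amplitudes=np.array([p["a1"].value, p["a2"].value, p["a3"].value]),
        sigmas=np.array([p["s1"].value, p["s2"].value, p["s3"].value]),
        sigma_bounds=sigma_bounds,
        success=bool(result.success),
        message=str(result.message),
    )


def cohort_refit(fits: list[DipModelFit]) -> tuple[list[DipModelFit], np.ndarray]:
    """Refit every sample with the across-sample median sigmas fixed.

    Returns (refitted fits, the fixed sigma triple). Only amplitudes and
    the intercept vary in the second pass.
    """
    if len(fits) < 1:
        raise ValueError("need at least one fit")
    sigmas = np.median(np.array([f.sigmas for f in fits]), axis=0)
    refits = [
        fit_dip_model(f.x, f.y, sigma_bounds=f.sigma_bounds, fixed_sigmas=sigmas)
        for f in fits
    ]
    return refits, sigmas


def detect_signal(
    sample_metric: float,
    control_metrics: np.ndarray,
    threshold: float = 3.0,
    leave_one_out_index: int | None = None,
) -> tuple[float, bool]:
    """z-score of a sample metric against healthy controls.

    z = (x - mean(controls)) / sd(controls) with the sample standard
    deviation (ddof=1); the flag uses strict inequality |z| > threshold.
    When the sample is itself one of the controls, pass its index as
    ``leave_one_out_index`` to score it against the remaining controls.
    """
    controls = np.asarray(control_metrics, dtype=float)
    if leave_one_out_index is not None:
        controls = np.delete(controls, leave_one_out_index)
    if len(controls) < 3:
        raise ValueError("need >= 3 controls")
    sd = float(np.std(controls, ddof=1))
    if sd == 0:
        raise ValueError("control metrics have zero spread")
    z = (float(sample_metric) - float(np.mean(controls))) / sd
    return z, bool(abs(z) > threshold)
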