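"""Dose-response models for competition binding and cell-viability assays.

Two curve families are implemented:

* the single-site Hill binding model used to extract a dissociation constant
  Kd from competition-binding %control readouts,

      response(d) = background + (signal - background) / (1 + d / Kd)

  (Hill slope fixed at 1; response falls from ``signal`` at zero dose to
  ``background`` at saturating dose, with midpoint at d = Kd), and

* the four-parameter logistic viability model

      y(x) = A + (B - A) / (1 + (C / x)^D)

  with lower/upper limits A and B, midpoint concentration C (the EC50) and
  Hill slope D.  For a viability readout that falls with dose, D is
  negative in this parameterization.

From a fitted viability curve three potency summaries are derived: EC50
(the midpoint C), IC50 (concentration where y reaches half the upper limit
B), and GI50 (concentration where y reaches the level midway between the
upper limit and the time-zero cell count, i.e. half-maximal growth
inhibition).  The activity area summarizes a whole dilution series as the
sum of clipped inhibition fractions over the tested concentrations: 0 means
no inhibition anywhere, n (=10 for a standard 10-point series) means
complete inhibition everywhere.

Note on conventions: the IC50 definition used here — "half the maximum
possible response", read as y = B/2 — and the activity-area clipped sum are
stated interpretations of assay-vendor summaries; both are documented in
the methods note.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import optimize

__all__ = [
    "DoseResponseCurve",
    "HillFit",
    "SigmoidFit",
    "percent_control",
    "hill_response",
    "fit_hill",
    "sigmoid_response",
    "fit_sigmoid",
    "derive_response_parameters",
    "ResponseParameters",
    "activity_area",
]


@dataclass(frozen=True)
class DoseResponseCurve:
    """Paired (dose, response) measurements, doses in µM strictly increasing.

    ``time_zero_count`` is the relative cell count at compound addition,
    needed for GI50.
    """

    doses: tuple[float, ...]
    responses: tuple[float, ...]
    time_zero_count: Optional[float] = None

    def __post_init__(self) -> None:
        doses = tuple(float(d) for d in self.doses)
        responses = tuple(float(y) for y in self.responses)
        object.__setattr__(self, "doses", doses)
        object.__setattr__(self, "responses", responses)
        if len(doses) != len(responses):
            raise ValueError("doses and responses must have equal length")
        if any(d <= 0 for d in doses):
            raise ValueError("doses must be positive")
        if any(doses[i] >= doses[i + 1] for i in range(len(doses) - 1)):
            raise ValueError("doses must be strictly increasing")


@dataclass(frozen=True)
class HillFit:
    background: float
    signal: float
    kd: float
    rss: float

    def __post_init__(self) -> None:
        if self.kd <= 0:
            raise ValueError(f"Kd must be positive, got {self.kd}")


@dataclass(frozen=True)
class SigmoidFit:
    A: float  # lower limit
    B: float  # upper limit
    C: float  # midpoint concentration (EC50)
    D: float  # Hill slope
    rss: float

    def __post_init__(self) -> None:
        if self.C <= 0:
            raise ValueError(f"midpoint concentration must be positive, got {self.C}")


def percent_control(
    test_signal: float, positive_control_signal: float, negative_control_signal: float
) -> float:
    """Competition-binding readout normalized between controls.

    0 = signal equals the positive control (complete displacement, strong
    binding); 100 = equals the negative (DMSO) control (no binding).
    """
    if negative_control_signal == positive_control_signal:
        raise ZeroDivisionError("negative and positive control signals coincide")
    return (
        (test_signal - positive_control_signal)
        / (negative_control_signal - positive_control_signal)
        * 100.0
    )


def hill_response(dose, background: float, signal: float, kd: float):
    """Single-site competition binding curve, Hill slope 1."""
    if kd <= 0:
        raise ValueError(f"Kd must be positive, got {kd}")
    dose = np.asarray(dose, dtype=float)
    if np.any(dose < 0):
        raise ValueError("dose must be nonnegative")
    out = background + (signal - background) / (1.0 + dose / kd)
    return float(out) if out.ndim == 0 else out


def fit_hill(
    curve: DoseResponseCurve,
    init: Optional[tuple[float, float, float]] = None,
    bounds: Optional[tuple] = None,
) -> HillFit:
    """Levenberg-Marquardt least-squares fit of the Hill binding model.

    Requires >= 4 points.  Default initialization: background = min
    response, signal = max response, Kd = geometric mean of the doses.
    Deterministic for a fixed ``init``.
    """
    x = np.asarray(curve.doses)
    y = np.asarray(curve.responses)
    if len(x) < 4:
        raise ValueError(f"need >= 4 points to fit, got {len(x)}")
    if init is None:
        init = (float(y.min()), float(y.max()), float(np.exp(np.mean(np.log(x)))))
    try:
        if bounds is None:
            popt, _ = optimize.curve_fit(hill_response, x, y, p0=init, method="lm", maxfev=20000)
        else:
            popt, _ = optimize.curve_fit(hill_response, x, y, p0=init, bounds=bounds, maxfev=20000)
    except RuntimeError as exc:
        raise RuntimeError(f"Hill fit did not converge: {exc}") from exc
    background, signal, kd = (float(v) for v in popt)
    if kd <= 0 or not np.isfinite(kd):
        raise RuntimeError(f"Hill fit produced non-physical Kd = {kd}")
    rss = float(np.sum((hill_response(x, *popt) - y) ** 2))
    return HillFit(background=background, signal=signal, kd=kd, rss=rss)


def sigmoid_response(x, A: float, B: float, C: float, D: float):
    """Four-parameter logistic: y = A + (B - A) / (1 + (C/x)^D)."""
    if C <= 0:
        raise ValueError(f"midpoint concentration must be positive, got {C}")
    x = np.asarray(x, dtype=float)
    if np.any(x <= 0):
        raise ValueError("concentration must be positive")
    out = A + (B - A) / (1.0 + (C / x) ** D)
    return float(out) if out.ndim == 0 else out


def _sigmoid_logc(x, A, B, logC, D):
    # internal parameterization keeping C > 0 during optimization
    return A + (B - A) / (1.0 + np.exp(D * (logC - np.log(x))))


def fit_sigmoid(curve: DoseResponseCurve) -> SigmoidFit:
    """Nonlinear least-squares fit of the four-parameter logistic.

    Requires >= 5 points and a non-degenerate response range.  The midpoint
    is optimized on the log scale so C stays positive; the initial Hill
    slope sign follows the observed response direction.
    """
    x = np.asarray(curve.doses)
    y = np.asarray(curve.responses)
    if len(x) < 5:
        raise ValueError(f"need >= 5 points to fit, got {len(x)}")
    if np.ptp(y) < 1e-12 * max(1.0, abs(y[0])):
        raise ValueError("constant responses: sigmoid fit is degenerate")
    d0 = 1.0 if y[-1] >= y[0] else -1.0  # rising vs falling with dose
    init = (float(y.min()), float(y.max()), float(np.mean(np.log(x))), d0)
    try:
        popt, _ = optimize.curve_fit(_sigmoid_logc, x, y, p0=init, method="lm", maxfev=20000)
    except RuntimeError as exc:
        raise RuntimeError(f"sigmoid fit did not converge: {exc}") from exc
    A, B, logC, D = (float(v) for v in popt)
    C = math.exp(logC)
    rss = float(np.sum((_sigmoid_logc(x, *popt) - y) ** 2))
    return SigmoidFit(A=A, B=B, C=C, D=D, rss=rss)


def _invert_sigmoid(fit: SigmoidFit, level: float) -> Optional[float]:
    """Concentration where the fitted curve crosses ``level``.

    Solving A + (B-A)/(1+(C/x)^D) = L gives (C/x)^D = (B-L)/(L-A), so
    x = C * ((L-A)/(B-L))^(1/D).  Returns None when the level lies outside
    the open range between the asymptotes (not reached on the fitted curve).
    """
    lo, hi = sorted((fit.A, fit.B))
    if not lo < level < hi:
        return None
    ratio = (fit.B - level) / (level - fit.A)
    return fit.C * ratio ** (-1.0 / fit.D)


@dataclass(frozen=True)
class ResponseParameters:
    """Potency summaries from a fitted viability curve; None = not reached."""

    ec50: float
    ic50: Optional[float]
    gi50: Optional[float]
    gi50_degenerate: bool = False


def derive_response_parameters(
    fit: SigmoidFit, curve: Optional[DoseResponseCurve] = None
) -> ResponseParameters:
    """EC50, IC50 and GI50 from a fitted sigmoid.

    * EC50 is the fitted midpoint C.
    * IC50 solves y(x) = 0.5 * B (half the upper limit).
    * GI50 solves y(x) = (B + time_zero_count) / 2; it requires the
      time-zero cell count from the curve and is flagged degenerate when
      that level sits at the curve maximum.
    """
    ec50 = fit.C
    ic50 = _invert_sigmoid(fit, 0.5 * fit.B)
    gi50 = None
    degenerate = False
    t0 = curve.time_zero_count if curve is not None else None
    if t0 is not None:
        level = 0.5 * (fit.B + t0)
        if abs(level - fit.B) <= 1e-6 * max(abs(fit.B - fit.A), 1e-12):
            degenerate = True
        else:
            gi50 = _invert_sigmoid(fit, level)
    return ResponseParameters(ec50=ec50, ic50=ic50, gi50=gi50, gi50_degenerate=degenerate)


def activity_area(responses: Sequence[float], n_max: Optional[int] = None) -> float:
    """Sum of clipped inhibition fractions over the tested concentrations.

    Each concentration contributes clip(1 - y, 0, 1), so the area lies in
    [0, n] for an n-point series; 0 = no inhibition at any concentration,
    n = complete inhibition at every concentration.  ``n_max`` (default the
    series length) only validates the expected series size.
    """
    y = np.asarray(responses, dtype=float)
    if n_max is not None and len(y) != n_max:
        raise ValueError(f"expected {n_max} concentrations, got {len(y)}")
    return float(np.clip(1.0 - y, 0.0, 1.0).sum())
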