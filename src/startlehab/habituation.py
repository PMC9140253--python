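"""Startle-reflex habituation (SRH) quantification.

Two layers of summary are computed from the per-stimulus distance traces:

* **TDT20** — total distance travelled over the 20 stimulus windows of one
  test, per fish; the group value is the arithmetic mean over fish.
* **The exponential SRH model** — the group-level habituation curve (mean
  distance per stimulus) is fitted with a first-order exponential

      d(n) = C + (A - C) * exp(-(n - 1) / tau),   n = 1..20

  whose three parameters quantify startle behaviour: the *amplitude* A is
  the fitted response to the first stimulus (startle vigorousness), the
  *offset* C is the steady-state per-stimulus response after habituation,
  and the *decay constant* tau is the number of stimuli for the baseline-
  subtracted response to fall to 1/e (~36.8%) of its initial value.  A very
  large tau means the response barely decays: absent habituation.  tau is
  capped (default 100 stimuli, five times the stimulus count) because
  beyond that the curve is observationally flat; a fit at the cap is
  flagged as non-identified rather than failed.

The exponential argument uses (n - 1) so the model value at the first
stimulus equals A exactly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares

from .config import N_STIMULI, load_defaults

__all__ = ["HabituationCurve", "SRHFit", "tdt20", "group_mean_tdt20",
           "mean_curve", "srh_model", "fit_exponential"]


@dataclass(frozen=True)
class HabituationCurve:
    """Group-level habituation curve: per-stimulus mean (and SE) over fish."""

    mean_distance: np.ndarray   # mm, length 20
    n_fish: int
    se_distance: np.ndarray | None = None

    def __post_init__(self) -> None:
        m = np.asarray(self.mean_distance, dtype=float)
        if m.shape != (N_STIMULI,):
            raise ValueError(f"expected {N_STIMULI} values, got {m.shape}")
        if not np.all(np.isfinite(m)) or np.any(m < 0):
            raise ValueError("curve values must be finite and nonnegative")
        object.__setattr__(self, "mean_distance", m)


@dataclass(frozen=True)
class SRHFit:
    """Fitted parameters of the exponential habituation model."""

    amplitude: float       # A, mm: fitted response at stimulus 1
    decay_constant: float  # tau, stimuli
    offset: float          # C, mm: steady-state response
    residual_sse: float    # mm^2
    converged: bool
    identified: bool = True  # False when the curve is flat / tau at its cap

    def predict(self, n_stimuli: int = N_STIMULI) -> np.ndarray:
        return srh_model(np.arange(1, n_stimuli + 1), self.amplitude,
                         self.offset, self.decay_constant)


_FITTING_DEFAULTS: dict | None = None


def _fitting_defaults() -> dict:
    global _FITTING_DEFAULTS
    if _FITTING_DEFAULTS is None:
        _FITTING_DEFAULTS = load_defaults()["fitting"]
    return _FITTING_DEFAULTS


def srh_model(n, A: float, C: float, tau: float) -> np.ndarray:
    """Model response at stimulus number(s) ``n`` (1-based)."""
    n = np.asarray(n, dtype=float)
    return C + (A - C) * np.exp(-(n - 1.0) / tau)


def tdt20(trace) -> float:
    """Total distance travelled over the 20 stimulus windows of one trace."""
    d = np.asarray(trace.distances if hasattr(trace, "distances") else trace,
                   dtype=float)
    if d.shape != (N_STIMULI,):
        raise ValueError(f"expected {N_STIMULI} per-stimulus distances, "
                         f"got shape {d.shape}")
    if np.any(~np.isfinite(d)):
        raise ValueError("missing or non-finite stimulus distances")
    return float(d.sum())


def group_mean_tdt20(traces) -> float:
    """Group TDT20: arithmetic mean of per-fish TDT20 values."""
    values = [tdt20(t) for t in traces]
    if not values:
        raise ValueError("no traces supplied")
    return float(np.mean(values))


def mean_curve(traces) -> HabituationCurve:
    """Per-stimulus mean (+/- SE) habituation curve over a set of fish."""
    stack = np.array([np.asarray(t.distances, dtype=float) for t in traces])
    if stack.size == 0:
        raise ValueError("no traces supplied")
    se = (stack.std(axis=0, ddof=1) / np.sqrt(len(stack))
          if len(stack) > 1 else np.zeros(N_STIMULI))
    return HabituationCurve(mean_distance=stack.mean(axis=0),
                            n_fish=len(stack), se_distance=se)


def _initial_guess(d: np.ndarray, tau_cap: float) -> tuple[float, float, float]:
    # deterministic derivative-free start: A from the first response, C from
    # the tail, tau from a log-linear regression of the excess over C
    A0 = d[0]
    C0 = float(d[-5:].mean())
    eps = max(1e-3, 1e-3 * max(d.max(), 1.0))
    excess = np.maximum(d - C0, eps)
    n = np.arange(len(d), dtype=float)
    slope = np.polyfit(n, np.log(excess), 1)[0]
    tau0 = -1.0 / slope if slope < -1e-12 else tau_cap / 2
    return A0, C0, float(np.clip(tau0, 0.1, tau_cap))


def fit_exponential(curve, tau_cap: float | None = None,
                    ftol: float | None = None) -> SRHFit:
    """Least-squares fit of the exponential SRH model to a 20-point curve.

    Plain (unweighted) sum of squares, bounded parameters: A, C in
    [0, 10 * max(curve)], tau in (0, tau_cap].  A flat curve (A ~ C) makes
    tau unidentifiable; such fits return A = C = mean with tau at the cap
    and ``identified=False`` instead of raising.
    """
    if tau_cap is None or ftol is None:
        defaults = _fitting_defaults()
        tau_cap = defaults["tau_cap"] if tau_cap is None else float(tau_cap)
        ftol = defaults["ftol"] if ftol is None else float(ftol)
    tau_cap, ftol = float(tau_cap), float(ftol)

    d = np.asarray(curve.mean_distance if hasattr(curve, "mean_distance")
                   else curve, dtype=float)
    if d.shape != (N_STIMULI,) or not np.all(np.isfinite(d)):
        raise ValueError(f"curve must hold {N_STIMULI} finite values")

    n = np.arange(1, N_STIMULI + 1, dtype=float)
    spread = float(d.max() - d.min())
    if spread < 1e-12 * max(1.0, d.max()):
        m = float(d.mean())
        sse = float(((d - m) ** 2).sum())
        return SRHFit(amplitude=m, decay_constant=tau_cap, offset=m,
                      residual_sse=sse, converged=True, identified=False)

    hi = 10.0 * max(d.max(), 1e-12)
    A0, C0, tau0 = _initial_guess(d, tau_cap)
    x0 = np.array([np.clip(A0, 0, hi), np.clip(C0, 0, hi), tau0])

    def residuals(x):
        return srh_model(n, x[0], x[1], x[2]) - d

    def jacobian(x):
        A, C, tau = x
        e = np.exp(-(n - 1.0) / tau)
        return np.column_stack([e, 1.0 - e, (A - C) * e * (n - 1.0) / tau ** 2])

    sol = least_squares(residuals, x0, jac=jacobian,
                        bounds=([0, 0, 1e-6], [hi, hi, tau_cap]),
                        ftol=ftol, xtol=1e-12, gtol=1e-12)
    A, C, tau = (float(v) for v in sol.x)
    identified = tau < tau_cap * (1 - 1e-9) and abs(A - C) > 1e-9 * max(1.0, d.max())
    return SRHFit(amplitude=A, decay_constant=tau, offset=C,
                  residual_sse=float(2 * sol.cost), converged=bool(sol.success),
                  identified=identified)
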