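"""Biphasic melting-curve model, fitting and mono/biphasic classification.

Thermal denaturation of a DNA:DNA:RNA triplex is biphasic: the Hoogsteen
hydrogen bonds holding the third strand release first, the Watson-Crick
duplex melts at a higher temperature. On normalized ellipticity data both
transitions are sigmoidal, so the melting signal f at temperature x is
modelled as a sum of two logistic transitions

    f(x) = a / (1 + exp(-(x - x0)/b)) + c / (1 + exp(-(x - x2)/d))

with amplitudes a, c, midpoints x0, x2 (the reported melting temperatures)
and slope widths b, d (°C). A monophasic melt is the special case c = 0.
Model choice between the two is made by a corrected information criterion
with a parsimony margin, plus a minimum midpoint separation, so that one
broad transition is not over-fitted as two.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares

#: Minimum points / temperature span a curve must have to be fitted.
MIN_FIT_POINTS = 12
MIN_FIT_SPAN = 30.0

#: Model-selection defaults: AICc margin and midpoint separation (°C)
#: required before the biphasic model is preferred.
DEFAULT_AICC_MARGIN = 10.0
DEFAULT_MIN_SEPARATION = 5.0

_SSE_FLOOR = 1e-20  # keeps the information criterion finite on exact fits


class FitFailure(RuntimeError):
    """Raised when no optimisation start converges; carries diagnostics."""


@dataclass(frozen=True)
class MeltingCurve:
    """A (temperature, normalized ellipticity) series."""

    temperatures: np.ndarray
    values: np.ndarray
    curve_id: str = ""

    def __post_init__(self):
        t = np.asarray(self.temperatures, dtype=float)
        v = np.asarray(self.values, dtype=float)
        if t.shape != v.shape or t.ndim != 1:
            raise ValueError("temperatures and values must be equal-length 1-D arrays")
        if len(t) >= 2 and not np.all(np.diff(t) > 0):
            raise ValueError("temperatures must be strictly increasing")
        object.__setattr__(self, "temperatures", t)
        object.__setattr__(self, "values", v)

    def __len__(self) -> int:
        return len(self.temperatures)

    @property
    def span(self) -> float:
        return float(self.temperatures[-1] - self.temperatures[0])


def eval_model(params, temperature):
    """Evaluate the double-sigmoid melting model.

    ``params`` is (a, x0, b, c, x2, d); slopes b and d must be positive.
    Accepts scalar or array temperatures.
    """
    a, x0, b, c, x2, d = (float(p) for p in params)
    if b <= 0 or d <= 0:
        raise ValueError("slope parameters b and d must be positive")
    x = np.asarray(temperature, dtype=float)
    with np.errstate(over="ignore"):  # far tails saturate cleanly to 0 / a+c
        out = a / (1.0 + np.exp(-(x - x0) / b)) + c / (1.0 + np.exp(-(x - x2) / d))
    return out if out.ndim else float(out)


def normalize_ellipticity(raw_values, temperatures=None) -> np.ndarray:
    """Min-max scale a melting signal to [0, 1], oriented to rise with T.

    Orientation is chosen so the normalized signal is on average
    non-decreasing with temperature (unfolding convention); the result is
    invariant to affine transformations of the raw signal. Constant input
    is rejected.
    """
    v = np.asarray(raw_values, dtype=float)
    if v.ndim != 1 or len(v) < 2:
        raise ValueError("need a 1-D signal with at least two points")
    lo, hi = v.min(), v.max()
    if hi == lo:
        raise ValueError("constant signal cannot be normalized")
    x = np.arange(len(v)) if temperatures is None else np.asarray(temperatures, float)
    slope = np.polyfit(x, v, 1)[0]
    if slope < 0:
        v = -v
        lo, hi = -hi, -lo
    return (v - lo) / (hi - lo)


@dataclass(frozen=True)
class BiphasicFit:
    """Least-squares fit of the melting model to one curve.

    ``tm1``/``tm2`` are the midpoint parameters in canonical order
    (tm1 < tm2); for a monophasic fit tm2 is None and c is fixed at 0.
    ``stderr`` holds asymptotic standard errors from the fit curvature,
    in parameter order (a, x0, b, c, x2, d), NaN where not estimable.
    """

    curve_id: str
    model: str  # 'monophasic' or 'biphasic'
    a: float
    x0: float
    b: float
    c: float
    x2: float
    d: float
    residual_sse: float
    n_points: int
    stderr: tuple = field(default=(float("nan"),) * 6)
    degenerate: bool = False
    selection_stat: float | None = None

    @property
    def tm1(self) -> float:
        return self.x0

    @property
    def tm2(self) -> float | None:
        return None if self.model == "monophasic" else self.x2

    @property
    def aicc(self) -> float:
        n = self.n_points
        k = 3 if self.model == "monophasic" else 6
        sse = max(self.residual_sse, _SSE_FLOOR)
        penalty = 2 * k * (k + 1) / (n - k - 1) if n > k + 1 else np.inf
        return n * np.log(sse / n) + 2 * k + penalty


def _check_fittable(curve: MeltingCurve):
    if len(curve) < MIN_FIT_POINTS:
        raise ValueError(f"need at least {MIN_FIT_POINTS} points to fit, got {len(curve)}")
    if curve.span < MIN_FIT_SPAN:
        raise ValueError(
            f"need a temperature span of at least {MIN_FIT_SPAN} degC, got {curve.span:.1f}"
        )


def _grid_starts(t, v, model, grid_step=5.0, slope_start=3.0):
    lo, hi = t[0], t[-1]
    mids = np.arange(lo + grid_step, hi, grid_step)
    rng_v = max(v.max() - v.min(), 1e-6)
    starts = []
    if model == "monophasic":
        for x0 in mids:
            starts.append([rng_v, x0, slope_start])
    else:
        for i, x0 in enumerate(mids):
            for x2 in mids[i + 1:]:
                starts.append([rng_v / 2, x0, slope_start, rng_v / 2, x2, slope_start])
    return starts


def fit_melting(curve: MeltingCurve, model: str = "biphasic",
                grid_step: float = 5.0, slope_start: float = 3.0) -> BiphasicFit:
    """Least-squares fit of the melting model to a normalized curve.

    Initialization is a coarse grid over midpoints (every ``grid_step`` °C,
    x0 < x2 for the biphasic model) with amplitudes split evenly from the
    observed range and slopes started at ``slope_start`` °C; the best
    converged start by residual sum of squares wins. Midpoints are
    reported in canonical order tm1 < tm2.
    """
    if model not in ("monophasic", "biphasic"):
        raise ValueError(f"model must be 'monophasic' or 'biphasic', got {model!r}")
    _check_fittable(curve)
    t, v = curve.temperatures, curve.values
    v_range = float(v.max() - v.min())

    if model == "monophasic":
        def resid(p):
            return eval_model((p[0], p[1], p[2], 0.0, t[-1], 1.0), t) - v
        lower = [0.0, t[0] - 20.0, 1e-2]
        upper = [np.inf, t[-1] + 20.0, 100.0]
    else:
        def resid(p):
            return eval_model(p, t) - v
        lower = [0.0, t[0] - 20.0, 1e-2] * 2
        upper = [np.inf, t[-1] + 20.0, 100.0] * 2

    # rank grid starts by their initial residual and optimise the best few
    starts = _grid_starts(t, v, model, grid_step, slope_start)
    if len(starts) > 8:
        initial_sse = [float(np.sum(resid(p0) ** 2)) for p0 in starts]
        starts = [starts[i] for i in np.argsort(initial_sse)[:8]]

    best = None
    failures = []
    for p0 in starts:
        try:
            sol = least_squares(resid, p0, bounds=(lower, upper), method="trf")
        except Exception as exc:  # pragma: no cover - scipy-internal failures
            failures.append(str(exc))
            continue
        if not np.all(np.isfinite(sol.x)):
            continue
        sse = float(np.sum(sol.fun ** 2))
        if best is None or sse < best[0]:
            best = (sse, sol)
    if best is None:
        raise FitFailure(
            f"no optimisation start converged for {curve.curve_id!r}: {failures[:3]}"
        )
    sse, sol = best

    # asymptotic standard errors from the jacobian at the optimum
    n, k = len(t), len(sol.x)
    stderr_p = np.full(k, np.nan)
    if n > k:
        try:
            cov = np.linalg.pinv(sol.jac.T @ sol.jac) * sse / (n - k)
            stderr_p = np.sqrt(np.clip(np.diag(cov), 0, None))
        except np.linalg.LinAlgError:
            pass

    if model == "monophasic":
        a, x0, b = sol.x
        params = (a, x0, b, 0.0, float(t[-1]), 1.0)
        stderr = (stderr_p[0], stderr_p[1], stderr_p[2], np.nan, np.nan, np.nan)
    else:
        a, x0, b, c, x2, d = sol.x
        se = list(stderr_p)
        if x0 > x2:  # canonical ordering: first transition first
            a, x0, b, c, x2, d = c, x2, d, a, x0, b
            se = se[3:] + se[:3]
        params = (a, x0, b, c, x2, d)
        stderr = tuple(se)

    degenerate = v_range <= 0 or (params[0] + params[3]) < 1e-2 * max(v_range, 1e-12)
    return BiphasicFit(
        curve_id=curve.curve_id, model=model,
        a=params[0], x0=params[1], b=params[2],
        c=params[3], x2=params[4], d=params[5],
        residual_sse=sse, n_points=n, stderr=tuple(float(s) for s in stderr),
        degenerate=degenerate,
    )


@dataclass(frozen=True)
class TransitionCall:
    """Both model fits plus the mono/biphasic decision and its trace."""

    curve_id: str
    model: str
    monophasic: BiphasicFit
    biphasic: BiphasicFit
    delta_aicc: float
    separation: float
    aicc_margin: float
    min_separation: float

    @property
    def best(self) -> BiphasicFit:
        return self.biphasic if self.model == "biphasic" else self.monophasic


def classify_transition(curve: MeltingCurve,
                        aicc_margin: float = DEFAULT_AICC_MARGIN,
                        min_separation: float = DEFAULT_MIN_SEPARATION) -> TransitionCall:
    """Fit both models and decide whether the melt is mono- or biphasic.

    The biphasic model is selected only when it improves the corrected
    information criterion by more than ``aicc_margin`` AND its midpoints are
    more than ``min_separation`` °C apart; otherwise the single transition
    is kept (parsimony — a broad single melt must not be split in two).
    """
    mono = fit_melting(curve, "monophasic")
    bi = fit_melting(curve, "biphasic")
    delta = mono.aicc - bi.aicc
    separation = abs(bi.x2 - bi.x0)
    is_bi = (delta > aicc_margin) and (separation > min_separation) and not bi.degenerate
    return TransitionCall(
        curve_id=curve.curve_id,
        model="biphasic" if is_bi else "monophasic",
        monophasic=mono, biphasic=bi,
        delta_aicc=float(delta), separation=float(separation),
        aicc_margin=aicc_margin, min_separation=min_separation,
    )
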