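"""Four-parameter logistic (4PL) dose-response fitting and the extra
sum-of-squares F test for comparing two groups' response curves.

The model is the standard increasing sigmoid

    y = bottom + (top - bottom) / (1 + (ec50 / x) ** hill)

so that y(ec50) = (bottom + top) / 2 and ``hill`` controls steepness.
Group comparison follows the nested-model logic: a *shared* model fits one
curve (4 parameters) to the pooled points, a *separate* model fits one
curve per group (8 parameters); the F statistic measures whether the drop
in residual sum of squares justifies the extra parameters.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, NamedTuple, Optional, Sequence, Tuple

import numpy as np
from scipy import optimize, stats


class FourPLParams(NamedTuple):
    """4PL parameters: shared concentration units for ec50, response units
    for bottom/top, dimensionless positive hill slope."""

    bottom: float
    top: float
    ec50: float
    hill: float


def four_pl(x, bottom: float, top: float, ec50: float, hill: float):
    """Evaluate the 4PL sigmoid; x = 0 maps to ``bottom`` (the basal asymptote)."""
    x = np.asarray(x, dtype=float)
    if ec50 <= 0:
        raise ValueError("ec50 must be positive")
    out = np.full(x.shape, float(bottom))
    pos = x > 0
    with np.errstate(over="ignore"):
        z = np.exp(hill * (np.log(ec50) - np.log(x[pos])))
    out[pos] = bottom + (top - bottom) / (1.0 + z)
    if out.ndim == 0:
        return float(out)
    return out


@dataclass
class DoseResponseFit:
    """Result of a least-squares 4PL fit.

    ``converged`` is False for degenerate inputs (e.g. a flat response,
    where the hill slope is unidentifiable); such fits are flagged rather
    than raised so callers can propagate the diagnosis.
    """

    bottom: float
    top: float
    ec50: float
    hill: float
    rss: float
    n_points: int
    converged: bool
    message: str = ""
    residuals: np.ndarray = field(default_factory=lambda: np.empty(0))

    @property
    def df(self) -> int:
        return self.n_points - 4

    @property
    def params(self) -> FourPLParams:
        return FourPLParams(self.bottom, self.top, self.ec50, self.hill)

    def predict(self, x):
        return four_pl(x, *self.params)


class FTestResult(NamedTuple):
    """Extra sum-of-squares F test between a shared and a separate 4PL model."""

    ss_shared: float
    df_shared: int
    ss_separate: float
    df_separate: int
    F: float
    p: float


def _residual_fn(x: np.ndarray, y: np.ndarray):
    def fn(theta: np.ndarray) -> np.ndarray:
        return four_pl(x, *theta) - y

    return fn


def fit_4pl(
    concentrations: Sequence[float],
    responses: Sequence[float],
    extra_starts: Optional[Sequence[Sequence[float]]] = None,
) -> DoseResponseFit:
    """Fit a 4PL curve by bounded least squares with multi-start initialisation.

    Starts combine bottom = min(y), top = max(y) with hill in {1, 3, 6} and
    ec50 at the 25/50/75% concentration quantiles; the lowest residual sum
    of squares wins. ec50 is constrained to [min(x)/3, 3 max(x)].

    Requires >= 5 points over >= 3 distinct positive concentrations.
    """
    x = np.asarray(concentrations, dtype=float)
    y = np.asarray(responses, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("concentrations and responses must be 1-D and equal length")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("non-finite concentrations or responses")
    if np.any(x <= 0):
        raise ValueError("concentrations must be positive for a 4PL fit")
    if len(x) < 5:
        raise ValueError("need at least 5 points for a 4-parameter fit")
    if len(np.unique(x)) < 3:
        raise ValueError("need at least 3 distinct concentrations")

    yspan = float(np.ptp(y))
    if yspan == 0.0:
        # Flat response: hill (and ec50) unidentifiable. Flag, do not raise.
        return DoseResponseFit(
            bottom=float(y[0]),
            top=float(y[0]),
            ec50=float(np.median(x)),
            hill=float("nan"),
            rss=0.0,
            n_points=len(x),
            converged=False,
            message="flat response; hill slope unidentifiable",
            residuals=np.zeros_like(y),
        )

    lo = np.array([y.min() - yspan, y.min() - yspan, x.min() / 3.0, 1e-2])
    hi = np.array([y.max() + yspan, y.max() + yspan, x.max() * 3.0, 50.0])

    starts = []
    ec50_starts = np.quantile(np.unique(x), [0.25, 0.5, 0.75])
    for hill0 in (1.0, 3.0, 6.0):
        for ec0 in ec50_starts:
            starts.append([y.min(), y.max(), ec0, hill0])
    if extra_starts is not None:
        starts.extend([list(map(float, s)) for s in extra_starts])

    fn = _residual_fn(x, y)
    best = None
    best_rss = np.inf
    for s0 in starts:
        s0 = np.clip(np.asarray(s0, dtype=float), lo, hi)
        try:
            res = optimize.least_squares(
                fn, s0, bounds=(lo, hi), method="trf",
                xtol=1e-14, ftol=1e-14, gtol=1e-14, max_nfev=2000,
            )
        except Exception:  # pragma: no cover - defensive
            continue
        rss = float(np.sum(res.fun**2))
        if rss < best_rss:
            best_rss = rss
            best = res

    if best is None:  # pragma: no cover - defensive
        return DoseResponseFit(
            bottom=float("nan"), top=float("nan"), ec50=float("nan"),
            hill=float("nan"), rss=float("nan"), n_points=len(x),
            converged=False, message="no start converged", residuals=np.full_like(y, np.nan),
        )

    bottom, top, ec50, hill = (float(v) for v in best.x)
    return DoseResponseFit(
        bottom=bottom, top=top, ec50=ec50, hill=hill,
        rss=best_rss, n_points=len(x),
        converged=bool(best.success), message=str(best.status),
        residuals=np.asarray(best.fun, dtype=float),
    )


def compare_fits_ess(
    x_a: Sequence[float],
    y_a: Sequence[float],
    x_b: Sequence[float],
    y_b: Sequence[float],
) -> Tuple[FTestResult, Dict[str, DoseResponseFit]]:
    """Compare two groups' dose responses by the extra sum-of-squares F test.

    Fits one shared 4PL to the pooled points and one 4PL per group, then

        F = ((SS_shared - SS_separate) / (df_shared - df_separate))
            / (SS_separate / df_separate)

    with df_shared = n - 4 and df_separate = n - 8. Identical groups give
    F = 0, p = 1. Each fit is seeded with the others' solutions so the
    nested inequality SS_shared >= SS_separate holds at the optima found.
    """
    x_a = np.asarray(x_a, dtype=float)
    y_a = np.asarray(y_a, dtype=float)
    x_b = np.asarray(x_b, dtype=float)
    y_b = np.asarray(y_b, dtype=float)

    fit_a = fit_4pl(x_a, y_a)
    fit_b = fit_4pl(x_b, y_b)
    x_pool = np.concatenate([x_a, x_b])
    y_pool = np.concatenate([y_a, y_b])
    shared = fit_4pl(x_pool, y_pool, extra_starts=[fit_a.params, fit_b.params])
    # Re-fit each group seeded with the shared solution; keep the better fit.
    fit_a2 = fit_4pl(x_a, y_a, extra_starts=[shared.params])
    fit_b2 = fit_4pl(x_b, y_b, extra_starts=[shared.params])
    if fit_a2.rss < fit_a.rss:
        fit_a = fit_a2
    if fit_b2.rss < fit_b.rss:
        fit_b = fit_b2

    fits = {"shared": shared, "a": fit_a, "b": fit_b}
    n = len(x_pool)
    df_shared = n - 4
    df_separate = n - 8
    if df_separate <= 0:
        raise ValueError("too few points for the separate 8-parameter model")

    if not (shared.converged and fit_a.converged and fit_b.converged):
        return (
            FTestResult(shared.rss, df_shared, fit_a.rss + fit_b.rss,
                        df_separate, float("nan"), float("nan")),
            fits,
        )

    ss_shared = shared.rss
    ss_separate = fit_a.rss + fit_b.rss
    F = ((ss_shared - ss_separate) / (df_shared - df_separate)) / (
        ss_separate / df_separate
    )
    F = max(0.0, float(F))
    p = float(stats.f.sf(F, df_shared - df_separate, df_separate))
    return FTestResult(ss_shared, df_shared, ss_separate, df_separate, F, p), fits
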