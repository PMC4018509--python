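"""Powell direction-set minimization with Brent line searches.

Rigid registration here is a 3-parameter derivative-free maximization,
for which the classical pairing of Powell's direction-set method with
Brent's 1D search is the standard choice.  The heavy lifting is done by
scipy's implementations; this module adds parameter scaling (so a unit
step means 1 px of translation or 1 degree of rotation), per-sweep
objective tracing, and the package's error contracts.

Everything is deterministic: no randomness is involved anywhere.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import optimize as sopt

from .errors import BracketingError, ObjectiveError

__all__ = ["OptimizerConfig", "brent_minimize", "powell_minimize"]


@dataclass
class OptimizerConfig:
    """Tolerances and budgets for the direction-set search.

    xtol below 1 scaled unit is required for subpixel registration
    accuracy; the defaults aim roughly three orders below that.
    """

    xtol: float = 1e-3
    ftol: float = 1e-5
    max_iter: int = 50
    max_line_evals: int = 200
    bracket_step: float = 1.0
    param_scales: tuple[float, ...] = (1.0, 1.0, 1.0)

    def __post_init__(self):
        if self.xtol <= 0 or self.ftol <= 0:
            raise ValueError("tolerances must be > 0")
        if self.max_iter < 1:
            raise ValueError("max_iter must be >= 1")


def _counted(f):
    def wrapper(x):
        wrapper.evals += 1
        v = f(x)
        if not np.all(np.isfinite(v)):
            raise ObjectiveError(f"objective returned non-finite value at {x!r}", point=x)
        return v

    wrapper.evals = 0
    return wrapper


def brent_minimize(f, bracket=None, cfg: OptimizerConfig | None = None):
    """Minimize a 1D function with Brent's method.

    ``bracket`` may be a full triple ``(a, b, c)`` with
    ``f(b) < min(f(a), f(c))``, a pair to start golden-ratio expansion
    from, or None (expansion from ``(0, bracket_step)``).

    Returns ``(x_min, f_min, evals)``.
    """
    cfg = cfg or OptimizerConfig()
    fc = _counted(f)
    if bracket is not None and len(bracket) == 3:
        a, b, c = bracket
        fa, fb, fcv = fc(a), fc(b), fc(c)
        if not (fb < fa and fb < fcv):
            raise BracketingError(f"({a}, {b}, {c}) does not bracket a minimum")
        brack = (a, b, c)
    elif bracket is not None:
        # A pair is an *interval*: probe golden-section interior points
        # until one dips below its neighbors; monotone functions exhaust
        # the budget and raise.
        a, b = sorted(bracket)
        pts = [(a, fc(a)), (b, fc(b))]
        brack = None
        while fc.evals < cfg.max_line_evals:
            i = min(range(len(pts)), key=lambda k: pts[k][1])
            if 0 < i < len(pts) - 1:
                brack = (pts[i - 1][0], pts[i][0], pts[i + 1][0])
                break
            j = 0 if i == 0 else len(pts) - 2  # split the interval at the winning end
            xm = pts[j][0] + 0.381966 * (pts[j + 1][0] - pts[j][0])
            pts.insert(j + 1, (xm, fc(xm)))
        if brack is None:
            raise BracketingError(f"no interior minimum found in [{a}, {b}] within {cfg.max_line_evals} evaluations")
    else:
        try:
            xa, xb, xc, fa, fb, fcv, calls = sopt.bracket(fc, xa=0.0, xb=cfg.bracket_step, maxiter=cfg.max_line_evals)
        except Exception as exc:  # scipy raises RuntimeError/BracketError
            raise BracketingError(f"failed to bracket a minimum from (0, {cfg.bracket_step}): {exc}") from exc
        brack = (xa, xb, xc) if xa < xc else (xc, xb, xa)
    x_min, f_min, _, funcalls = sopt.brent(fc, brack=brack, tol=max(cfg.xtol * 1e-2, 1e-11), full_output=True)
    return float(x_min), float(f_min), fc.evals


def powell_minimize(f, x0, cfg: OptimizerConfig | None = None):
    """Minimize a vector function with Powell's direction-set method.

    Parameters are optimized in units of ``cfg.param_scales``; the
    initial directions are the scaled coordinate axes and scipy applies
    the standard direction-replacement rule.  The returned ``trace``
    holds the objective after the start and after every sweep and is
    non-increasing.

    Returns ``(x_star, f_star, trace)``.
    """
    cfg = cfg or OptimizerConfig()
    x0 = np.asarray(x0, dtype=np.float64)
    scales = np.asarray(cfg.param_scales[: x0.size], dtype=np.float64)
    if scales.size != x0.size:
        scales = np.ones(x0.size)
    fc = _counted(lambda u: f(u * scales))
    trace = [fc(x0 / scales)]

    def cb(uk):
        trace.append(min(trace[-1], fc(uk)))

    res = sopt.minimize(
        fc,
        x0 / scales,
        method="Powell",
        callback=cb,
        options={
            "xtol": cfg.xtol,
            "ftol": cfg.ftol,
            "maxiter": cfg.max_iter,
            "maxfev": 10000,
            "disp": False,
        },
    )
    x_star = res.x * scales
    f_star = float(res.fun)
    trace.append(min(trace[-1], f_star))
    return x_star, f_star, trace
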