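"""LN and spatial-contrast (SC) encoding models for flashed-image responses.

Both models map a scalar image drive F through a softplus output
nonlinearity

    r(F) = a1 * ln(1 + exp(a2 * (F + a3)))

to a predicted spike count.  The classical LN model uses F = I_mean (the
RF-weighted mean contrast); the SC model adds the local spatial contrast
with a single free weight,

    F_SC = I_mean + w * LSC.

Fitting minimizes the squared error between the softplus prediction and
the trial-averaged counts of a training image set, with a derivative-free
simplex search.  The SC model alternates least-squares optimization of
the nonlinearity (a1, a2, a3) and of the weight w until convergence or a
maximum number of alternations; both fits restart from many random
initializations and keep the best residual.  a1 and a2 are kept positive
through a log parameterization, so the nonlinearity stays monotonically
increasing and a cell's polarity is carried by the sign of its drive.

Performance is the squared Pearson correlation R^2 between predicted and
observed mean counts on held-out test images (affine-invariant, so a
miscalibrated but correlated prediction still scores high); the SC/LN
prediction improvement is the ratio of the two R^2 values.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize
from scipy.stats import pearsonr

__all__ = [
    "LNModel",
    "SCModel",
    "FitEvaluation",
    "softplus",
    "fit_ln",
    "fit_sc",
    "predict",
    "evaluate",
    "prediction_improvement",
    "split_train_test",
]

MAX_ALTERNATIONS = 500
REL_TOL = 1e-8
PARAM_TOL = 1e-6


def softplus(f, a1: float, a2: float, a3: float):
    """r(F) = a1 * ln(1 + exp(a2 * (F + a3))), overflow-safe."""
    out = a1 * np.logaddexp(0.0, a2 * (np.asarray(f, dtype=float) + a3))
    return out


@dataclass
class LNModel:
    """Softplus nonlinearity on the I_mean drive."""

    a1: float
    a2: float
    a3: float
    fit_info: dict = field(default_factory=dict, repr=False)

    def drive(self, i_mean, lsc=None) -> np.ndarray:
        return np.asarray(i_mean, dtype=float)

    def predict(self, i_mean, lsc=None) -> np.ndarray:
        return softplus(self.drive(i_mean, lsc), self.a1, self.a2, self.a3)


@dataclass
class SCModel(LNModel):
    """Softplus on the spatial-contrast drive F = I_mean + w * LSC."""

    w: float = 0.0

    def drive(self, i_mean, lsc=None) -> np.ndarray:
        if lsc is None:
            raise ValueError("SC model needs LSC values")
        return np.asarray(i_mean, dtype=float) + self.w * np.asarray(lsc, dtype=float)


def _sse(theta: np.ndarray, f: np.ndarray, y: np.ndarray) -> float:
    # log params capped: the simplex may wander to scales where exp overflows
    log_a1, log_a2, a3 = np.minimum(theta, 500.0)
    pred = np.exp(log_a1) * np.logaddexp(0.0, np.exp(min(log_a2, 30.0)) * (f + a3))
    return float(np.sum((pred - y) ** 2))


def _fit_nonlinearity(f, y, theta0, maxiter=400):
    res = minimize(_sse, theta0, args=(f, y), method="Nelder-Mead",
                   options={"maxiter": maxiter, "xatol": 1e-9, "fatol": 1e-12})
    return res.x, float(res.fun)


def _random_inits(f, y, n, rng):
    """Data-scaled random starting points (log a1, log a2, a3, w).

    Drawn one restart at a time, so the first k restarts are identical
    for any total count — best-of-restarts is monotone in n.
    """
    ymax = max(float(np.max(y)), 1e-3)
    fsd = float(np.std(f))
    fsd = fsd if fsd > 0 else 1.0
    out = []
    for _ in range(n):
        log_a1 = np.log(ymax * rng.uniform(0.2, 1.5))
        log_a2 = np.log(rng.uniform(0.5, 8.0) / fsd)
        a3 = -np.median(f) + fsd * rng.normal(0, 1.0)
        w = rng.uniform(-2.0, 2.0)
        out.append((np.array([log_a1, log_a2, a3]), float(w)))
    return out


def _unpack(theta):
    return float(np.exp(min(theta[0], 500.0))), float(np.exp(min(theta[1], 30.0))), float(theta[2])


def fit_ln(i_mean, counts, n_restarts: int = 200, seed: int | None = 0) -> LNModel:
    """Fit the LN model's softplus to (I_mean, mean count) training pairs."""
    f = np.asarray(i_mean, dtype=float)
    y = np.asarray(counts, dtype=float)
    if f.size < 4:
        raise ValueError("need at least 4 training points")
    if np.ptp(f) == 0:
        raise ValueError("constant I_mean; nonlinearity not identifiable")
    rng = np.random.default_rng(seed)
    inits = _random_inits(f, y, n_restarts, rng)
    best_theta, best_sse = None, np.inf
    for theta0, _ in inits:
        theta, sse = _fit_nonlinearity(f, y, theta0)
        if sse < best_sse:
            best_theta, best_sse = theta, sse
    a1, a2, a3 = _unpack(best_theta)
    info = {"residual": best_sse, "n_restarts": n_restarts,
            "degenerate": bool(np.all(y == 0))}
    return LNModel(a1=a1, a2=a2, a3=a3, fit_info=info)


def _fit_weight(i_mean, lsc, y, theta, w0, maxiter=200):
    a1, a2, a3 = _unpack(theta)

    def sse_w(wv):
        pred = softplus(i_mean + wv[0] * lsc, a1, a2, a3)
        return float(np.sum((pred - y) ** 2))

    res = minimize(sse_w, [w0], method="Nelder-Mead",
                   options={"maxiter": maxiter, "xatol": 1e-10, "fatol": 1e-12})
    return float(res.x[0]), float(res.fun)


def fit_sc(
    i_mean,
    lsc,
    counts,
    n_restarts: int = 200,
    seed: int | None = 0,
    max_alternations: int = MAX_ALTERNATIONS,
    extra_inits: list[tuple[float, float, float, float]] | None = None,
) -> SCModel:
    """Fit the SC model by alternating least squares.

    Each restart alternates (i) a simplex fit of (a1, a2, a3) with w
    fixed and (ii) a simplex fit of w with the nonlinearity fixed, until
    the relative residual change falls below 1e-8, the parameters move by
    less than 1e-6, or ``max_alternations`` is reached.  The restart with
    the smallest residual wins.  If LSC is constant, w is not
    identifiable: the fit falls back to an LN-equivalent model (w = 0,
    flagged in ``fit_info``).

    ``extra_inits`` adds deterministic starting points (a1, a2, a3, w) to
    the random restarts — e.g. a warm start from a neighboring smoothing
    scale during a scale sweep.
    """
    f = np.asarray(i_mean, dtype=float)
    s = np.asarray(lsc, dtype=float)
    y = np.asarray(counts, dtype=float)
    if f.size < 5:
        raise ValueError("need at least 5 training points")
    if np.ptp(s) == 0:
        ln = fit_ln(f, y, n_restarts=n_restarts, seed=seed)
        info = dict(ln.fit_info, w_identifiable=False)
        return SCModel(a1=ln.a1, a2=ln.a2, a3=ln.a3, w=0.0, fit_info=info)

    rng = np.random.default_rng(seed)
    inits = _random_inits(f, y, n_restarts, rng)
    # first start always from the LN basin (w = 0): its first alternation
    # fits the plain-I_mean nonlinearity, so SC explores the LN solution
    inits[0] = (inits[0][0], 0.0)
    for a1, a2, a3, w0 in extra_inits or []:
        inits.append((np.array([np.log(a1), np.log(a2), a3]), float(w0)))

    best = None
    for theta0, w0 in inits:
        theta, w = theta0.copy(), float(w0)
        sse = _sse(theta, f + w * s, y)
        trace = [sse]
        converged = False
        for it in range(max_alternations):
            theta_new, sse_nl = _fit_nonlinearity(f + w * s, y, theta)
            w_new, sse_w = _fit_weight(f, s, y, theta_new, w)
            dparam = max(np.max(np.abs(theta_new - theta)), abs(w_new - w))
            rel = (sse - sse_w) / sse if sse > 0 else 0.0
            theta, w, sse = theta_new, w_new, sse_w
            trace.append(sse)
            if rel < REL_TOL or dparam < PARAM_TOL:
                converged = True
                break
        if best is None or sse < best[2]:
            best = (theta, w, sse, trace, converged)

    theta, w, sse, trace, converged = best
    a1, a2, a3 = _unpack(theta)
    info = {"residual": sse, "n_restarts": n_restarts, "sse_trace": trace,
            "converged": converged, "w_identifiable": True,
            "degenerate": bool(np.all(y == 0))}
    return SCModel(a1=a1, a2=a2, a3=a3, w=w, fit_info=info)


def predict(model: LNModel, i_mean, lsc=None) -> np.ndarray:
    """Predicted counts for a feature table or arrays of drives."""
    return model.predict(i_mean, lsc)


@dataclass
class FitEvaluation:
    """Held-out performance: Pearson r and R^2 between prediction and data."""

    r: float
    r2: float
    n_test: int
    improvement: float | None = None


def evaluate(pred, observed) -> FitEvaluation:
    """Squared Pearson correlation between predicted and observed mean counts."""
    p = np.asarray(pred, dtype=float)
    o = np.asarray(observed, dtype=float)
    if p.size < 3:
        raise ValueError("need at least 3 test points")
    if np.ptp(o) == 0 or np.ptp(p) == 0:
        raise ValueError("correlation undefined for constant vectors")
    r = float(pearsonr(p, o).statistic)
    return FitEvaluation(r=r, r2=r * r, n_test=int(p.size))


def prediction_improvement(eval_sc: FitEvaluation, eval_ln: FitEvaluation) -> float:
    """SC-model R^2 normalized by LN-model R^2 on the same test set."""
    if eval_ln.r2 == 0:
        raise ValueError("LN model R^2 is zero; improvement undefined")
    return eval_sc.r2 / eval_ln.r2


def split_train_test(n_images: int, fraction: float = 0.5, seed: int | None = 0):
    """Disjoint, exhaustive random train/test split of image indices."""
    if n_images < 2:
        raise ValueError("need at least 2 images to split")
    if not 0 < fraction < 1:
        raise ValueError("fraction must lie in (0, 1)")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n_images)
    n_train = int(round(n_images * fraction))
    n_train = min(max(n_train, 1), n_images - 1)
    return np.sort(perm[:n_train]), np.sort(perm[n_train:])
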