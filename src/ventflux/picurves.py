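"""Photosynthesis-irradiance (PI) curve fitting and irradiance adjustment.

Net photosynthesis rises with photosynthetically active radiation (PAR) and
saturates; the response is modelled as

    y(x) = alpha * (1 - beta * exp(gamma * x)),   gamma < 0,

where ``alpha`` is the maximum photosynthetic rate (the saturation plateau),
``beta`` the curvature constant (beta = 1 forces y(0) = 0) and ``gamma`` the
saturation constant per (umol photons m-2 s-1).  gamma is constrained
negative: with gamma > 0 the expression diverges and alpha could not be a
maximum.

Fitted curves are used to adjust incubation rates measured at arbitrary PAR
to a common reference irradiance (default 600 umol m-2 s-1, the maximum
recorded in the field), so that tiles incubated at different times of day
are comparable.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares

__all__ = ["PICurve", "PICurveFit", "predict_np", "adjust_to_reference", "PAR_REFERENCE"]

PAR_REFERENCE = 600.0  # umol photons m-2 s-1, max PAR recorded in the field


class PIFitError(RuntimeError):
    pass


@dataclass(frozen=True)
class PICurveFit:
    """Fitted saturating-exponential PI curve (the Results object).

    alpha: plateau rate (units of the input NP); beta: curvature
    (dimensionless); gamma: saturation constant (< 0, per umol m-2 s-1);
    r_squared: 1 - SSE/SST on the training points.
    """

    alpha: float
    beta: float
    gamma: float
    r_squared: float
    n_points: int = 0

    def predict(self, par):
        return predict_np(self, par)

    def adjust_to_reference(self, np_measured, par_during, par_ref=PAR_REFERENCE,
                            mode="ratio"):
        return adjust_to_reference(np_measured, par_during, self, par_ref, mode)

    def summary(self) -> str:
        return (
            "PI curve fit: y = alpha (1 - beta exp(gamma x))\n"
            f"  alpha (max rate) : {self.alpha:.4g}\n"
            f"  beta  (curvature): {self.beta:.4g}\n"
            f"  gamma (satur.)   : {self.gamma:.4g}\n"
            f"  R^2              : {self.r_squared:.3f}  (n = {self.n_points})"
        )


class PICurve:
    """PI-curve model over (PAR, net photosynthesis) points.

    Nonlinear least squares with multi-start over the saturation constant;
    ``fit()`` returns a :class:`PICurveFit`.
    """

    #: starting saturation constants; best final SSE wins, ties to smallest |gamma|
    GAMMA_STARTS = (-0.001, -0.01, -0.1)

    def __init__(self, par, np_rate):
        par = np.asarray(par, dtype=float)
        np_rate = np.asarray(np_rate, dtype=float)
        if par.shape != np_rate.shape:
            raise PIFitError("par and np arrays must have equal length")
        if len(par) < 5:
            raise PIFitError(f"need >= 5 points, got {len(par)}")
        pos = par[par > 0]
        if len(pos) == 0 or pos.max() / max(pos.min(), 1e-12) < 10.0:
            raise PIFitError(
                "degenerate PAR range: points must span at least a 10-fold range"
            )
        self.par = par
        self.np_rate = np_rate

    @staticmethod
    def _model(theta, x):
        alpha, beta, gamma = theta
        return alpha * (1.0 - beta * np.exp(gamma * x))

    def fit(self) -> PICurveFit:
        x, y = self.par, self.np_rate
        sst = float(np.sum((y - y.mean()) ** 2))

        if np.allclose(y, y[0]):
            # flat-curve limit: alpha = the constant, beta -> 0
            return PICurveFit(alpha=float(y[0]), beta=0.0,
                              gamma=self.GAMMA_STARTS[1], r_squared=1.0,
                              n_points=len(x))

        alpha0 = float(np.max(y)) if np.max(y) != 0 else 1.0
        best = None
        for g0 in self.GAMMA_STARTS:
            try:
                res = least_squares(
                    lambda th: self._model(th, x) - y,
                    x0=[alpha0, 1.0, g0],
                    bounds=([-np.inf, -np.inf, -np.inf], [np.inf, np.inf, -1e-12]),
                    xtol=1e-14, ftol=1e-14, gtol=1e-14,
                )
            except Exception:
                continue
            sse = float(2.0 * res.cost)
            if best is None or sse < best[0] - 1e-12 or (
                abs(sse - best[0]) <= 1e-12 and abs(res.x[2]) < abs(best[1][2])
            ):
                best = (sse, res.x, res.success)
        if best is None or not best[2]:
            raise PIFitError(
                "PI-curve fit failed to converge from all starting points"
                + ("" if best is None else f"; best SSE {best[0]:.4g}")
            )
        sse, theta, _ = best
        r2 = 1.0 - sse / sst if sst > 0 else 1.0
        return PICurveFit(
            alpha=float(theta[0]), beta=float(theta[1]), gamma=float(theta[2]),
            r_squared=float(r2), n_points=len(x),
        )


def fit_pi_curve(points) -> PICurveFit:
    """Functional wrapper: ``points`` is a sequence of (par, np) pairs."""
    arr = np.asarray(points, dtype=float)
    return PICurve(arr[:, 0], arr[:, 1]).fit()


def predict_np(fit: PICurveFit, par):
    """Predicted net photosynthesis at irradiance ``par`` (>= 0)."""
    par = np.asarray(par, dtype=float)
    if np.any(par < 0):
        raise PIFitError("par must be >= 0")
    out = fit.alpha * (1.0 - fit.beta * np.exp(fit.gamma * par))
    return float(out) if out.ndim == 0 else out


def adjust_to_reference(np_measured, par_during, fit: PICurveFit,
                        par_ref: float = PAR_REFERENCE, mode: str = "ratio"):
    """Adjust a measured NP to the reference irradiance.

    ``ratio`` (default) multiplies by y(par_ref)/y(par_during), preserving
    zeros and per-tile activity differences; ``substitute`` returns the
    curve's own prediction at par_ref and ignores the measurement.
    """
    y_ref = predict_np(fit, par_ref)
    if mode == "substitute":
        return y_ref
    if mode != "ratio":
        raise PIFitError(f"unknown adjust mode {mode!r}")
    y_during = predict_np(fit, par_during)
    if np.any(np.isclose(y_during, 0.0)):
        raise PIFitError(
            "predicted NP at incubation PAR is zero; exclude dawn/dusk "
            "incubations before adjusting"
        )
    return np_measured * y_ref / y_during
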