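"""Hierarchical Bayesian response model for standardised biomass and rates.

Each tile belongs to one of three community types (calcifying-, mixed- or
fleshy-algae-dominated) and sits in one of three pH zones (ambient, low,
extreme low).  Responses standardised to their initial measurement — biomass
ratios B > 0, process-rate ratios F of any sign — are modelled as

    B ~ Weibull(mu_B, sigma_B)        (log link for the mean, shape sigma_B)
    F ~ Normal(mu_F, sigma_F)

    mu_i = beta + zeta[g(i), 1] + zeta[g(i), 2] * time_i

where g(i) is the (community, pH) cell of observation i (s = 3 x 3 = 9
cells), beta is the global coefficient, and the cell effects form an s-by-2
matrix zeta — column 1 an additive level deviation, column 2 a time-slope
deviation — factored through standardised effects:

    zeta = delta_s  diag(sigma_zeta)  L'          (L = Cholesky factor of
                                                   the 2x2 correlation)

Priors: beta ~ flat (Normal(0, 1000) in practice); sigma and sigma_zeta ~
Gamma(0.01, 0.01) (shape-rate); delta_s ~ Student-t(3, 0, 2.5);
correlation ~ LKJ(1) (uniform on the 2x2 correlation matrix).

Sampling uses an affine-invariant / differential-evolution ensemble MCMC
backend.  The sampler walks the centred variables (zeta itself, with the
delta prior applied through the exact change of variables); delta is derived
afterwards, which keeps the factorisation identity while avoiding the funnel
geometry that defeats ensemble moves when the data strongly determine the
cell effects.  "Chains" are independent ensembles; retained draws are
thinned deterministically to chains x (iterations - warmup), so the study
plan of four chains x 10,000 iterations with 2,000 warm-up retains 32,000
draws.  An effect between two conditions is called meaningful when their
equal-tailed 75% credible intervals are disjoint (touching endpoints count
as overlap).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
import emcee

__all__ = [
    "ModelSpec",
    "CommunityResponseModel",
    "CommunityResponseResults",
    "retained_draws",
    "meaningful_effect",
    "build_zeta",
    "COMMUNITY_LEVELS",
    "PH_LEVELS",
]

COMMUNITY_LEVELS = ("calcifying", "mixed", "fleshy")
PH_LEVELS = ("ambient", "low", "extreme_low")


class ModelError(ValueError):
    pass


def retained_draws(chains: int, iterations: int, warmup: int) -> int:
    """Posterior draws kept by the sampling plan: chains x (iterations - warmup)."""
    if warmup >= iterations:
        raise ModelError("warmup must be smaller than iterations")
    return chains * (iterations - warmup)


def build_zeta(delta: np.ndarray, sigma_zeta: np.ndarray, rho) -> np.ndarray:
    """Assemble cell effects zeta = delta diag(sigma_zeta) L'.

    ``delta`` has shape (..., s, 2); ``sigma_zeta`` (..., 2); ``rho`` the
    intercept-slope correlation.  L = [[1, 0], [rho, sqrt(1-rho^2)]] is the
    lower Cholesky factor of the correlation matrix.
    """
    delta = np.asarray(delta, dtype=float)
    sigma_zeta = np.asarray(sigma_zeta, dtype=float)
    rho = np.asarray(rho, dtype=float)
    c = np.sqrt(1.0 - rho**2)
    scaled0 = delta[..., 0] * sigma_zeta[..., 0:1]
    scaled1 = delta[..., 1] * sigma_zeta[..., 1:2]
    z0 = scaled0
    z1 = scaled0 * rho[..., None] + scaled1 * c[..., None]
    return np.stack([z0, z1], axis=-1)


def invert_zeta(zeta: np.ndarray, sigma_zeta: np.ndarray, rho) -> np.ndarray:
    """Recover the standardised effects delta from zeta (exact inverse)."""
    zeta = np.asarray(zeta, dtype=float)
    sigma_zeta = np.asarray(sigma_zeta, dtype=float)
    rho = np.asarray(rho, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        c = np.sqrt(1.0 - rho**2)
        d0 = zeta[..., 0] / sigma_zeta[..., 0:1]
        d1 = (zeta[..., 1] - rho[..., None] * zeta[..., 0]) / (
            c[..., None] * sigma_zeta[..., 1:2]
        )
    return np.stack([d0, d1], axis=-1)


@dataclass(frozen=True)
class ModelSpec:
    """Model family + design description.

    family: 'weibull' (biomass, strictly positive response) or 'gaussian'
    (process rates, any sign).  time is in days since the first measurement.
    """

    family: str
    community_levels: tuple = COMMUNITY_LEVELS
    ph_levels: tuple = PH_LEVELS

    def __post_init__(self):
        if self.family not in ("weibull", "gaussian"):
            raise ModelError(f"family must be weibull/gaussian, got {self.family!r}")

    @property
    def n_cells(self) -> int:
        return len(self.community_levels) * len(self.ph_levels)

    def cell_index(self, community: str, ph_zone: str) -> int:
        try:
            i = self.community_levels.index(community)
            j = self.ph_levels.index(ph_zone)
        except ValueError as e:
            raise ModelError(f"unknown cell ({community!r}, {ph_zone!r})") from e
        return i * len(self.ph_levels) + j


# ---------------------------------------------------------------------------
# log posterior over the sampled (centred) variables, vectorised over walkers
# ---------------------------------------------------------------------------

def _unpack(theta: np.ndarray, s: int):
    """theta columns: beta, zeta (2s, cell-major), log sig_z (2), atanh rho, log sigma."""
    beta = theta[:, 0]
    zeta = theta[:, 1:1 + 2 * s].reshape(-1, s, 2)
    log_sz = theta[:, 1 + 2 * s:3 + 2 * s]
    zrho = theta[:, 3 + 2 * s]
    log_sigma = theta[:, 4 + 2 * s]
    return beta, zeta, log_sz, zrho, log_sigma


def _make_log_prob(family: str, y: np.ndarray, t: np.ndarray, g: np.ndarray, s: int):
    log_y = np.log(y) if family == "weibull" else None
    n = len(y)

    def log_prob(theta: np.ndarray, _errstate={"divide": "ignore",
                                               "invalid": "ignore",
                                               "over": "ignore"}) -> np.ndarray:
        theta = np.atleast_2d(theta)
        with np.errstate(**_errstate):
            return _eval(theta)

    def _eval(theta: np.ndarray) -> np.ndarray:
        beta, zeta, log_sz, zrho, log_sigma = _unpack(theta, s)
        sig_z = np.exp(log_sz)
        rho = np.tanh(zrho)
        sigma = np.exp(log_sigma)
        c = np.sqrt(1.0 - rho**2)

        # priors -----------------------------------------------------------
        lp = -0.5 * (beta / 1000.0) ** 2  # near-flat global coefficient

        # Student-t(3, 0, 2.5) on the standardised effects delta = f(zeta),
        # with the change-of-variables Jacobian |det(diag(sz) L')|^-s
        delta = invert_zeta(zeta, sig_z, rho)
        nu, sc = 3.0, 2.5
        lp += np.sum(-0.5 * (nu + 1.0) * np.log1p((delta / sc) ** 2 / nu),
                     axis=(1, 2))
        lp -= s * (log_sz[:, 0] + log_sz[:, 1] + np.log(c))

        # Gamma(0.01, 0.01) shape-rate on the sds, log-space Jacobian folded in
        a = rate = 0.01
        for col in (log_sz[:, 0], log_sz[:, 1], log_sigma):
            lp += a * col - rate * np.exp(col)

        # LKJ(1): uniform on rho; Jacobian of atanh is log(1 - rho^2)
        lp += np.log1p(-rho**2)

        # likelihood --------------------------------------------------------
        mu = beta[:, None] + zeta[:, g, 0] + zeta[:, g, 1] * t[None, :]
        if family == "gaussian":
            ll = -0.5 * np.sum(((y[None, :] - mu) / sigma[:, None]) ** 2, axis=1)
            ll -= n * np.log(sigma)
        else:
            # Weibull with shape k = sigma, scale set so the mean is exp(mu)
            k = sigma
            lg = np.array([math.lgamma(1.0 + 1.0 / ki) for ki in k])
            log_lam = mu - lg[:, None]
            z = np.exp(np.clip(k[:, None] * (log_y[None, :] - log_lam), None, 700.0))
            ll = np.sum(
                np.log(k)[:, None] + (k[:, None] - 1.0) * log_y[None, :]
                - k[:, None] * log_lam - z,
                axis=1,
            )
        out = lp + ll
        out[~np.isfinite(out)] = -np.inf
        return out

    return log_prob


# ---------------------------------------------------------------------------
# model / results
# ---------------------------------------------------------------------------

class CommunityResponseModel:
    """Hierarchical community x pH response model over a tidy DataFrame.

    Expects columns ``community``, ``ph_zone``, ``time_days`` and
    ``response`` (other columns are carried but ignored).  ``fit()`` runs
    the MCMC and returns a :class:`CommunityResponseResults`.
    """

    def __init__(self, data: pd.DataFrame, family: str = "gaussian",
                 spec: ModelSpec | None = None):
        self.spec = spec if spec is not None else ModelSpec(family=family)
        required = {"community", "ph_zone", "time_days", "response"}
        missing = required - set(data.columns)
        if missing:
            raise ModelError(f"data missing columns {sorted(missing)}")
        if len(data) == 0:
            raise ModelError("data is empty")
        self.data = data.reset_index(drop=True)
        self.y = self.data["response"].to_numpy(dtype=float)
        if self.spec.family == "weibull" and np.any(self.y <= 0):
            raise ModelError("Weibull responses must be strictly positive")
        self.t = self.data["time_days"].to_numpy(dtype=float)
        if np.any(self.t < 0):
            raise ModelError("time_days must be >= 0")
        self.g = np.array(
            [self.spec.cell_index(c, z)
             for c, z in zip(self.data["community"], self.data["ph_zone"])]
        )
        self.ndim = 5 + 2 * self.spec.n_cells

    @classmethod
    def from_dataframe(cls, data: pd.DataFrame, family: str = "gaussian"):
        return cls(data, family=family)

    def _initial_state(self, rng: np.random.Generator, nwalkers: int) -> np.ndarray:
        """Small ball around data-informed values (per-cell OLS lines)."""
        s = self.spec.n_cells
        y, t, g, fam = self.y, self.t, self.g, self.spec.family
        target = np.log(np.clip(y, 1e-6, None)) if fam == "weibull" else y
        center = np.zeros(self.ndim)
        center[0] = float(np.mean(target))
        for cell in range(s):
            sel = g == cell
            if sel.sum() >= 2 and np.ptp(t[sel]) > 0:
                a = np.vstack([np.ones(sel.sum()), t[sel]]).T
                coef, *_ = np.linalg.lstsq(a, target[sel], rcond=None)
                center[1 + 2 * cell] = coef[0] - center[0]
                center[2 + 2 * cell] = coef[1]
        center[1 + 2 * s:3 + 2 * s] = np.log(0.5)
        sd0 = float(np.std(target)) or 1.0
        center[4 + 2 * s] = np.log(2.0) if fam == "weibull" else np.log(sd0)
        return center + 0.05 * rng.standard_normal((nwalkers, self.ndim))

    def fit(
        self,
        chains: int = 4,
        iterations: int = 10_000,
        warmup: int = 2_000,
        seed: int | None = None,
        nwalkers: int | None = None,
        progress: bool = False,
    ) -> "CommunityResponseResults":
        """Sample the posterior.

        ``chains`` independent ensembles each run ``iterations`` steps;
        the first ``warmup`` are discarded and the remainder thinned
        deterministically to iterations - warmup retained draws per chain.
        A seed is mandatory.
        """
        if chains < 1:
            raise ModelError("need at least one chain")
        if seed is None:
            raise ModelError("a seed is mandatory for sampling")
        n_keep = iterations - warmup
        if n_keep <= 0:
            raise ModelError("warmup must be smaller than iterations")
        s = self.spec.n_cells
        w = nwalkers if nwalkers is not None else max(2 * self.ndim + 2, 48)
        log_prob = _make_log_prob(self.spec.family, self.y, self.t, self.g, s)
        moves = [
            (emcee.moves.DEMove(), 0.8),
            (emcee.moves.DESnookerMove(), 0.2),
        ]

        chain_draws = np.empty((chains, n_keep, self.ndim))
        root = np.random.SeedSequence(seed)
        for c, ss in enumerate(root.spawn(chains)):
            rng = np.random.default_rng(ss)
            sampler = emcee.EnsembleSampler(
                w, self.ndim, log_prob, vectorize=True, moves=moves
            )
            sampler.random_state = np.random.RandomState(
                int(ss.generate_state(1)[0] % (2**31))
            ).get_state()
            state = self._initial_state(rng, w)
            sampler.run_mcmc(state, iterations, progress=progress,
                             skip_initial_state_check=True)
            flat = sampler.get_chain(discard=warmup, flat=True)
            idx = np.linspace(0, len(flat) - 1, n_keep).astype(int)
            chain_draws[c] = flat[idx]

        return CommunityResponseResults(
            model=self, draws=chain_draws, chains=chains,
            iterations=iterations, warmup=warmup, seed=seed,
        )


@dataclass
class CommunityResponseResults:
    """Posterior draws plus diagnostics for a fitted community-response model."""

    model: CommunityResponseModel
    draws: np.ndarray  # (chains, n_keep, ndim)
    chains: int
    iterations: int
    warmup: int
    seed: int

    def __post_init__(self):
        s = self.model.spec.n_cells
        c, d, _ = self.draws.shape
        flat = self.draws.reshape(c * d, -1)
        beta, zeta, log_sz, zrho, log_sigma = _unpack(flat, s)
        self.beta = beta.reshape(c, d)
        self.zeta = zeta.reshape(c, d, s, 2)
        self.sigma_zeta = np.exp(log_sz).reshape(c, d, 2)
        self.rho = np.tanh(zrho).reshape(c, d)
        self.sigma = np.exp(log_sigma).reshape(c, d)
        self.delta = invert_zeta(self.zeta, self.sigma_zeta, self.rho)

    # -- bookkeeping ---------------------------------------------------------

    @property
    def n_retained(self) -> int:
        return self.draws.shape[0] * self.draws.shape[1]

    def _named_draws(self) -> dict:
        s = self.model.spec.n_cells
        out = {"beta": self.beta, "sigma": self.sigma, "rho": self.rho}
        for j in range(2):
            out[f"sigma_zeta[{j}]"] = self.sigma_zeta[..., j]
        for cell in range(s):
            out[f"zeta[{cell},intercept]"] = self.zeta[..., cell, 0]
            out[f"zeta[{cell},slope]"] = self.zeta[..., cell, 1]
        return out

    # -- diagnostics ---------------------------------------------------------

    def rhat(self) -> dict:
        """Split-R_hat per reported parameter (requires >= 2 chains)."""
        if self.chains < 2:
            raise ModelError("R_hat undefined for a single chain")
        import arviz as az

        return {
            name: float(az.rhat(np.asarray(arr)))
            for name, arr in self._named_draws().items()
        }

    def convergence_check(self, threshold: float = 1.05):
        """(passed, offending) — fails iff any parameter's R_hat >= threshold."""
        rh = self.rhat()
        offending = {k: v for k, v in rh.items() if v >= threshold}
        return len(offending) == 0, offending

    # -- summaries -----------------------------------------------------------

    @staticmethod
    def credible_interval(draws_1d, level: float = 0.95) -> tuple[float, float]:
        """Equal-tailed credible interval of a 1-D draw array."""
        a = (1.0 - level) / 2.0
        lo, hi = np.quantile(np.asarray(draws_1d).ravel(), [a, 1.0 - a])
        return float(lo), float(hi)

    def cell_draws(self, community: str, ph_zone: str, quantity: str = "slope",
                   time: float | None = None) -> np.ndarray:
        """Flattened posterior draws of a cell-level quantity.

        quantity: 'slope' (time-slope deviation), 'intercept'
        (beta + level deviation) or 'fitted' (linear predictor at ``time``).
        """
        cell = self.model.spec.cell_index(community, ph_zone)
        z = self.zeta.reshape(-1, self.model.spec.n_cells, 2)
        b = self.beta.ravel()
        if quantity == "slope":
            return z[:, cell, 1]
        if quantity == "intercept":
            return b + z[:, cell, 0]
        if quantity == "fitted":
            if time is None:
                raise ModelError("'fitted' needs a time")
            return b + z[:, cell, 0] + z[:, cell, 1] * time
        raise ModelError(f"unknown quantity {quantity!r}")

    def meaningful_effect(self, draws_a, draws_b, level: float = 0.75) -> bool:
        """Decision rule: disjoint equal-tailed credible intervals."""
        return meaningful_effect(draws_a, draws_b, level)

    def fitted_draws(self) -> np.ndarray:
        """Linear predictor mu for every observation, per retained draw."""
        z = self.zeta.reshape(-1, self.model.spec.n_cells, 2)
        b = self.beta.ravel()
        g, t = self.model.g, self.model.t
        return b[:, None] + z[:, g, 0] + z[:, g, 1] * t[None, :]

    def bayes_r2(self) -> float:
        """Posterior-averaged var(fitted) / (var(fitted) + residual variance)."""
        mu = self.fitted_draws()
        if self.model.spec.family == "gaussian":
            fitted = mu
            resid_var = np.broadcast_to(
                (self.sigma.ravel() ** 2)[:, None], mu.shape
            )
        else:
            k = self.sigma.ravel()
            g1 = np.array([math.gamma(1.0 + 1.0 / ki) for ki in k])
            g2 = np.array([math.gamma(1.0 + 2.0 / ki) for ki in k])
            fitted = np.exp(mu)
            lam = fitted / g1[:, None]
            resid_var = lam**2 * (g2[:, None] - g1[:, None] ** 2)
        var_fit = fitted.var(axis=1)
        r2 = var_fit / (var_fit + resid_var.mean(axis=1))
        return float(np.mean(r2))

    def summary(self, levels=(0.75, 0.95)) -> pd.DataFrame:
        """Posterior summary table: mean, sd, equal-tailed CIs, R_hat."""
        rows = []
        rh = self.rhat() if self.chains >= 2 else {}
        for name, arr in self._named_draws().items():
            flat = np.asarray(arr).ravel()
            row = {"parameter": name, "mean": flat.mean(), "sd": flat.std()}
            for lv in levels:
                lo, hi = self.credible_interval(flat, lv)
                row[f"ci{int(lv * 100)}_low"] = lo
                row[f"ci{int(lv * 100)}_high"] = hi
            row["r_hat"] = rh.get(name, np.nan)
            rows.append(row)
        return pd.DataFrame(rows).set_index("parameter")


def meaningful_effect(draws_a, draws_b, level: float = 0.75) -> bool:
    """True iff the equal-tailed ``level`` credible intervals are disjoint.

    Intervals sharing exactly one endpoint count as overlapping.
    """
    a = np.asarray(draws_a, dtype=float).ravel()
    b = np.asarray(draws_b, dtype=float).ravel()
    q = (1.0 - level) / 2.0
    a_lo, a_hi = np.quantile(a, [q, 1.0 - q])
    b_lo, b_hi = np.quantile(b, [q, 1.0 - q])
    return bool(a_hi < b_lo or b_hi < a_lo)
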