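"""Univariable proportional-odds (cumulative logit) regression.

The model for an ordinal outcome Y with levels 0..K and a scalar
predictor x is

    logit P(Y <= k | x) = c_k - beta * x,      c_0 < c_1 < ... < c_{K-1}

so a positive beta (odds ratio exp(beta) > 1) means higher predictor
values shift probability mass toward *higher* outcome levels.  One beta
shifts all K cumulative log-odds equally — the proportional-odds
assumption.

Fitting is by maximum likelihood: BFGS on a reparameterized surface
(c_0 and log-increments between consecutive cutpoints, which enforces
monotonicity), refined by Newton steps on the original parameters until
the gradient norm drops below 1e-8.  Standard errors come from the
inverse observed information; inference (CI, p) is Wald.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.special import expit, log_expit

__all__ = ["ProportionalOdds", "ProportionalOddsResults"]

_GTOL = 1e-8
_MAX_NEWTON = 200


def _pack(beta: float, cutpoints: np.ndarray) -> np.ndarray:
    """(beta, c) -> unconstrained theta via log-increments."""
    c = np.asarray(cutpoints, dtype=float)
    return np.concatenate([[beta, c[0]], np.log(np.diff(c))]) if len(c) > 1 else np.array([beta, c[0]])


def _unpack(theta: np.ndarray) -> tuple[float, np.ndarray]:
    beta = theta[0]
    c = np.empty(len(theta) - 1)
    c[0] = theta[1]
    if len(c) > 1:
        c[1:] = theta[1] + np.cumsum(np.exp(theta[2:]))
    return beta, c


class ProportionalOdds:
    """Cumulative-logit model of an ordinal outcome on one predictor.

    Parameters
    ----------
    endog : ordinal outcome levels (integers; any subset of 0..6 or a
        general ordered coding).  Unobserved intermediate levels are
        collapsed before fitting (with a note in the results) so the
        information matrix stays nonsingular.
    exog : predictor values, same length.

    Examples
    --------
    >>> model = ProportionalOdds.from_dataframe(df, y="mrs_90d", x="ffmf_percent")
    >>> res = model.fit()
    >>> res.odds_ratio, res.conf_int_or(), res.pvalue
    """

    def __init__(self, endog, exog):
        y = np.asarray(endog)
        x = np.asarray(exog, dtype=float)
        if y.shape != x.shape or y.ndim != 1:
            raise ValueError("endog and exog must be 1D and the same length")
        if not np.all(np.isfinite(x)):
            raise ValueError("exog contains non-finite values")
        yi = y.astype(int)
        if not np.all(yi == y):
            raise ValueError("endog must be integer-coded ordinal levels")
        levels = np.unique(yi)
        if len(levels) < 2:
            raise ValueError("need >= 2 distinct outcome levels")
        if len(yi) <= len(levels):
            raise ValueError("need n > number of parameters")
        self.endog_levels = levels                      # original codes, ascending
        self.collapsed = len(levels) < (levels.max() - levels.min() + 1)
        self._y = np.searchsorted(levels, yi)           # contiguous 0..m-1
        self._x = x
        self.n_cutpoints = len(levels) - 1

    @classmethod
    def from_dataframe(cls, data: pd.DataFrame, y: str, x: str) -> "ProportionalOdds":
        d = data[[y, x]].dropna()
        return cls(d[y].to_numpy(), d[x].to_numpy())

    # -- likelihood machinery ------------------------------------------------

    def _cell_logprob(self, beta: float, c: np.ndarray):
        """log P(Y = y_i) for every observation, plus the cumulative pieces."""
        eta = beta * self._x
        z = np.concatenate([[-np.inf], c])[self._y] - eta      # lower cut
        zu = np.concatenate([c, [np.inf]])[self._y] - eta      # upper cut
        # P = expit(zu) - expit(z); computed stably via expit differences
        p = expit(zu) - expit(z)
        return p, z, zu

    def loglike(self, beta: float, cutpoints: np.ndarray) -> float:
        p, _, _ = self._cell_logprob(beta, np.asarray(cutpoints, dtype=float))
        if np.any(p <= 0):
            return -np.inf
        return float(np.log(p).sum())

    def score(self, beta: float, cutpoints: np.ndarray) -> np.ndarray:
        """Analytic gradient of the log-likelihood in (beta, c_0..c_{K-1})."""
        c = np.asarray(cutpoints, dtype=float)
        p, z, zu = self._cell_logprob(beta, c)
        fu = expit(zu) * (1 - expit(zu))     # logistic pdf at upper cut
        fl = np.where(np.isneginf(z), 0.0, expit(z) * (1 - expit(z)))
        # guard against underflow at extreme trial parameters during line search
        inv_p = 1.0 / np.clip(p, 1e-300, None)
        g_beta = float(np.sum((-fu + fl) * self._x * inv_p))
        K = self.n_cutpoints
        g_c = np.zeros(K)
        upper_idx = self._y          # cutpoint index of the upper bound (K = none)
        lower_idx = self._y - 1      # cutpoint index of the lower bound (-1 = none)
        np.add.at(g_c, upper_idx[upper_idx < K], (fu * inv_p)[upper_idx < K])
        sel = lower_idx >= 0
        np.add.at(g_c, lower_idx[sel], (-fl * inv_p)[sel])
        return np.concatenate([[g_beta], g_c])

    def _negloglike_packed(self, theta: np.ndarray) -> float:
        beta, c = _unpack(theta)
        return -self.loglike(beta, c)

    def _neggrad_packed(self, theta: np.ndarray) -> np.ndarray:
        beta, c = _unpack(theta)
        g = self.score(beta, c)          # gradient in (beta, c)
        K = len(c)
        # chain rule to (beta, c0, log-increments)
        out = np.empty(1 + K)
        out[0] = g[0]
        out[1] = g[1:].sum()
        for j in range(1, K):
            out[1 + j] = g[1 + j:].sum() * np.exp(theta[1 + j])
        return -out

    def _hessian_fd(self, beta: float, c: np.ndarray, eps: float = 1e-6) -> np.ndarray:
        """Observed information by central differences of the analytic score."""
        theta = np.concatenate([[beta], c])
        k = len(theta)
        H = np.zeros((k, k))
        for i in range(k):
            tp, tm = theta.copy(), theta.copy()
            tp[i] += eps
            tm[i] -= eps
            gp = self.score(tp[0], tp[1:])
            gm = self.score(tm[0], tm[1:])
            H[i] = (gp - gm) / (2 * eps)
        return -0.5 * (H + H.T)          # symmetrized negative Hessian

    def _start(self) -> np.ndarray:
        """Intercept-only start: beta 0, cutpoints at empirical logits."""
        m = self.n_cutpoints + 1
        freq = np.bincount(self._y, minlength=m) / len(self._y)
        cum = np.clip(np.cumsum(freq)[:-1], 1e-4, 1 - 1e-4)
        return _pack(0.0, np.log(cum / (1 - cum)))

    # -- fitting -------------------------------------------------------------

    def fit(self, maxiter: int = _MAX_NEWTON, gtol: float = _GTOL) -> "ProportionalOddsResults":
        """Maximize the likelihood; returns a results object.

        Non-convergence or an ill-conditioned information matrix is
        reported through ``converged`` and ``diagnostics`` on the result,
        never silently.
        """
        res = optimize.minimize(
            self._negloglike_packed,
            self._start(),
            jac=self._neggrad_packed,
            method="BFGS",
            options={"gtol": gtol / 10, "maxiter": 500},
        )
        beta, c = _unpack(res.x)
        diagnostics: list[str] = []
        if self.collapsed:
            observed = ", ".join(map(str, self.endog_levels))
            diagnostics.append(
                f"empty outcome categories collapsed; observed levels: {observed}"
            )

        # Newton refinement on the original parameters
        n_iter = 0
        gnorm = np.linalg.norm(self.score(beta, c))
        for n_iter in range(1, maxiter + 1):
            if gnorm < gtol:
                break
            g = self.score(beta, c)
            H = self._hessian_fd(beta, c)
            try:
                step = np.linalg.solve(H, g)
            except np.linalg.LinAlgError:
                diagnostics.append("singular information matrix during refinement")
                break
            # damped step, keeping cutpoints ordered and likelihood finite
            lam = 1.0
            ll0 = self.loglike(beta, c)
            while lam > 1e-6:
                nb, nc = beta + lam * step[0], c + lam * step[1:]
                if np.all(np.diff(nc) > 0) and self.loglike(nb, nc) >= ll0 - 1e-10:
                    beta, c = nb, nc
                    break
                lam /= 2.0
            else:
                break
            gnorm = np.linalg.norm(self.score(beta, c))

        converged = bool(gnorm < gtol)
        if not converged:
            diagnostics.append(
                f"gradient norm {gnorm:.3g} after refinement (target {gtol:g}); "
                "possible separation or flat likelihood"
            )

        H = self._hessian_fd(beta, c)
        try:
            cov = np.linalg.inv(H)
            if np.any(np.diag(cov) <= 0):
                raise np.linalg.LinAlgError("non-positive variance")
        except np.linalg.LinAlgError:
            cov = np.full((len(c) + 1, len(c) + 1), np.nan)
            converged = False
            diagnostics.append(
                "observed information not invertible: complete or quasi-complete "
                "separation suspected; SEs unavailable"
            )
        ses = np.sqrt(np.diag(cov)) if np.all(np.isfinite(cov)) else np.array([np.inf])
        scale = max(1.0, np.std(self._x))
        if np.any(ses * scale > 50.0) or abs(beta) * scale > 20.0:
            diagnostics.append(
                "extreme coefficient or standard error: complete or quasi-complete "
                "separation likely; Wald inference unreliable"
            )
        return ProportionalOddsResults(
            model=self,
            beta=float(beta),
            cutpoints=c.copy(),
            cov_params=cov,
            llf=self.loglike(beta, c),
            llnull=self._llnull(),
            converged=converged,
            n_iter=n_iter,
            diagnostics=diagnostics,
        )

    def _llnull(self) -> float:
        """Log-likelihood of the intercepts-only (beta = 0) model — the
        multinomial MLE at the observed category frequencies."""
        m = self.n_cutpoints + 1
        counts = np.bincount(self._y, minlength=m)
        freq = counts / counts.sum()
        nz = counts > 0
        return float(np.sum(counts[nz] * np.log(freq[nz])))


@dataclass
class ProportionalOddsResults:
    """MLE results: coefficient, uncertainty, cutpoints, diagnostics."""

    model: ProportionalOdds
    beta: float
    cutpoints: np.ndarray
    cov_params: np.ndarray
    llf: float
    llnull: float
    converged: bool
    n_iter: int
    diagnostics: list = field(default_factory=list)

    @property
    def bse_beta(self) -> float:
        return float(np.sqrt(self.cov_params[0, 0]))

    @property
    def odds_ratio(self) -> float:
        """exp(beta): cumulative odds ratio per unit of the predictor."""
        return float(np.exp(self.beta))

    @property
    def pvalue(self) -> float:
        """Two-sided Wald p for beta = 0."""
        from scipy.stats import norm

        z = self.beta / self.bse_beta
        return float(2 * norm.sf(abs(z)))

    @property
    def lr_statistic(self) -> float:
        """Likelihood-ratio statistic vs the intercepts-only model."""
        return 2.0 * (self.llf - self.llnull)

    def conf_int(self, alpha: float = 0.05) -> tuple[float, float]:
        """Wald CI for beta."""
        from scipy.stats import norm

        z = norm.ppf(1 - alpha / 2)
        return (self.beta - z * self.bse_beta, self.beta + z * self.bse_beta)

    def conf_int_or(self, alpha: float = 0.05) -> tuple[float, float]:
        """Wald CI for the odds ratio (exponentiated beta interval)."""
        lo, hi = self.conf_int(alpha)
        return (float(np.exp(lo)), float(np.exp(hi)))

    def predict(self, x) -> np.ndarray:
        """Category probabilities at predictor values ``x``.

        Returns an (n, m) array over the *observed* outcome levels
        (``model.endog_levels``); rows are >= 0 and sum to 1.
        """
        x = np.atleast_1d(np.asarray(x, dtype=float))
        cum = expit(self.cutpoints[None, :] - self.beta * x[:, None])
        cum = np.hstack([np.zeros((len(x), 1)), cum, np.ones((len(x), 1))])
        return np.diff(cum, axis=1)

    def to_dict(self) -> dict:
        lo, hi = self.conf_int_or()
        return {
            "beta": self.beta,
            "se_beta": self.bse_beta,
            "odds_ratio": self.odds_ratio,
            "or_ci95": [lo, hi],
            "p_value": self.pvalue,
            "cutpoints": self.cutpoints.tolist(),
            "outcome_levels": self.model.endog_levels.tolist(),
            "log_likelihood": self.llf,
            "log_likelihood_null": self.llnull,
            "lr_statistic": self.lr_statistic,
            "converged": self.converged,
            "n_iter": self.n_iter,
            "diagnostics": list(self.diagnostics),
        }

    def summary(self) -> str:
        lo, hi = self.conf_int_or()
        lines = [
            "Proportional-odds (cumulative logit) regression",
            "  logit P(Y <= k | x) = c_k - beta * x   "
            "(beta > 0: higher x -> higher outcome levels)",
            f"  n = {len(self.model._y)}, outcome levels: "
            f"{self.model.endog_levels.tolist()}",
            f"  beta      = {self.beta:+.5f}  (SE {self.bse_beta:.5f})",
            f"  OR        = {self.odds_ratio:.4f}  "
            f"[95% CI {lo:.4f}, {hi:.4f}]",
            f"  p (Wald)  = {self.pvalue:.4g}",
            f"  cutpoints = {np.array2string(self.cutpoints, precision=3)}",
            f"  loglik    = {self.llf:.3f}  (null {self.llnull:.3f}, "
            f"LR {self.lr_statistic:.3f})",
            f"  converged = {self.converged} in {self.n_iter} Newton steps",
        ]
        for d in self.diagnostics:
            lines.append(f"  note: {d}")
        return "\n".join(lines)
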