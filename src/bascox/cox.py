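"""Cox proportional-hazards core: partial likelihood, Newton fitting, concordance.

Implements the semi-parametric Cox model from first principles: the negative
log partial likelihood with Breslow or Efron tie corrections (value, analytic
gradient and Hessian), a Newton–Raphson maximizer with step-halving and Wald
inference, and Harrell's concordance index for censored data.

Coefficients are log hazard ratios; ``exp(beta)`` is the hazard ratio per one
unit of the covariate (one SD when covariates are inverse-normal transformed).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats


class DegenerateDesignError(ValueError):
    """Raised when the design matrix cannot identify the coefficients."""


@dataclass
class SurvivalData:
    """Right-censored survival data: follow-up times, event flags, covariates.

    Parameters
    ----------
    time : array of positive follow-up times (years).
    event : array in {0, 1}; 1 = event observed, 0 = censored.
    X : (n, p) design matrix; no missing or non-finite cells.
    names : optional covariate labels.
    """

    time: np.ndarray
    event: np.ndarray
    X: np.ndarray
    names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.event = np.asarray(self.event, dtype=int)
        X = np.asarray(self.X, dtype=float)
        if X.ndim == 1:
            X = X[:, None]
        self.X = X
        n = self.time.shape[0]
        if self.event.shape[0] != n or self.X.shape[0] != n:
            raise ValueError("time, event and X must have equal length")
        if not np.all(np.isfinite(self.time)) or np.any(self.time <= 0):
            raise ValueError("times must be positive and finite")
        if not set(np.unique(self.event)) <= {0, 1}:
            raise ValueError("event indicators must be 0/1")
        if self.event.sum() < 1:
            raise ValueError("at least one event is required")
        if not np.all(np.isfinite(self.X)):
            raise ValueError("design matrix contains non-finite values")
        if not self.names:
            self.names = [f"x{j}" for j in range(self.X.shape[1])]

    @property
    def n(self) -> int:
        return self.time.shape[0]

    @property
    def p(self) -> int:
        return self.X.shape[1]


def _sorted_views(data: SurvivalData):
    """Return (order, time, event, X) sorted by ascending time, events first
    within a tie so tie groups are contiguous."""
    order = np.lexsort((1 - data.event, data.time))
    return order, data.time[order], data.event[order], data.X[order]


def neg_log_partial_likelihood(
    beta: np.ndarray,
    data: SurvivalData,
    ties: str = "efron",
    order: int = 2,
):
    """Negative log partial likelihood with analytic derivatives.

    Parameters
    ----------
    beta : coefficient vector (length p).
    data : survival data.
    ties : 'breslow' or 'efron' tie correction; identical when no ties exist.
    order : 0 returns the value only, 1 adds the gradient, 2 adds the Hessian.

    Returns
    -------
    value, or (value, grad), or (value, grad, hess) of -l(beta).
    """
    if ties not in ("breslow", "efron"):
        raise ValueError(f"unknown ties method {ties!r}")
    beta = np.asarray(beta, dtype=float)
    _, t, d, X = _sorted_views(data)
    n, p = X.shape
    eta = X @ beta
    if not np.all(np.isfinite(eta)):
        raise ValueError("non-finite linear predictor")
    # guard against overflow in exp for wildly diverging beta
    shift = eta.max()
    r = np.exp(eta - shift)
    rx = r[:, None] * X
    # suffix sums: risk set at time t = subjects with time >= t
    S0 = np.cumsum(r[::-1])[::-1]                       # (n,)
    S1 = np.cumsum(rx[::-1], axis=0)[::-1]              # (n, p)
    if order >= 2:
        rxx = rx[:, :, None] * X[:, None, :]
        S2 = np.cumsum(rxx[::-1], axis=0)[::-1]         # (n, p, p)

    value = 0.0
    grad = np.zeros(p)
    hess = np.zeros((p, p))
    i = 0
    while i < n:
        # tie group [i, j): equal times, events sorted first
        j = i + 1
        while j < n and t[j] == t[i]:
            j += 1
        dd = int(d[i:j].sum())
        if dd > 0:
            ev = slice(i, i + dd)  # events are first in the group
            s0, s1 = S0[i], S1[i]
            s2 = S2[i] if order >= 2 else None
            value -= eta[ev].sum() - dd * shift
            if ties == "breslow" or dd == 1:
                value += dd * np.log(s0)
                if order >= 1:
                    grad += dd * s1 / s0 - X[ev].sum(axis=0)
                if order >= 2:
                    hess += dd * (s2 / s0 - np.outer(s1, s1) / s0**2)
            else:
                e0 = r[ev].sum()
                e1 = rx[ev].sum(axis=0)
                e2 = rxx[ev].sum(axis=0) if order >= 2 else None
                for l in range(dd):
                    f = l / dd
                    z0 = s0 - f * e0
                    value += np.log(z0)
                    if order >= 1:
                        z1 = s1 - f * e1
                        grad += z1 / z0
                    if order >= 2:
                        z2 = s2 - f * e2
                        hess += z2 / z0 - np.outer(z1, z1) / z0**2
                if order >= 1:
                    grad -= X[ev].sum(axis=0)
        i = j
    if order == 0:
        return value
    if order == 1:
        return value, grad
    return value, grad, hess


@dataclass
class CoxPHResults:
    """Fitted Cox model: estimates, Wald inference and diagnostics."""

    params: np.ndarray
    cov_params: np.ndarray
    loglik: float
    names: list[str]
    ties: str
    iterations: int
    converged: bool
    diagnostics: str = ""
    n: int = 0
    n_events: int = 0

    @property
    def bse(self) -> np.ndarray:
        return np.sqrt(np.diag(self.cov_params))

    @property
    def hazard_ratios(self) -> np.ndarray:
        return np.exp(self.params)

    def conf_int(self, alpha: float = 0.05) -> np.ndarray:
        """(p, 2) array of HR confidence limits."""
        z = stats.norm.ppf(1 - alpha / 2)
        lo = np.exp(self.params - z * self.bse)
        hi = np.exp(self.params + z * self.bse)
        return np.column_stack([lo, hi])

    @property
    def pvalues(self) -> np.ndarray:
        with np.errstate(divide="ignore", invalid="ignore"):
            z = self.params / self.bse
        return 2 * stats.norm.sf(np.abs(z))

    def summary(self) -> str:
        ci = self.conf_int()
        lines = [
            f"Cox PH model  (n={self.n}, events={self.n_events}, "
            f"ties={self.ties}, loglik={self.loglik:.4f}, "
            f"converged={self.converged})",
            f"{'covariate':<16}{'coef':>10}{'HR':>10}{'se':>10}"
            f"{'HR 95% CI':>22}{'p':>12}",
        ]
        for k, name in enumerate(self.names):
            lines.append(
                f"{name:<16}{self.params[k]:>10.4f}{self.hazard_ratios[k]:>10.4f}"
                f"{self.bse[k]:>10.4f}"
                f"{'(%.3f, %.3f)' % (ci[k, 0], ci[k, 1]):>22}"
                f"{self.pvalues[k]:>12.3g}"
            )
        if self.diagnostics:
            lines.append(f"note: {self.diagnostics}")
        return "\n".join(lines)

    def to_dict(self) -> dict:
        ci = self.conf_int()
        return {
            "names": list(self.names),
            "coef": self.params.tolist(),
            "se": self.bse.tolist(),
            "hr": self.hazard_ratios.tolist(),
            "hr_ci_low": ci[:, 0].tolist(),
            "hr_ci_high": ci[:, 1].tolist(),
            "p": self.pvalues.tolist(),
            "loglik": self.loglik,
            "ties": self.ties,
            "converged": self.converged,
            "diagnostics": self.diagnostics,
            "n": self.n,
            "n_events": self.n_events,
        }


class CoxPH:
    """Unpenalized Cox proportional-hazards model.

    ``CoxPH(data).fit()`` maximizes the partial likelihood by Newton–Raphson
    with step-halving; Wald standard errors come from the inverse observed
    information. Monotone-likelihood divergence (perfect separation) is
    flagged, not silently returned.
    """

    def __init__(self, data: SurvivalData, ties: str = "efron"):
        if ties not in ("breslow", "efron"):
            raise ValueError(f"unknown ties method {ties!r}")
        sd = np.std(data.X, axis=0)
        if np.any(sd == 0):
            bad = [data.names[j] for j in np.where(sd == 0)[0]]
            raise DegenerateDesignError(f"constant column(s): {bad}")
        self.data = data
        self.ties = ties

    @classmethod
    def from_dataframe(cls, df, duration_col: str, event_col: str,
                       covariates: Sequence[str], ties: str = "efron") -> "CoxPH":
        data = SurvivalData(
            time=df[duration_col].to_numpy(),
            event=df[event_col].to_numpy(),
            X=df[list(covariates)].to_numpy(dtype=float),
            names=list(covariates),
        )
        return cls(data, ties=ties)

    def fit(
        self,
        max_iter: int = 100,
        score_tol: float = 1e-9,
        loglik_rtol: float = 1e-10,
        beta_escape: float = 20.0,
    ) -> CoxPHResults:
        data, ties = self.data, self.ties
        p = data.p
        beta = np.zeros(p)
        nll, grad, hess = neg_log_partial_likelihood(beta, data, ties)
        converged = False
        diagnostics = ""
        it = 0
        for it in range(1, max_iter + 1):
            try:
                step = np.linalg.solve(hess, grad)
            except np.linalg.LinAlgError:
                diagnostics = "singular information matrix"
                break
            # step-halving to guarantee monotone improvement
            t_step = 1.0
            for _ in range(30):
                cand = beta - t_step * step
                cand_nll = neg_log_partial_likelihood(cand, data, ties, order=0)
                if cand_nll <= nll + 1e-14:
                    break
                t_step /= 2
            new_nll, grad, hess = neg_log_partial_likelihood(cand, data, ties)
            rel = abs(new_nll - nll) / max(1.0, abs(nll))
            beta, nll = cand, new_nll
            if np.max(np.abs(beta)) > beta_escape:
                diagnostics = (
                    "monotone likelihood: coefficient diverging "
                    "(possible perfect separation)"
                )
                break
            if np.max(np.abs(grad)) < score_tol or rel < loglik_rtol:
                converged = True
                break
        try:
            cov = np.linalg.inv(hess)
        except np.linalg.LinAlgError:
            cov = np.full((p, p), np.nan)
        return CoxPHResults(
            params=beta,
            cov_params=cov,
            loglik=-nll,
            names=list(data.names),
            ties=ties,
            iterations=it,
            converged=converged,
            diagnostics=diagnostics,
            n=data.n,
            n_events=int(data.event.sum()),
        )


def fit_cox(data: SurvivalData, ties: str = "efron", **kwargs) -> CoxPHResults:
    """Functional wrapper around :class:`CoxPH`."""
    return CoxPH(data, ties=ties).fit(**kwargs)


def concordance_index(risk: np.ndarray, time: np.ndarray, event: np.ndarray) -> float:
    """Harrell's C-index for right-censored data.

    A pair (i, j) is comparable when the subject with the shorter time had an
    event (including equal times where exactly one subject had the event).
    Concordant pairs — higher risk fails first — score 1, tied risks score
    0.5. Returns concordant / comparable in [0, 1].
    """
    risk = np.asarray(risk, dtype=float)
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    if not (len(risk) == len(time) == len(event)):
        raise ValueError("risk, time, event must have equal length")
    # pairwise masks; fine for the cohort sizes this pipeline handles
    ti, tj = time[:, None], time[None, :]
    di = event[:, None].astype(bool)
    dj = event[None, :].astype(bool)
    comparable = (ti < tj) & di
    comparable |= (ti == tj) & di & ~dj
    n_comp = comparable.sum()
    if n_comp == 0:
        raise ValueError("no comparable pairs")
    ri, rj = risk[:, None], risk[None, :]
    score = np.where(ri > rj, 1.0, np.where(ri == rj, 0.5, 0.0))
    return float((score * comparable).sum() / n_comp)
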