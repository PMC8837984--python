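"""Cox proportional-hazards engine for counting-process (start, stop] data.

Implements the log partial likelihood, its analytic score and Hessian,
and a Newton solver with step-halving, for right-censored data with
time-varying covariates encoded as risk intervals.  Breslow tie handling
is the default; Efron is available.  A column can additionally be entered
as ``x * log(t)`` (evaluated exactly at each event time), which is how
the proportional-hazards check is carried out.

The risk set at an event time t is {rows : start < t <= stop}.  For the
plain (time-fixed-within-row) model the risk-set aggregates S0, S1, S2
are obtained from suffix cumulative sums over rows sorted by start and
stop, so one likelihood/score/Hessian evaluation is O(n p^2) independent
of the number of events.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats


class ConvergenceError(RuntimeError):
    """Newton iteration failed to converge; carries the iteration log."""

    def __init__(self, message, history):
        super().__init__(message)
        self.history = history


@dataclass
class CoxFit:
    params: np.ndarray
    se: np.ndarray
    cov: np.ndarray
    loglik: float
    n_events: int
    n_rows: int
    n_iter: int
    names: list

    def hazard_ratios(self):
        return np.exp(self.params)

    def confint(self, alpha: float = 0.05):
        z = stats.norm.ppf(1 - alpha / 2)
        with np.errstate(over="ignore"):  # near-empty quintiles give huge SEs
            return np.exp(self.params - z * self.se), np.exp(self.params + z * self.se)

    def wald_z(self):
        return self.params / self.se

    def wald_p(self):
        return 2 * stats.norm.sf(np.abs(self.wald_z()))

    def summary(self):
        import pandas as pd

        lo, hi = self.confint()
        return pd.DataFrame(
            {
                "coef": self.params,
                "hr": self.hazard_ratios(),
                "se": self.se,
                "hr_ci_low": lo,
                "hr_ci_high": hi,
                "z": self.wald_z(),
                "p": self.wald_p(),
            },
            index=self.names,
        )


class CoxPartialLikelihood:
    """Log partial likelihood and derivatives on a counting-process table.

    Parameters
    ----------
    start, stop, event
        Risk-interval arrays; event flags must be 0/1 and an event row
        contributes a death at its stop time.
    X
        Covariate matrix (n_rows x p), constant within each interval.
    ties
        "breslow" (default) or "efron".
    log_time_idx
        Optional column index entered additionally as ``X[:, idx] *
        log(t)`` with t the current event time (appends one coefficient).
    """

    def __init__(self, start, stop, event, X, ties="breslow", log_time_idx=None):
        self.start = np.asarray(start, dtype=float)
        self.stop = np.asarray(stop, dtype=float)
        self.event = np.asarray(event, dtype=int)
        self.X = np.atleast_2d(np.asarray(X, dtype=float))
        if self.X.shape[0] != self.start.size:
            raise ValueError("X rows must match number of intervals")
        if np.any(self.stop <= self.start):
            raise ValueError("intervals must satisfy start < stop")
        if ties not in ("breslow", "efron"):
            raise ValueError(f"unknown tie method {ties!r}")
        self.ties = ties
        self.log_time_idx = log_time_idx
        if log_time_idx is not None and ties == "efron":
            raise NotImplementedError("log-time interaction requires Breslow ties")
        self.n, self.p = self.X.shape
        self.n_events = int(self.event.sum())
        if self.n_events == 0:
            raise ValueError("no events in the risk table")

        died = self.event == 1
        self.event_times, inv = np.unique(self.stop[died], return_inverse=True)
        m = self.event_times.size
        # per-event-time death counts and covariate sums
        self.d = np.bincount(inv, minlength=m).astype(float)
        Xd = self.X[died]
        self.sum_x_d = np.zeros((m, self.p))
        np.add.at(self.sum_x_d, inv, Xd)
        self._death_groups = [np.flatnonzero(inv == j) for j in range(m)]
        self._Xd = Xd
        # sort orders for the suffix-cumsum fast path
        self._ord_stop = np.argsort(self.stop, kind="mergesort")
        self._ord_start = np.argsort(self.start, kind="mergesort")
        self._stop_sorted = self.stop[self._ord_stop]
        self._start_sorted = self.start[self._ord_start]
        self._idx_stop = np.searchsorted(self._stop_sorted, self.event_times, "left")
        self._idx_start = np.searchsorted(self._start_sorted, self.event_times, "left")

    @property
    def n_params(self) -> int:
        return self.p + (1 if self.log_time_idx is not None else 0)

    # ---------- risk-set aggregates ----------
    def _aggregates(self, beta):
        """S0 (m,), S1 (m,p), S2 (m,p,p) at each event time."""
        eta = self.X @ beta
        c = eta.max()
        e = np.exp(eta - c)
        m = self.event_times.size

        def suffix(arr, order, idx):
            s = np.cumsum(arr[order][::-1], axis=0)[::-1]
            # pad so idx == n gives 0
            pad = np.zeros((1,) + arr.shape[1:])
            s = np.concatenate([s, pad], axis=0)
            return s[idx]

        ex = e[:, None] * self.X
        exx = ex[:, :, None] * self.X[:, None, :]
        S0 = suffix(e[:, None], self._ord_stop, self._idx_stop)[:, 0] - suffix(
            e[:, None], self._ord_start, self._idx_start
        )[:, 0]
        S1 = suffix(ex, self._ord_stop, self._idx_stop) - suffix(
            ex, self._ord_start, self._idx_start
        )
        S2 = suffix(exx, self._ord_stop, self._idx_stop) - suffix(
            exx, self._ord_start, self._idx_start
        )
        # guard tiny negative round-off in S0
        S0 = np.maximum(S0, 1e-300)
        sum_eta_d = float((self.sum_x_d.sum(axis=0) @ beta))
        return e, c, S0, S1, S2, sum_eta_d

    def _efron_terms(self, beta, e):
        """Per-event-time aggregates over the death set (for Efron)."""
        m = self.event_times.size
        S0d = np.zeros(m)
        S1d = np.zeros((m, self.p))
        S2d = np.zeros((m, self.p, self.p))
        died = self.event == 1
        ed = e[died]
        for j, g in enumerate(self._death_groups):
            w = ed[g]
            Xg = self._Xd[g]
            S0d[j] = w.sum()
            S1d[j] = w @ Xg
            S2d[j] = (w[:, None] * Xg).T @ Xg
        return S0d, S1d, S2d

    def _derivs_fast(self, beta):
        e, c, S0, S1, S2, sum_eta_d = self._aggregates(beta)
        ll = float(sum_eta_d - (self.d * (np.log(S0) + c)).sum())
        xbar = S1 / S0[:, None]
        grad = (self.sum_x_d - self.d[:, None] * xbar).sum(axis=0)
        hess = -(
            (S2 / S0[:, None, None] - xbar[:, :, None] * xbar[:, None, :])
            * self.d[:, None, None]
        ).sum(axis=0)
        return ll, grad, hess

    def _derivs_logtime(self, beta):
        """General path: the last coefficient multiplies x_int * log(t_j)."""
        b = beta[: self.p]
        theta = beta[self.p]
        xint = self.X[:, self.log_time_idx]
        eta = self.X @ b
        logt = np.log(self.event_times)
        died = self.event == 1
        ll = 0.0
        grad = np.zeros(self.p + 1)
        hess = np.zeros((self.p + 1, self.p + 1))
        for j, t in enumerate(self.event_times):
            at_risk = (self.start < t) & (self.stop >= t)
            zj = xint * logt[j]
            eta_j = eta + theta * zj
            cj = eta_j[at_risk].max()
            e = np.where(at_risk, np.exp(eta_j - cj), 0.0)
            s0 = e.sum()
            Z = np.concatenate([self.X, zj[:, None]], axis=1)
            s1 = e @ Z
            s2 = (e[:, None] * Z).T @ Z
            g = self._death_groups[j]
            didx = np.flatnonzero(died)[g]
            ll += eta_j[didx].sum() - self.d[j] * (np.log(s0) + cj)
            xbar = s1 / s0
            grad += Z[didx].sum(axis=0) - self.d[j] * xbar
            hess -= self.d[j] * (s2 / s0 - np.outer(xbar, xbar))
        return float(ll), grad, hess

    def loglik_grad_hess(self, beta):
        beta = np.asarray(beta, dtype=float)
        if beta.size != self.n_params:
            raise ValueError(f"expected {self.n_params} parameters, got {beta.size}")
        if self.log_time_idx is not None:
            return self._derivs_logtime(beta)
        if self.ties == "efron":
            return self._derivs_efron(beta)
        return self._derivs_fast(beta)

    def _derivs_efron(self, beta):
        e, c, S0, S1, S2, sum_eta_d = self._aggregates(beta)
        S0d, S1d, S2d = self._efron_terms(beta, e)
        ll = float(sum_eta_d)
        grad = self.sum_x_d.sum(axis=0).astype(float)
        hess = np.zeros((self.p, self.p))
        for j in range(self.event_times.size):
            d = int(self.d[j])
            for l in range(d):
                f = l / d
                s0 = S0[j] - f * S0d[j]
                s1 = S1[j] - f * S1d[j]
                s2 = S2[j] - f * S2d[j]
                ll -= np.log(s0) + c
                xbar = s1 / s0
                grad -= xbar
                hess -= s2 / s0 - np.outer(xbar, xbar)
        return ll, grad, hess

    def loglik(self, beta) -> float:
        return self.loglik_grad_hess(beta)[0]

    def score(self, beta) -> np.ndarray:
        return self.loglik_grad_hess(beta)[1]

    def hessian(self, beta) -> np.ndarray:
        return self.loglik_grad_hess(beta)[2]

    # ---------- Newton solver ----------
    def fit(
        self,
        names=None,
        init=None,
        tol: float = 1e-9,
        max_iter: int = 100,
        ridge_on_singular: float = 1e-8,
    ) -> CoxFit:
        """Maximize the log partial likelihood by Newton iteration.

        Converges when the relative change in log likelihood falls below
        ``tol``; overshooting steps are halved (up to 30 times).
        """
        k = self.n_params
        beta = np.zeros(k) if init is None else np.asarray(init, dtype=float).copy()
        ll, grad, hess = self.loglik_grad_hess(beta)
        history = [ll]
        for it in range(1, max_iter + 1):
            try:
                step = np.linalg.solve(-hess, grad)
            except np.linalg.LinAlgError:
                step = np.linalg.solve(
                    -hess + ridge_on_singular * np.eye(k), grad
                )
            scale = 1.0
            for _ in range(30):
                cand = beta + scale * step
                ll_new = self.loglik(cand)
                if np.isfinite(ll_new) and ll_new >= ll - 1e-12:
                    break
                scale *= 0.5
            else:
                if np.isfinite(ll_new) and abs(ll_new - ll) <= 1e-8 * (abs(ll) + 1):
                    break  # flat likelihood: no step improves, accept current beta
                raise ConvergenceError(
                    "step-halving failed to improve the partial likelihood", history
                )
            beta = cand
            ll_prev = ll
            ll, grad, hess = self.loglik_grad_hess(beta)
            history.append(ll)
            if abs(ll - ll_prev) <= tol * (abs(ll_prev) + tol):
                break
        else:
            raise ConvergenceError(
                f"Newton iteration did not converge in {max_iter} iterations "
                f"(log-likelihood path: {history[-5:]})",
                history,
            )
        cov = np.linalg.inv(-hess)
        se = np.sqrt(np.diag(cov))
        if names is None:
            names = [f"x{i}" for i in range(self.p)]
        if self.log_time_idx is not None:
            names = list(names) + [f"{names[self.log_time_idx]}:log(t)"]
        return CoxFit(
            params=beta,
            se=se,
            cov=cov,
            loglik=ll,
            n_events=self.n_events,
            n_rows=self.n,
            n_iter=it,
            names=list(names),
        )
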