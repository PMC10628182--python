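"""Three-component circular mixture of report errors (Bays-type model).

Report errors e (radians, target-relative) are modelled as

    p(e) = pT * VM(e; 0, kappa) + pN * mean_j VM(e - delta_j; 0, kappa) + pU / 2pi

where delta_j are the non-target offsets of the trial (the non-target's
position expressed as a target-relative error) and a single concentration
kappa is shared by the target and non-target components.  Fitted by
expectation-maximization with closed-form weight updates and Newton inversion
of A(kappa) = I1(kappa)/I0(kappa) for kappa.
"""

from __future__ import annotations

import numpy as np
from scipy import special
from sklearn.base import BaseEstimator

from .wheel import TWO_PI
from .fokker_planck import solve_kappa

KAPPA_CAP = 1e4


def _vm_logpdf(x, kappa):
    return kappa * (np.cos(x) - 1.0) - np.log(TWO_PI * special.i0e(kappa))


def mixture_loglik(kappa, p_target, p_nontarget, p_uniform, errors, nontarget_offsets=None):
    """Log-likelihood of the three-component mixture at fixed parameters.

    ``nontarget_offsets`` is an (n,) array of non-target-relative positions
    (NaN where a trial has no non-target) or None for target-only data.
    """
    errors = np.asarray(errors, dtype=float)
    dens = p_target * np.exp(_vm_logpdf(errors, kappa)) + p_uniform / TWO_PI
    if nontarget_offsets is not None and p_nontarget > 0:
        off = np.asarray(nontarget_offsets, dtype=float)
        has = ~np.isnan(off)
        nt = np.zeros_like(errors)
        nt[has] = np.exp(_vm_logpdf(off[has], kappa))
        dens = dens + p_nontarget * nt
    return float(np.sum(np.log(np.maximum(dens, 1e-300))))


class VonMisesMixture(BaseEstimator):
    """EM fit of the target / non-target / uniform response mixture.

    Parameters
    ----------
    n_restarts : int
        EM restarts from stratified starting weights; the best final
        log-likelihood wins.
    tol : float
        Relative log-likelihood change declaring convergence.
    max_iter : int
        Iteration cap per restart.
    random_state : int
        Seed for the (deterministic) restart jitter.

    Attributes
    ----------
    kappa_ : float
        Shared von Mises concentration (capped at 1e4 for degenerate data).
    p_target_, p_nontarget_, p_uniform_ : float
        Component probabilities; sum to 1.  ``p_nontarget_`` is forced to 0
        when no trial carries a non-target offset.
    loglik_ : float
        Final log-likelihood (non-decreasing across EM iterations).
    responsibilities_ : ndarray of shape (n, 3)
        Posterior component probabilities per trial (target, non-target,
        uniform).
    n_iter_ : int, converged_ : bool
    """

    def __init__(self, n_restarts: int = 5, tol: float = 1e-8, max_iter: int = 500, random_state: int = 0):
        self.n_restarts = n_restarts
        self.tol = tol
        self.max_iter = max_iter
        self.random_state = random_state

    def fit(self, errors, nontarget_offsets=None):
        errors = np.asarray(errors, dtype=float).ravel()
        n = len(errors)
        if n < 10:
            raise ValueError(f"need at least 10 trials, got {n}")
        if nontarget_offsets is None:
            off = np.full(n, np.nan)
        else:
            off = np.asarray(nontarget_offsets, dtype=float).ravel()
            if len(off) != n:
                raise ValueError("nontarget_offsets must align with errors")
        allow_nt = bool(np.any(~np.isnan(off)))

        rng = np.random.default_rng(self.random_state)
        starts = [(0.6, 0.2 if allow_nt else 0.0, 0.2 if allow_nt else 0.4, 5.0)]
        for _ in range(self.n_restarts - 1):
            w = rng.dirichlet([2.0, 1.0 if allow_nt else 1e-6, 1.0])
            starts.append((w[0], w[1] if allow_nt else 0.0, w[2] + (0 if allow_nt else w[1]), float(rng.uniform(1, 20))))

        best = None
        for pT0, pN0, pU0, k0 in starts:
            fitres = self._em(errors, off, allow_nt, pT0, pN0, pU0, k0)
            if best is None or fitres["loglik"] > best["loglik"]:
                best = fitres
        self.kappa_ = best["kappa"]
        self.p_target_ = best["pT"]
        self.p_nontarget_ = best["pN"]
        self.p_uniform_ = best["pU"]
        self.loglik_ = best["loglik"]
        self.n_iter_ = best["n_iter"]
        self.converged_ = best["converged"]
        self.loglik_trace_ = best["trace"]
        self.responsibilities_ = best["resp"]
        return self

    def _em(self, errors, off, allow_nt, pT, pN, pU, kappa):
        n = len(errors)
        has_nt = ~np.isnan(off)
        # off already holds the response's deviation from the non-target
        shifted = np.where(has_nt, off, 0.0)
        trace = []
        prev = -np.inf
        converged = False
        for it in range(1, self.max_iter + 1):
            # E-step: responsibilities
            dT = pT * np.exp(_vm_logpdf(errors, kappa))
            dN = np.where(has_nt, pN * np.exp(_vm_logpdf(shifted, kappa)), 0.0) if allow_nt else np.zeros(n)
            dU = np.full(n, pU / TWO_PI)
            tot = np.maximum(dT + dN + dU, 1e-300)
            ll = float(np.sum(np.log(tot)))
            trace.append(ll)
            rT, rN, rU = dT / tot, dN / tot, dU / tot
            if ll - prev < self.tol * abs(ll) and it > 1:
                converged = True
                break
            prev = ll
            # M-step: closed-form weights, kappa via Bessel-ratio inversion
            pT = float(rT.mean())
            pN = float(rN.mean()) if allow_nt else 0.0
            pU = max(1.0 - pT - pN, 1e-12)
            wsum = rT.sum() + rN.sum()
            if wsum > 1e-12:
                c = float(np.sum(rT * np.cos(errors)) + np.sum(rN * np.cos(shifted)))
                s = float(np.sum(rT * np.sin(errors)) + np.sum(rN * np.sin(shifted)))
                rbar = np.hypot(c, s) / wsum
                kappa = solve_kappa(min(rbar, 1 - 1e-12), cap=KAPPA_CAP)
        resp = np.stack([rT, rN, rU], axis=1)
        return {
            "kappa": kappa, "pT": pT, "pN": pN, "pU": pU,
            "loglik": trace[-1], "n_iter": it, "converged": converged,
            "trace": np.array(trace), "resp": resp,
        }

    def score(self, errors, nontarget_offsets=None) -> float:
        """Log-likelihood of data under the fitted parameters."""
        return mixture_loglik(
            self.kappa_, self.p_target_, self.p_nontarget_, self.p_uniform_,
            errors, nontarget_offsets,
        )

    def to_dict(self) -> dict:
        return {
            "kappa": self.kappa_, "p_target": self.p_target_,
            "p_nontarget": self.p_nontarget_, "p_uniform": self.p_uniform_,
            "loglik": self.loglik_, "n_iter": self.n_iter_, "converged": self.converged_,
        }


def fit_mixture(errors, nontarget_offsets=None, **kwargs) -> VonMisesMixture:
    """Functional wrapper over :class:`VonMisesMixture`."""
    return VonMisesMixture(**kwargs).fit(errors, nontarget_offsets)


def swap_error_rate(fit: VonMisesMixture) -> dict:
    """Swap-error quantification from a fitted load-2 mixture.

    Returns both the mixture weight ``p_nontarget`` and the posterior count:
    the fraction of trials whose non-target responsibility exceeds both the
    target and uniform responsibilities.
    """
    resp = fit.responsibilities_
    posterior = float(np.mean((resp[:, 1] > resp[:, 0]) & (resp[:, 1] > resp[:, 2])))
    return {"p_nontarget": fit.p_nontarget_, "posterior_fraction": posterior}


def vonmises_mle_kappa(angles) -> float:
    """Closed-form von Mises concentration MLE A^-1(Rbar) (no mixture)."""
    angles = np.asarray(angles, dtype=float)
    rbar = float(np.hypot(np.cos(angles).sum(), np.sin(angles).sum()) / len(angles))
    return solve_kappa(rbar, cap=KAPPA_CAP)
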