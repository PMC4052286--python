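"""Internal maximum-likelihood engine for covariance/mean structure models.

One quasi-Newton problem class serves both single-group fits and
multi-group fits with equality constraints.  The parameter vector theta
stacks, per sharing block: free path coefficients (row-major over the
beta mask), log error variances (positivity enforced by the log scale),
free error covariances (upper triangle, row-major) and, when the mean
structure is on, structural intercepts nu with implied means
mu = (I - B)^-1 nu.

The fitted discrepancy is the multi-group ML objective

    Q(theta) = sum_g n_g * [ log|Sigma_g| + tr(S_g Sigma_g^-1)
                             + (ybar_g - mu_g)' Sigma_g^-1 (ybar_g - mu_g)
                             - log|S_g| - p ]

which equals -2 log LR against the saturated model (sample covariances
use the ML divisor n_g).  Gradients are analytic; the observed
information is a finite-difference Hessian of Q/2 and the expected
(Fisher) information has the usual closed form in dSigma/dtheta.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from numpy.linalg import LinAlgError
from scipy import optimize
from scipy.linalg import cho_factor, cho_solve

from .errors import ConvergenceError
from .model import PathModel

_BIG = 1e12


@dataclass
class GroupMoments:
    """Sufficient statistics of one sample: n, ML covariance, mean."""

    n: int
    S: np.ndarray
    ybar: np.ndarray | None
    logdetS: float


def moments_from_data(X: np.ndarray, mean_structure: bool) -> GroupMoments:
    X = np.asarray(X, dtype=float)
    if X.ndim != 2:
        raise ValueError("data must be a 2-D samples x variables array")
    if np.isnan(X).any():
        keep = ~np.isnan(X).any(axis=1)
        dropped = int((~keep).sum())
        import warnings

        warnings.warn(f"listwise deletion removed {dropped} incomplete sample(s)")
        X = X[keep]
    n, p = X.shape
    if n < 2:
        raise ValueError("need at least 2 complete samples")
    ybar = X.mean(axis=0)
    Xc = X - ybar
    S = Xc.T @ Xc / n
    sign, logdetS = np.linalg.slogdet(S)
    if sign <= 0:
        raise ValueError("sample covariance matrix is not positive definite")
    return GroupMoments(n=n, S=S, ybar=ybar if mean_structure else None, logdetS=logdetS)


def moments_from_cov(S: np.ndarray, n: int, ybar: np.ndarray | None = None) -> GroupMoments:
    S = np.asarray(S, dtype=float)
    sign, logdetS = np.linalg.slogdet(S)
    if sign <= 0:
        raise ValueError("sample covariance matrix is not positive definite")
    return GroupMoments(n=int(n), S=S, ybar=None if ybar is None else np.asarray(ybar, float), logdetS=logdetS)


class MLProblem:
    """ML discrepancy, gradient and information for a (multi-)group path model.

    ``share_cov`` ties all beta/psi parameters across groups; ``share_nu``
    ties the intercepts.  With a single group the sharing flags are inert.
    """

    def __init__(
        self,
        model: PathModel,
        groups: Sequence[GroupMoments],
        mean_structure: bool | None = None,
        share_cov: bool = True,
        share_nu: bool = True,
    ) -> None:
        self.model = model
        self.groups = list(groups)
        self.G = len(self.groups)
        self.p = model.p
        self.mean_structure = (
            model.mean_structure if mean_structure is None else bool(mean_structure)
        )
        if self.mean_structure and any(g.ybar is None for g in self.groups):
            raise ValueError("mean structure requested but group means unavailable")
        self.share_cov = bool(share_cov) or self.G == 1
        self.share_nu = bool(share_nu) or self.G == 1

        p = self.p
        bi, bj = np.nonzero(model.beta_free)
        self.beta_rows, self.beta_cols = bi, bj
        oi, oj = np.nonzero(np.triu(model.psi_free, k=1))
        self.psio_rows, self.psio_cols = oi, oj
        self.n_beta = bi.size
        self.n_psio = oi.size
        self.block_cov = self.n_beta + p + self.n_psio

        # Global parameter layout: cov blocks first, then nu blocks.
        self.keys: list[tuple] = []
        cov_blocks = [None] if self.share_cov else list(range(self.G))
        for blk in cov_blocks:
            self.keys += [("beta", int(i), int(j), blk) for i, j in zip(bi, bj)]
            self.keys += [("psi_d", int(i), int(i), blk) for i in range(p)]
            self.keys += [("psi_o", int(i), int(j), blk) for i, j in zip(oi, oj)]
        self._cov_offset = {}
        for g in range(self.G):
            blk = 0 if self.share_cov else g
            self._cov_offset[g] = blk * self.block_cov if not self.share_cov else 0
        n_cov_total = len(self.keys)
        self._nu_offset = {}
        if self.mean_structure:
            nu_blocks = [None] if self.share_nu else list(range(self.G))
            for k, blk in enumerate(nu_blocks):
                self.keys += [("nu", int(i), int(i), blk) for i in range(p)]
            for g in range(self.G):
                blk = 0 if self.share_nu else g
                self._nu_offset[g] = n_cov_total + blk * p
        self.T = len(self.keys)

    # -- parameter access ---------------------------------------------
    def key_index(self) -> dict:
        return {k: i for i, k in enumerate(self.keys)}

    def _slices(self, g: int):
        o = self._cov_offset[g]
        sl_beta = slice(o, o + self.n_beta)
        sl_psid = slice(o + self.n_beta, o + self.n_beta + self.p)
        sl_psio = slice(o + self.n_beta + self.p, o + self.block_cov)
        sl_nu = None
        if self.mean_structure:
            on = self._nu_offset[g]
            sl_nu = slice(on, on + self.p)
        return sl_beta, sl_psid, sl_psio, sl_nu

    def matrices(self, theta: np.ndarray, g: int):
        """(B, Psi, nu) for group g at theta."""
        p = self.p
        sl_beta, sl_psid, sl_psio, sl_nu = self._slices(g)
        B = np.zeros((p, p))
        B[self.beta_rows, self.beta_cols] = theta[sl_beta]
        Psi = np.zeros((p, p))
        np.fill_diagonal(Psi, np.exp(theta[sl_psid]))
        Psi[self.psio_rows, self.psio_cols] = theta[sl_psio]
        Psi[self.psio_cols, self.psio_rows] = theta[sl_psio]
        nu = theta[sl_nu].copy() if sl_nu is not None else None
        return B, Psi, nu

    # -- objective ------------------------------------------------------
    def value_and_grad(self, theta: np.ndarray):
        p = self.p
        I = np.eye(p)
        f_total = 0.0
        grad = np.zeros(self.T)
        for g, gm in enumerate(self.groups):
            sl_beta, sl_psid, sl_psio, sl_nu = self._slices(g)
            B, Psi, nu = self.matrices(theta, g)
            try:
                A = np.linalg.solve(I - B, I)
            except LinAlgError:
                return _BIG, np.zeros(self.T)
            Sigma = A @ Psi @ A.T
            try:
                c, low = cho_factor((Sigma + Sigma.T) / 2.0)
            except LinAlgError:
                return _BIG, np.zeros(self.T)
            logdet = 2.0 * np.log(np.diag(c)).sum()
            P = cho_solve((c, low), I)  # Sigma^-1
            fg = logdet + float((P * gm.S).sum()) - gm.logdetS - p
            W = P - P @ gm.S @ P
            if self.mean_structure:
                mu = A @ nu
                r = gm.ybar - mu
                q = P @ r
                fg += float(r @ q)
                W = W - np.outer(q, q)
            f_total += gm.n * fg

            SWA = Sigma @ W @ A
            G_beta = 2.0 * SWA.T  # indexed [target i, source j]
            M = A.T @ W @ A
            if self.mean_structure:
                Aq = A.T @ q
                G_beta = G_beta + np.outer(-2.0 * Aq, mu)
                np.add.at(grad, np.arange(sl_nu.start, sl_nu.stop), gm.n * (-2.0 * Aq))
            np.add.at(
                grad,
                np.arange(sl_beta.start, sl_beta.stop),
                gm.n * G_beta[self.beta_rows, self.beta_cols],
            )
            np.add.at(
                grad,
                np.arange(sl_psid.start, sl_psid.stop),
                gm.n * np.diag(M) * np.exp(theta[sl_psid]),
            )
            if self.n_psio:
                np.add.at(
                    grad,
                    np.arange(sl_psio.start, sl_psio.stop),
                    gm.n * 2.0 * M[self.psio_rows, self.psio_cols],
                )
        return f_total, grad

    # -- starting values -------------------------------------------------
    def start_values(self) -> np.ndarray:
        """Per-equation OLS starts (exact MLE for recursive diagonal models)."""
        theta = np.zeros(self.T)
        p = self.p
        wsum = float(sum(g.n for g in self.groups))
        cov_blocks = [None] if self.share_cov else list(range(self.G))
        for blk in cov_blocks:
            if blk is None:
                S = sum(g.n * g.S for g in self.groups) / wsum
            else:
                S = self.groups[blk].S
            B = np.zeros((p, p))
            for i in range(p):
                parents = self.beta_cols[self.beta_rows == i]
                if parents.size:
                    Spp = S[np.ix_(parents, parents)]
                    try:
                        B[i, parents] = np.linalg.solve(
                            Spp + 1e-10 * np.eye(parents.size), S[parents, i]
                        )
                    except LinAlgError:
                        pass
            R = (np.eye(p) - B) @ S @ (np.eye(p) - B).T
            psid = np.maximum(np.diag(R), 0.05 * np.diag(S))
            off = self._cov_offset[blk or 0] if blk is not None else 0
            theta[off : off + self.n_beta] = B[self.beta_rows, self.beta_cols]
            theta[off + self.n_beta : off + self.n_beta + p] = np.log(psid)
            if self.n_psio:
                theta[off + self.n_beta + p : off + self.block_cov] = R[
                    self.psio_rows, self.psio_cols
                ]
        if self.mean_structure:
            nu_blocks = [None] if self.share_nu else list(range(self.G))
            for blk in nu_blocks:
                if blk is None:
                    ybar = sum(g.n * g.ybar for g in self.groups) / wsum
                    gref = 0
                else:
                    ybar = self.groups[blk].ybar
                    gref = blk
                Bg, _, _ = self.matrices(theta, gref)
                on = self._nu_offset[gref]
                theta[on : on + p] = (np.eye(p) - Bg) @ ybar
        return theta

    # -- optimization -----------------------------------------------------
    def fit(
        self,
        x0: np.ndarray | None = None,
        max_iter: int = 1000,
        gtol: float = 1e-7,
        restarts: int = 3,
        seed: int = 0,
    ):
        """Minimize Q; random jittered restarts under a fixed seed on failure."""
        if x0 is None:
            x0 = self.start_values()
        rng = np.random.default_rng(seed)
        best = None
        for attempt in range(restarts + 1):
            start = x0 if attempt == 0 else x0 + rng.normal(0, 0.1, size=self.T)
            res = optimize.minimize(
                self.value_and_grad,
                start,
                jac=True,
                method="L-BFGS-B",
                options={"maxiter": max_iter, "ftol": 1e-14, "gtol": gtol},
            )
            gnorm = float(np.max(np.abs(res.jac))) if res.jac is not None else np.inf
            ok = res.fun < _BIG and (res.success or gnorm < 1e-4 * (1.0 + abs(res.fun)))
            if best is None or res.fun < best[0].fun:
                best = (res, ok)
            if ok:
                return res.x, float(res.fun), True, int(res.nit)
        res, ok = best
        raise ConvergenceError(
            f"ML optimization failed after {restarts + 1} attempt(s): {res.message}",
            best_theta=res.x,
            best_objective=float(res.fun),
        )

    # -- information ------------------------------------------------------
    def hessian_fd(self, theta: np.ndarray) -> np.ndarray:
        """Central finite-difference Hessian of Q from the analytic gradient."""
        T = self.T
        H = np.zeros((T, T))
        for j in range(T):
            h = 1e-5 * (1.0 + abs(theta[j]))
            tp = theta.copy()
            tp[j] += h
            tm = theta.copy()
            tm[j] -= h
            _, gp = self.value_and_grad(tp)
            _, gm = self.value_and_grad(tm)
            H[:, j] = (gp - gm) / (2.0 * h)
        return (H + H.T) / 2.0

    def observed_covariance(self, theta: np.ndarray) -> np.ndarray:
        """Parameter covariance 2 * H^-1 from the observed information H/2."""
        H = self.hessian_fd(theta)
        try:
            cov = 2.0 * np.linalg.inv(H)
        except LinAlgError:
            from .errors import IdentificationError

            raise IdentificationError("empirically under-identified: singular information matrix")
        if not np.all(np.isfinite(cov)) or np.any(np.diag(cov) < 0) or np.linalg.cond(H) > 1e10:
            from .errors import IdentificationError

            raise IdentificationError("empirically under-identified: singular information matrix")
        return cov

    def expected_information(self, theta: np.ndarray) -> np.ndarray:
        """Fisher information of the log-likelihood at theta (T x T)."""
        p = self.p
        I = np.eye(p)
        info = np.zeros((self.T, self.T))
        for g, gm in enumerate(self.groups):
            sl_beta, sl_psid, sl_psio, sl_nu = self._slices(g)
            B, Psi, nu = self.matrices(theta, g)
            A = np.linalg.solve(I - B, I)
            Sigma = A @ Psi @ A.T
            P = np.linalg.inv((Sigma + Sigma.T) / 2.0)
            idx = (
                list(range(sl_beta.start, sl_beta.stop))
                + list(range(sl_psid.start, sl_psid.stop))
                + list(range(sl_psio.start, sl_psio.stop))
            )
            if sl_nu is not None:
                idx += list(range(sl_nu.start, sl_nu.stop))
            m = len(idx)
            dS = np.zeros((m, p, p))
            dMu = np.zeros((m, p)) if self.mean_structure else None
            mu = A @ nu if self.mean_structure else None
            k = 0
            APsiA = Sigma  # A Psi A'
            for i, j in zip(self.beta_rows, self.beta_cols):
                # dSigma for beta_ij: A E_ij Sigma + (.)'
                outer = np.outer(A[:, i], Sigma[j, :])
                dS[k] = outer + outer.T
                if self.mean_structure:
                    dMu[k] = A[:, i] * mu[j]
                k += 1
            psid = np.exp(theta[sl_psid])
            for i in range(p):
                dS[k] = psid[i] * np.outer(A[:, i], A[:, i])
                k += 1
            for i, j in zip(self.psio_rows, self.psio_cols):
                outer = np.outer(A[:, i], A[:, j])
                dS[k] = outer + outer.T
                k += 1
            if self.mean_structure:
                for i in range(p):
                    dMu[k] = A[:, i]
                    k += 1
            K = np.einsum("ij,ajk,kl->ail", P, dS, P)
            block = 0.5 * gm.n * np.einsum("aij,bji->ab", K, dS)
            if self.mean_structure:
                block += gm.n * (dMu @ P @ dMu.T)
            info[np.ix_(idx, idx)] += block
        return info
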