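"""Variance-component estimation for Gaussian linear mixed models.

The model is y = X b + sum_k u_k + e with u_k ~ N(0, sigma2_k G_k) and
e ~ N(0, sigma2_e I).  Each random term supplies either a design matrix Z
(G_k = Z Z', e.g. a factor's indicator matrix or the Cholesky-type factor of
a genomic kernel) or a full covariance matrix C (G_k = C), in which case the
parameter may optionally be sign-unconstrained (covariance components in
multi-trait models).

Fitting is restricted (or full) maximum likelihood by average-information
updates with EM fallback steps and step halving, so the (restricted)
log-likelihood is non-decreasing over iterations; non-negative components
are kept off zero by a small positive floor and flagged as boundary
estimates.  Two equivalent evaluators are used: a Woodbury-identity path in
the total random-effect dimension q (fast when all terms are design
matrices, as in trial models with thousands of plots) and a dense n x n
path that also supports covariance terms.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import linalg


@dataclass
class RandomTerm:
    """One variance component: name plus Z (n x q) or cov (n x n)."""

    name: str
    Z: np.ndarray | None = None
    cov: np.ndarray | None = None
    nonneg: bool = True

    def __post_init__(self) -> None:
        if (self.Z is None) == (self.cov is None):
            raise ValueError("provide exactly one of Z or cov")


def factor_kernel(K: np.ndarray, tol: float = 1e-8) -> np.ndarray:
    """PSD factor L with L L' = K (eigendecomposition, small negatives clipped)."""
    K = np.asarray(K, float)
    vals, vecs = np.linalg.eigh(0.5 * (K + K.T))
    floor = -tol * max(float(np.trace(K)), 1.0)
    if vals.min() < floor:
        raise ValueError("kernel is not positive semi-definite within tolerance")
    vals = np.clip(vals, 0.0, None)
    keep = vals > tol * max(vals.max(), 1.0)
    return vecs[:, keep] * np.sqrt(vals[keep])


class _State:
    """Per-iteration quantities shared by both evaluators."""

    __slots__ = ("llf", "score", "ai", "beta", "cov_beta", "Py", "yPy", "ok")


class _WoodburyEval:
    """All-Z evaluator working in the q-dimensional random-effect space."""

    def __init__(self, y, X, terms):
        self.y = y
        self.X = X
        self.n, self.p = X.shape
        self.qs = [t.Z.shape[1] for t in terms]
        self.K = len(terms)
        self.W = np.hstack([t.Z for t in terms])
        self.q = self.W.shape[1]
        self.WtW = self.W.T @ self.W
        self.WtX = self.W.T @ X
        self.Wty = self.W.T @ y
        self.XtX = X.T @ X
        self.Xty = X.T @ y
        self.yty = float(y @ y)
        self.ZtZdiag = [float(np.sum(t.Z * t.Z)) for t in terms]
        self.blocks = np.concatenate([[0], np.cumsum(self.qs)])

    def evaluate(self, theta, reml=True, need_derivs=True) -> _State:
        st = _State()
        st.ok = True
        th = np.asarray(theta, float)
        sig = th[:-1]
        se = th[-1]
        dinv = np.concatenate([np.full(q, 1.0 / s) for q, s in zip(self.qs, sig)])
        M = self.WtW + np.diag(se * dinv)
        try:
            cM = linalg.cho_factor(M, lower=True)
        except linalg.LinAlgError:
            st.ok = False
            return st
        MiWtX = linalg.cho_solve(cM, self.WtX)
        MiWty = linalg.cho_solve(cM, self.Wty)
        XtViX = (self.XtX - self.WtX.T @ MiWtX) / se
        XtViy = (self.Xty - self.WtX.T @ MiWty) / se
        try:
            cXVX = linalg.cho_factor(XtViX, lower=True)
        except linalg.LinAlgError:
            st.ok = False
            return st
        beta = linalg.cho_solve(cXVX, XtViy)
        r = self.y - self.X @ beta
        Wtr = self.Wty - self.WtX @ beta
        Py = (r - self.W @ linalg.cho_solve(cM, Wtr)) / se
        yPy = float(self.y @ Py)  # equals r'Py since X'Py = 0
        logdetM = 2.0 * np.sum(np.log(np.diag(cM[0])))
        logdetV = ((self.n - self.q) * np.log(se) + logdetM
                   + float(np.sum(np.array(self.qs) * np.log(sig))))
        ll = -0.5 * (logdetV + yPy)
        if reml:
            ll -= 0.5 * 2.0 * np.sum(np.log(np.diag(cXVX[0])))
        st.llf = ll
        st.beta = beta
        st.cov_beta = linalg.cho_solve(cXVX, np.eye(self.p))
        st.Py = Py
        st.yPy = yPy
        if not need_derivs:
            return st
        # traces of P G_k (REML) or V^-1 G_k (ML)
        MiWtW = linalg.cho_solve(cM, self.WtW)
        XtViW = (self.WtX.T - self.WtX.T @ MiWtW) / se  # p x q
        WtPy = (Wtr - self.WtW @ linalg.cho_solve(cM, Wtr)) / se
        quad = np.empty(self.K + 1)
        tr = np.empty(self.K + 1)
        us = []
        for k in range(self.K):
            a, b = self.blocks[k], self.blocks[k + 1]
            zpy = WtPy[a:b]
            quad[k] = float(zpy @ zpy)
            trv = (self.ZtZdiag[k]
                   - float(np.sum(self.WtW[:, a:b] * MiWtW[:, a:b]))) / se
            if reml:
                Bk = XtViW[:, a:b]
                trv -= float(np.sum(Bk * linalg.cho_solve(cXVX, Bk)))
            tr[k] = trv
            us.append(zpy)
        quad[-1] = float(Py @ Py)
        dof = self.n - self.p if reml else self.n
        tr[-1] = (dof - float(np.sum(sig * tr[:-1]))) / se
        st.score = -0.5 * (tr - quad)
        # average information
        U = np.empty((self.n, self.K + 1))
        for k in range(self.K):
            a, b = self.blocks[k], self.blocks[k + 1]
            U[:, k] = self.W[:, a:b] @ us[k]
        U[:, -1] = Py
        WtU = self.W.T @ U
        ViU = (U - self.W @ linalg.cho_solve(cM, WtU)) / se
        UtViU = U.T @ ViU
        if reml:
            XtViU = self.X.T @ ViU
            UtViU -= XtViU.T @ linalg.cho_solve(cXVX, XtViU)
        st.ai = 0.5 * UtViU
        return st


class _DenseEval:
    """Dense n x n evaluator; supports covariance (possibly signed) terms."""

    def __init__(self, y, X, terms):
        self.y = y
        self.X = X
        self.n, self.p = X.shape
        self.Cs = []
        for t in terms:
            C = t.cov if t.cov is not None else t.Z @ t.Z.T
            self.Cs.append(np.asarray(C, float))
        self.Cs.append(np.eye(self.n))  # residual
        self.K = len(terms)

    def evaluate(self, theta, reml=True, need_derivs=True) -> _State:
        st = _State()
        st.ok = True
        V = sum(t * C for t, C in zip(theta, self.Cs))
        try:
            cV = linalg.cho_factor(V, lower=True)
        except linalg.LinAlgError:
            st.ok = False
            return st
        Vinv = linalg.cho_solve(cV, np.eye(self.n))
        ViX = Vinv @ self.X
        XtViX = self.X.T @ ViX
        try:
            cXVX = linalg.cho_factor(XtViX, lower=True)
        except linalg.LinAlgError:
            st.ok = False
            return st
        beta = linalg.cho_solve(cXVX, ViX.T @ self.y)
        r = self.y - self.X @ beta
        Py = Vinv @ r
        yPy = float(self.y @ Py)
        logdetV = 2.0 * np.sum(np.log(np.diag(cV[0])))
        ll = -0.5 * (logdetV + yPy)
        if reml:
            ll -= 0.5 * 2.0 * np.sum(np.log(np.diag(cXVX[0])))
        st.llf = ll
        st.beta = beta
        st.cov_beta = linalg.cho_solve(cXVX, np.eye(self.p))
        st.Py = Py
        st.yPy = yPy
        if not need_derivs:
            return st
        if reml:
            Pmat = Vinv - ViX @ linalg.cho_solve(cXVX, ViX.T)
        else:
            Pmat = Vinv
        nt = self.K + 1
        tr = np.array([float(np.sum(Pmat * C)) for C in self.Cs])
        U = np.column_stack([C @ Py for C in self.Cs])
        quad = np.array([float(Py @ U[:, k]) for k in range(nt)])
        st.score = -0.5 * (tr - quad)
        PU = (Vinv @ U)
        if reml:
            XtViU = ViX.T @ U
            PU -= ViX @ linalg.cho_solve(cXVX, XtViU)
        st.ai = 0.5 * (U.T @ PU)
        return st


@dataclass
class MixedModelResults:
    """REML/ML estimates, fixed-effect GLS solutions, and diagnostics."""

    model: "MixedModel" = field(repr=False)
    params: pd.Series
    fe_params: np.ndarray
    cov_fe_params: np.ndarray = field(repr=False)
    llf: float
    converged: bool
    n_iter: int
    method: str
    boundary: pd.Series
    _Py: np.ndarray = field(repr=False, default=None)
    cov_params: pd.DataFrame | None = field(repr=False, default=None)

    def blup(self, name: str) -> np.ndarray:
        """Best linear unbiased prediction of the named random effect."""
        i = self.model.term_names.index(name)
        t = self.model.terms[i]
        s2 = self.params[name]
        if t.Z is not None:
            return s2 * (t.Z.T @ self._Py)
        return s2 * (t.cov @ self._Py)

    def blup_individual(self, name: str) -> np.ndarray:
        """BLUP mapped to observations (Z u for Z terms, C Py-scaled otherwise)."""
        i = self.model.term_names.index(name)
        t = self.model.terms[i]
        u = self.blup(name)
        return t.Z @ u if t.Z is not None else u

    def summary(self) -> str:
        lines = [
            f"Mixed model ({self.method.upper()}), "
            f"n={self.model.n}, p={self.model.p}",
            f"logLik: {self.llf:.4f}  converged: {self.converged} "
            f"(iterations: {self.n_iter})",
            "",
            "Variance components:",
        ]
        for k, v in self.params.items():
            flag = " (boundary)" if self.boundary.get(k, False) else ""
            lines.append(f"  {k:<16s} {v:12.6g}{flag}")
        lines.append("")
        lines.append("Fixed effects:")
        se = np.sqrt(np.diag(self.cov_fe_params))
        for name, b, s in zip(self.model.fe_names, self.fe_params, se):
            lines.append(f"  {name:<16s} {b:12.6g}  (SE {s:.6g})")
        return "\n".join(lines)


class MixedModel:
    """Gaussian mixed model with variance components.

    Parameters
    ----------
    y : (n,) response.
    X : (n, p) fixed-effect design (full column rank).
    terms : list of RandomTerm; the iid residual is implicit and always last
        in the fitted parameter vector under the name "residual".
    fe_names : optional fixed-effect column names.
    """

    def __init__(self, y, X, terms, fe_names=None):
        self.y = np.asarray(y, float)
        X = np.asarray(X, float)
        if X.ndim == 1:
            X = X[:, None]
        self.X = X
        self.n, self.p = X.shape
        if self.y.shape != (self.n,):
            raise ValueError("y and X have inconsistent lengths")
        self.terms = list(terms)
        self.term_names = [t.name for t in self.terms]
        if len(set(self.term_names)) != len(self.term_names):
            raise ValueError("duplicate term names")
        self.fe_names = (list(fe_names) if fe_names is not None
                         else [f"x{j}" for j in range(self.p)])
        self._has_free = any(not t.nonneg for t in self.terms)
        all_z = all(t.Z is not None for t in self.terms)
        # Woodbury pays off when q << n; dense is simpler and fine for small n
        qtot = sum(t.Z.shape[1] for t in self.terms) if all_z else None
        if all_z and not self._has_free and (self.n > 700 or qtot < self.n):
            self._eval = _WoodburyEval(self.y, self.X, self.terms)
        else:
            self._eval = _DenseEval(self.y, self.X, self.terms)

    def fit(self, reml: bool = True, start=None, max_iter: int = 200,
            tol: float = 1e-8) -> MixedModelResults:
        K = len(self.terms)
        vary = float(np.var(self.y)) or 1.0
        floor = 1e-8 * vary
        nonneg = np.array([t.nonneg for t in self.terms] + [True])
        if start is None:
            theta = np.full(K + 1, vary / (K + 1))
            theta[[i for i, t in enumerate(self.terms) if not t.nonneg]] = 0.0
        else:
            theta = np.asarray(start, float).copy()
        theta[nonneg] = np.maximum(theta[nonneg], floor)

        st = self._eval.evaluate(theta, reml=reml)
        if not st.ok:
            raise linalg.LinAlgError("initial covariance not positive definite")
        converged = False
        it = 0
        for it in range(1, max_iter + 1):
            prev_ll = st.llf
            # propose AI step (Levenberg-damped on failure)
            step = None
            ai = st.ai
            for damp in (0.0, 0.1, 1.0, 10.0):
                try:
                    A = ai + damp * np.diag(np.maximum(np.diag(ai), 1e-12))
                    step = np.linalg.solve(A, st.score)
                    break
                except np.linalg.LinAlgError:
                    continue
            accepted = False
            if step is not None:
                frac = 1.0
                for _ in range(12):
                    cand = theta + frac * step
                    cand[nonneg] = np.maximum(cand[nonneg], floor)
                    st_c = self._eval.evaluate(cand, reml=reml)
                    if st_c.ok and st_c.llf >= prev_ll - 1e-10:
                        theta, st = cand, st_c
                        accepted = True
                        break
                    frac *= 0.5
            if not accepted:
                # EM fallback using the score identity
                # score_k = -0.5 (tr_k - quad_k), EM step
                # theta_k+ = theta_k + theta_k^2/q_k (quad_k - tr_k)
                cand = theta.copy()
                sizes = self._term_sizes()
                for k in range(K + 1):
                    cand[k] = theta[k] + (theta[k] ** 2 / sizes[k]) * (
                        2.0 * st.score[k])
                    if nonneg[k]:
                        cand[k] = max(cand[k], floor)
                st_c = self._eval.evaluate(cand, reml=reml)
                if st_c.ok and st_c.llf >= prev_ll - 1e-10:
                    theta, st = cand, st_c
                    accepted = True
            if not accepted:
                # neither a damped AI step nor EM improves the objective:
                # we are at a (possibly boundary-constrained) optimum
                converged = True
                break
            denom = abs(prev_ll) + 1.0
            if abs(st.llf - prev_ll) / denom < tol and it > 1:
                converged = True
                break
        if not converged and it == max_iter:
            warnings.warn("mixed model did not converge; returning last iterate")
        names = self.term_names + ["residual"]
        boundary = pd.Series(
            [bool(nonneg[k] and theta[k] <= floor * (1 + 1e-6))
             for k in range(K + 1)], index=names)
        params = pd.Series(theta, index=names)
        # report boundary (floored) non-residual components as exactly zero
        for k in names[:-1]:
            if boundary[k]:
                params[k] = 0.0
        # asymptotic covariance of the variance parameters: inverse AI
        try:
            cov_params = pd.DataFrame(np.linalg.pinv(st.ai), index=names,
                                      columns=names)
        except np.linalg.LinAlgError:
            cov_params = None
        return MixedModelResults(
            model=self, params=params, fe_params=st.beta,
            cov_fe_params=st.cov_beta, llf=st.llf, converged=converged,
            n_iter=it, method="reml" if reml else "ml",
            boundary=boundary, _Py=st.Py, cov_params=cov_params)

    def _term_sizes(self) -> np.ndarray:
        sizes = []
        for t in self.terms:
            sizes.append(t.Z.shape[1] if t.Z is not None else self.n)
        sizes.append(self.n)
        return np.asarray(sizes, float)


def design_matrix(levels: pd.Series | np.ndarray):
    """Indicator (one-hot) design matrix and level labels for a factor."""
    s = pd.Series(levels).astype(str)
    cats = sorted(s.unique())
    idx = s.map({c: i for i, c in enumerate(cats)}).to_numpy()
    Z = np.zeros((len(s), len(cats)))
    Z[np.arange(len(s)), idx] = 1.0
    return Z, cats
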