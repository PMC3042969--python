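"""Linear mixed-model machinery for QTL scans and full-model estimation.

The scan stages use Henderson's method III: the extra sum of squares of a
block of candidate columns given a conditioning design is the difference of
projections onto the two column spaces, and the partial F statistic

    F = [SSR(Q|M) / (rank(X_QM) - rank(X_M))] / [SSE / (n - rank(X_M))]

compares it with the residual mean square of the conditioning-only fit.

The full model is a Gaussian mixed linear model
``y ~ N(Xb, V)``, ``V = sum_u sigma2_u U_u U_u' + sigma2_e I``.
Variance components are estimated by REML, fixed effects by GLS, random
effects by BLUP rescaled so the empirical variance of each term's predicted
levels matches its estimated component (adjusted unbiased prediction).
Posterior distributions of all parameters come from a Gibbs sampler
initialized at the REML/GLS/AUP solution, with effects estimated by
posterior means and tested by t = mean / SD.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.linalg
from scipy import optimize, stats

__all__ = [
    "DesignMatrices",
    "FTestResult",
    "FitReport",
    "DegenerateDesignError",
    "orthonormal_basis",
    "henderson3_extra_ss",
    "partial_f",
    "NestedFTester",
    "reml_components",
    "gls_fixed",
    "aup_random",
    "gibbs_estimate",
    "fit_mixed_model",
]

RANK_TOL = 1e-10  # relative tolerance of pivoted rank computation (fixed:
                  # it sets the degrees of freedom of the partial F test)


class DegenerateDesignError(ValueError):
    """More parameters than observations, or an empty test block."""


@dataclass
class DesignMatrices:
    """Labeled fixed and random design blocks of one mixed model."""

    X: np.ndarray
    x_labels: list
    U_list: list = field(default_factory=list)
    u_terms: list = field(default_factory=list)          # one name per U
    u_level_labels: list = field(default_factory=list)   # level names per U

    def __post_init__(self):
        self.X = np.atleast_2d(np.asarray(self.X, dtype=float))
        if self.X.shape[1] != len(self.x_labels):
            raise ValueError("fixed-effect labels do not match X columns")
        if len(self.U_list) != len(self.u_terms):
            raise ValueError("random-term names do not match U_list")
        if not self.u_level_labels:
            self.u_level_labels = [
                [f"{t}[{j}]" for j in range(U.shape[1])]
                for t, U in zip(self.u_terms, self.U_list)
            ]
        for U in self.U_list:
            if U.shape[0] != self.X.shape[0]:
                raise ValueError("random-term row count does not match X")

    @property
    def n(self):
        return self.X.shape[0]


@dataclass(frozen=True)
class FTestResult:
    F: float
    df_num: int
    df_den: int
    ssr_extra: float
    sse: float
    pvalue: float


def orthonormal_basis(X, tol=RANK_TOL):
    """Orthonormal basis of the column space via pivoted QR; returns (Q, rank)."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[1] == 0:
        return np.empty((X.shape[0], 0)), 0
    Q, R, _ = scipy.linalg.qr(X, mode="economic", pivoting=True)
    diag = np.abs(np.diag(R))
    rank = int(np.sum(diag > tol * (diag[0] if diag.size and diag[0] > 0 else 1.0)))
    return Q[:, :rank], rank


def henderson3_extra_ss(y, X_full, X_reduced):
    """Extra sum of squares of the full over the reduced design.

    Returns ``(ssr_extra, sse, rank_full, rank_reduced)`` where
    ``ssr_extra = y'(P_full - P_reduced)y`` and ``sse = y'(I - P_full)y``,
    with P the orthogonal projectors onto the column spaces (rank
    deficiency handled by the pivoted-QR basis).
    """
    y = np.asarray(y, dtype=float)
    Qf, rank_full = orthonormal_basis(X_full)
    Qr, rank_reduced = orthonormal_basis(X_reduced)
    n = len(y)
    if n <= rank_full:
        raise DegenerateDesignError(
            f"n={n} observations cannot support a rank-{rank_full} design"
        )
    yty = float(y @ y)
    ss_full = float(np.sum((Qf.T @ y) ** 2))
    ss_reduced = float(np.sum((Qr.T @ y) ** 2))
    ssr_extra = max(ss_full - ss_reduced, 0.0)
    sse = max(yty - ss_full, 0.0)
    return ssr_extra, sse, rank_full, rank_reduced


_F_EPS = 1e-12


def partial_f(y, X_full, X_reduced):
    """Partial F test of the extra columns of ``X_full`` over ``X_reduced``."""
    y = np.asarray(y, dtype=float)
    ssr_extra, sse, rank_full, rank_reduced = henderson3_extra_ss(y, X_full, X_reduced)
    df_num = rank_full - rank_reduced
    df_den = len(y) - rank_reduced
    if df_num == 0:
        raise DegenerateDesignError("tested block adds no rank to the design")
    scale = float(y @ y) / len(y)
    F = (ssr_extra / df_num) / max(sse / df_den, _F_EPS * max(scale, _F_EPS))
    pvalue = float(stats.f.sf(F, df_num, df_den))
    return FTestResult(F=float(F), df_num=df_num, df_den=df_den,
                       ssr_extra=ssr_extra, sse=sse, pvalue=pvalue)


class NestedFTester:
    """Vectorized partial F tests against a fixed conditioning design.

    Orthogonalizes the conditioning design once; each call residualizes a
    candidate block against it and evaluates the partial F statistic for
    every column of a response matrix simultaneously (used for permutation
    thresholds).
    """

    def __init__(self, X_base):
        self.Q_base, self.rank_base = orthonormal_basis(X_base)
        self.n = self.Q_base.shape[0]

    def prepare(self, Y):
        """Cache projections of a response matrix (n,) or (n, m)."""
        Y = np.asarray(Y, dtype=float)
        Y2d = Y[:, None] if Y.ndim == 1 else Y
        return {
            "Y": Y2d,
            "yty": np.sum(Y2d * Y2d, axis=0),
            "ss_base": np.sum((self.Q_base.T @ Y2d) ** 2, axis=0),
            "scalar": Y.ndim == 1,
        }

    def f_stats(self, X_extra, prep):
        """Partial F of ``X_extra | base`` for each prepared response."""
        E = np.asarray(X_extra, dtype=float)
        E = E - self.Q_base @ (self.Q_base.T @ E)
        Qe, rank_extra = orthonormal_basis(E)
        # no testable columns, or no residual degrees of freedom left in
        # the conditioning design: the test is undefined, report F = 0
        if rank_extra == 0 or self.n - self.rank_base <= 0:
            out = np.zeros_like(prep["yty"])
            return (float(out[0]), 0) if prep["scalar"] else (out, rank_extra)
        ss_extra = np.sum((Qe.T @ prep["Y"]) ** 2, axis=0)
        sse = np.maximum(prep["yty"] - prep["ss_base"] - ss_extra, 0.0)
        df_den = self.n - self.rank_base
        scale = np.maximum(prep["yty"] / self.n, _F_EPS)
        F = (ss_extra / rank_extra) / np.maximum(sse / df_den, _F_EPS * scale)
        return (float(F[0]), rank_extra) if prep["scalar"] else (F, rank_extra)


# ---------------------------------------------------------------------------
# REML / GLS / AUP
# ---------------------------------------------------------------------------


class _MixedModelWork:
    """Precomputed cross-products for fast repeated likelihood evaluation.

    With all random-term correlation structures the identity, V has the
    low-rank form ``sigma2_e I + U D U'`` (U the concatenated random
    design, D diagonal), so every REML evaluation reduces to q x q linear
    algebra via the Woodbury identity, q = total random levels.
    """

    def __init__(self, y, dm):
        self.y = np.asarray(y, dtype=float)
        self.dm = dm
        self.n = dm.n
        self.X = dm.X
        self.U = np.hstack(dm.U_list) if dm.U_list else np.empty((self.n, 0))
        self.block_sizes = [U.shape[1] for U in dm.U_list]
        self.block_index = np.repeat(np.arange(len(dm.U_list)),
                                     self.block_sizes).astype(int)
        self.UtU = self.U.T @ self.U
        self.UtX = self.U.T @ self.X
        self.Uty = self.U.T @ self.y
        self.XtX = self.X.T @ self.X
        self.Xty = self.X.T @ self.y
        self.yty = float(self.y @ self.y)
        _, self.rank_X = orthonormal_basis(self.X)

    def _woodbury(self, sig_u, sig_e):
        """Returns pieces of V^{-1} = (I - U M K^{-1} M U'/sig_e)/sig_e."""
        d = np.repeat(sig_u, self.block_sizes)
        m = np.sqrt(d)
        K = np.eye(len(d)) + (m[:, None] * self.UtU * m[None, :]) / sig_e
        cK, low = scipy.linalg.cho_factor(K, lower=True)
        logdetV = self.n * np.log(sig_e) + 2.0 * np.sum(np.log(np.diag(cK)))
        def vinv_quad(AtB, At_left, At_right):
            # computes L'V^{-1}R given U'R products: At* are U'L, U'R
            mL = m[:, None] * At_left
            mR = m[:, None] * At_right
            corr = mL.T @ scipy.linalg.cho_solve((cK, low), mR)
            return (AtB - corr / sig_e) / sig_e
        return vinv_quad, logdetV, (cK, low), m

    def reml_loglik(self, sig_u, sig_e):
        vinv_quad, logdetV, _, _ = self._woodbury(sig_u, sig_e)
        XtVX = vinv_quad(self.XtX, self.UtX, self.UtX)
        XtVy = vinv_quad(self.Xty[:, None], self.UtX, self.Uty[:, None])[:, 0]
        ytVy = vinv_quad(np.array([[self.yty]]), self.Uty[:, None],
                         self.Uty[:, None])[0, 0]
        eigvals = np.linalg.eigvalsh(XtVX)
        pos = eigvals[eigvals > RANK_TOL * max(eigvals.max(), 1.0)]
        logdetXVX = float(np.sum(np.log(pos)))
        beta = np.linalg.pinv(XtVX, rcond=RANK_TOL) @ XtVy
        ytPy = ytVy - float(XtVy @ beta)
        return -0.5 * (logdetV + logdetXVX + ytPy)


def reml_components(y, dm, start=None, maxiter=200):
    """REML variance-component estimates of the mixed model.

    Non-convergence is flagged in the result, not raised; estimates are
    clipped to be non-negative (boundary solutions are legitimate).

    Returns a dict with per-term ``components``, ``var_e``, ``converged``,
    ``loglik`` and the optimizer diagnostics.
    """
    work = _MixedModelWork(y, dm)
    if not dm.U_list:
        # no random terms: REML degenerates to the OLS residual variance
        Q, rank = orthonormal_basis(dm.X)
        resid = work.y - Q @ (Q.T @ work.y)
        var_e = float(resid @ resid) / max(work.n - rank, 1)
        return {"components": {}, "var_e": var_e, "converged": True,
                "loglik": np.nan, "n_iter": 0}
    if work.n <= work.rank_X:
        raise DegenerateDesignError("no residual degrees of freedom for REML")

    r = len(dm.U_list)
    var_y = max(float(np.var(work.y)), 1e-8)
    x0 = np.full(r + 1, var_y / (r + 1)) if start is None else np.asarray(start)
    bounds = [(0.0, 50.0 * var_y)] * (r + 1)

    def negloglik(theta):
        sig_u, sig_e = theta[:r], max(theta[r], 1e-10 * var_y)
        return -work.reml_loglik(sig_u, sig_e)

    res = optimize.minimize(negloglik, x0, method="L-BFGS-B", bounds=bounds,
                            options={"maxiter": maxiter, "ftol": 1e-12})
    theta = np.maximum(res.x, 0.0)
    components = dict(zip(dm.u_terms, theta[:r]))
    return {
        "components": components,
        "var_e": float(max(theta[r], 1e-10 * var_y)),
        "converged": bool(res.success),
        "loglik": float(-res.fun),
        "n_iter": int(res.nit),
    }


def _build_V_solver(work, components, var_e):
    sig_u = np.array([components[t] for t in work.dm.u_terms])
    return work._woodbury(np.maximum(sig_u, 0.0), max(var_e, 1e-12)), sig_u


def gls_fixed(y, dm, components=None, var_e=None):
    """Generalized least squares fixed effects under estimated components.

    With ``V = I`` (no random terms / var_e only) this is OLS.  Returns a
    dict with ``estimates``, ``cov`` and ``labels``.  A singular V is
    handled through the pseudo-inverse with a warning.
    """
    work = _MixedModelWork(y, dm)
    if components is None:
        components = {t: 0.0 for t in dm.u_terms}
    if var_e is None:
        var_e = float(np.var(work.y)) or 1.0
    if var_e <= 0:
        warnings.warn("non-positive residual variance; ridge-stabilized solve")
        var_e = 1e-8 * max(float(np.var(work.y)), 1.0)
    (vinv_quad, _, _, _), _ = _build_V_solver(work, components, var_e)
    XtVX = vinv_quad(work.XtX, work.UtX, work.UtX)
    XtVy = vinv_quad(work.Xty[:, None], work.UtX, work.Uty[:, None])[:, 0]
    cov = np.linalg.pinv(XtVX, rcond=RANK_TOL)
    beta = cov @ XtVy
    return {"estimates": beta, "cov": cov, "labels": list(dm.x_labels)}


def aup_random(y, dm, components, var_e, fixed=None):
    """Adjusted unbiased prediction of the random-effect levels.

    BLUP ``sigma2_u U_u' V^{-1}(y - Xb)`` rescaled per term so the
    empirical variance of the predicted levels equals the estimated
    component.  Two-level deviation terms keep their sum-to-zero structure
    under the common rescaling.
    """
    work = _MixedModelWork(y, dm)
    if fixed is None:
        fixed = gls_fixed(y, dm, components, var_e)
    beta = fixed["estimates"]
    (vinv_quad, _, _, _), sig_u = _build_V_solver(work, components, var_e)
    # U'V^{-1}(y - Xb) via the same Woodbury pieces
    Ut_resid = work.Uty - work.UtX @ beta
    UtVresid = vinv_quad(Ut_resid[:, None], work.UtU, Ut_resid[:, None])[:, 0]
    out = {}
    start = 0
    for term, size, s2 in zip(dm.u_terms, work.block_sizes, sig_u):
        raw = s2 * UtVresid[start:start + size]
        start += size
        emp = float(np.mean(raw ** 2))
        scale = np.sqrt(s2 / emp) if emp > 0 and s2 > 0 else 0.0
        out[term] = raw * scale
    return out


# ---------------------------------------------------------------------------
# Gibbs sampling
# ---------------------------------------------------------------------------


@dataclass
class FitReport:
    """Posterior summaries of the full mixed model."""

    fixed: pd.DataFrame
    random: pd.DataFrame
    varcomps: pd.DataFrame
    meta: dict

    def fixed_estimate(self, label):
        row = self.fixed.loc[self.fixed["label"] == label]
        if row.empty:
            raise KeyError(label)
        return float(row["estimate"].iloc[0])

    def to_json(self):
        import json

        return json.dumps({
            "fixed": self.fixed.to_dict(orient="records"),
            "random": self.random.to_dict(orient="records"),
            "varcomps": self.varcomps.to_dict(orient="records"),
            "meta": {k: v for k, v in self.meta.items()
                     if isinstance(v, (int, float, str, bool))},
        }, indent=2)


def gibbs_estimate(y, dm, init=None, n_iter=11_000, burn_in=1_000, seed=0,
                   prior_df=1.0, prior_scale=None, alpha=0.05,
                   variance_cap=None):
    """Gibbs sampler for the mixed model; posterior means, SDs and t tests.

    Conditionals are normal for fixed and random effects and scaled
    inverse-chi-square for the variances, with a weakly informative prior
    (``prior_df`` pseudo-observations at ``prior_scale``, which defaults to
    the initializing REML estimates).  Divergent variance draws beyond
    ``variance_cap`` (default 1e4 x the phenotypic variance) are capped and
    flagged in ``meta['capped_draws']``.

    Chains are reproducible under ``seed``.  Each effect is declared
    significant when |mean/SD| exceeds the two-sided Student-t critical
    value at ``alpha`` with n - rank(X) degrees of freedom.
    """
    if n_iter <= burn_in:
        raise ValueError("n_iter must exceed burn_in")
    rng = np.random.default_rng(seed)
    work = _MixedModelWork(y, dm)
    n, p = work.n, work.X.shape[1]
    r = len(dm.U_list)
    var_y = max(float(np.var(work.y)), 1e-12)
    cap = variance_cap if variance_cap is not None else 1e4 * var_y

    if init is None:
        init = reml_components(y, dm)
    comp0 = init["components"]
    var_e = max(init["var_e"], 1e-8 * var_y)
    if prior_scale is None:
        prior_scale = {t: max(comp0.get(t, 0.0), 1e-3 * var_y)
                       for t in dm.u_terms}
        prior_scale["_e"] = max(var_e, 1e-3 * var_y)
    fixed0 = gls_fixed(y, dm, comp0, var_e)
    b = fixed0["estimates"].copy()

    XtX = work.XtX + np.eye(p) * (RANK_TOL * max(np.trace(work.XtX), 1.0))
    cX = scipy.linalg.cho_factor(XtX, lower=True)
    # lower-triangular factor of (X'X)^{-1} for sampling b
    Linv = scipy.linalg.solve_triangular(cX[0], np.eye(p), lower=True).T

    Us = dm.U_list
    UtU_diag, UtU_chol = [], []
    for U in Us:
        M = U.T @ U
        off = M - np.diag(np.diag(M))
        if np.abs(off).max() < 1e-12 * max(np.abs(M).max(), 1.0):
            UtU_diag.append(np.diag(M).copy())
            UtU_chol.append(None)
        else:
            UtU_diag.append(None)
            UtU_chol.append(M)
    e_list = [np.zeros(U.shape[1]) for U in Us]
    sig_u = np.array([max(comp0.get(t, 0.0), 1e-4 * var_y) for t in dm.u_terms])

    keep = n_iter - burn_in
    b_draws = np.empty((keep, p))
    e_draws = [np.empty((keep, U.shape[1])) for U in Us]
    s_draws = np.empty((keep, r + 1))
    capped = 0

    Xb = work.X @ b
    Ue = [U @ e for U, e in zip(Us, e_list)]
    for it in range(n_iter):
        # fixed effects
        resid_b = work.y - sum(Ue, np.zeros(n)) if r else work.y
        mean_b = scipy.linalg.cho_solve(cX, work.X.T @ resid_b)
        b = mean_b + np.sqrt(var_e) * (Linv @ rng.standard_normal(p))
        Xb = work.X @ b
        # random effects
        for u in range(r):
            partial = work.y - Xb
            for v in range(r):
                if v != u:
                    partial = partial - Ue[v]
            rhs = Us[u].T @ partial / var_e
            if UtU_diag[u] is not None:
                prec = UtU_diag[u] / var_e + 1.0 / sig_u[u]
                mean_e = rhs / prec
                e_list[u] = mean_e + rng.standard_normal(len(rhs)) / np.sqrt(prec)
            else:
                P = UtU_chol[u] / var_e + np.eye(len(rhs)) / sig_u[u]
                cP = scipy.linalg.cho_factor(P, lower=True)
                mean_e = scipy.linalg.cho_solve(cP, rhs)
                z = scipy.linalg.solve_triangular(
                    cP[0], rng.standard_normal(len(rhs)), lower=True, trans="T")
                e_list[u] = mean_e + z
            Ue[u] = Us[u] @ e_list[u]
        # variance components
        for u in range(r):
            q_u = len(e_list[u])
            shape = prior_df + q_u
            scale = prior_df * prior_scale[dm.u_terms[u]] + float(e_list[u] @ e_list[u])
            draw = scale / rng.chisquare(shape)
            if draw > cap:
                draw, capped = cap, capped + 1
            sig_u[u] = draw
        resid = work.y - Xb - (sum(Ue, np.zeros(n)) if r else 0.0)
        rss = float(resid @ resid)
        var_e = (prior_df * prior_scale["_e"] + rss) / rng.chisquare(prior_df + n)
        var_e = min(var_e, cap)

        if it >= burn_in:
            k = it - burn_in
            b_draws[k] = b
            for u in range(r):
                e_draws[u][k] = e_list[u]
            s_draws[k, :r] = sig_u
            s_draws[k, r] = var_e

    df_t = max(n - work.rank_X, 1)
    tcrit = stats.t.ppf(1 - alpha / 2, df_t)

    def summarize(labels, draws, terms=None):
        means = draws.mean(axis=0)
        sds = draws.std(axis=0, ddof=1)
        tval = np.where(sds > 0, means / np.where(sds > 0, sds, 1.0), np.inf)
        pv = 2 * stats.t.sf(np.abs(tval), df_t)
        rec = {"label": labels, "estimate": means, "sd": sds,
               "t": tval, "pvalue": pv, "significant": np.abs(tval) > tcrit}
        if terms is not None:
            rec = {"term": terms, **rec}
        return pd.DataFrame(rec)

    fixed = summarize(list(dm.x_labels), b_draws)
    if r:
        random = pd.concat([
            summarize(dm.u_level_labels[u], e_draws[u],
                      terms=[dm.u_terms[u]] * Us[u].shape[1])
            for u in range(r)
        ], ignore_index=True)
    else:
        random = pd.DataFrame(
            columns=["term", "label", "estimate", "sd", "t", "pvalue",
                     "significant"])
    vlabels = list(dm.u_terms) + ["residual"]
    varcomps = pd.DataFrame({
        "term": vlabels,
        "estimate": s_draws.mean(axis=0),
        "sd": s_draws.std(axis=0, ddof=1),
    })
    meta = {"n_iter": n_iter, "burn_in": burn_in, "seed": seed,
            "df_t": df_t, "alpha": alpha, "capped_draws": capped,
            "init_loglik": init.get("loglik", np.nan),
            "init_converged": init.get("converged", True)}
    return FitReport(fixed=fixed, random=random, varcomps=varcomps, meta=meta)


def fit_mixed_model(y, dm, n_iter=11_000, burn_in=1_000, seed=0, alpha=0.05):
    """REML -> GLS/AUP -> Gibbs convenience wrapper returning a FitReport."""
    init = reml_components(y, dm)
    return gibbs_estimate(y, dm, init=init, n_iter=n_iter, burn_in=burn_in,
                          seed=seed, alpha=alpha)
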