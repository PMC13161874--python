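"""Zero-inflated Poisson mixed models with a per-subject random intercept.

The count model for observation :math:`y_{ij}` of subject :math:`i` is

.. math::

    y_{ij} \\sim \\pi\\,\\delta_0 + (1-\\pi)\\,
        \\mathrm{Poisson}(\\lambda_{ij}), \\qquad
    \\log \\lambda_{ij} = x_{ij}^\\top \\beta + u_i, \\qquad
    u_i \\sim N(0, \\sigma_u^2),

with a single constant zero-inflation mass :math:`\\pi` (no covariates on
the zero process) and the random intercept entering the Poisson log-rate
only.  The marginal likelihood integrates the random intercept out by
adaptive Gauss--Hermite quadrature (default 15 nodes); one node gives the
Laplace approximation, used as a fast mode inside permutation loops.

Fitting maximizes the marginal likelihood directly.  Two execution paths
share the same objective: a scipy quasi-Newton path for single fits, and a
batched damped-Newton path (`fit_zip_batch`) that fits many models with a
common observation layout simultaneously — this is what makes refitting
hundreds of region-pair models per permutation tractable.

Quadrature nodes are re-centred on the per-subject posterior mode between
optimizer rounds and held fixed within a round, so gradients of the
smoothed objective are analytic; rounds repeat until the marginal
log-likelihood is stable to 1e-6 (relative).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, special, stats

__all__ = [
    "ModelSpec",
    "ZipGlmmFit",
    "LRTResult",
    "zip_logpmf",
    "build_design",
    "marginal_loglik",
    "fit_zip_glmm",
    "fit_zip_batch",
    "likelihood_ratio_test",
    "predict_marginal_mean",
]

_LOG2PI = np.log(2.0 * np.pi)
_RHO_BOUNDS = (np.log(1e-3), np.log(5.0))
_ALPHA_BOUNDS = (special.logit(1e-4), special.logit(0.95))


# ---------------------------------------------------------------------------
# elementary distribution
# ---------------------------------------------------------------------------

def zip_logpmf(y, lam, pi):
    """Log-pmf of the zero-inflated Poisson.

    ``P(0) = pi + (1-pi) e^{-lam}``; for ``y > 0``,
    ``P(y) = (1-pi) Poisson(y; lam)``.

    Parameters broadcast; ``lam`` must be positive and ``pi`` in [0, 1).
    """
    y = np.asarray(y)
    lam = np.asarray(lam, dtype=float)
    pi = np.asarray(pi, dtype=float)
    if np.any(lam <= 0):
        raise ValueError("lam must be positive")
    if np.any((pi < 0) | (pi >= 1)):
        raise ValueError("pi must be in [0, 1)")
    with np.errstate(divide="ignore"):
        log_pi = np.log(pi)
        log1m = np.log1p(-pi)
    zero = np.logaddexp(log_pi, log1m - lam)
    pos = log1m + stats.poisson.logpmf(y, lam)
    return np.where(y == 0, zero, pos)


# ---------------------------------------------------------------------------
# design-matrix builder (tiny, deterministic formula terms)
# ---------------------------------------------------------------------------

def _term_columns(data: pd.DataFrame, term: str, levels: dict) -> tuple[np.ndarray, list[str]]:
    parts = term.split(":")
    cols = [np.ones((len(data), 1))]
    names: list[list[str]] = [[""]]
    for part in parts:
        if part not in data.columns:
            raise KeyError(f"term {term!r}: column {part!r} not in design data")
        v = data[part]
        if v.dtype.kind in "OUSb" or isinstance(v.dtype, pd.CategoricalDtype):
            if part not in levels:
                levels[part] = sorted(pd.unique(v.astype(str)))
            lv = levels[part]
            block = np.column_stack(
                [(v.astype(str) == l).to_numpy(float) for l in lv[1:]]
            ) if len(lv) > 1 else np.zeros((len(data), 0))
            bnames = [f"{part}[T.{l}]" for l in lv[1:]]
        else:
            block = v.to_numpy(float)[:, None]
            bnames = [part]
        new_cols, new_names = [], []
        for c, n in zip(cols, names):
            for j in range(block.shape[1]):
                new_cols.append(c * block[:, j : j + 1])
                new_names.append(n + [bnames[j]])
        cols, names = new_cols, new_names
    X = np.hstack(cols) if cols else np.zeros((len(data), 0))
    out_names = [":".join(x for x in n if x) for n in names]
    return X, out_names


def build_design(
    data: pd.DataFrame, terms, levels: dict | None = None
) -> tuple[np.ndarray, list[str], dict]:
    """Build a fixed-effects design matrix with an intercept.

    ``terms`` is an ordered list like ``["moca", "pair", "pair:moca"]``;
    string/categorical columns are dummy-coded against their first sorted
    level, interactions are products of component codings.  ``levels``
    caches factor levels so prediction grids reuse the fit's encoding.
    """
    levels = {} if levels is None else dict(levels)
    X_parts = [np.ones((len(data), 1))]
    names = ["Intercept"]
    for term in terms:
        if term in ("1", ""):
            continue
        Xt, nt = _term_columns(data, term, levels)
        X_parts.append(Xt)
        names.extend(nt)
    X = np.hstack(X_parts)
    if not np.all(np.isfinite(X)):
        bad = [names[j] for j in range(X.shape[1]) if not np.all(np.isfinite(X[:, j]))]
        raise ValueError(f"non-finite values in design columns {bad}")
    return X, names, levels


# ---------------------------------------------------------------------------
# model specification and fit container
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ModelSpec:
    """Specification of a ZIP mixed model.

    ``fixed_terms`` uses the tiny term language of :func:`build_design`;
    ``random_intercept_group`` names the grouping column (``None`` drops the
    random intercept); ``zero_inflation`` is ``"constant"`` or ``"none"``.
    """

    response: str
    fixed_terms: tuple = ()
    random_intercept_group: str | None = "subject"
    zero_inflation: str = "constant"

    def __post_init__(self) -> None:
        object.__setattr__(self, "fixed_terms", tuple(self.fixed_terms))
        if self.zero_inflation not in ("constant", "none"):
            raise ValueError("zero_inflation must be 'constant' or 'none'")
        if self.random_intercept_group == "":
            raise ValueError("random_intercept_group must be non-empty or None")


@dataclass
class ZipGlmmFit:
    """A fitted (or degenerate) ZIP mixed model."""

    spec: ModelSpec
    beta: pd.Series
    se_beta: pd.Series
    sigma_u: float
    pi: float
    loglik: float
    converged: bool
    n_obs: int
    n_groups: int
    method: str = "agq"
    n_nodes: int = 15
    cov_params: np.ndarray | None = None
    param_names: list = field(default_factory=list)
    levels: dict = field(default_factory=dict)

    @property
    def n_params(self) -> int:
        return len(self.param_names)

    def to_dict(self) -> dict:
        return {
            "response": self.spec.response,
            "fixed_terms": list(self.spec.fixed_terms),
            "beta": {k: float(v) for k, v in self.beta.items()},
            "se_beta": {k: float(v) for k, v in self.se_beta.items()},
            "sigma_u": float(self.sigma_u),
            "pi": float(self.pi),
            "loglik": float(self.loglik),
            "converged": bool(self.converged),
            "n_obs": self.n_obs,
            "n_groups": self.n_groups,
            "method": self.method,
        }


# ---------------------------------------------------------------------------
# batched numerical core
# ---------------------------------------------------------------------------

def _obs_scores(y, lam, pi, log1m_pi, need_dpi=False, need_d2=False):
    """Per-observation ZIP log-lik, d/deta, optional d/dpi and d2/deta2.

    All arguments broadcast against the shape of ``lam``.
    """
    with np.errstate(divide="ignore"):
        log_pi = np.log(pi)
    logD = np.logaddexp(log_pi, log1m_pi - lam)  # log P(0)
    q = np.exp(log1m_pi - lam - logD)            # (1-pi)e^-lam / P(0), in (0,1]
    is_zero = y == 0
    ll = np.where(is_zero, logD, log1m_pi + y * np.log(lam) - lam - special.gammaln(y + 1.0))
    s = np.where(is_zero, -q * lam, y - lam)
    dpi = d2 = None
    if need_dpi:
        with np.errstate(divide="ignore", invalid="ignore"):
            dpi = np.where(is_zero, -np.expm1(-lam) / np.exp(logD), -1.0 / (1.0 - pi))
    if need_d2:
        d2 = np.where(is_zero, -q * lam * (1.0 - lam * (1.0 - q)), -lam)
    return ll, s, dpi, d2


class _Layout:
    """Shared observation layout: counts sorted by group, group boundaries."""

    def __init__(self, groups: np.ndarray):
        groups = np.asarray(groups)
        if np.any(np.diff(groups) < 0):
            raise ValueError("observations must be sorted by group")
        self.starts = np.r_[0, 1 + np.nonzero(np.diff(groups))[0]]
        self.g_index = np.cumsum(np.r_[0, np.diff(groups) != 0])
        self.n_groups = len(self.starts)
        self.n_obs = len(groups)

    def group_sum(self, arr: np.ndarray, axis: int = 1) -> np.ndarray:
        return np.add.reduceat(arr, self.starts, axis=axis)


def _linear_predictor(X, beta):
    if X.ndim == 2:
        return beta @ X.T
    return np.einsum("bnp,bp->bn", X, beta)


def _adapt_nodes(eta, sigma, y, pi, log1m_pi, lay: _Layout, K: int, v0=None):
    """Posterior mode and curvature of the scaled random effect, per group.

    Returns node positions ``v`` (B, G, K) and log-weights (B, G, K) such
    that the per-group marginal is ``logsumexp_k(logW + sum_obs ll)``.
    """
    B = eta.shape[0]
    v = np.zeros((B, lay.n_groups)) if v0 is None else v0.copy()
    sig = sigma[:, None]
    for _ in range(30):
        lam = np.exp(np.clip(eta + sig * v[:, lay.g_index], -30, 30))
        _, s, _, d2_obs = _obs_scores(y, lam, pi, log1m_pi, need_d2=True)
        d1 = sig * lay.group_sum(s) - v
        d2 = sig**2 * lay.group_sum(d2_obs) - 1.0
        step = d1 / np.maximum(-d2, 0.25)
        np.clip(step, -3.0, 3.0, out=step)
        v += step
        if np.max(np.abs(d1)) < 1e-7:
            break
    shat = 1.0 / np.sqrt(np.maximum(-d2, 1e-3))
    z, w = np.polynomial.hermite.hermgauss(K)
    nodes = v[..., None] + np.sqrt(2.0) * shat[..., None] * z
    logW = (
        np.log(w)
        + z**2
        + 0.5 * np.log(2.0)
        + np.log(shat)[..., None]
        - 0.5 * nodes**2
        - 0.5 * _LOG2PI
    )
    return nodes, logW, v


def _theta_unpack(theta, p, has_re, has_zi):
    beta = theta[:, :p]
    sigma = np.exp(theta[:, p]) if has_re else np.zeros(theta.shape[0])
    if has_zi:
        pi = special.expit(theta[:, p + has_re])
    else:
        pi = np.zeros(theta.shape[0])
    return beta, sigma, pi


def _loglik_grad(theta, y, X, lay, nodes, logW, p, has_re, has_zi, want_grad,
                 cache=None, want_group_scores=False):
    """Marginal log-likelihood and gradient with frozen quadrature nodes.

    ``cache`` optionally holds precomputed y-dependent pieces
    (``is_zero``, ``gammaln(y+1)``) shared across evaluations.  With
    ``want_group_scores`` the per-subject score vectors (B, G, q) are
    returned as a third element (their sum over subjects is the gradient),
    from which a BHHH/empirical-Fisher Hessian approximation can be built
    without extra likelihood evaluations.
    """
    beta, sigma, pi = _theta_unpack(theta, p, has_re, has_zi)
    eta = _linear_predictor(X, beta)
    v_obs = nodes[:, lay.g_index, :]  # (B, N, K)
    K = v_obs.shape[2]
    lin = np.clip(eta[..., None] + sigma[:, None, None] * v_obs, -30, 30)
    lam = np.exp(lin)
    pi_b = pi[:, None, None]
    with np.errstate(divide="ignore"):
        log_pi = np.log(pi_b)
    log1m = np.log1p(-pi_b)
    yk = y[..., None]
    if cache is None:
        is_zero = yk == 0
        gln = special.gammaln(y + 1.0)[..., None]
    else:
        is_zero, gln = cache
    logD = np.logaddexp(log_pi, log1m - lam)
    ll = np.where(is_zero, logD, log1m + yk * lin - lam - gln)
    S = lay.group_sum(ll)  # (B, G, K)
    A = logW + S
    if K == 1:
        Li = A[:, :, 0]
    else:
        Li = special.logsumexp(A, axis=2)  # (B, G)
    L = Li.sum(axis=1)
    if not want_grad:
        return L, None
    q = np.exp(log1m - lam - logD)
    s = np.where(is_zero, -q * lam, yk - lam)
    if K == 1:
        ws = s[:, :, 0]
        w_obs = None
    else:
        post = np.exp(A - Li[..., None])  # (B, G, K)
        w_obs = post[:, lay.g_index, :]   # (B, N, K)
        ws = (w_obs * s).sum(axis=2)      # (B, N)
    if want_group_scores:
        # per-observation q-dim score, then summed within subject
        cols = [ws[..., None] * X] if X.ndim == 3 else [ws[..., None] * X[None]]
        if has_re:
            if K == 1:
                wsv = ws * v_obs[:, :, 0]
            else:
                wsv = (w_obs * s * v_obs).sum(axis=2)
            cols.append((sigma[:, None] * wsv)[..., None])
        if has_zi:
            with np.errstate(divide="ignore", invalid="ignore"):
                dpi = np.where(
                    is_zero, -np.expm1(-lam) / np.exp(logD), -1.0 / (1.0 - pi_b)
                )
            if K == 1:
                wdpi = dpi[:, :, 0]
            else:
                wdpi = (w_obs * dpi).sum(axis=2)
            cols.append(((pi * (1 - pi))[:, None] * wdpi)[..., None])
        obs_scores = np.concatenate(cols, axis=2)  # (B, N, q)
        grp = lay.group_sum(obs_scores, axis=1)    # (B, G, q)
        return L, grp.sum(axis=1), grp
    if X.ndim == 2:
        gbeta = ws @ X
    else:
        gbeta = np.einsum("bn,bnp->bp", ws, X)
    parts = [gbeta]
    if has_re:
        if K == 1:
            grho = sigma * (ws * v_obs[:, :, 0]).sum(axis=1)
        else:
            grho = sigma * (w_obs * s * v_obs).sum(axis=(1, 2))
        parts.append(grho[:, None])
    if has_zi:
        with np.errstate(divide="ignore", invalid="ignore"):
            dpi = np.where(is_zero, -np.expm1(-lam) / np.exp(logD), -1.0 / (1.0 - pi_b))
        if K == 1:
            galpha = (pi * (1 - pi)) * dpi[:, :, 0].sum(axis=1)
        else:
            galpha = (pi * (1 - pi)) * (w_obs * dpi).sum(axis=(1, 2))
        parts.append(galpha[:, None])
    return L, np.hstack(parts)


def _clip_theta(theta, p, has_re, has_zi):
    if has_re:
        theta[:, p] = np.clip(theta[:, p], *_RHO_BOUNDS)
    if has_zi:
        theta[:, p + has_re] = np.clip(theta[:, p + has_re], *_ALPHA_BOUNDS)
    return theta


def _init_theta(y, X, lay, has_re, has_zi):
    """Poisson-IRLS start for beta, zero-excess start for pi, MoM for sigma."""
    B, N = y.shape
    p = X.shape[-1]
    beta = np.zeros((B, p))
    beta[:, 0] = np.log(y.mean(axis=1) + 0.01)
    Xs = X if X.ndim == 3 else np.broadcast_to(X, (B, N, p))
    for _ in range(8):
        eta = np.einsum("bnp,bp->bn", Xs, beta)
        lam = np.exp(np.clip(eta, -30, 30))
        z = eta + (y - lam) / np.maximum(lam, 1e-8)
        W = lam
        XtWX = np.einsum("bnp,bn,bnq->bpq", Xs, W, Xs) + 1e-8 * np.eye(p)
        XtWz = np.einsum("bnp,bn->bp", Xs, W * z)
        try:
            beta = np.linalg.solve(XtWX, XtWz[..., None])[..., 0]
        except np.linalg.LinAlgError:
            break
        np.clip(beta, -20, 20, out=beta)
    eta = np.einsum("bnp,bp->bn", Xs, beta)
    lam = np.exp(np.clip(eta, -30, 30))
    cols = [beta]
    if has_re:
        mu_g = lay.group_sum(y, axis=1) / lay.group_sum(np.ones_like(y, dtype=float))
        lam_g = lay.group_sum(lam) / lay.group_sum(np.ones_like(lam))
        u = np.log((mu_g + 0.5) / (lam_g + 0.5))
        sig0 = np.clip(u.std(axis=1), 0.05, 2.0)
        cols.append(np.log(sig0)[:, None])
    if has_zi:
        p0_obs = (y == 0).mean(axis=1)
        p0_mod = np.exp(-lam).mean(axis=1)
        pi0 = np.clip((p0_obs - p0_mod) / np.maximum(1 - p0_mod, 1e-6), 0.02, 0.8)
        cols.append(special.logit(pi0)[:, None])
    return np.hstack(cols)


def fit_zip_batch(
    y: np.ndarray,
    X: np.ndarray,
    groups: np.ndarray,
    *,
    n_nodes: int = 1,
    zero_inflation: bool = True,
    random_intercept: bool = True,
    max_outer: int = 6,
    max_newton: int = 5,
    tol: float = 1e-6,
    compute_se: bool = False,
    theta0: np.ndarray | None = None,
    final_readapt: bool = True,
):
    """Fit many ZIP random-intercept models sharing one observation layout.

    Parameters
    ----------
    y
        Counts of shape ``(B, N)``: B independent models over the same N
        observations (e.g. one model per region pair, or per permutation x
        region pair).
    X
        Fixed-effects design, shape ``(N, p)`` shared or ``(B, N, p)``.
    groups
        Integer group (subject) labels per observation, sorted ascending.
    n_nodes
        Quadrature nodes; 1 = Laplace fast mode.

    Returns
    -------
    dict with ``beta`` (B, p), ``sigma_u`` (B,), ``pi`` (B,), ``loglik``
    (B,), ``converged`` (B,) and, when ``compute_se``, ``se_beta`` (B, p)
    and ``cov`` (B, q, q) on the internal ``[beta, log sigma, logit pi]``
    parameterization.
    """
    y = np.asarray(y, dtype=float)
    B, N = y.shape
    p = X.shape[-1]
    lay = _Layout(groups)
    has_re = bool(random_intercept)
    has_zi = bool(zero_inflation)
    q = p + has_re + has_zi

    degenerate = ~(y > 0).any(axis=1)
    if theta0 is None:
        theta = _init_theta(y, X, lay, has_re, has_zi)
    else:
        theta = np.array(theta0, dtype=float)
    theta = _clip_theta(theta, p, has_re, has_zi)

    def nodes_for(th, v0=None):
        beta, sigma, pi = _theta_unpack(th, p, has_re, has_zi)
        eta = _linear_predictor(X, beta)
        K = n_nodes if has_re else 1
        if not has_re:
            # no random effect: single pseudo-group of zero-width nodes
            nodes = np.zeros((B, lay.n_groups, 1))
            logW = np.zeros((B, lay.n_groups, 1))
            return nodes, logW, None
        return _adapt_nodes(
            eta, sigma, y, pi[:, None], np.log1p(-pi)[:, None], lay, K, v0
        )

    _cache = (y[..., None] == 0, special.gammaln(y + 1.0)[..., None])

    def f_and_g(th, nodes, logW, want_grad=True, idx=None):
        if idx is None:
            return _loglik_grad(
                th, y, X, lay, nodes, logW, p, has_re, has_zi, want_grad, cache=_cache
            )
        Xi = X if X.ndim == 2 else X[idx]
        sub_cache = (_cache[0][idx], _cache[1][idx])
        return _loglik_grad(
            th[idx], y[idx], Xi, lay, nodes[idx], logW[idx],
            p, has_re, has_zi, want_grad, cache=sub_cache,
        )

    L_prev = np.full(B, -np.inf)
    converged = np.zeros(B, dtype=bool)
    vhat_all = np.zeros((B, lay.n_groups))
    act = np.arange(B)
    for outer in range(max_outer):
        if len(act) == 0:
            break
        y_s = y[act]
        X_s = X if X.ndim == 2 else X[act]
        cache_s = (_cache[0][act], _cache[1][act])
        th = theta[act]
        Bs = len(act)

        def fg(t, nd, lw, want_grad=True, idx=None):
            if idx is None:
                return _loglik_grad(
                    t, y_s, X_s, lay, nd, lw, p, has_re, has_zi, want_grad,
                    cache=cache_s,
                )
            Xi = X_s if X_s.ndim == 2 else X_s[idx]
            return _loglik_grad(
                t[idx], y_s[idx], Xi, lay, nd[idx], lw[idx], p, has_re, has_zi,
                want_grad, cache=(cache_s[0][idx], cache_s[1][idx]),
            )

        if has_re:
            beta_s, sigma_s, pi_s = _theta_unpack(th, p, has_re, has_zi)
            eta_s = _linear_predictor(X_s, beta_s)
            nodes, logW, vh = _adapt_nodes(
                eta_s, sigma_s, y_s, pi_s[:, None], np.log1p(-pi_s)[:, None],
                lay, n_nodes, vhat_all[act],
            )
            vhat_all[act] = vh
        else:
            nodes = np.zeros((Bs, lay.n_groups, 1))
            logW = np.zeros((Bs, lay.n_groups, 1))

        K_round = nodes.shape[2]
        th_round_start = th.copy()
        L, g, Sg = _loglik_grad(
            th, y_s, X_s, lay, nodes, logW, p, has_re, has_zi, True,
            cache=cache_s, want_group_scores=True,
        )
        A = None  # cached modified-Newton factor (K=1 path)
        for _ in range(max_newton):
            if K_round > 1:
                # BHHH direction: the empirical Fisher (sum of per-subject
                # score outer products) is positive definite by
                # construction, so the step is always ascent and costs no
                # extra likelihood evaluations
                Hb = np.einsum("bgq,bgr->bqr", Sg, Sg)
                ridge = 1e-6 + 1e-3 * np.einsum("bii->b", Hb) / q
                Hb += ridge[:, None, None] * np.eye(q)
                try:
                    d = np.linalg.solve(Hb, g[..., None])[..., 0]
                except np.linalg.LinAlgError:
                    d = g / (1.0 + np.abs(g).max(axis=1, keepdims=True))
            else:
                # single-node (Laplace) objective: the score outer product
                # is a poor curvature proxy there, so use a finite-
                # difference Hessian with clamped eigenvalues (always an
                # ascent direction), reused chord-style within the round
                if A is None:
                    H = np.empty((Bs, q, q))
                    for j in range(q):
                        epsj = 1e-5 * (1.0 + np.abs(th[:, j]))
                        th2 = th.copy()
                        th2[:, j] += epsj
                        _, g2 = fg(th2, nodes, logW)
                        H[:, :, j] = (g2 - g) / epsj[:, None]
                    H = 0.5 * (H + np.swapaxes(H, 1, 2))
                    try:
                        evals, evecs = np.linalg.eigh(-H)
                    except np.linalg.LinAlgError:
                        evals = np.ones((Bs, q))
                        evecs = np.broadcast_to(np.eye(q), (Bs, q, q)).copy()
                    A = (evecs, np.maximum(evals, 1e-2))
                evecs, evals = A
                d = np.einsum(
                    "bqk,bk->bq", evecs, np.einsum("bqk,bq->bk", evecs, g) / evals
                )
            # trust region: variance / zero-inflation moves interact with the
            # node adaptation, so keep per-step changes modest
            np.clip(d[:, :p], -2.0, 2.0, out=d[:, :p])
            np.clip(d[:, p:], -1.0, 1.0, out=d[:, p:])
            step = np.ones(Bs)
            improved = np.zeros(Bs, dtype=bool)
            L_new, th_new = L.copy(), th.copy()
            for _ls in range(10):
                open_idx = np.nonzero(~improved)[0]
                if len(open_idx) == 0:
                    break
                trial = _clip_theta(th + step[:, None] * d, p, has_re, has_zi)
                Lt = np.full(Bs, -np.inf)
                Lt[open_idx], _ = fg(trial, nodes, logW, want_grad=False, idx=open_idx)
                better = (Lt > L_new) & ~improved & np.isfinite(Lt)
                th_new[better] = trial[better]
                L_new[better] = Lt[better]
                improved |= better | (
                    ~improved
                    & np.isfinite(Lt)
                    & (np.abs(Lt - L) < tol * (1 + np.abs(L)))
                )
                step *= 0.5
            if np.any(step < 0.5):
                A = None  # direction was poor somewhere: refresh curvature
            moved = np.abs(L_new - L) > tol * (1 + np.abs(L))
            th = th_new
            L, g, Sg = _loglik_grad(
                th, y_s, X_s, lay, nodes, logW, p, has_re, has_zi, True,
                cache=cache_s, want_group_scores=True,
            )
            if not moved.any():
                break
        theta[act] = th
        # convergence: the marginal log-likelihood is stable across node
        # re-adaptation rounds, or the parameters themselves have stopped
        # moving (the Laplace objective value jitters slightly as nodes
        # re-centre even at a parameter fixed point)
        stable_L = np.abs(L - L_prev[act]) < tol * (1 + np.abs(L))
        stable_th = np.max(np.abs(th - th_round_start), axis=1) < 1e-4
        done = (stable_L | stable_th) & np.isfinite(L)
        L_prev[act] = L
        if outer >= 1:
            converged[act] = done
            act = act[~done]
    # final re-adaptation for an honest marginal log-likelihood (skippable
    # in permutation loops where only the coefficients are consumed)
    if final_readapt or compute_se:
        nodes, logW, _ = nodes_for(theta, vhat_all)
        L, g = f_and_g(theta, nodes, logW)
    else:
        L, g = L_prev, None
    if g is not None:
        gnorm_ok = np.max(np.abs(g), axis=1) < 1e-2 * (1 + np.abs(L))
        converged = (converged | gnorm_ok) & np.isfinite(L) & ~degenerate
    else:
        converged = converged & np.isfinite(L) & ~degenerate

    # rare Laplace stalls: retry the failed items with a denser quadrature
    failed = ~converged & ~degenerate
    if has_re and n_nodes < 7 and failed.any() and max_outer > 2:
        retry = fit_zip_batch(
            y[failed],
            X if X.ndim == 2 else X[failed],
            groups,
            n_nodes=7,
            zero_inflation=has_zi,
            random_intercept=has_re,
            max_outer=max_outer,
            max_newton=max_newton,
            tol=tol,
            compute_se=False,
        )
        theta[failed] = retry["theta"]
        converged[failed] = retry["converged"]
        L[failed] = retry["loglik"]
        nodes, logW, _ = nodes_for(theta, vhat_all)
        L2, _ = f_and_g(theta, nodes, logW, want_grad=False)
        L = np.where(failed & converged, L2, L)

    beta, sigma, pi = _theta_unpack(theta, p, has_re, has_zi)
    out = {
        "beta": np.where(degenerate[:, None], np.nan, beta),
        "sigma_u": np.where(degenerate, np.nan, sigma),
        "pi": np.where(degenerate, np.nan, pi),
        "loglik": np.where(degenerate, np.nan, L),
        "converged": converged,
        "theta": theta,
        "n_obs": N,
        "n_groups": lay.n_groups,
    }
    if compute_se:
        H = np.empty((B, q, q))
        for j in range(q):
            epsj = 1e-5 * (1.0 + np.abs(theta[:, j]))
            thp = theta.copy()
            thp[:, j] += epsj
            thm = theta.copy()
            thm[:, j] -= epsj
            _, gp = f_and_g(thp, nodes, logW)
            _, gm = f_and_g(thm, nodes, logW)
            H[:, :, j] = (gp - gm) / (2 * epsj[:, None])
        H = 0.5 * (H + np.swapaxes(H, 1, 2))
        cov = np.full((B, q, q), np.nan)
        se = np.full((B, p), np.nan)
        ok = converged.copy()
        for b in np.nonzero(ok)[0]:
            try:
                cb = np.linalg.inv(-H[b] + 1e-10 * np.eye(q))
                if np.all(np.diag(cb)[:p] > 0):
                    cov[b] = cb
                    se[b] = np.sqrt(np.diag(cb)[:p])
                else:
                    out["converged"][b] = False
            except np.linalg.LinAlgError:
                out["converged"][b] = False
        out["se_beta"] = se
        out["cov"] = cov
    return out


# ---------------------------------------------------------------------------
# public single-model API
# ---------------------------------------------------------------------------

def _prepare(spec: ModelSpec, data: pd.DataFrame, levels=None):
    group_col = spec.random_intercept_group
    if group_col is not None:
        if group_col not in data.columns:
            raise KeyError(f"grouping column {group_col!r} not in data")
        data = data.sort_values(group_col, kind="stable").reset_index(drop=True)
        codes = pd.factorize(data[group_col])[0]
    else:
        codes = np.zeros(len(data), dtype=int)
    X, names, levels = build_design(data, spec.fixed_terms, levels)
    y = data[spec.response].to_numpy(dtype=float)
    if np.any(y < 0) or np.any(y != np.rint(y)):
        raise ValueError("response must contain non-negative integer counts")
    return y, X, codes, names, levels, data


def marginal_loglik(
    spec: ModelSpec,
    params: dict,
    data: pd.DataFrame,
    *,
    n_nodes: int = 15,
) -> float:
    """Marginal log-likelihood at candidate parameters.

    ``params`` holds ``beta`` (sequence aligned with the design columns of
    ``spec``), ``sigma_u`` and ``pi``.  The subject random intercept is
    integrated out with ``n_nodes``-point adaptive Gauss--Hermite
    quadrature (1 node = Laplace).
    """
    y, X, codes, names, _, _ = _prepare(spec, data)
    beta = np.asarray(params["beta"], dtype=float)
    if beta.shape != (X.shape[1],):
        raise ValueError(f"beta must have length {X.shape[1]} ({names})")
    sigma = float(params.get("sigma_u", 0.0))
    pi = float(params.get("pi", 0.0))
    if sigma < 0:
        raise ValueError("sigma_u must be >= 0")
    lay = _Layout(codes)
    eta = (X @ beta)[None, :]
    if not np.all(np.isfinite(eta)):
        raise FloatingPointError("non-finite linear predictor")
    if sigma == 0.0:
        return float(zip_logpmf(y, np.exp(np.clip(eta[0], -30, 30)), pi).sum())
    nodes, logW, _ = _adapt_nodes(
        eta, np.array([sigma]), y[None, :], pi, np.log1p(-pi), lay, n_nodes
    )
    theta = np.r_[beta, np.log(sigma), special.logit(max(pi, 1e-12))][None, :]
    has_zi = True
    L, _ = _loglik_grad(
        theta, y[None, :], X, lay, nodes, logW, X.shape[1], True, has_zi, False
    )
    return float(L[0])


def _fit_single(y, X, codes, n_nodes, has_re, has_zi, tol=1e-6):
    """Quasi-Newton fit of one model, re-adapting nodes per evaluation.

    Single fits (e.g. the heavily structured frontoparietal models) can
    sit in ill-conditioned likelihood valleys where the batched damped
    Newton crawls; L-BFGS-B on the exactly re-adapted objective is robust
    there.  Returns the same dict layout as :func:`fit_zip_batch`.
    """
    p = X.shape[1]
    q = p + has_re + has_zi
    lay = _Layout(codes)
    yb = y[None, :]
    cache = (yb[..., None] == 0, special.gammaln(yb + 1.0)[..., None])

    def eval_Lg(theta_flat, want_grad=True):
        th = theta_flat[None, :]
        beta, sigma, pi = _theta_unpack(th, p, has_re, has_zi)
        if has_re:
            eta = _linear_predictor(X, beta)
            nodes, logW, _ = _adapt_nodes(
                eta, sigma, yb, pi[:, None], np.log1p(-pi)[:, None], lay, n_nodes
            )
        else:
            nodes = np.zeros((1, lay.n_groups, 1))
            logW = np.zeros((1, lay.n_groups, 1))
        L, g = _loglik_grad(
            th, yb, X, lay, nodes, logW, p, has_re, has_zi, want_grad, cache=cache
        )
        return L[0], (None if g is None else g[0])

    def objective(theta_flat):
        L, g = eval_Lg(theta_flat)
        if not np.isfinite(L):
            return np.inf, np.zeros(q)
        return -L, -g

    theta0 = _init_theta(yb, X, lay, has_re, has_zi)[0]
    theta0 = _clip_theta(theta0[None, :], p, has_re, has_zi)[0]
    bounds = [(None, None)] * p
    if has_re:
        bounds.append(_RHO_BOUNDS)
    if has_zi:
        bounds.append(_ALPHA_BOUNDS)
    if has_re and n_nodes == 1:
        # the single-node (Laplace) objective's gradient is not the
        # mode-score; use finite differences of the re-adapted objective
        opt = optimize.minimize(
            lambda t: objective(t)[0],
            theta0,
            jac=None,
            method="L-BFGS-B",
            bounds=bounds,
            options={"maxiter": 500, "ftol": tol, "gtol": 1e-6},
        )
    else:
        opt = optimize.minimize(
            objective,
            theta0,
            jac=True,
            method="L-BFGS-B",
            bounds=bounds,
            options={"maxiter": 500, "ftol": tol, "gtol": 1e-6},
        )
    theta = opt.x[None, :]
    L, g = eval_Lg(opt.x)
    if has_re and n_nodes == 1:
        converged = bool(opt.success)
        # value-based observed information (the single-node gradient proxy
        # is not the Laplace objective's gradient)
        H = np.empty((q, q))
        eps = 1e-4 * (1 + np.abs(opt.x))
        f0 = L

        def val(t):
            return eval_Lg(t, want_grad=False)[0]

        for i in range(q):
            for j in range(i, q):
                if i == j:
                    tp, tm = opt.x.copy(), opt.x.copy()
                    tp[i] += eps[i]
                    tm[i] -= eps[i]
                    H[i, i] = (val(tp) - 2 * f0 + val(tm)) / eps[i] ** 2
                else:
                    tpp, tpm = opt.x.copy(), opt.x.copy()
                    tmp, tmm = opt.x.copy(), opt.x.copy()
                    tpp[[i, j]] += eps[[i, j]]
                    tpm[i] += eps[i]
                    tpm[j] -= eps[j]
                    tmp[i] -= eps[i]
                    tmp[j] += eps[j]
                    tmm[[i, j]] -= eps[[i, j]]
                    H[i, j] = H[j, i] = (
                        val(tpp) - val(tpm) - val(tmp) + val(tmm)
                    ) / (4 * eps[i] * eps[j])
    else:
        converged = bool(opt.success or np.max(np.abs(g)) < 1e-3 * (1 + abs(L)))
        # observed information by central differences of the gradient
        H = np.empty((q, q))
        for j in range(q):
            eps_j = 1e-5 * (1 + abs(opt.x[j]))
            tp, tm = opt.x.copy(), opt.x.copy()
            tp[j] += eps_j
            tm[j] -= eps_j
            _, gp = eval_Lg(tp)
            _, gm = eval_Lg(tm)
            H[:, j] = (gp - gm) / (2 * eps_j)
        H = 0.5 * (H + H.T)
    beta, sigma, pi = _theta_unpack(theta, p, has_re, has_zi)
    cov = np.full((q, q), np.nan)
    se = np.full(p, np.nan)
    try:
        c = np.linalg.inv(-H + 1e-10 * np.eye(q))
        if np.all(np.diag(c)[:p] > 0):
            cov, se = c, np.sqrt(np.diag(c)[:p])
        else:
            converged = False
    except np.linalg.LinAlgError:
        converged = False
    return {
        "beta": beta,
        "sigma_u": sigma,
        "pi": pi,
        "loglik": np.array([L]),
        "converged": np.array([converged]),
        "se_beta": se[None, :],
        "cov": cov[None, :, :],
        "n_obs": len(y),
        "n_groups": lay.n_groups,
    }


def fit_zip_glmm(
    spec: ModelSpec,
    data: pd.DataFrame,
    *,
    n_nodes: int = 15,
    method: str = "agq",
) -> ZipGlmmFit:
    """Fit a ZIP mixed model by maximum marginal likelihood.

    ``method="laplace"`` forces the single-node fast mode.  A model whose
    response is all zero, or whose optimizer fails, is returned with
    ``converged=False`` (never an exception) so selection and permutation
    loops can skip it.
    """
    if method == "laplace":
        n_nodes = 1
    y, X, codes, names, levels, sorted_data = _prepare(spec, data)
    has_re = spec.random_intercept_group is not None
    if not (y > 0).any():
        res = {
            "beta": np.full((1, X.shape[1]), np.nan),
            "se_beta": np.full((1, X.shape[1]), np.nan),
            "sigma_u": np.array([np.nan]),
            "pi": np.array([np.nan]),
            "loglik": np.array([np.nan]),
            "converged": np.array([False]),
            "cov": np.full((1, 1, 1), np.nan),
            "n_obs": len(y),
            "n_groups": len(np.unique(codes)),
        }
    else:
        res = _fit_single(
            y, X, codes, n_nodes, has_re, spec.zero_inflation == "constant"
        )
    pnames = list(names)
    if has_re:
        pnames.append("log_sigma_u")
    if spec.zero_inflation == "constant":
        pnames.append("logit_pi")
    return ZipGlmmFit(
        spec=spec,
        beta=pd.Series(res["beta"][0], index=names),
        se_beta=pd.Series(res["se_beta"][0], index=names),
        sigma_u=float(res["sigma_u"][0]) if has_re else 0.0,
        pi=float(res["pi"][0]) if spec.zero_inflation == "constant" else 0.0,
        loglik=float(res["loglik"][0]),
        converged=bool(res["converged"][0]),
        n_obs=int(res["n_obs"]),
        n_groups=int(res["n_groups"]),
        method="laplace" if n_nodes == 1 else "agq",
        n_nodes=n_nodes,
        cov_params=res["cov"][0],
        param_names=pnames,
        levels=levels,
    )


@dataclass(frozen=True)
class LRTResult:
    statistic: float
    df: int
    pvalue: float


def likelihood_ratio_test(fit_full: ZipGlmmFit, fit_reduced: ZipGlmmFit) -> LRTResult:
    """Chi-square likelihood-ratio test of nested ZIP mixed models."""
    if not (set(fit_reduced.spec.fixed_terms) <= set(fit_full.spec.fixed_terms)):
        raise ValueError("models are not nested (reduced terms not a subset)")
    if fit_full.spec.response != fit_reduced.spec.response:
        raise ValueError("models have different responses")
    if not (fit_full.converged and fit_reduced.converged):
        raise ValueError("both fits must have converged")
    df = fit_full.n_params - fit_reduced.n_params
    stat = max(2.0 * (fit_full.loglik - fit_reduced.loglik), 0.0)
    p = float(stats.chi2.sf(stat, df)) if df > 0 else 1.0
    return LRTResult(statistic=stat, df=df, pvalue=p)


def predict_marginal_mean(fit: ZipGlmmFit, at: pd.DataFrame | dict) -> pd.DataFrame:
    """Expected count marginal over the random intercept, with delta SE.

    The marginal mean is ``(1 - pi) * exp(x beta + sigma_u^2 / 2)``; the
    standard error propagates the full parameter covariance through the
    log of that expression.
    """
    if not fit.converged:
        raise ValueError("fit did not converge")
    grid = pd.DataFrame(at if isinstance(at, (pd.DataFrame, dict)) else at)
    if isinstance(at, dict):
        grid = pd.DataFrame({k: np.atleast_1d(v) for k, v in at.items()})
    X, names, _ = build_design(grid, fit.spec.fixed_terms, fit.levels)
    if names != list(fit.beta.index):
        raise KeyError(
            "prediction grid does not reproduce the fit's design columns; "
            f"expected {list(fit.beta.index)}, got {names}"
        )
    p = X.shape[1]
    q = fit.cov_params.shape[0]
    log_m = X @ fit.beta.to_numpy() + 0.5 * fit.sigma_u**2 + np.log1p(-fit.pi)
    G = np.zeros((len(grid), q))
    G[:, :p] = X
    j = p
    if fit.spec.random_intercept_group is not None:
        G[:, j] = fit.sigma_u**2  # d(sigma^2/2)/d log sigma
        j += 1
    if fit.spec.zero_inflation == "constant":
        G[:, j] = -fit.pi  # d log(1-pi)/d logit pi
    var = np.einsum("np,pq,nq->n", G, fit.cov_params, G)
    est = np.exp(log_m)
    out = grid.copy()
    out["estimate"] = est
    out["se"] = est * np.sqrt(np.maximum(var, 0.0))
    return out
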