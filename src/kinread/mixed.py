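"""Mixed-effects models by maximum likelihood with a Laplace approximation.

Supports the three families used by the trial-level analyses:

* ``gamma-identity`` — RTs linearly affected by predictors (shape
  estimated by ML);
* ``binomial-logit`` — binary outcomes (fixations, accuracies);
* ``cumulative-logit`` — ordinal confidence ratings (lowest two
  categories collapsed before fitting when four are present).

Random effects are independent (diagonal-covariance) intercepts and
slopes for crossed grouping factors.  For fixed variance parameters the
joint penalized likelihood is maximized over fixed effects and random
effects by damped Newton steps; the marginal likelihood is the Laplace
approximation, maximized over variance parameters (and the gamma shape)
by Nelder-Mead.  Reported log-likelihoods are comparable across nested
fits (LRT) and enter BIC for random-effects selection.

Categorical predictors use sum contrasts (first level +1, last level -1
for two-level factors), matching the convention where a two-level
coefficient is half the cell-mean difference.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import optimize, stats
from scipy.special import expit, gammaln

from .exceptions import FittingError, SchemaError

__all__ = [
    "RandomTerm",
    "ModelSpec",
    "MixedFitResult",
    "fit_mixed",
    "lrt",
    "select_random_effects",
]


@dataclass(frozen=True)
class RandomTerm:
    """Random effects for one grouping factor: '1' is an intercept, other
    entries are (numeric or two-level categorical) slope covariates."""

    group: str
    terms: tuple[str, ...] = ("1",)


@dataclass(frozen=True)
class ModelSpec:
    response: str
    family: str
    fixed: tuple[str, ...] = ()
    random: tuple[RandomTerm, ...] = ()

    def __post_init__(self):
        if self.family not in ("gamma-identity", "binomial-logit", "cumulative-logit"):
            raise SchemaError(f"unknown family: {self.family}")

    def drop_fixed(self, *terms: str) -> "ModelSpec":
        missing = set(terms) - set(self.fixed)
        if missing:
            raise SchemaError(f"terms not in spec: {sorted(missing)}")
        return replace(self, fixed=tuple(t for t in self.fixed if t not in terms))


# --------------------------------------------------------------------------
# design building

def _encode_column(df: pd.DataFrame, name: str, levels_map: dict | None = None):
    """Encode one column: numeric as-is, categorical as sum contrasts.

    ``levels_map`` carries the training-time level sets so prediction
    grids reproduce the fitted design even when a level is absent.
    """
    col = df[name]
    known = None if levels_map is None else levels_map.get(name)
    if known is None and pd.api.types.is_numeric_dtype(col) and not isinstance(
        col.dtype, pd.CategoricalDtype
    ):
        return col.to_numpy(dtype=float)[:, None], [name], {name: None}
    levels = known if known is not None else sorted(map(str, col.dropna().unique()))
    if len(levels) < 2:
        raise SchemaError(f"factor {name!r} has fewer than 2 levels")
    vals = col.astype(str).to_numpy()
    cols, names = [], []
    for lev in levels[:-1]:
        c = np.where(vals == lev, 1.0, np.where(vals == levels[-1], -1.0, 0.0))
        cols.append(c)
        names.append(f"{name}[{lev}]")
    return np.stack(cols, axis=1), names, {name: levels}


def _encode_term(df: pd.DataFrame, term: str, levels_map: dict | None = None):
    """Encode a (possibly interaction) term such as 'a:b:c'."""
    if term == "1":
        return np.ones((len(df), 1)), ["(Intercept)"], {}
    parts = term.split(":")
    mat, names, meta = _encode_column(df, parts[0], levels_map)
    for p in parts[1:]:
        m2, n2, meta2 = _encode_column(df, p, levels_map)
        mat = np.einsum("ni,nj->nij", mat, m2).reshape(len(df), -1)
        names = [f"{a}:{b}" for a in names for b in n2]
        meta.update(meta2)
    return mat, names, meta


def _build_fixed(df: pd.DataFrame, spec: ModelSpec, intercept: bool,
                 levels_map: dict | None = None):
    cols, names, meta = [], [], {}
    if intercept:
        cols.append(np.ones((len(df), 1)))
        names.append("(Intercept)")
    for term in spec.fixed:
        m, n, md = _encode_term(df, term, levels_map)
        cols.append(m)
        names.extend(n)
        meta.update(md)
    X = np.concatenate(cols, axis=1) if cols else np.zeros((len(df), 0))
    return X, names, meta


class _RandomStructure:
    """Covariate matrices and level codes for all random terms."""

    def __init__(self, df: pd.DataFrame, terms: tuple[RandomTerm, ...]):
        self.entries = []  # (group, codes, n_levels, S, covariate names)
        self.comp_names: list[str] = []
        for rt in terms:
            codes, levels = pd.factorize(df[rt.group].astype(str), sort=True)
            cols, names = [], []
            for t in rt.terms:
                m, n, _ = _encode_term(df, t)
                if m.shape[1] != 1:
                    raise SchemaError(
                        f"random slope {t!r} must encode to a single column"
                    )
                cols.append(m[:, 0])
                names.append(t)
            S = np.stack(cols, axis=1)
            self.entries.append((rt.group, codes, len(levels), S, names))
            self.comp_names.extend(f"{t}|{rt.group}" for t in names)
        self.block_sizes = [L * S.shape[1] for _, _, L, S, _ in self.entries]
        self.q = int(sum(self.block_sizes))
        self.offsets = np.concatenate([[0], np.cumsum(self.block_sizes)])[:-1]
        self.n_components = len(self.comp_names)

    def component_index(self):
        """Map each u element to its variance-component index."""
        idx = np.empty(self.q, dtype=int)
        comp = 0
        for e, (_, _, L, S, _) in enumerate(self.entries):
            off = self.offsets[e]
            for c in range(S.shape[1]):
                idx[off + c * L : off + (c + 1) * L] = comp
                comp += 1
        return idx

    def eta(self, u: np.ndarray, n: int) -> np.ndarray:
        out = np.zeros(n)
        for e, (_, codes, L, S, _) in enumerate(self.entries):
            off = self.offsets[e]
            for c in range(S.shape[1]):
                out += S[:, c] * u[off + c * L : off + (c + 1) * L][codes]
        return out

    def zt_dot(self, v: np.ndarray) -> np.ndarray:
        """Z' v via weighted bincounts."""
        out = np.empty(self.q)
        for e, (_, codes, L, S, _) in enumerate(self.entries):
            off = self.offsets[e]
            for c in range(S.shape[1]):
                out[off + c * L : off + (c + 1) * L] = np.bincount(
                    codes, weights=v * S[:, c], minlength=L
                )
        return out

    def zt_diag_z(self, h: np.ndarray) -> np.ndarray:
        """Z' diag(h) Z, exploiting the indicator structure."""
        M = np.zeros((self.q, self.q))
        E = self.entries
        for e1, (_, c1, L1, S1, _) in enumerate(E):
            o1 = self.offsets[e1]
            m1 = S1.shape[1]
            for a in range(m1):
                for b in range(a, m1):
                    d = np.bincount(c1, weights=h * S1[:, a] * S1[:, b], minlength=L1)
                    idx = np.arange(L1)
                    M[o1 + a * L1 + idx, o1 + b * L1 + idx] += d
                    if a != b:
                        M[o1 + b * L1 + idx, o1 + a * L1 + idx] += d
            for e2 in range(e1 + 1, len(E)):
                _, c2, L2, S2, _ = E[e2]
                o2 = self.offsets[e2]
                for a in range(m1):
                    for b in range(S2.shape[1]):
                        blk = np.zeros((L1, L2))
                        np.add.at(blk, (c1, c2), h * S1[:, a] * S2[:, b])
                        M[o1 + a * L1 : o1 + (a + 1) * L1,
                          o2 + b * L2 : o2 + (b + 1) * L2] += blk
                        M[o2 + b * L2 : o2 + (b + 1) * L2,
                          o1 + a * L1 : o1 + (a + 1) * L1] += blk.T
        return M

    def xt_diag_z(self, h: np.ndarray, X: np.ndarray) -> np.ndarray:
        k = X.shape[1]
        M = np.empty((k, self.q))
        for e, (_, codes, L, S, _) in enumerate(self.entries):
            off = self.offsets[e]
            for c in range(S.shape[1]):
                w = h * S[:, c]
                for a in range(k):
                    M[a, off + c * L : off + (c + 1) * L] = np.bincount(
                        codes, weights=w * X[:, a], minlength=L
                    )
        return M


# --------------------------------------------------------------------------
# families

class _Family:
    n_aux = 0

    def loglik(self, y, eta, aux):  # pragma: no cover - interface
        raise NotImplementedError

    def g_h(self, y, eta, aux):
        """Per-observation dl/deta and positive curvature -E[d2l/deta2]."""
        raise NotImplementedError

    def valid_eta(self, eta):
        return True


class _GammaIdentity(_Family):
    n_aux = 1  # log shape

    def loglik(self, y, eta, aux):
        k = np.exp(aux[0])
        mu = eta
        return float(
            np.sum(k * np.log(k / mu) + (k - 1) * np.log(y) - k * y / mu - gammaln(k))
        )

    def g_h(self, y, eta, aux):
        k = np.exp(aux[0])
        mu = eta
        return k * (y - mu) / mu**2, k / mu**2

    def valid_eta(self, eta):
        return bool(np.all(eta > 1e-6))


class _BinomialLogit(_Family):
    def loglik(self, y, eta, aux):
        return float(np.sum(y * eta - np.logaddexp(0.0, eta)))

    def g_h(self, y, eta, aux):
        p = expit(eta)
        return y - p, np.maximum(p * (1 - p), 1e-10)


_FAMILIES = {"gamma-identity": _GammaIdentity, "binomial-logit": _BinomialLogit}


# --------------------------------------------------------------------------
# results

@dataclass
class MixedFitResult:
    spec: ModelSpec
    fixed_names: list[str]
    coef: np.ndarray
    se: np.ndarray
    vcov: np.ndarray
    loglik: float
    bic: float
    n_obs: int
    n_params: int
    converged: bool
    varcomp: dict[str, float]
    shape: float | None = None
    cutpoints: np.ndarray | None = None
    u_hat: np.ndarray | None = None
    meta: dict = field(default_factory=dict)

    def summary(self) -> pd.DataFrame:
        z = self.coef / self.se
        return pd.DataFrame(
            {
                "estimate": self.coef,
                "se": self.se,
                "z": z,
                "p": 2 * stats.norm.sf(np.abs(z)),
            },
            index=self.fixed_names,
        )

    def predict_eta(self, newdata: pd.DataFrame) -> np.ndarray:
        """Population-level linear predictor (random effects at zero)."""
        return self.eta_gradient(newdata) @ self.coef

    def eta_gradient(self, newdata: pd.DataFrame) -> np.ndarray:
        X, names, _ = _build_fixed(
            newdata, self.spec,
            intercept=self.spec.family != "cumulative-logit",
            levels_map=self.meta.get("levels"),
        )
        if names != self.fixed_names:
            raise SchemaError("newdata does not reproduce the fitted design")
        return X


# --------------------------------------------------------------------------
# inner solvers

def _solve_psd(M, g):
    ridge = 0.0
    for _ in range(8):
        try:
            L = np.linalg.cholesky(M + ridge * np.eye(M.shape[0]))
            x = np.linalg.solve(L.T, np.linalg.solve(L, g))
            return x
        except np.linalg.LinAlgError:
            ridge = max(ridge * 10, 1e-8 * (1 + np.abs(np.diag(M)).max()))
    raise FittingError("Hessian not positive definite")


def _inner_glm(y, X, rs, family, aux, pen, z0, max_iter=80, tol=1e-9):
    """Maximize the penalized log-likelihood over (beta, u).

    ``pen`` is the diagonal penalty (0 for fixed effects, 1/sigma^2 for
    random effects).  Returns the mode, the penalized ll at the mode and
    the per-observation curvature there.
    """
    n, k = X.shape
    z = z0.copy()

    def split(z):
        return z[:k], z[k:]

    def eta_of(z):
        b, u = split(z)
        return X @ b + rs.eta(u, n)

    def pll(z, eta):
        return family.loglik(y, eta, aux) - 0.5 * float(np.sum(pen * z**2))

    eta = eta_of(z)
    if not family.valid_eta(eta):
        # pull the linear predictor into the valid region (gamma identity)
        b, u = split(z)
        z = np.concatenate([b, u * 0])
        if k > 0:
            z[:k] = 0
            # crude valid start: intercept at mean(y)
            z[0] = float(np.mean(y))
        eta = eta_of(z)
        if not family.valid_eta(eta):
            raise FittingError("no valid starting point for the mean model")
    f = pll(z, eta)
    converged = False
    for _ in range(max_iter):
        g_i, h_i = family.g_h(y, eta, aux)
        grad = np.concatenate([X.T @ g_i, rs.zt_dot(g_i)]) - pen * z
        gnorm = float(np.max(np.abs(grad))) if grad.size else 0.0
        if gnorm < tol * (1.0 + abs(f)):
            converged = True
            break
        XtX = (X * h_i[:, None]).T @ X
        XtZ = rs.xt_diag_z(h_i, X)
        ZtZ = rs.zt_diag_z(h_i)
        M = np.block([[XtX, XtZ], [XtZ.T, ZtZ]]) + np.diag(pen)
        step = _solve_psd(M, grad)
        t = 1.0
        improved = False
        for _ in range(40):
            z_new = z + t * step
            eta_new = eta_of(z_new)
            if family.valid_eta(eta_new):
                f_new = pll(z_new, eta_new)
                if f_new >= f - 1e-12:
                    z, eta, f = z_new, eta_new, f_new
                    improved = True
                    break
            t *= 0.5
        if not improved:
            break
    g_i, h_i = family.g_h(y, eta, aux)
    return z, f, h_i, converged


def _clmm_loglik_parts(y_cat, eta, cuts):
    """Cumulative-logit per-observation pieces.

    ``y_cat`` holds 0-based category codes; ``cuts`` the ordered
    thresholds.  Returns ll plus first/second derivative accumulators with
    respect to eta and the cutpoints.
    """
    J = len(cuts) + 1
    big = 1e10
    upper = np.concatenate([cuts, [big]])[y_cat] - eta
    lower = np.concatenate([[-big], cuts])[y_cat] - eta
    Fa, Fb = expit(upper), expit(lower)
    p = np.clip(Fa - Fb, 1e-12, None)
    ll = float(np.sum(np.log(p)))
    fa = Fa * (1 - Fa)
    fb = Fb * (1 - Fb)
    dla = fa / p
    dlb = -fb / p
    d_eta = -(dla + dlb)
    faa = fa * (1 - 2 * Fa)
    fbb = fb * (1 - 2 * Fb)
    laa = faa / p - dla**2
    lbb = -fbb / p - dlb**2
    lab = fa * fb / p**2
    h_eta = -(laa + 2 * lab + lbb)  # positive curvature wrt eta
    return ll, dla, dlb, d_eta, h_eta, laa, lbb, lab


def _inner_clmm(y_cat, X, rs, n_cut, pen_bu, z0, max_iter=80, tol=1e-9):
    """Penalized-likelihood mode over (cutpoints, beta, u)."""
    n, k = X.shape

    def unpack(z):
        return z[:n_cut], z[n_cut : n_cut + k], z[n_cut + k :]

    def eta_of(c, b, u):
        return X @ b + rs.eta(u, n)

    def pll(z):
        c, b, u = unpack(z)
        if np.any(np.diff(c) <= 0):
            return None, None
        eta = eta_of(c, b, u)
        ll = _clmm_loglik_parts(y_cat, eta, c)[0]
        return ll - 0.5 * float(np.sum(pen_bu * np.concatenate([b, u]) ** 2)), eta

    z = z0.copy()
    f, eta = pll(z)
    if f is None:
        raise FittingError("invalid cutpoint start")
    converged = False
    h_eta = None
    for _ in range(max_iter):
        c, b, u = unpack(z)
        ll, dla, dlb, d_eta, h_eta, laa, lbb, lab = _clmm_loglik_parts(y_cat, eta, c)
        # gradient; cut j is the upper bound of category j, lower of j+1
        g_c = np.zeros(n_cut)
        for j in range(n_cut):
            g_c[j] = float(np.sum(dla[y_cat == j])) + float(np.sum(dlb[y_cat == j + 1]))
        g_b = X.T @ d_eta - pen_bu[:k] * b
        g_u = rs.zt_dot(d_eta) - pen_bu[k:] * u
        grad = np.concatenate([g_c, g_b, g_u])
        if float(np.max(np.abs(grad))) < tol * (1.0 + abs(f)):
            converged = True
            break
        # negative Hessian assembly
        M_cc = np.zeros((n_cut, n_cut))
        for j in range(n_cut):
            M_cc[j, j] = -(float(np.sum(laa[y_cat == j])) + float(np.sum(lbb[y_cat == j + 1])))
            if j + 1 < n_cut:
                v = -float(np.sum(lab[y_cat == j + 1]))
                M_cc[j, j + 1] += v
                M_cc[j + 1, j] += v
        # cross cut x (eta coefficients): d2l/(dc_j d eta)
        cross = np.zeros((n_cut, n))
        for j in range(n_cut):
            mj = y_cat == j
            cross[j, mj] += laa[mj] + lab[mj]
            mj1 = y_cat == j + 1
            cross[j, mj1] += lab[mj1] + lbb[mj1]
        M_cb = cross @ X
        M_cu = np.stack([rs.zt_dot(cross[j]) for j in range(n_cut)]) if rs.q else np.zeros((n_cut, 0))
        XtX = (X * h_eta[:, None]).T @ X
        XtZ = rs.xt_diag_z(h_eta, X)
        ZtZ = rs.zt_diag_z(h_eta)
        M = np.block(
            [
                [M_cc, M_cb, M_cu],
                [M_cb.T, XtX, XtZ],
                [M_cu.T, XtZ.T, ZtZ],
            ]
        )
        M[n_cut:, n_cut:] += np.diag(pen_bu)
        step = _solve_psd(M, grad)
        t = 1.0
        improved = False
        for _ in range(40):
            z_new = z + t * step
            f_new, eta_new = pll(z_new)
            if f_new is not None and f_new >= f - 1e-12:
                z, f, eta = z_new, f_new, eta_new
                improved = True
                break
            t *= 0.5
        if not improved:
            break
    if h_eta is None:
        h_eta = _clmm_loglik_parts(y_cat, eta, unpack(z)[0])[4]
    return z, f, h_eta, converged


# --------------------------------------------------------------------------
# top-level fitting

def _collapse_ordinal(y: np.ndarray) -> np.ndarray:
    """Collapse the two lowest of four confidence categories."""
    cats = np.unique(y)
    if cats.size == 4:
        y = np.where(y == cats[1], cats[0], y)
    return y


def fit_mixed(
    spec: ModelSpec,
    df: pd.DataFrame,
    maxiter_outer: int = 200,
    start_logsd: float = np.log(0.5),
    collapse_confidence: bool = True,
) -> MixedFitResult:
    """Maximum-likelihood fit of a mixed model (Laplace approximation)."""
    used = {spec.response}
    for t in spec.fixed:
        used.update(t.split(":"))
    for rt in spec.random:
        used.add(rt.group)
        for t in rt.terms:
            if t != "1":
                used.update(t.split(":"))
    used.discard("1")
    missing = used - set(df.columns)
    if missing:
        raise SchemaError(f"missing columns: {sorted(missing)}")
    data = df.dropna(subset=sorted(used)).reset_index(drop=True)
    n = len(data)
    if n == 0:
        raise FittingError("no complete observations")

    is_clmm = spec.family == "cumulative-logit"
    X, fixed_names, levels_map = _build_fixed(data, spec, intercept=not is_clmm)
    rs = _RandomStructure(data, spec.random)
    comp_idx = rs.component_index()
    k = X.shape[1]

    yraw = data[spec.response].to_numpy()
    if spec.family == "gamma-identity":
        y = yraw.astype(float)
        if np.any(y <= 0):
            raise SchemaError("gamma response must be positive")
        family: _Family = _GammaIdentity()
        aux0 = [np.log(max((np.mean(y) / max(np.std(y), 1e-9)) ** 2, 0.5))]
        sd_scale = max(float(np.std(y)), 1e-6)
    elif spec.family == "binomial-logit":
        y = yraw.astype(float)
        if not set(np.unique(y)) <= {0.0, 1.0}:
            raise SchemaError("binomial response must be 0/1")
        family = _BinomialLogit()
        aux0 = []
        sd_scale = 1.0
    else:
        y_ord = yraw.astype(float)
        if collapse_confidence:
            y_ord = _collapse_ordinal(y_ord)
        cats = np.unique(y_ord)
        if cats.size < 2:
            raise FittingError("fewer than 2 ordinal categories after collapsing")
        y = np.searchsorted(cats, y_ord)  # 0-based codes
        n_cut = cats.size - 1
        sd_scale = 1.0

    n_comp = rs.n_components
    if spec.family == "gamma-identity":
        theta0 = np.concatenate(
            [np.full(n_comp, np.log(0.2 * sd_scale)), np.asarray(aux0)]
        )
    else:
        theta0 = np.full(n_comp, start_logsd)

    state = {"z": None}

    def neg_laplace(theta):
        logsd = theta[:n_comp]
        aux = theta[n_comp:]
        sigma2 = np.exp(2 * np.clip(logsd, -12, 8))
        pen_u = 1.0 / sigma2[comp_idx] if rs.q else np.zeros(0)
        if is_clmm:
            pen = np.concatenate([np.zeros(k), pen_u])
            if state["z"] is None:
                # category-frequency cutpoints as starting values
                freq = np.bincount(y, minlength=n_cut + 1) / n
                cum = np.cumsum(freq)[:-1]
                c0 = np.log(cum / (1 - cum))
                state["z"] = np.concatenate([c0, np.zeros(k + rs.q)])
            try:
                z, f, h_i, ok = _inner_clmm(
                    y, X, rs, n_cut, pen, state["z"]
                )
            except FittingError:
                return 1e12
            n_fix = n_cut + k
        else:
            pen = np.concatenate([np.zeros(k), pen_u])
            if state["z"] is None:
                z0 = np.zeros(k + rs.q)
                if spec.family == "gamma-identity" and k > 0:
                    z0[0] = float(np.mean(y))
                state["z"] = z0
            try:
                z, f, h_i, ok = _inner_glm(y, X, rs, family, aux, pen, state["z"])
            except FittingError:
                return 1e12
            n_fix = k
        state["z"] = z.copy()
        state["h_i"] = h_i
        state["ok"] = ok
        state["n_fix"] = n_fix
        # Laplace correction: -1/2 log det(I + D^1/2 Z'hZ D^1/2)
        if rs.q:
            ZtZ = rs.zt_diag_z(h_i)
            dhalf = np.sqrt(sigma2[comp_idx])
            A = np.eye(rs.q) + (dhalf[:, None] * ZtZ) * dhalf[None, :]
            sign, logdet = np.linalg.slogdet(A)
            if sign <= 0:
                return 1e12
            corr = -0.5 * logdet
        else:
            corr = 0.0
        return -(f + corr)

    if n_comp + len(theta0[n_comp:]) > 0:
        res = optimize.minimize(
            neg_laplace,
            theta0,
            method="Nelder-Mead",
            options={
                "maxiter": maxiter_outer * max(1, len(theta0)),
                "xatol": 1e-3,
                "fatol": 1e-5,
            },
        )
        theta = res.x
        outer_ok = bool(res.success) or res.fun < neg_laplace(theta0)
    else:
        theta = theta0
        outer_ok = True
    nll = neg_laplace(theta)
    if nll >= 1e12:
        raise FittingError("mixed-model fit failed to find a valid mode")
    loglik = -float(nll)
    z = state["z"]
    h_i = state["h_i"]
    inner_ok = state["ok"]

    logsd = theta[:n_comp]
    sigma = np.exp(np.clip(logsd, -12, 8))
    sigma2 = sigma**2
    pen_u = 1.0 / sigma2[comp_idx] if rs.q else np.zeros(0)

    # conditional covariance of the fixed block at the mode
    if is_clmm:
        n_cut_eff = n_cut
        cuts = z[:n_cut_eff]
        beta = z[n_cut_eff : n_cut_eff + k]
        u_hat = z[n_cut_eff + k :]
        # rebuild full negative Hessian for vcov
        _, _, _, d_eta, h_eta, laa, lbb, lab = _clmm_loglik_parts(
            y, X @ beta + rs.eta(u_hat, n), cuts
        )
        M_cc = np.zeros((n_cut_eff, n_cut_eff))
        for j in range(n_cut_eff):
            M_cc[j, j] = -(float(np.sum(laa[y == j])) + float(np.sum(lbb[y == j + 1])))
            if j + 1 < n_cut_eff:
                v = -float(np.sum(lab[y == j + 1]))
                M_cc[j, j + 1] += v
                M_cc[j + 1, j] += v
        cross = np.zeros((n_cut_eff, n))
        for j in range(n_cut_eff):
            mj = y == j
            cross[j, mj] += laa[mj] + lab[mj]
            mj1 = y == j + 1
            cross[j, mj1] += lab[mj1] + lbb[mj1]
        M_cb = cross @ X
        M_cu = (
            np.stack([rs.zt_dot(cross[j]) for j in range(n_cut_eff)])
            if rs.q
            else np.zeros((n_cut_eff, 0))
        )
        XtX = (X * h_eta[:, None]).T @ X
        XtZ = rs.xt_diag_z(h_eta, X)
        ZtZ = rs.zt_diag_z(h_eta)
        M = np.block(
            [[M_cc, M_cb, M_cu], [M_cb.T, XtX, XtZ], [M_cu.T, XtZ.T, ZtZ]]
        )
        M[n_cut_eff:, n_cut_eff:] += np.diag(
            np.concatenate([np.zeros(k), pen_u])
        )
        n_fixed_block = n_cut_eff + k
        shape = None
    else:
        beta = z[:k]
        u_hat = z[k:]
        cuts = None
        XtX = (X * h_i[:, None]).T @ X
        XtZ = rs.xt_diag_z(h_i, X)
        ZtZ = rs.zt_diag_z(h_i)
        M = np.block([[XtX, XtZ], [XtZ.T, ZtZ]]) + np.diag(
            np.concatenate([np.zeros(k), pen_u])
        )
        n_fixed_block = k
        shape = float(np.exp(theta[n_comp])) if spec.family == "gamma-identity" else None

    try:
        Minv = np.linalg.inv(M + 1e-10 * np.eye(M.shape[0]))
        vcov_full = Minv[:n_fixed_block, :n_fixed_block]
        pd_ok = bool(np.all(np.diag(vcov_full) > 0))
    except np.linalg.LinAlgError:
        vcov_full = np.full((n_fixed_block, n_fixed_block), np.nan)
        pd_ok = False

    if is_clmm:
        vcov = vcov_full[n_cut:, n_cut:]
        coef = beta
        se = np.sqrt(np.clip(np.diag(vcov), 0, None))
        n_params = n_cut + k + n_comp
    else:
        vcov = vcov_full
        coef = beta
        se = np.sqrt(np.clip(np.diag(vcov), 0, None))
        n_params = k + n_comp + (1 if shape is not None else 0)

    bic = -2.0 * loglik + n_params * np.log(n)
    return MixedFitResult(
        spec=spec,
        fixed_names=fixed_names,
        coef=coef,
        se=se,
        vcov=vcov,
        loglik=loglik,
        bic=float(bic),
        n_obs=n,
        n_params=n_params,
        converged=bool(outer_ok and inner_ok and pd_ok),
        varcomp=dict(zip(rs.comp_names, sigma.tolist())),
        shape=shape,
        cutpoints=None if cuts is None else np.asarray(cuts),
        u_hat=u_hat,
        meta={
            "vcov_with_cutpoints": vcov_full if is_clmm else None,
            "levels": levels_map,
        },
    )


def lrt(full: MixedFitResult, reduced: MixedFitResult) -> dict:
    """Likelihood-ratio test of nested mixed models."""
    if reduced.n_params > full.n_params:
        raise FittingError("reduced model must not have more parameters")
    if not set(reduced.fixed_names) <= set(full.fixed_names):
        raise FittingError("models are not nested in their fixed effects")
    if not (full.converged and reduced.converged):
        raise FittingError("LRT requires both fits to have converged")
    stat = 2.0 * (full.loglik - reduced.loglik)
    df = full.n_params - reduced.n_params
    if df == 0:
        # identical specifications: degenerate test
        return {"stat": max(float(stat), 0.0), "df": 0, "p": 1.0}
    if stat < -1e-3:
        raise FittingError(
            f"negative LRT statistic ({stat:.4g}): convergence failure"
        )
    stat = max(stat, 0.0)
    return {"stat": float(stat), "df": int(df), "p": float(stats.chi2.sf(stat, df))}


def _single_deletions(spec: ModelSpec) -> list[ModelSpec]:
    """Submodels with one random-slope covariate removed."""
    subs = []
    for i, rt in enumerate(spec.random):
        for t in rt.terms:
            if t == "1":
                continue
            new_terms = tuple(x for x in rt.terms if x != t)
            new_rt = RandomTerm(rt.group, new_terms or ("1",))
            subs.append(
                replace(
                    spec,
                    random=tuple(
                        new_rt if j == i else r for j, r in enumerate(spec.random)
                    ),
                )
            )
    return subs


def select_random_effects(
    candidates: list[ModelSpec], df: pd.DataFrame, **fit_kwargs
) -> tuple[ModelSpec, MixedFitResult, pd.DataFrame]:
    """Lowest-BIC converged candidate whose single-deletion submodels also
    converge (so LRTs against them are usable)."""
    rows = []
    fits: dict[int, MixedFitResult] = {}
    for i, spec in enumerate(candidates):
        try:
            fit = fit_mixed(spec, df, **fit_kwargs)
            fits[i] = fit
            rows.append({"index": i, "bic": fit.bic, "converged": fit.converged})
        except (FittingError, SchemaError) as exc:
            rows.append({"index": i, "bic": np.inf, "converged": False, "error": str(exc)})
    table = pd.DataFrame(rows).sort_values("bic").reset_index(drop=True)
    for _, row in table.iterrows():
        if not row["converged"]:
            continue
        i = int(row["index"])
        spec = candidates[i]
        ok = True
        for sub in _single_deletions(spec):
            try:
                if not fit_mixed(sub, df, **fit_kwargs).converged:
                    ok = False
                    break
            except (FittingError, SchemaError):
                ok = False
                break
        if ok:
            return spec, fits[i], table
    raise FittingError(f"no candidate random-effects structure converged: {table}")
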