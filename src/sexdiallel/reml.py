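"""Hayman-class diallel mixed models with sex interactions.

The full sexed model partitions log fitness into fixed effects (intercept,
block x, inbreeding b1, sex S, S x b1) and random inheritance classes:
additive a, parental c, parent-specific dominance b2, symmetric epistasis
b3, asymmetric (reciprocal) epistasis d, plus the sex interaction S x q of
each.  Variance components are estimated by *unconstrained* restricted
maximum likelihood: the REML log-likelihood is maximised directly in the
variance-component parameters with no positivity transform, subject only
to the marginal covariance V = sum_q sigma2_q Z_q Z_q' + sigma2_e I
remaining positive definite.  Negative estimates are therefore possible
and are reported as such (they read as "not different from zero").

Incidence coding (strain k, dam i, sire j; n strains):

* a   one column per strain: [k==i] + [k==j]  (2 on selfs)
* c   one column per strain: [k==i] - [k==j]  (0 on selfs)
* b2  one column per strain: [k in {i,j}] on outcross rows, 0 on selfs
* b3  one column per unordered outcross pair {i,j}, i<j: the pair
      indicator (1 for both orientations; n(n-1)/2 levels) projected
      orthogonal to the strain-margin space, so b3 carries only
      pair-specific *interaction* deviations (Hayman's residual
      symmetric epistasis) and cannot absorb additive or
      parent-specific dominance margins
* d   one column per unordered outcross pair: the signed indicator
      (+1 when i<j, -1 when i>j) projected orthogonal to the
      strain-difference (maternal c) margins, leaving only
      pair-specific reciprocal interaction
* Sxq the q incidence multiplied row-wise by the sex contrast
      (+1 female, -1 male)
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import linalg, optimize, stats

from .io import SEX_F, SEX_M, DiallelDataset

FIXED_TERMS = ("mu", "x", "b1", "S", "S.b1")
RANDOM_TERMS = ("a", "S.a", "c", "S.c", "b2", "S.b2", "b3", "S.b3",
                "d", "S.d")
UNSEXED_TERMS = ("a", "c", "b2", "b3", "d")
PAIR_TERMS = ("b3", "S.b3", "d", "S.d")

_LOG2PI = float(np.log(2.0 * np.pi))


@dataclass(frozen=True)
class ModelSpec:
    """Which fixed and random terms to fit, on which sex subset.

    ``subset`` is 'full', 'male' or 'female'; sex-subset models may not
    contain S or S x terms.  The response is log(fitness + offset).
    """

    fixed: tuple[str, ...] = FIXED_TERMS
    random: tuple[str, ...] = RANDOM_TERMS
    subset: str = "full"
    offset: float = 1.0

    def __post_init__(self):
        for t in self.fixed:
            if t not in FIXED_TERMS:
                raise ValueError(f"unknown fixed term {t!r}")
        for t in self.random:
            if t not in RANDOM_TERMS:
                raise ValueError(f"unknown random term {t!r}")
        if "mu" not in self.fixed:
            raise ValueError("the intercept 'mu' is required")
        if self.subset not in ("full", "male", "female"):
            raise ValueError("subset must be full/male/female")
        if self.subset != "full":
            sexed = [t for t in self.fixed + self.random
                     if t == "S" or t.startswith("S.")]
            if sexed:
                raise ValueError(
                    f"sex-subset model cannot contain sexed terms {sexed}")

    @classmethod
    def full_sexed(cls, offset: float = 1.0) -> "ModelSpec":
        return cls(offset=offset)

    @classmethod
    def sex_specific(cls, sex: str, offset: float = 1.0) -> "ModelSpec":
        subset = {"M": "male", "F": "female",
                  "male": "male", "female": "female"}[sex]
        return cls(fixed=("mu", "x", "b1"), random=UNSEXED_TERMS,
                   subset=subset, offset=offset)

    @classmethod
    def residualization(cls, remove_sc_additive: bool = False,
                        offset: float = 1.0) -> "ModelSpec":
        """The SSDR residualization model y = mu + x + b3 (+ a) + eps."""
        random = ("a", "b3") if remove_sc_additive else ("b3",)
        return cls(fixed=("mu", "x"), random=random, offset=offset)


@dataclass
class DesignBundle:
    """Response, fixed design and per-random-term incidence matrices."""

    y: np.ndarray
    X: np.ndarray
    fixed_names: list[str]
    fixed_term_cols: dict
    dropped_fixed: list[str]
    Z: dict
    labels: dict
    spec: ModelSpec
    ds: DiallelDataset

    @property
    def n(self) -> int:
        return len(self.y)

    @property
    def random_terms(self) -> tuple[str, ...]:
        return tuple(self.Z.keys())


def _pair_labels(n: int) -> list[tuple[int, int]]:
    return [(i, j) for i in range(1, n + 1) for j in range(i + 1, n + 1)]


def build_design(ds: DiallelDataset, spec: ModelSpec) -> DesignBundle:
    """Assemble the response and all design matrices for one model."""
    if spec.subset == "male":
        ds = ds.subset_sex(SEX_M)
    elif spec.subset == "female":
        ds = ds.subset_sex(SEX_F)
    df = ds.df
    n_rec = len(df)
    n = ds.n_strains
    dam = df["dam"].to_numpy()
    sire = df["sire"].to_numpy()
    self_row = (dam == sire).astype(float)
    sex_c = np.where(df["sex"].to_numpy() == SEX_F, 1.0, -1.0)
    y = np.log(df["fitness"].to_numpy(dtype=float) + spec.offset)

    # fixed part
    cols, names, term_cols = [], [], {}
    for term in spec.fixed:
        start = len(names)
        if term == "mu":
            cols.append(np.ones(n_rec))
            names.append("mu")
        elif term == "x":
            levels = sorted(df["block"].unique(), key=str)
            for lvl in levels[1:]:
                cols.append((df["block"] == lvl).to_numpy(float))
                names.append(f"x[{lvl}]")
        elif term == "b1":
            cols.append(self_row.copy())
            names.append("b1")
        elif term == "S":
            cols.append(sex_c.copy())
            names.append("S")
        elif term == "S.b1":
            cols.append(sex_c * self_row)
            names.append("S.b1")
        term_cols[term] = list(range(start, len(names)))
    X = np.column_stack(cols)

    # drop aliased fixed columns by rank-revealing QR
    _, R, piv = linalg.qr(X, mode="economic", pivoting=True)
    diag = np.abs(np.diag(R))
    tol = diag.max() * max(X.shape) * np.finfo(float).eps if diag.size else 0
    rank = int((diag > tol).sum())
    keep = np.sort(piv[:rank])
    dropped = [names[i] for i in range(X.shape[1]) if i not in set(keep)]
    if dropped:
        X = X[:, keep]
        old_to_new = {old: new for new, old in enumerate(keep)}
        names = [names[i] for i in keep]
        term_cols = {t: [old_to_new[c] for c in cs if c in old_to_new]
                     for t, cs in term_cols.items()}

    # random incidence matrices
    strains = np.arange(1, n + 1)
    A = ((dam[:, None] == strains).astype(float)
         + (sire[:, None] == strains).astype(float))
    C = ((dam[:, None] == strains).astype(float)
         - (sire[:, None] == strains).astype(float))
    outcross = (dam != sire)
    B2 = np.where(outcross[:, None],
                  ((dam[:, None] == strains) | (sire[:, None] == strains))
                  .astype(float), 0.0)
    pairs = _pair_labels(n)
    pair_index = {p: k for k, p in enumerate(pairs)}
    B3 = np.zeros((n_rec, len(pairs)))
    D = np.zeros((n_rec, len(pairs)))
    for row in np.nonzero(outcross)[0]:
        i, j = dam[row], sire[row]
        k = pair_index[(min(i, j), max(i, j))]
        B3[row, k] = 1.0
        D[row, k] = 1.0 if i < j else -1.0
    # project pair effects orthogonal to strain margins: b3 and d model
    # interaction-only deviations, so a residualization on b3 leaves
    # additive and parent-specific dominance variation in the data
    Qs = np.zeros((len(pairs), n + 1))
    Qd = np.zeros((len(pairs), n))
    for (i, j), k in pair_index.items():
        Qs[k, i - 1] = 1.0
        Qs[k, j - 1] = 1.0
        Qd[k, i - 1] = 1.0
        Qd[k, j - 1] = -1.0
    Qs[:, n] = 1.0
    B3 = B3 @ (np.eye(len(pairs)) - Qs @ np.linalg.pinv(Qs))
    D = D @ (np.eye(len(pairs)) - Qd @ np.linalg.pinv(Qd))

    base = {"a": (A, list(strains)), "c": (C, list(strains)),
            "b2": (B2, list(strains)), "b3": (B3, pairs), "d": (D, pairs)}
    Z, labels = {}, {}
    for term in spec.random:
        if term.startswith("S."):
            M, lab = base[term[2:]]
            M = M * sex_c[:, None]
        else:
            M, lab = base[term]
        if not np.any(M):
            raise ValueError(f"random term {term!r} has no non-empty levels")
        Z[term] = M
        labels[term] = list(lab)
    return DesignBundle(y=y, X=X, fixed_names=names, fixed_term_cols=term_cols,
                        dropped_fixed=dropped, Z=Z, labels=labels, spec=spec,
                        ds=ds)


@dataclass
class RemlOptions:
    max_iter: int = 500
    gtol: float = 1e-8
    start: np.ndarray | None = None
    compute_se: bool = True


@dataclass
class BlupVector:
    """Predicted random-effect levels for one inheritance class."""

    term: str
    model: str                       # full / male / female
    labels: list
    values: np.ndarray
    standardized: bool = False

    def standardize(self) -> "BlupVector":
        """Divide by the sample standard deviation (ddof=1), no centering:
        BLUPs are already centred near zero by construction."""
        sd = float(np.std(self.values, ddof=1))
        if sd == 0:
            raise ValueError(f"cannot standardize constant BLUPs for "
                             f"{self.term!r}")
        return BlupVector(self.term, self.model, list(self.labels),
                          self.values / sd, standardized=True)


@dataclass
class FitResult:
    """Unconstrained REML estimates, tests, BLUPs and diagnostics."""

    spec: ModelSpec
    varcomp: dict                 # term -> sigma^2 (negative permitted)
    varcomp_se: dict
    sigma2_eps: float
    sigma2_eps_se: float
    beta: np.ndarray
    fixed_names: list
    fixed_tests: pd.DataFrame     # term, F, df1, df2, p
    loglik: float
    converged: bool
    n_iter: int
    message: str
    design: DesignBundle
    _raw_blups: dict = field(repr=False, default_factory=dict)

    @property
    def model_id(self) -> str:
        return self.spec.subset

    def varcomp_table(self) -> pd.DataFrame:
        rows = [(t, self.varcomp[t], self.varcomp_se.get(t, np.nan))
                for t in self.varcomp]
        rows.append(("eps", self.sigma2_eps, self.sigma2_eps_se))
        return pd.DataFrame(rows, columns=["term", "sigma2", "se"])


class _RemlProblem:
    """Pre-reduced REML objective: all likelihood work in q x q space.

    With V = sigma2_e I + Z G Z' (G block-diagonal in the per-term
    variances), Woodbury gives every needed quantity from Z'Z, Z'[y X]
    and [y X]'[y X]; positive definiteness of V is checked through the
    eigenvalues of R G R' where Z'Z = R'R.
    """

    def __init__(self, design: DesignBundle):
        self.design = design
        self.terms = list(design.Z.keys())
        self.X = design.X
        self.y = design.y
        self.n, self.p = design.X.shape
        if self.terms:
            self.Zfull = np.concatenate([design.Z[t] for t in self.terms],
                                        axis=1)
        else:
            self.Zfull = np.zeros((self.n, 0))
        self.q = self.Zfull.shape[1]
        self.slices = {}
        off = 0
        for t in self.terms:
            w = design.Z[t].shape[1]
            self.slices[t] = slice(off, off + w)
            off += w
        YX = np.column_stack([self.y, self.X])
        self.YX = YX
        self.YtY = YX.T @ YX
        self.ZtZ = self.Zfull.T @ self.Zfull
        self.Myx = self.Zfull.T @ YX
        lam, U = np.linalg.eigh(self.ZtZ) if self.q else (np.zeros(0),
                                                          np.zeros((0, 0)))
        keep = lam > (lam.max() * 1e-12 if lam.size else 0)
        self.R = (U[:, keep] * np.sqrt(lam[keep])).T  # r x q
        self.K_terms = {t: self.R[:, s] @ self.R[:, s].T
                        for t, s in self.slices.items()}
        self._pd_tol = 1e-12

    def _split(self, theta):
        return np.asarray(theta[:-1], float), float(theta[-1])

    def is_pd(self, theta) -> bool:
        sig, se2 = self._split(theta)
        if se2 <= self._pd_tol:
            return False
        if not self.q:
            return True
        K = sum(s * self.K_terms[t] for t, s in zip(self.terms, sig))
        lam_min = np.linalg.eigvalsh(K)[0] if self.terms else 0.0
        return se2 + lam_min > self._pd_tol

    def _penalty(self, theta):
        sig, se2 = self._split(theta)
        grad = np.zeros(len(theta))
        viol = 0.0
        if se2 <= self._pd_tol:
            viol += self._pd_tol - se2
            grad[-1] -= 1.0
        if self.q and self.terms:
            K = sum(s * self.K_terms[t] for t, s in zip(self.terms, sig))
            lam, vecs = np.linalg.eigh(K)
            if se2 + lam[0] <= self._pd_tol:
                viol += self._pd_tol - (se2 + lam[0])
                v = vecs[:, 0]
                for k, t in enumerate(self.terms):
                    grad[k] -= float(v @ self.K_terms[t] @ v)
                grad[-1] -= 1.0
        scale = 1e8
        return scale * (1.0 + viol), scale * grad

    def neg_loglik_grad(self, theta):
        if not self.is_pd(theta):
            return self._penalty(theta)
        sig, se2 = self._split(theta)
        n, p, q = self.n, self.p, self.q
        g = np.zeros(q)
        for t, s in zip(self.terms, sig):
            g[self.slices[t]] = s
        A = se2 * np.eye(q) + g[:, None] * self.ZtZ
        lu, piv = linalg.lu_factor(A) if q else (np.zeros((0, 0)),
                                                 np.zeros(0, dtype=np.int32))
        B = linalg.lu_solve((lu, piv), g[:, None] * self.Myx) if q \
            else np.zeros((0, p + 1))
        Sv = (self.YtY - self.Myx.T @ B) / se2
        logdetA = float(np.sum(np.log(np.abs(np.diag(lu))))) if q else 0.0
        logdetV = (n - q) * np.log(se2) + logdetA
        XVX = Sv[1:, 1:]
        XVy = Sv[1:, 0]
        yVy = Sv[0, 0]
        try:
            cf = linalg.cho_factor(XVX)
        except linalg.LinAlgError:
            return self._penalty(theta)
        beta = linalg.cho_solve(cf, XVy)
        yPy = yVy - XVy @ beta
        logdetXVX = 2.0 * float(np.sum(np.log(np.diag(cf[0]))))
        nll = 0.5 * (logdetV + logdetXVX + yPy + (n - p) * _LOG2PI)

        grad = np.zeros(len(self.terms) + 1)
        if q:
            C = linalg.lu_solve((lu, piv), g[:, None] * self.ZtZ)
            ZVZ = (self.ZtZ - self.ZtZ @ C) / se2
            ZVyX = (self.Myx - self.ZtZ @ B) / se2
            ZVX = ZVyX[:, 1:]
            ZVy = ZVyX[:, 0]
            w = ZVy - ZVX @ beta
            XVXi_ZVXt = linalg.cho_solve(cf, ZVX.T)  # p x q
            for k, t in enumerate(self.terms):
                s = self.slices[t]
                tr_vz = float(np.trace(ZVZ[s, s]))
                tr_px = float(np.sum(ZVX[s, :] * XVXi_ZVXt[:, s].T))
                grad[k] = 0.5 * ((tr_vz - tr_px) - float(w[s] @ w[s]))
            trC = float(np.trace(C))
        else:
            w = np.zeros(0)
            trC = 0.0
        trVinv = (n - trC) / se2
        V2 = (self.YtY - self.Myx.T @ B - B.T @ self.Myx
              + B.T @ self.ZtZ @ B) / se2 ** 2
        XV2X = V2[1:, 1:]
        XV2y = V2[1:, 0]
        yV2y = V2[0, 0]
        rV2r = yV2y - 2.0 * XV2y @ beta + beta @ XV2X @ beta
        trP_eps = trVinv - float(np.trace(linalg.cho_solve(cf, XV2X)))
        grad[-1] = 0.5 * (trP_eps - rV2r)

        cache = {"beta": beta, "XVX": XVX, "w": w, "loglik": -nll}
        return nll, grad, cache

    def objective(self, theta):
        out = self.neg_loglik_grad(theta)
        return out[0], out[1]


def fit_reml(design: DesignBundle,
             options: RemlOptions | None = None) -> FitResult:
    """Maximise the REML log-likelihood over unconstrained components.

    Returns estimates, standard errors from the observed information
    matrix at the optimum, GLS fixed effects with Wald F tests
    (denominator df = n - rank(X)), BLUPs per random term, and
    convergence diagnostics.  Non-convergence is flagged on the result,
    never silent.
    """
    options = options or RemlOptions()
    prob = _RemlProblem(design)
    n, p = prob.n, prob.p
    nterms = len(prob.terms)

    if options.start is not None:
        x0 = np.asarray(options.start, dtype=float)
        if len(x0) != nterms + 1:
            raise ValueError("start must have one entry per random term "
                             "plus the residual")
    else:
        beta_ols, *_ = np.linalg.lstsq(prob.X, prob.y, rcond=None)
        resid = prob.y - prob.X @ beta_ols
        v = float(resid @ resid) / max(n - p, 1)
        x0 = np.full(nterms + 1, 0.1 * v / max(nterms, 1))
        x0[-1] = 0.9 * v

    if options.max_iter == 0:
        # evaluate at the supplied point without optimisation
        res = optimize.OptimizeResult(x=x0, success=False, nit=0,
                                      message="evaluation only")
    else:
        res = optimize.minimize(prob.objective, x0, jac=True,
                                method="L-BFGS-B",
                                options={"maxiter": options.max_iter,
                                         "ftol": 1e-14,
                                         "gtol": options.gtol})
    theta = res.x
    out = prob.neg_loglik_grad(theta)
    if len(out) != 3:
        raise RuntimeError("REML solver terminated outside the positive-"
                           "definite region; data may be degenerate")
    nll, grad, cache = out
    converged = bool(res.success) or float(np.max(np.abs(grad))) < 1e-4

    se = np.full(nterms + 1, np.nan)
    if options.compute_se:
        H = _numeric_hessian(prob, theta)
        try:
            cov = np.linalg.inv(H)
            d = np.diag(cov).copy()
            d[d < 0] = np.nan
            se = np.sqrt(d)
        except np.linalg.LinAlgError:
            converged = False

    beta = cache["beta"]
    XVX = cache["XVX"]
    tests = _wald_tests(design, beta, XVX, n)
    sig = dict(zip(prob.terms, theta[:nterms]))
    blups = {t: theta[k] * cache["w"][prob.slices[t]]
             for k, t in enumerate(prob.terms)}
    return FitResult(
        spec=design.spec,
        varcomp=sig,
        varcomp_se=dict(zip(prob.terms, se[:nterms])),
        sigma2_eps=float(theta[-1]),
        sigma2_eps_se=float(se[-1]),
        beta=beta,
        fixed_names=list(design.fixed_names),
        fixed_tests=tests,
        loglik=float(cache["loglik"]),
        converged=converged,
        n_iter=int(res.nit),
        message=str(res.message),
        design=design,
        _raw_blups=blups,
    )


def _numeric_hessian(prob: _RemlProblem, theta: np.ndarray) -> np.ndarray:
    """Observed information: central differences of the analytic gradient."""
    m = len(theta)
    H = np.zeros((m, m))
    for k in range(m):
        h = 1e-6 + 1e-4 * abs(theta[k])
        for sgn, tp in ((1.0, theta.copy()), (-1.0, theta.copy())):
            tp[k] += sgn * h
            out = prob.neg_loglik_grad(tp)
            H[:, k] += sgn * out[1] / (2.0 * h)
    return 0.5 * (H + H.T)


def _wald_tests(design: DesignBundle, beta: np.ndarray, XVX: np.ndarray,
                n: int) -> pd.DataFrame:
    XVX_inv = np.linalg.inv(XVX)
    df2 = n - design.X.shape[1]
    rows = []
    for term, cols in design.fixed_term_cols.items():
        if term == "mu" or not cols:
            continue
        b = beta[cols]
        Vb = XVX_inv[np.ix_(cols, cols)]
        F = float(b @ np.linalg.solve(Vb, b)) / len(cols)
        pval = float(stats.f.sf(F, len(cols), df2))
        rows.append((term, F, len(cols), df2, pval))
    return pd.DataFrame(rows, columns=["term", "F", "df1", "df2", "p"])


def extract_blups(fit: FitResult, term: str) -> BlupVector:
    """Empirical BLUPs u_q = sigma2_q Z_q' V^-1 (y - X beta) for one term.

    Refused for terms whose variance estimate is negative: shrinkage with
    a negative variance is not a prediction, so those BLUPs are invalid.
    """
    if term not in fit.varcomp:
        raise KeyError(f"term {term!r} not in fitted model")
    if fit.varcomp[term] < 0:
        raise ValueError(
            f"BLUPs invalid for negative component {term!r} "
            f"(sigma2 = {fit.varcomp[term]:.3g})")
    return BlupVector(term=term, model=fit.model_id,
                      labels=list(fit.design.labels[term]),
                      values=np.array(fit._raw_blups[term]))


@dataclass
class ResidualDataset:
    """A dataset together with per-record conditional residuals."""

    ds: DiallelDataset
    residuals: np.ndarray
    removed: tuple
    skipped_negative: tuple = ()


def conditional_residuals(fit: FitResult,
                          remove: Iterable[str] = ()) -> ResidualDataset:
    """Response minus the fitted fixed part minus the BLUP contributions
    of the designated random terms.

    The whole fixed part (including the intercept) is always removed;
    names of fixed terms in ``remove`` are accepted and simply confirm
    membership.  Residuals are *not* variance-standardized.  Random terms
    whose variance estimate is negative have invalid BLUPs; they are
    skipped (contribution zero) and reported on the result.
    """
    remove = tuple(remove)
    design = fit.design
    for t in remove:
        if t not in fit.varcomp and t not in design.fixed_term_cols:
            raise KeyError(f"term {t!r} not in fitted model")
    resid = design.y - design.X @ fit.beta
    skipped = []
    for t in remove:
        if t in fit.varcomp:
            if fit.varcomp[t] < 0:
                skipped.append(t)
                continue
            resid = resid - design.Z[t] @ fit._raw_blups[t]
    return ResidualDataset(ds=design.ds, residuals=resid, removed=remove,
                           skipped_negative=tuple(skipped))
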