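"""Linear mixed model with kinship, household, and block random effects.

The null model for a quantitative trait y is

    y = X b + g + h + u + e,
    g ~ N(0, sigma2_kin * K),     h ~ N(0, sigma2_household * Z_h Z_h'),
    u ~ N(0, sigma2_block * Z_b Z_b'),   e ~ N(0, sigma2_resid * I),

where K is a (relationship-scaled) kinship matrix and Z_h, Z_b are
household and block membership indicators. Variance components are
estimated by REML with a bounded quasi-Newton optimizer on the
log-variance scale (fixed starting values: the phenotypic variance split
equally across the active components), so fits are deterministic. Fixed
effects are the GLS solution at the REML estimates.

Marker and local-ancestry tests are Wald tests of focal columns appended
to the null design with the variance components held at the null fit, the
standard mixed-model GWAS practice: the null covariance is factorized
once and reused across all tests.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats
from scipy.linalg import cho_factor, cho_solve


class CollinearityError(ValueError):
    """A focal predictor is (numerically) collinear with the design."""


class _CovSolver:
    """Applies V^{-1}: a Cholesky factor for structured covariances, a
    scalar division when V = s I."""

    def __init__(self, chol=None, scale=None):
        self._chol = chol
        self._scale = scale

    def solve(self, B):
        if self._chol is not None:
            return cho_solve(self._chol, B)
        return np.asarray(B, dtype=float) / self._scale


@dataclass
class TestResult:
    """Wald test of one or two focal fixed-effect columns.

    For df=1 ``effect``/``se`` are scalars and ``stat = (effect/se)**2``;
    for df=2 they are length-2 arrays and ``stat`` is the quadratic form
    against the joint covariance. ``p`` is the chi-square(df) upper tail.
    """

    effect: float | np.ndarray
    se: float | np.ndarray
    stat: float
    df: int
    p: float


def _cluster_indicator_product(ids) -> np.ndarray:
    """n x n 0/1 matrix: 1 where two individuals share a cluster (Z Z')."""
    codes = pd.factorize(np.asarray(ids))[0]
    return (codes[:, None] == codes[None, :]).astype(float)


class AdmixtureMixedModel:
    """REML linear mixed model for admixture/association mapping.

    Parameters
    ----------
    y : array (n,)
        Trait values.
    X : array (n, p) or DataFrame
        Fixed-effect design including the intercept (covariates such as
        sex, age, centre, sampling weight, ancestry PCs).
    kinship : array (n, n), optional
        Symmetric PSD relationship matrix (unit diagonal convention).
        ``None`` or the identity drops the kinship component.
    household_ids, block_ids : array (n,), optional
        Cluster labels; all-singleton clusters drop the component (their
        indicator product is the identity and would be confounded with
        the residual).
    """

    def __init__(self, y, X, kinship=None, household_ids=None, block_ids=None, exog_names=None):
        self.y = np.asarray(y, dtype=float).ravel()
        n = len(self.y)
        if isinstance(X, pd.DataFrame):
            exog_names = list(X.columns)
            X = X.to_numpy(dtype=float)
        self.X = np.asarray(X, dtype=float)
        if self.X.ndim == 1:
            self.X = self.X[:, None]
        if self.X.shape[0] != n:
            raise ValueError("y and X have incompatible shapes")
        if n <= self.X.shape[1]:
            raise ValueError("need more observations than fixed effects")
        if np.linalg.matrix_rank(self.X) < self.X.shape[1]:
            raise ValueError("singular fixed-effect design")
        self.exog_names = exog_names or [f"x{j}" for j in range(self.X.shape[1])]

        self.vc_names: list[str] = []
        self._structures: list[np.ndarray] = []
        if kinship is not None:
            K = np.asarray(kinship, dtype=float)
            if K.shape != (n, n):
                raise ValueError("kinship matrix shape mismatch")
            if not np.allclose(K, K.T, atol=1e-10):
                raise ValueError("kinship matrix must be symmetric")
            if not np.allclose(K, np.eye(n)):
                self.vc_names.append("kinship")
                self._structures.append(K)
        for name, ids in (("household", household_ids), ("block", block_ids)):
            if ids is None:
                continue
            if len(ids) != n:
                raise ValueError(f"{name} ids length mismatch")
            if pd.isna(np.asarray(ids, dtype=object)).any():
                raise ValueError(f"incomplete {name} cluster ids")
            M = _cluster_indicator_product(ids)
            if not np.allclose(M, np.eye(n)):
                self.vc_names.append(name)
                self._structures.append(M)
        self.vc_names.append("residual")

    @classmethod
    def from_dataframe(
        cls,
        data: pd.DataFrame,
        trait: str,
        covariates: list[str],
        kinship: pd.DataFrame | np.ndarray | None = None,
        household: str | None = "household_id",
        block: str | None = "block_id",
        add_intercept: bool = True,
    ) -> "AdmixtureMixedModel":
        """Build the model from a phenotype table.

        Categorical covariates are dummy-coded (first level dropped); an
        intercept column is prepended. If ``kinship`` is a labelled
        DataFrame it is aligned to the table's ``sample`` column.
        """
        y = data[trait].to_numpy(dtype=float)
        Xdf = pd.get_dummies(data[covariates], drop_first=True, dtype=float)
        if add_intercept:
            Xdf.insert(0, "intercept", 1.0)
        if isinstance(kinship, pd.DataFrame) and "sample" in data:
            kinship = kinship.loc[data["sample"], data["sample"]].to_numpy()
        return cls(
            y,
            Xdf,
            kinship=kinship,
            household_ids=data[household].to_numpy() if household and household in data else None,
            block_ids=data[block].to_numpy() if block and block in data else None,
        )

    # REML machinery -----------------------------------------------------

    def _covariance(self, variances: np.ndarray) -> np.ndarray:
        n = len(self.y)
        V = variances[-1] * np.eye(n)
        for s2, G in zip(variances[:-1], self._structures):
            V += s2 * G
        return V

    def reml_loglike(self, variances) -> float:
        """Restricted log-likelihood at the given variance components
        (ordered as ``vc_names``, residual last)."""
        variances = np.asarray(variances, dtype=float)
        if not self._structures:
            # Structureless case: V = s I, closed-form restricted likelihood.
            s = variances[-1]
            n, p = self.X.shape
            beta, rss, _, _ = np.linalg.lstsq(self.X, self.y, rcond=None)
            resid = self.y - self.X @ beta
            quad = float(resid @ resid) / s
            sign, logdet_XtX = np.linalg.slogdet(self.X.T @ self.X)
            return -0.5 * (
                n * np.log(s) + (logdet_XtX - p * np.log(s)) + quad + (n - p) * np.log(2 * np.pi)
            )
        V = self._covariance(variances)
        c = cho_factor(V, lower=True)
        Vinv_y = cho_solve(c, self.y)
        Vinv_X = cho_solve(c, self.X)
        XtVX = self.X.T @ Vinv_X
        sign, logdet_XtVX = np.linalg.slogdet(XtVX)
        if sign <= 0:
            return -np.inf
        logdet_V = 2.0 * np.sum(np.log(np.diag(c[0])))
        beta = np.linalg.solve(XtVX, self.X.T @ Vinv_y)
        resid = self.y - self.X @ beta
        quad = resid @ cho_solve(c, resid)
        n, p = self.X.shape
        return -0.5 * (logdet_V + logdet_XtVX + quad + (n - p) * np.log(2 * np.pi))

    def fit(self, tol: float = 1e-8, maxiter: int = 500, vc_se: bool = False) -> "MixedModelResults":
        """Estimate variance components by REML and fixed effects by GLS.

        Optimizes the restricted likelihood over log-variances with
        L-BFGS-B (bounds keep each component above a negligible floor,
        the non-negativity constraint); components whose estimate lands
        on the floor are reported as 0. ``vc_se=True`` additionally
        computes asymptotic standard errors of the variance components
        from a finite-difference Hessian of the REML surface.
        """
        var_y = float(np.var(self.y, ddof=1))
        n_vc = len(self.vc_names)
        if not self._structures:
            # REML optimum is analytic: sigma2 = RSS / (n - p).
            n, p = self.X.shape
            _, rss, _, _ = np.linalg.lstsq(self.X, self.y, rcond=None)
            resid_ss = float(rss[0]) if len(rss) else float(
                np.sum((self.y - self.X @ np.linalg.lstsq(self.X, self.y, rcond=None)[0]) ** 2)
            )
            s2 = resid_ss / (n - p)
            variances = np.array([s2])
            c = _CovSolver(scale=s2)
            Vinv_X = self.X / s2
            XtVX_inv = np.linalg.inv(self.X.T @ Vinv_X)
            Vinv_y = self.y / s2
            beta = XtVX_inv @ (self.X.T @ Vinv_y)
            return MixedModelResults(
                model=self,
                params=beta,
                bse=np.sqrt(np.diag(XtVX_inv)),
                vc={"residual": s2},
                loglik=float(self.reml_loglike(variances)),
                converged=True,
                n_iter=0,
                message="closed-form REML (no random structure)",
                _chol=c,
                _Vinv_X=Vinv_X,
                _XtVX_inv=XtVX_inv,
                _Vinv_y=Vinv_y,
                vc_bse={"residual": s2 * np.sqrt(2.0 / (n - p))} if vc_se else None,
            )
        start = np.full(n_vc, np.log(var_y / n_vc))
        floor = np.log(var_y * 1e-8)
        ceil = np.log(var_y * 1e4)

        trace: list[float] = []

        def neg(logv):
            ll = self.reml_loglike(np.exp(logv))
            trace.append(ll)
            return -ll

        res = optimize.minimize(
            neg,
            start,
            method="L-BFGS-B",
            bounds=[(floor, ceil)] * n_vc,
            options={"maxiter": maxiter, "ftol": tol, "gtol": 1e-10},
        )
        variances = np.exp(res.x)
        # Components that land on the lower bound are genuinely zero.
        variances[variances <= var_y * 2e-8] = 0.0
        V = self._covariance(variances)
        if variances[-1] == 0.0:  # keep the factorization well-posed
            V = V + var_y * 1e-10 * np.eye(len(self.y))
        c = _CovSolver(chol=cho_factor(V, lower=True))
        Vinv_X = c.solve(self.X)
        XtVX = self.X.T @ Vinv_X
        XtVX_inv = np.linalg.inv(XtVX)
        Vinv_y = c.solve(self.y)
        beta = XtVX_inv @ (self.X.T @ Vinv_y)
        try:
            loglik = float(self.reml_loglike(variances))
        except np.linalg.LinAlgError:
            loglik = float(-res.fun)
        vc_bse = None
        if vc_se:
            vc_bse = self._vc_standard_errors(np.exp(res.x))
        return MixedModelResults(
            model=self,
            params=beta,
            bse=np.sqrt(np.diag(XtVX_inv)),
            vc=dict(zip(self.vc_names, variances)),
            loglik=float(loglik),
            converged=bool(res.success),
            n_iter=int(res.nit),
            message=str(res.message),
            _chol=c,
            _Vinv_X=Vinv_X,
            _XtVX_inv=XtVX_inv,
            _Vinv_y=Vinv_y,
            vc_bse=vc_bse,
        )

    def _vc_standard_errors(self, variances: np.ndarray) -> dict:
        """Asymptotic SEs from the REML expected information,
        I_ij = tr(P G_i P G_j) / 2 with P the REML projection."""
        n = len(self.y)
        V = self._covariance(variances)
        c = cho_factor(V, lower=True)
        Vinv = cho_solve(c, np.eye(n))
        Vinv_X = Vinv @ self.X
        P = Vinv - Vinv_X @ np.linalg.solve(self.X.T @ Vinv_X, Vinv_X.T)
        mats = [P @ G for G in self._structures] + [P]  # residual structure is I
        d = len(mats)
        info = np.empty((d, d))
        for i in range(d):
            for j in range(i, d):
                info[i, j] = info[j, i] = 0.5 * np.sum(mats[i] * mats[j].T)
        try:
            cov = np.linalg.inv(info)
            se = np.sqrt(np.clip(np.diag(cov), 0, None))
        except np.linalg.LinAlgError:
            se = np.full(d, np.nan)
        return dict(zip(self.vc_names, se))


class MixedModelResults:
    """Fitted null mixed model: REML variance components, GLS fixed
    effects, and the factorized trait covariance reused by every marker
    and local-ancestry test."""

    def __init__(self, model, params, bse, vc, loglik, converged, n_iter, message,
                 _chol, _Vinv_X, _XtVX_inv, _Vinv_y, vc_bse=None):
        self.model = model
        self.params = params
        self.bse = bse
        self.vc = vc
        self.loglik = loglik
        self.converged = converged
        self.n_iter = n_iter
        self.message = message
        self.vc_bse = vc_bse
        self._chol = _chol
        self._Vinv_X = _Vinv_X
        self._XtVX_inv = _XtVX_inv
        self._Vinv_y = _Vinv_y
        # Projected response P y, with P = Vinv - Vinv X (X'Vinv X)^-1 X'Vinv.
        self._Py = _Vinv_y - _Vinv_X @ (_XtVX_inv @ (model.X.T @ _Vinv_y))

    @property
    def nobs(self) -> int:
        return len(self.model.y)

    def project(self, G: np.ndarray) -> np.ndarray:
        """Apply the REML projection P to columns of G."""
        G = np.atleast_2d(np.asarray(G, dtype=float))
        if G.shape[0] != self.nobs:
            G = G.T
        Vinv_G = self._chol.solve(G)
        return Vinv_G - self._Vinv_X @ (self._XtVX_inv @ (self.model.X.T @ Vinv_G))

    def test_fixed_effect(self, focal, names=None) -> TestResult:
        """Wald test of one or two focal columns added to the null design.

        Variance components are held at the null REML estimates. Raises
        `CollinearityError` (naming the offending column) when a focal
        column lies in the span of the design plus the other focal
        columns.
        """
        G = np.asarray(focal, dtype=float)
        if G.ndim == 1:
            G = G[:, None]
        if G.shape[0] != self.nobs:
            raise ValueError("focal predictor not aligned with fitted individuals")
        d = G.shape[1]
        if d not in (1, 2):
            raise ValueError("only 1-df and 2-df tests are supported")
        names = names or [f"focal{j}" for j in range(d)]
        Vinv_G = self._chol.solve(G)
        PG = Vinv_G - self._Vinv_X @ (self._XtVX_inv @ (self.model.X.T @ Vinv_G))
        S = G.T @ PG  # Schur complement: inverse covariance of focal effects
        diag_S = np.diag(S)
        # A column in the span of the design has g'Pg ~ 0 while g'Vinv g is O(n).
        ref = np.einsum("ij,ij->j", G, Vinv_G)
        bad = np.where(diag_S <= 1e-8 * np.maximum(ref, 1e-300))[0]
        if len(bad):
            raise CollinearityError(f"focal column {names[bad[0]]!r} is collinear with the null design")
        if d == 2 and np.linalg.det(S) <= 1e-8 * diag_S[0] * diag_S[1]:
            raise CollinearityError(f"focal columns {names[0]!r} and {names[1]!r} are mutually collinear")
        rhs = G.T @ self._Py
        cov = np.linalg.inv(S)
        b = cov @ rhs
        stat = float(b @ S @ b)
        p = float(stats.chi2.sf(stat, df=d))
        if d == 1:
            return TestResult(effect=float(b[0]), se=float(np.sqrt(cov[0, 0])), stat=stat, df=1, p=p)
        return TestResult(effect=b, se=np.sqrt(np.diag(cov)), stat=stat, df=2, p=p)

    def batch_test(self, G: np.ndarray) -> pd.DataFrame:
        """Vectorized 1-df Wald tests for each column of G.

        Identical to `test_fixed_effect` per column (cross-checked in the
        test suite); constant columns are returned with NaN and flagged.
        """
        G = np.asarray(G, dtype=float)
        if G.ndim == 1:
            G = G[:, None]
        PG = self.project(G)
        gPg = np.einsum("ij,ij->j", G, PG)
        gPy = G.T @ self._Py
        monomorphic = G.var(axis=0) == 0
        with np.errstate(divide="ignore", invalid="ignore"):
            effect = gPy / gPg
            se = 1.0 / np.sqrt(gPg)
            stat = gPy**2 / gPg
        p = stats.chi2.sf(stat, df=1)
        out = pd.DataFrame({"effect": effect, "se": se, "stat": stat, "p": p, "monomorphic": monomorphic})
        out.loc[monomorphic, ["effect", "se", "stat", "p"]] = np.nan
        return out

    def with_covariates(self, extra: np.ndarray, names=None) -> "MixedModelResults":
        """Results object with extra fixed covariates, variance components
        held at this fit — the conditional-analysis device.

        Extra columns collinear with the current design are dropped with a
        warning (recorded in ``dropped_covariates``).
        """
        import warnings

        extra = np.atleast_2d(np.asarray(extra, dtype=float))
        if extra.shape[0] != self.nobs:
            extra = extra.T
        names = names or [f"cond{j}" for j in range(extra.shape[1])]
        keep_cols, keep_names, dropped = [], [], []
        X = self.model.X
        for j in range(extra.shape[1]):
            candidate = np.column_stack([X] + keep_cols + [extra[:, j]])
            if np.linalg.matrix_rank(candidate) < candidate.shape[1]:
                dropped.append(names[j])
                continue
            keep_cols.append(extra[:, j])
            keep_names.append(names[j])
        if dropped:
            warnings.warn(f"dropped collinear conditioning covariates: {dropped}")
        if not keep_cols:
            new = self._copy()
            new.dropped_covariates = dropped
            return new
        Xnew = np.column_stack([X] + keep_cols)
        model = AdmixtureMixedModel.__new__(AdmixtureMixedModel)
        model.y = self.model.y
        model.X = Xnew
        model.exog_names = list(self.model.exog_names) + keep_names
        model.vc_names = self.model.vc_names
        model._structures = self.model._structures
        c = self._chol
        Vinv_X = c.solve(Xnew)
        XtVX_inv = np.linalg.inv(Xnew.T @ Vinv_X)
        beta = XtVX_inv @ (Xnew.T @ self._Vinv_y)
        new = MixedModelResults(
            model=model,
            params=beta,
            bse=np.sqrt(np.diag(XtVX_inv)),
            vc=dict(self.vc),
            loglik=np.nan,
            converged=self.converged,
            n_iter=0,
            message="conditional fit at null variance components",
            _chol=c,
            _Vinv_X=Vinv_X,
            _XtVX_inv=XtVX_inv,
            _Vinv_y=self._Vinv_y,
        )
        new.dropped_covariates = dropped
        return new

    def _copy(self) -> "MixedModelResults":
        return MixedModelResults(
            model=self.model, params=self.params, bse=self.bse, vc=dict(self.vc),
            loglik=self.loglik, converged=self.converged, n_iter=self.n_iter,
            message=self.message, _chol=self._chol, _Vinv_X=self._Vinv_X,
            _XtVX_inv=self._XtVX_inv, _Vinv_y=self._Vinv_y,
        )

    def summary(self) -> str:
        lines = ["Admixture mixed model (REML)", "=" * 60]
        lines.append(f"n = {self.nobs}, fixed effects = {self.model.X.shape[1]}")
        lines.append(f"REML log-likelihood = {self.loglik:.4f}  (converged: {self.converged}, iters: {self.n_iter})")
        lines.append("-" * 60)
        lines.append("Variance components:")
        for name, v in self.vc.items():
            lines.append(f"  {name:<12} {v:12.5f}")
        lines.append("-" * 60)
        lines.append(f"{'Fixed effect':<20}{'coef':>12}{'SE':>12}{'z':>9}{'p':>12}")
        for name, b, s in zip(self.model.exog_names, self.params, self.bse):
            z = b / s if s > 0 else np.nan
            p = 2 * stats.norm.sf(abs(z))
            lines.append(f"{name:<20}{b:>12.5f}{s:>12.5f}{z:>9.3f}{p:>12.3g}")
        return "\n".join(lines)
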