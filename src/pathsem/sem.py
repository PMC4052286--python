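"""Maximum-likelihood fitting of observed-variable path models.

The model is the linear system Y = B Y + U with Cov(U) = Psi, implying the
covariance structure Sigma(theta) = (I - B)^-1 Psi (I - B)^-T.  Parameters
are estimated by minimizing the ML discrepancy

    F = log|Sigma(theta)| + tr(S Sigma(theta)^-1) - log|S| - p

over the free entries of B and Psi; n * F at the optimum is the chi-square
likelihood-ratio statistic against the saturated model with
d = p(p+1)/2 - t degrees of freedom.  Alongside the exact-fit test the
module provides RMSEA with its close-fit probability (noncentral
chi-square), the standardized root-mean-square residual (SRMR),
standard errors from the observed information, score-test modification
indices for fixed parameters, total/direct/indirect effect decompositions
and parametric or nonparametric bootstrap distributions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from ._engine import GroupMoments, MLProblem, moments_from_cov, moments_from_data
from .errors import IdentificationError
from .model import PathModel

__all__ = [
    "FitConfig",
    "SEMParameters",
    "FitResult",
    "implied_covariance",
    "degrees_of_freedom",
    "rmsea",
    "rmsea_pclose",
    "srmr",
    "fit_ml",
    "standard_errors",
    "modification_indices",
    "effects_decomposition",
    "bootstrap_fit",
    "BootstrapResult",
    "Effects",
]


@dataclass(frozen=True)
class FitConfig:
    """Conventions, thresholds and optimizer controls for SEM fitting.

    ``chisq_n_convention`` / ``rmsea_n_convention`` choose the sample-size
    multiplier (``"N"`` or ``"N_minus_1"``); the default total-N reproduces
    published RMSEA values computed from chi-square, df and N.
    ``close_fit_epsilon`` is the RMSEA null value for the close-fit test;
    ``z_threshold`` the one-sided retention cutoff for refined edges;
    ``srmr_adequate`` the adequate-fit SRMR bound.
    """

    chisq_n_convention: str = "N"
    rmsea_n_convention: str = "N"
    close_fit_epsilon: float = 0.05
    alpha: float = 0.05
    z_threshold: float = 1.64
    srmr_adequate: float = 0.10
    max_iter: int = 1000
    gradient_tolerance: float = 1e-7
    restarts: int = 3
    seed: int = 0
    pvalue_method: str = "asymptotic"  # or "bootstrap"
    bootstrap_reps: int = 1000
    max_refine_steps: int = 50

    def __post_init__(self):
        if self.chisq_n_convention not in ("N", "N_minus_1"):
            raise ValueError("chisq_n_convention must be 'N' or 'N_minus_1'")
        if self.rmsea_n_convention not in ("N", "N_minus_1"):
            raise ValueError("rmsea_n_convention must be 'N' or 'N_minus_1'")
        for name in ("alpha", "z_threshold", "srmr_adequate"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.close_fit_epsilon < 0:
            raise ValueError("close_fit_epsilon must be non-negative")


@dataclass
class SEMParameters:
    """Point values of the structural matrices (0 where fixed)."""

    beta: np.ndarray
    psi: np.ndarray
    means: np.ndarray | None = None  # structural intercepts nu


def implied_covariance(params: SEMParameters) -> np.ndarray:
    """Sigma(theta) = (I - B)^-1 Psi (I - B)^-T."""
    B = np.asarray(params.beta, float)
    Psi = np.asarray(params.psi, float)
    p = B.shape[0]
    IB = np.eye(p) - B
    if abs(np.linalg.det(IB)) < 1e-12:
        raise ValueError("non-convergent system: I - B is singular")
    A = np.linalg.solve(IB, np.eye(p))
    Sigma = A @ Psi @ A.T
    return (Sigma + Sigma.T) / 2.0


def degrees_of_freedom(model: PathModel, p: int | None = None) -> int:
    """d = p(p+1)/2 - t for the covariance structure.

    Saturated per-group means (the only mean structure this package fits)
    cancel against their own saturated count and do not change d.
    """
    p = model.p if p is None else int(p)
    t = model.n_free_beta + model.n_free_psi
    d = p * (p + 1) // 2 - t
    if d < 0:
        raise ValueError(f"over-parameterized: t={t} exceeds p(p+1)/2={p * (p + 1) // 2}")
    return d


def _nconv(n: int, convention: str) -> int:
    return n if convention == "N" else n - 1


def rmsea(chisq: float, d: int, n: int, config: FitConfig | None = None) -> float:
    """Root-mean-square error of approximation sqrt(max(0, (chi2-d)/(d*m)))."""
    config = config or FitConfig()
    if d < 1:
        raise ValueError("RMSEA is undefined for d = 0")
    if n < 2:
        raise ValueError("need n >= 2")
    m = _nconv(n, config.rmsea_n_convention)
    return float(np.sqrt(max(0.0, (chisq - d) / (d * m))))


def rmsea_pclose(chisq: float, d: int, n: int, config: FitConfig | None = None) -> float:
    """Close-fit probability P[chi2(lambda, d) >= chisq], lambda=(n-1)*d*eps^2."""
    config = config or FitConfig()
    if d < 1:
        raise ValueError("close-fit test is undefined for d = 0")
    if n < 2:
        raise ValueError("need n >= 2")
    lam = (n - 1) * d * config.close_fit_epsilon**2
    if lam == 0:
        return float(stats.chi2.sf(chisq, d))
    return float(stats.ncx2.sf(chisq, d, lam))


def srmr(S: np.ndarray, Sigma: np.ndarray) -> float:
    """Standardized root-mean-square residual between S and Sigma(theta).

    Includes the diagonal residuals; the denominator is the number of
    distinct (co)variances p(p+1)/2.
    """
    S = np.asarray(S, float)
    Sigma = np.asarray(Sigma, float)
    if S.shape != Sigma.shape or S.ndim != 2 or S.shape[0] != S.shape[1]:
        raise ValueError("S and Sigma must be square matrices of equal dimension")
    p = S.shape[0]
    d = np.sqrt(np.outer(np.diag(S), np.diag(S)))
    resid = (S - Sigma) / d
    iu = np.triu_indices(p)
    return float(np.sqrt((resid[iu] ** 2).sum() / (p * (p + 1) / 2)))


@dataclass
class FitResult:
    """A converged single-group fit with its indices and diagnostics."""

    model: PathModel
    config: FitConfig
    params: SEMParameters
    theta: np.ndarray
    loglik: float
    chisq: float
    df: int
    p_value: float
    rmsea: float
    rmsea_pclose: float
    srmr: float
    converged: bool
    n: int
    n_iter: int
    S: np.ndarray
    Sigma: np.ndarray
    problem: MLProblem = field(repr=False, default=None)
    _se: pd.Series | None = field(repr=False, default=None)

    @property
    def labels(self) -> list:
        """lavaan-style parameter labels aligned with theta."""
        v = self.model.variables
        out = []
        for kind, i, j, _ in self.problem.keys:
            if kind == "beta":
                out.append(f"{v[i]}~{v[j]}")
            elif kind == "psi_d":
                out.append(f"{v[i]}~~{v[i]}")
            elif kind == "psi_o":
                out.append(f"{v[i]}~~{v[j]}")
            else:
                out.append(f"{v[i]}~1")
        return out

    @property
    def se(self) -> pd.Series:
        if self._se is None:
            self._se = standard_errors(self)
        return self._se

    def estimates(self) -> pd.Series:
        """Estimates on the natural scale, indexed by parameter label."""
        vals = []
        for (kind, i, j, _), val in zip(self.problem.keys, self.theta):
            vals.append(np.exp(val) if kind == "psi_d" else val)
        return pd.Series(vals, index=self.labels)

    def param_table(self) -> pd.DataFrame:
        est = self.estimates()
        se = self.se
        z = est / se
        return pd.DataFrame(
            {
                "estimate": est,
                "se": se,
                "z": z,
                "p_value": 2.0 * stats.norm.sf(np.abs(z)),
            }
        )


def fit_ml(
    model: PathModel,
    data: "pd.DataFrame | np.ndarray | None" = None,
    *,
    S: np.ndarray | None = None,
    n: int | None = None,
    config: FitConfig | None = None,
) -> FitResult:
    """Fit a path model by maximum likelihood from data or from (S, n).

    ``data`` is samples x variables, column order matching
    ``model.variables`` (a DataFrame is reordered by name).  The chi-square
    statistic equals m * F at the optimum with m chosen by
    ``config.chisq_n_convention``.
    """
    config = config or FitConfig()
    if data is not None:
        if isinstance(data, pd.DataFrame):
            missing = [v for v in model.variables if v not in data.columns]
            if missing:
                raise ValueError(f"data is missing model variables: {missing}")
            X = data[list(model.variables)].to_numpy(float)
        else:
            X = np.asarray(data, float)
            if X.shape[1] != model.p:
                raise ValueError("data has wrong number of columns")
        gm = moments_from_data(X, mean_structure=False)
    elif S is not None:
        if n is None:
            raise ValueError("n is required when fitting from a covariance matrix")
        gm = moments_from_cov(S, n)
    else:
        raise ValueError("provide data or (S, n)")
    p = model.p
    if gm.S.shape[0] != p:
        raise ValueError("covariance dimension does not match the model")
    if gm.n <= p:
        warnings.warn(f"sample size n={gm.n} <= p={p}; fit may be unstable")
    df = degrees_of_freedom(model)

    problem = MLProblem(model, [gm], mean_structure=False)
    theta, fmin, converged, nit = problem.fit(
        max_iter=config.max_iter,
        gtol=config.gradient_tolerance,
        restarts=config.restarts,
        seed=config.seed,
    )
    B, Psi, _ = problem.matrices(theta, 0)
    Sigma = implied_covariance(SEMParameters(B, Psi))
    m = _nconv(gm.n, config.chisq_n_convention)
    chisq = max(0.0, fmin * m / gm.n)
    p_value = float(stats.chi2.sf(chisq, df)) if df > 0 else 1.0
    sign, logdetSig = np.linalg.slogdet(Sigma)
    trSP = float(np.trace(gm.S @ np.linalg.inv(Sigma)))
    loglik = -0.5 * gm.n * (logdetSig + trSP + p * np.log(2 * np.pi))
    return FitResult(
        model=model,
        config=config,
        params=SEMParameters(beta=B, psi=Psi),
        theta=theta,
        loglik=loglik,
        chisq=chisq,
        df=df,
        p_value=p_value,
        rmsea=rmsea(chisq, df, gm.n, config) if df > 0 else float("nan"),
        rmsea_pclose=rmsea_pclose(chisq, df, gm.n, config) if df > 0 else float("nan"),
        srmr=srmr(gm.S, Sigma),
        converged=converged,
        n=gm.n,
        n_iter=nit,
        S=gm.S,
        Sigma=Sigma,
        problem=problem,
    )


def standard_errors(fit: FitResult) -> pd.Series:
    """SEs from the observed information (numerical Hessian at the optimum).

    Error variances are reported on the natural scale via the delta method.
    Raises :class:`IdentificationError` when the information is singular.
    """
    if not fit.converged:
        raise ValueError("standard errors require a converged fit")
    cov = fit.problem.observed_covariance(fit.theta)
    se = np.sqrt(np.diag(cov))
    for k, (kind, i, j, _) in enumerate(fit.problem.keys):
        if kind == "psi_d":
            se[k] *= np.exp(fit.theta[k])  # d psi / d log psi
    return pd.Series(se, index=fit.labels)


def _default_candidates(model: PathModel) -> list:
    """All fixed path coefficients and error covariances, deterministic order."""
    out = []
    v = model.variables
    p = model.p
    for i in range(p):
        for j in range(p):
            if i != j and not model.beta_free[i, j]:
                out.append(("beta", v[i], v[j]))
    for i in range(p):
        for j in range(i + 1, p):
            if not model.psi_free[i, j]:
                out.append(("psi", v[i], v[j]))
    return out


def modification_indices(fit: FitResult, candidates: Sequence[tuple] | None = None) -> pd.DataFrame:
    """Univariate score-test (Lagrange multiplier) statistics for fixed parameters.

    Each MI estimates the chi-square drop from freeing one fixed parameter;
    ``epc`` is the expected value the parameter would take.  Candidates are
    ``("beta", target, source)`` or ``("psi", a, b)`` tuples; by default all
    fixed off-diagonal entries are scored.  Rows are sorted by descending MI
    (ties broken lexicographically by target then source, so results are
    reproducible).
    """
    model = fit.model
    if candidates is None:
        candidates = _default_candidates(model)
    ext = model.copy()
    cand_keys = []
    for cand in candidates:
        kind, a, b = cand
        i, j = model.index(a), model.index(b)
        if kind == "beta":
            if model.beta_free[i, j]:
                raise ValueError(f"candidate {cand} is already free")
            ext.add_beta(a, b, provenance="candidate")
            cand_keys.append(("beta", i, j, None))
        elif kind == "psi":
            if model.psi_free[i, j]:
                raise ValueError(f"candidate {cand} is already free")
            ext.add_psi(a, b, provenance="candidate")
            cand_keys.append(("psi_o", min(i, j), max(i, j), None))
        else:
            raise ValueError(f"unknown candidate kind {kind!r}")

    prob_ext = MLProblem(ext, fit.problem.groups, mean_structure=False)
    kidx = prob_ext.key_index()
    # Embed the fitted theta into the extended layout (candidates at 0).
    theta_ext = np.zeros(prob_ext.T)
    for k_old, key in enumerate(fit.problem.keys):
        theta_ext[kidx[key]] = fit.theta[k_old]
    _, g_ext = prob_ext.value_and_grad(theta_ext)
    info = prob_ext.expected_information(theta_ext)

    free_idx = [kidx[key] for key in fit.problem.keys]
    I_ff = info[np.ix_(free_idx, free_idx)]
    try:
        I_ff_inv = np.linalg.inv(I_ff)
    except np.linalg.LinAlgError:
        raise IdentificationError("singular information matrix at the fitted model")

    rows = []
    for cand, key in zip(candidates, cand_keys):
        c = kidx[key]
        U = -0.5 * g_ext[c]
        I_cc = info[c, c]
        I_cf = info[c, free_idx]
        denom = I_cc - I_cf @ I_ff_inv @ I_cf
        if denom <= 1e-12:
            mi, epc = 0.0, 0.0
        else:
            mi = float(U**2 / denom)
            epc = float(U / denom)
        kind, a, b = cand
        label = f"{a}~{b}" if kind == "beta" else f"{a}~~{b}"
        rows.append(
            {"param": label, "kind": kind, "target": a, "source": b, "mi": mi, "epc": epc}
        )
    table = pd.DataFrame(rows)
    # Ties (including score-equivalent beta/psi pairs) resolve to the path
    # coefficient first, then lexicographically by target and source.
    table = table.sort_values(
        ["mi", "kind", "target", "source"],
        ascending=[False, True, True, True],
        kind="mergesort",
    ).reset_index(drop=True)
    return table


@dataclass(frozen=True)
class Effects:
    """Total, direct and indirect effect matrices, TE = DE + IE."""

    total: np.ndarray
    direct: np.ndarray
    indirect: np.ndarray


def effects_decomposition(beta: np.ndarray) -> Effects:
    """TE = (I - B)^-1 - I summed over all directed paths; DE = B; IE = TE - DE."""
    B = np.asarray(beta, float)
    p = B.shape[0]
    rho = np.max(np.abs(np.linalg.eigvals(B)))
    if rho >= 1.0:
        raise ValueError(f"divergent feedback: spectral radius {rho:.3f} >= 1")
    TE = np.linalg.solve(np.eye(p) - B, np.eye(p)) - np.eye(p)
    return Effects(total=TE, direct=B.copy(), indirect=TE - B)


@dataclass
class BootstrapResult:
    """Bootstrap parameter and chi-square distributions."""

    params: pd.DataFrame  # one row per successful replicate
    chisq: np.ndarray
    n_requested: int
    n_failed: int
    mode: str
    seed: int

    @property
    def failure_rate(self) -> float:
        return self.n_failed / self.n_requested


def bootstrap_fit(
    model: PathModel,
    data: "pd.DataFrame | np.ndarray",
    reps: int = 100,
    mode: str = "model_based",
    seed: int = 0,
    config: FitConfig | None = None,
) -> BootstrapResult:
    """Bootstrap the fitted model.

    ``nonparametric`` resamples data rows with replacement; ``model_based``
    draws Gaussian samples from the fitted Sigma(theta).  Replicates that
    fail to converge are skipped and counted.  A fixed seed makes the whole
    distribution bit-reproducible.
    """
    if reps < 1:
        raise ValueError("reps must be >= 1")
    if mode not in ("nonparametric", "model_based"):
        raise ValueError("mode must be 'nonparametric' or 'model_based'")
    config = config or FitConfig()
    if isinstance(data, pd.DataFrame):
        X = data[list(model.variables)].to_numpy(float)
    else:
        X = np.asarray(data, float)
    base = fit_ml(model, X, config=config)
    rng = np.random.default_rng(seed)
    n = X.shape[0]
    est_rows, chisqs, failed = [], [], 0
    for _ in range(reps):
        if mode == "nonparametric":
            Xb = X[rng.integers(0, n, size=n)]
        else:
            Xb = rng.multivariate_normal(X.mean(axis=0), base.Sigma, size=n)
        try:
            fb = fit_ml(model, Xb, config=replace(config, restarts=1))
        except Exception:
            failed += 1
            continue
        est_rows.append(fb.estimates())
        chisqs.append(fb.chisq)
    params = pd.DataFrame(est_rows).reset_index(drop=True)
    return BootstrapResult(
        params=params,
        chisq=np.asarray(chisqs),
        n_requested=reps,
        n_failed=failed,
        mode=mode,
        seed=seed,
    )
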