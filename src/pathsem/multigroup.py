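"""Two-group SEM comparison: omnibus invariance tests and node/edge screens.

The experimental group is coded 1 and the control group 0.  Two omnibus
likelihood-ratio tests ask whether the groups differ globally in means
(H0: mu_1 = mu_2 subject to Sigma_1 = Sigma_2) or in covariance structure
(H0: Sigma_1 = Sigma_2 with means free).  Three Wald screens then localize
the differences:

* t_C — per node, the group difference in the conditional mean given the
  node's parents (the structural intercept), labelling genes up/down
  expressed;
* t_D — per edge, the difference d_ij = b_ij(exp) - b_ij(ctrl) of path
  coefficients, labelling edges up/down regulated;
* t1/t2 — per edge and group, a one-sided test of beta = 0 in the
  direction implied by the a-priori interaction type, labelling the edge
  ON or OFF in each group.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from ._engine import MLProblem, moments_from_data
from .model import PathModel
from .sem import FitConfig

__all__ = [
    "GroupedData",
    "OmnibusTest",
    "TwoGroupFit",
    "TwoGroupResult",
    "fit_two_group",
    "omnibus_mean_test",
    "omnibus_cov_test",
    "node_tests",
    "edge_tests",
    "onoff_tests",
    "two_group_analysis",
    "wald_pvalue_from_ci",
    "adjust_pvalues",
]

_CONSTRAINTS = ("none", "equal_means", "equal_cov_structure", "both")


@dataclass
class GroupedData:
    """Expression matrices (samples x variables) for the two groups.

    ``group1`` is the experimental group (coded 1), ``group2`` the control
    (coded 0).  Columns must match exactly in name and order.
    """

    group1: pd.DataFrame
    group2: pd.DataFrame

    def __post_init__(self):
        if list(self.group1.columns) != list(self.group2.columns):
            raise ValueError("group variable sets/orders differ")
        if len(self.group1) < 3 or len(self.group2) < 3:
            raise ValueError("need at least 3 samples per group")

    @property
    def n1(self) -> int:
        return len(self.group1)

    @property
    def n2(self) -> int:
        return len(self.group2)

    @property
    def variables(self) -> list:
        return list(self.group1.columns)

    def swapped(self) -> "GroupedData":
        return GroupedData(group1=self.group2.copy(), group2=self.group1.copy())

    def centered(self) -> "GroupedData":
        """Center every variable at its pooled (both-group) mean.

        Group contrasts of intercepts and all covariance-structure
        quantities are invariant; what changes is that intercept contrasts
        are no longer contaminated by (B1-B2) times the raw baseline level.
        """
        pooled = pd.concat([self.group1, self.group2]).mean(axis=0)
        return GroupedData(group1=self.group1 - pooled, group2=self.group2 - pooled)

    @staticmethod
    def from_frames(
        expr: pd.DataFrame, labels: pd.Series, experimental_label: str
    ) -> "GroupedData":
        """Split a samples x variables frame by a two-level label vector."""
        labels = labels.reindex(expr.index)
        levels = sorted(labels.dropna().unique())
        if len(levels) != 2:
            raise ValueError(f"group labels must have exactly two levels, got {levels}")
        if experimental_label not in levels:
            raise ValueError(f"experimental label {experimental_label!r} not in {levels}")
        g1 = expr.loc[labels == experimental_label]
        g2 = expr.loc[labels != experimental_label]
        return GroupedData(group1=g1, group2=g2)


@dataclass(frozen=True)
class OmnibusTest:
    chisq_diff: float
    df_diff: int
    p_value: float


@dataclass
class TwoGroupFit:
    """Joint ML fit of both groups under optional equality constraints."""

    model: PathModel
    constraints: str
    problem: MLProblem = field(repr=False)
    theta: np.ndarray = field(repr=False)
    objective: float
    loglik: float
    converged: bool
    config: FitConfig = field(repr=False, default=None)
    _cov: np.ndarray | None = field(repr=False, default=None)

    @property
    def t(self) -> int:
        return self.problem.T

    def covariance(self) -> np.ndarray:
        if self._cov is None:
            self._cov = self.problem.observed_covariance(self.theta)
        return self._cov

    def _key(self, kind: str, i: int, j: int, group: int):
        blk = None
        if kind in ("beta", "psi_d", "psi_o"):
            blk = None if self.problem.share_cov else group
        elif kind == "nu":
            blk = None if self.problem.share_nu else group
        return (kind, i, j, blk)

    def estimate(self, kind: str, i: int, j: int, group: int) -> tuple[float, int]:
        """(natural-scale estimate, theta index) of one parameter in one group."""
        idx = self.problem.key_index()[self._key(kind, i, j, group)]
        val = self.theta[idx]
        if kind == "psi_d":
            val = float(np.exp(val))
        return float(val), idx

    def contrast_se(self, idx1: int, idx2: int) -> float:
        """SE of theta[idx1] - theta[idx2] from the joint parameter covariance."""
        cov = self.covariance()
        if idx1 == idx2:
            return 0.0
        var = cov[idx1, idx1] + cov[idx2, idx2] - 2.0 * cov[idx1, idx2]
        return float(np.sqrt(max(var, 0.0)))


def _grouped_moments(model: PathModel, gd: GroupedData):
    cols = list(model.variables)
    missing = [v for v in cols if v not in gd.variables]
    if missing:
        raise ValueError(f"grouped data is missing model variables: {missing}")
    return [
        moments_from_data(gd.group1[cols].to_numpy(float), mean_structure=True),
        moments_from_data(gd.group2[cols].to_numpy(float), mean_structure=True),
    ]


def fit_two_group(
    model: PathModel,
    gd: GroupedData,
    constraints: str = "none",
    config: FitConfig | None = None,
) -> TwoGroupFit:
    """Joint ML over both groups with the stated equality constraints.

    ``constraints``: ``none`` (everything group-specific), ``equal_means``
    (shared intercepts), ``equal_cov_structure`` (shared beta and psi) or
    ``both``.  The mean structure is always on.  The ``objective`` is the
    -2 log likelihood-ratio against the two-group saturated model, so
    differences between nested fits are chi-square test statistics.
    """
    if constraints not in _CONSTRAINTS:
        raise ValueError(f"constraints must be one of {_CONSTRAINTS}")
    config = config or FitConfig()
    groups = _grouped_moments(model, gd)
    problem = MLProblem(
        model,
        groups,
        mean_structure=True,
        share_cov=constraints in ("equal_cov_structure", "both"),
        share_nu=constraints in ("equal_means", "both"),
    )
    try:
        theta, fmin, converged, _ = problem.fit(
            max_iter=config.max_iter,
            gtol=config.gradient_tolerance,
            restarts=config.restarts,
            seed=config.seed,
        )
    except Exception as exc:
        raise type(exc)(f"two-group fit ({constraints}) failed: {exc}") from exc
    p = model.p
    loglik = 0.0
    for g, gm in enumerate(groups):
        B, Psi, nu = problem.matrices(theta, g)
        A = np.linalg.solve(np.eye(p) - B, np.eye(p))
        Sigma = A @ Psi @ A.T
        r = gm.ybar - A @ nu
        sign, logdet = np.linalg.slogdet(Sigma)
        Sinv = np.linalg.inv(Sigma)
        loglik += -0.5 * gm.n * (
            logdet + float(np.trace(gm.S @ Sinv)) + float(r @ Sinv @ r) + p * np.log(2 * np.pi)
        )
    return TwoGroupFit(
        model=model,
        constraints=constraints,
        problem=problem,
        theta=theta,
        objective=float(fmin),
        loglik=loglik,
        converged=converged,
        config=config,
    )


def omnibus_mean_test(
    model: PathModel, gd: GroupedData, config: FitConfig | None = None
) -> OmnibusTest:
    """LRT of equal means vs free means, both under equal covariance structure."""
    h1 = fit_two_group(model, gd, constraints="equal_cov_structure", config=config)
    h0 = fit_two_group(model, gd, constraints="both", config=config)
    dchi = max(0.0, h0.objective - h1.objective)
    df = model.p
    return OmnibusTest(dchi, df, float(stats.chi2.sf(dchi, df)))


def omnibus_cov_test(
    model: PathModel, gd: GroupedData, config: FitConfig | None = None
) -> OmnibusTest:
    """LRT of equal covariance structure vs free, means free in both."""
    h1 = fit_two_group(model, gd, constraints="none", config=config)
    h0 = fit_two_group(model, gd, constraints="equal_cov_structure", config=config)
    dchi = max(0.0, h0.objective - h1.objective)
    df = model.n_free_beta + model.n_free_psi
    return OmnibusTest(dchi, df, float(stats.chi2.sf(dchi, df)))


def _bootstrap_diffs(model, gd, config, extractor, seed_offset=0):
    """Bootstrap distribution of per-parameter group differences."""
    rng = np.random.default_rng(config.seed + seed_offset)
    reps = config.bootstrap_reps
    out = []
    X1, X2 = gd.group1, gd.group2
    for _ in range(reps):
        b1 = X1.iloc[rng.integers(0, len(X1), len(X1))]
        b2 = X2.iloc[rng.integers(0, len(X2), len(X2))]
        try:
            fit = fit_two_group(model, GroupedData(b1, b2), "none", config)
        except Exception:
            continue
        out.append(extractor(fit))
    return pd.DataFrame(out)


def _pvalue_two_sided(z: float) -> float:
    return float(2.0 * stats.norm.sf(abs(z)))


def node_tests(
    model: PathModel,
    gd: GroupedData,
    config: FitConfig | None = None,
    fit: TwoGroupFit | None = None,
) -> pd.DataFrame:
    """The t_C screen: conditional mean difference per node, given its parents.

    The difference is the experimental-minus-control structural intercept,
    equivalent to the path coefficient of a group indicator coded 1/0.
    Negative differences label the experimental group down-expressed.
    """
    config = config or FitConfig()
    fit = fit or fit_two_group(model, gd, "none", config)
    if fit.problem.share_nu:
        raise ValueError("node tests require group-specific intercepts")
    rows = []
    boot = None
    if config.pvalue_method == "bootstrap":
        def _extract(f):
            return {
                v: f.estimate("nu", i, i, 0)[0] - f.estimate("nu", i, i, 1)[0]
                for i, v in enumerate(model.variables)
            }
        boot = _bootstrap_diffs(model, gd, config, _extract, seed_offset=1)
    for i, v in enumerate(model.variables):
        e1, i1 = fit.estimate("nu", i, i, 0)
        e2, i2 = fit.estimate("nu", i, i, 1)
        diff = e1 - e2
        se = fit.contrast_se(i1, i2)
        z = diff / se if se > 0 else np.nan
        if boot is not None and v in boot:
            d = boot[v].dropna().to_numpy()
            p = 2.0 * min((d <= 0).mean(), (d >= 0).mean()) if d.size else np.nan
        else:
            p = _pvalue_two_sided(z)
        rows.append(
            {
                "variable": v,
                "est_group1": e1,
                "est_group2": e2,
                "difference": diff,
                "se": se,
                "z": z,
                "ci_low": diff - 1.96 * se,
                "ci_high": diff + 1.96 * se,
                "p_value": p,
                "label": (
                    ("down-expressed" if diff < 0 else "up-expressed")
                    if p < config.alpha
                    else ""
                ),
            }
        )
    return pd.DataFrame(rows)


def edge_tests(
    model: PathModel,
    gd: GroupedData,
    config: FitConfig | None = None,
    fit: TwoGroupFit | None = None,
) -> pd.DataFrame:
    """The t_D screen: per-edge difference of path coefficients across groups."""
    config = config or FitConfig()
    fit = fit or fit_two_group(model, gd, "none", config)
    if fit.problem.share_cov:
        raise ValueError("edge tests require group-specific path coefficients")
    boot = None
    if config.pvalue_method == "bootstrap":
        def _extract(f):
            out = {}
            for tgt, src, _ in model.edges():
                i, j = model.index(tgt), model.index(src)
                out[f"{tgt}~{src}"] = (
                    f.estimate("beta", i, j, 0)[0] - f.estimate("beta", i, j, 1)[0]
                )
            return out
        boot = _bootstrap_diffs(model, gd, config, _extract, seed_offset=2)
    rows = []
    for tgt, src, prov in model.edges():
        i, j = model.index(tgt), model.index(src)
        b1, i1 = fit.estimate("beta", i, j, 0)
        b2, i2 = fit.estimate("beta", i, j, 1)
        d = b1 - b2
        se = fit.contrast_se(i1, i2)
        z = d / se if se > 0 else np.nan
        label = f"{tgt}~{src}"
        if boot is not None and label in boot:
            arr = boot[label].dropna().to_numpy()
            p = 2.0 * min((arr <= 0).mean(), (arr >= 0).mean()) if arr.size else np.nan
        else:
            p = _pvalue_two_sided(z)
        rows.append(
            {
                "edge": label,
                "target": tgt,
                "source": src,
                "type": prov,
                "b_group1": b1,
                "b_group2": b2,
                "difference": d,
                "se": se,
                "z": z,
                "ci_low": d - 1.96 * se,
                "ci_high": d + 1.96 * se,
                "p_value": p,
                "label": (
                    ("down-regulated" if d < 0 else "up-regulated")
                    if p < config.alpha
                    else ""
                ),
            }
        )
    return pd.DataFrame(rows)


def _edge_direction(provenance: str, pooled_sign: float) -> int:
    """A-priori sign of an edge: + for activation-like, - for inhibition-like."""
    prov = provenance.split(":", 1)[-1]
    if prov in ("activation", "phosphorylation", "expression"):
        return 1
    if prov in ("inhibition", "repression"):
        return -1
    return 1 if pooled_sign >= 0 else -1


def onoff_tests(
    model: PathModel,
    gd: GroupedData,
    config: FitConfig | None = None,
    fit: TwoGroupFit | None = None,
) -> pd.DataFrame:
    """The t1/t2 screen: one-sided per-group tests of beta = 0 per edge.

    The alternative's direction comes from the a-priori interaction type
    (activation positive, inhibition negative); for untyped edges it falls
    back to the sign of the pooled estimate.  An edge is ON in a group when
    its one-sided p-value is below alpha.
    """
    config = config or FitConfig()
    fit = fit or fit_two_group(model, gd, "none", config)
    if fit.problem.share_cov:
        raise ValueError("on/off tests require group-specific path coefficients")
    cov = fit.covariance()
    rows = []
    for tgt, src, prov in model.edges():
        i, j = model.index(tgt), model.index(src)
        ests, ses, ps = [], [], []
        b1, _ = fit.estimate("beta", i, j, 0)
        b2, _ = fit.estimate("beta", i, j, 1)
        direction = _edge_direction(prov, b1 + b2)
        for g in (0, 1):
            b, idx = fit.estimate("beta", i, j, g)
            se = float(np.sqrt(max(cov[idx, idx], 0.0)))
            z = b / se if se > 0 else np.nan
            p = float(stats.norm.sf(direction * z))  # one-sided
            ests.append(b)
            ses.append(se)
            ps.append(p)
        state = ["ON" if p < config.alpha else "OFF" for p in ps]
        rows.append(
            {
                "edge": f"{tgt}~{src}",
                "target": tgt,
                "source": src,
                "type": prov,
                "direction": "+" if direction > 0 else "-",
                "b_group1": ests[0],
                "se_group1": ses[0],
                "p_group1": ps[0],
                "b_group2": ests[1],
                "se_group2": ses[1],
                "p_group2": ps[1],
                "state_group1": state[0],
                "state_group2": state[1],
                "onoff": f"{state[0]}/{state[1]}",
            }
        )
    return pd.DataFrame(rows)


@dataclass
class TwoGroupResult:
    """Bundle of the full two-group analysis."""

    fit: TwoGroupFit
    mean_test: OmnibusTest
    cov_test: OmnibusTest
    node_table: pd.DataFrame
    edge_table: pd.DataFrame
    onoff_table: pd.DataFrame


def two_group_analysis(
    model: PathModel,
    gd: GroupedData,
    config: FitConfig | None = None,
    center: bool = True,
) -> TwoGroupResult:
    """Run the omnibus tests and all three screens on one model.

    By default the data are centered at the pooled per-variable mean first;
    every reported contrast and test is invariant to that shift, but the
    node-screen standard errors are not inflated by the raw baseline level.
    """
    config = config or FitConfig()
    if center:
        gd = gd.centered()
    fit = fit_two_group(model, gd, "none", config)
    return TwoGroupResult(
        fit=fit,
        mean_test=omnibus_mean_test(model, gd, config),
        cov_test=omnibus_cov_test(model, gd, config),
        node_table=node_tests(model, gd, config, fit=fit),
        edge_table=edge_tests(model, gd, config, fit=fit),
        onoff_table=onoff_tests(model, gd, config, fit=fit),
    )


def wald_pvalue_from_ci(estimate: float, ci_low: float, ci_high: float) -> float:
    """Two-sided normal p-value implied by an estimate and its 95% CI."""
    if not ci_low < ci_high:
        raise ValueError("degenerate confidence interval")
    if not (ci_low <= estimate <= ci_high):
        raise ValueError("estimate lies outside its confidence interval")
    se = (ci_high - ci_low) / (2.0 * 1.96)
    if se == 0:
        raise ValueError("degenerate confidence interval")
    return _pvalue_two_sided(estimate / se)


def adjust_pvalues(
    table: pd.DataFrame, method: str = "none", column: str = "p_value"
) -> pd.DataFrame:
    """Optionally append a Benjamini-Hochberg adjusted p-value column."""
    if method == "none":
        return table
    if method != "bh":
        raise ValueError("method must be 'none' or 'bh'")
    if column not in table.columns:
        raise ValueError(f"no {column!r} column to adjust")
    from statsmodels.stats.multitest import multipletests

    out = table.copy()
    mask = out[column].notna()
    adj = np.full(len(out), np.nan)
    if mask.any():
        adj[mask.to_numpy()] = multipletests(out.loc[mask, column], method="fdr_bh")[1]
    out[column + "_bh"] = adj
    return out
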