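"""GBLUP mixed models fitted by AI-REML.

Model (per trait): y = Xb + Zu + e with u ~ N(0, G * sigma2_u) and
e ~ N(0, I * sigma2_e); G is a (stabilized) realized genomic relationship
matrix and X carries an intercept plus contemporary-group contrasts.  The
bivariate model stacks two such traits with u ~ N(0, G x H) and
e ~ N(0, I x R) (Kronecker over the 2x2 genetic and residual covariance
matrices); the anchored variant holds the first trait's variance components
fixed at externally supplied values — the anchor-trait device used to guard
a selected sample against bias — and estimates only the covariances and the
second trait's components.

Estimation is restricted maximum likelihood with average-information (AI)
updates and an EM fallback whenever an AI step leaves the parameter space or
decreases the restricted log-likelihood.  Everything is dense linear
algebra: at a few hundred genotyped individuals that is both the simplest
and an entirely adequate strategy.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd
from scipy.linalg import cho_factor, cho_solve

from .grm import GRM

__all__ = [
    "ModelData",
    "VarianceComponents",
    "GEBV",
    "FitOptions",
    "make_model_data",
    "restricted_loglik",
    "fit_univariate",
    "fit_bivariate_anchored",
    "heritability",
    "heritability_report",
]


@dataclass
class ModelData:
    """Observations for one or two traits sharing a GRM.

    ``y[t]`` holds trait t's observation vector, ``X[t]`` its fixed-effect
    incidence (full column rank), and ``Z[t]`` the 0/1 incidence mapping
    observations to rows of G.
    """

    y: list[np.ndarray]
    X: list[np.ndarray]
    Z: list[np.ndarray]
    grm: GRM
    trait_names: list[str]

    def __post_init__(self) -> None:
        n_g = self.grm.matrix.shape[0]
        for t, (y, X, Z) in enumerate(zip(self.y, self.X, self.Z)):
            if np.isnan(y).any():
                raise ValueError(f"NaN in observations of trait {self.trait_names[t]}")
            if y.shape[0] != X.shape[0] or y.shape[0] != Z.shape[0]:
                raise ValueError("y, X, Z row counts disagree")
            if Z.shape[1] != n_g:
                raise ValueError("Z columns must match GRM dimension")
            if np.linalg.matrix_rank(X) < X.shape[1]:
                raise ValueError("X is rank deficient; check the group coding")


@dataclass
class FitOptions:
    max_iter: int = 200
    rel_tol: float = 1e-8
    grad_tol: float = 1e-6
    algorithm: str = "ai"  # "ai" (with EM fallback) or "em"
    verbose: bool = False


@dataclass
class VarianceComponents:
    sigma2_u: float | None = None
    sigma2_e: float | None = None
    H: np.ndarray | None = None
    R: np.ndarray | None = None
    se: dict[str, float] = field(default_factory=dict)
    h2: dict[str, float] = field(default_factory=dict)
    h2_se: dict[str, float] = field(default_factory=dict)
    genetic_corr: float | None = None
    genetic_corr_se: float | None = None
    loglik_trace: list[float] = field(default_factory=list)
    converged: bool = False
    n_iter: int = 0

    def to_frame(self) -> pd.DataFrame:
        rows = []
        if self.sigma2_u is not None:
            rows += [("sigma2_u", self.sigma2_u, self.se.get("sigma2_u", np.nan)),
                     ("sigma2_e", self.sigma2_e, self.se.get("sigma2_e", np.nan))]
        if self.H is not None:
            for (i, j), key in (((0, 0), "H11"), ((0, 1), "H12"), ((1, 1), "H22")):
                rows.append((key, self.H[i, j], self.se.get(key, np.nan)))
            for (i, j), key in (((0, 0), "R11"), ((0, 1), "R12"), ((1, 1), "R22")):
                rows.append((key, self.R[i, j], self.se.get(key, np.nan)))
        for t, v in self.h2.items():
            rows.append((f"h2[{t}]", v, self.h2_se.get(t, np.nan)))
        if self.genetic_corr is not None:
            rows.append(("genetic_corr", self.genetic_corr, self.genetic_corr_se or np.nan))
        return pd.DataFrame(rows, columns=["parameter", "estimate", "se"])


@dataclass
class GEBV:
    u_hat: pd.DataFrame  # index = G ids, one column per trait
    reliability: pd.DataFrame | None = None


def heritability(vg: float, ve: float) -> float:
    """h2 = vg / (vg + ve)."""
    if vg < 0 or ve < 0:
        raise ValueError("variance components must be non-negative")
    if vg + ve == 0:
        raise ValueError("vg + ve must be positive")
    return vg / (vg + ve)


def heritability_report(vg: float, ve: float) -> float:
    """h2 rounded half-up to 2 decimals, the usual reporting precision."""
    h = heritability(vg, ve)
    return float(Decimal(repr(h)).quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))


def make_model_data(
    phenotypes: pd.DataFrame,
    grm: GRM,
    traits: str | list[str],
    group_col: str = "group",
) -> ModelData:
    """Assemble ModelData from a phenotype table (id, group, trait columns).

    Fixed effects are an intercept plus drop-first contemporary-group
    contrasts (reference = first group by label sort).  Rows with a missing
    trait value are dropped for that trait only.
    """
    if isinstance(traits, str):
        traits = [traits]
    id_to_row = {iid: i for i, iid in enumerate(grm.individual_ids)}
    missing_ids = set(phenotypes["id"]) - set(id_to_row)
    if missing_ids:
        raise ValueError(f"phenotyped individuals absent from the GRM: {sorted(missing_ids)[:5]}")
    groups = sorted(phenotypes[group_col].astype(str).unique())
    ys, Xs, Zs = [], [], []
    for trait in traits:
        if trait not in phenotypes.columns:
            raise ValueError(f"unknown trait {trait!r}")
        sub = phenotypes.loc[phenotypes[trait].notna(), ["id", group_col, trait]]
        y = sub[trait].to_numpy(dtype=float)
        dummies = pd.get_dummies(
            pd.Categorical(sub[group_col].astype(str), categories=groups), drop_first=True
        ).to_numpy(dtype=float)
        X = np.column_stack([np.ones(len(sub)), dummies])
        # drop empty-group columns so X keeps full column rank
        X = X[:, (X != 0).any(axis=0)]
        Z = np.zeros((len(sub), grm.matrix.shape[0]))
        for r, iid in enumerate(sub["id"]):
            Z[r, id_to_row[iid]] = 1.0
        ys.append(y)
        Xs.append(X)
        Zs.append(Z)
    return ModelData(y=ys, X=Xs, Z=Zs, grm=grm, trait_names=list(traits))


# ---------------------------------------------------------------------------
# Dense REML machinery


def _reml_core(V: np.ndarray, X: np.ndarray, y: np.ndarray):
    """Factor V and return the pieces every REML quantity needs."""
    cho = cho_factor(V, lower=True)
    logdetV = 2.0 * np.sum(np.log(np.diag(cho[0])))
    Vinv = cho_solve(cho, np.eye(V.shape[0]))
    B = Vinv @ X  # V^-1 X
    C = X.T @ B  # X' V^-1 X
    sign, logdetC = np.linalg.slogdet(C)
    if sign <= 0:
        raise np.linalg.LinAlgError("X'V^-1X not positive definite")
    Cinv = np.linalg.inv(C)
    Vinv_y = Vinv @ y
    beta = Cinv @ (X.T @ Vinv_y)
    Py = Vinv_y - B @ beta
    ll = -0.5 * (logdetV + logdetC + float(y @ Py))
    return {"Vinv": Vinv, "B": B, "Cinv": Cinv, "Py": Py, "ll": ll, "beta": beta}


def _apply_P(v: np.ndarray, core) -> np.ndarray:
    return core["Vinv"] @ v - core["B"] @ (core["Cinv"] @ (core["B"].T @ v))


def _grad_and_ai(core, dVs: list[np.ndarray], y: np.ndarray):
    """REML score vector and average-information matrix for the given
    derivative structures dV_k = dV/dtheta_k."""
    Py = core["Py"]
    k = len(dVs)
    grad = np.empty(k)
    T = [dV @ Py for dV in dVs]
    for i, dV in enumerate(dVs):
        tr_P_dV = float(np.sum(core["Vinv"] * dV)) - float(
            np.sum(core["Cinv"] * (core["B"].T @ dV @ core["B"]))
        )
        grad[i] = -0.5 * (tr_P_dV - float(Py @ T[i]))
    AI = np.empty((k, k))
    PT = [_apply_P(t, core) for t in T]
    for i in range(k):
        for j in range(i, k):
            AI[i, j] = AI[j, i] = 0.5 * float(T[i] @ PT[j])
    return grad, AI


def restricted_loglik(theta, data: ModelData, trait: int = 0) -> float:
    """Restricted log-likelihood, up to a theta-independent constant.

    ``theta`` is ``(sigma2_u, sigma2_e)`` for a univariate model, or
    ``(H, R)`` with 2x2 covariance matrices for the bivariate model.
    Evaluates -1/2 [log|V| + log|X'V^-1 X| + y'Py].
    """
    if isinstance(theta, (tuple, list)) and np.ndim(theta[0]) == 2:
        H, R = np.asarray(theta[0], float), np.asarray(theta[1], float)
        y, X, V = _stack_bivariate(data, H, R)
        return _reml_core(V, X, y)["ll"]
    s2u, s2e = float(theta[0]), float(theta[1])
    y, X, Z = data.y[trait], data.X[trait], data.Z[trait]
    ZGZ = Z @ data.grm.matrix @ Z.T
    V = s2u * ZGZ + s2e * np.eye(len(y))
    return _reml_core(V, X, y)["ll"]


# ---------------------------------------------------------------------------
# Univariate fit


def fit_univariate(
    data: ModelData, opts: FitOptions | None = None, trait: int = 0
) -> tuple[VarianceComponents, GEBV]:
    """AI-REML fit of the single-trait GBLUP model.

    Starting values sigma2_u = sigma2_e = Var(y)/2; AI updates with an EM
    fallback (Harville's monotone update) whenever the AI step is infeasible
    or decreases the restricted log-likelihood; components clamped at
    1e-10 * Var(y).  With ``algorithm="em"`` every step is an EM step, which
    never decreases the likelihood.  Standard errors come from the inverse
    AI (observed information) matrix; the h2 SE by the delta method.
    """
    opts = opts or FitOptions()
    y, X, Z = data.y[trait], data.X[trait], data.Z[trait]
    n = len(y)
    if n < 2:
        raise ValueError("need at least 2 observations")
    vary = float(np.var(y, ddof=1))
    if vary == 0:
        raise ValueError("Var(y) is zero")
    floor = 1e-10 * vary
    ZGZ = Z @ data.grm.matrix @ Z.T
    I = np.eye(n)
    dVs = [ZGZ, I]
    q = [data.grm.matrix.shape[0], n]  # EM divisors: dim(u), n_obs

    theta = np.array([vary / 2.0, vary / 2.0])
    trace: list[float] = []
    core = _reml_core(theta[0] * ZGZ + theta[1] * I, X, y)
    converged = False
    it = 0
    for it in range(1, opts.max_iter + 1):
        trace.append(core["ll"])
        grad, AI = _grad_and_ai(core, dVs, y)
        # KKT: a component clamped at the floor whose gradient points further
        # down is at its constrained optimum — exclude it from the step and
        # the convergence check
        at_floor = theta <= floor * 1.001
        free = ~(at_floor & (grad < 0.0))
        if np.linalg.norm(grad[free]) < opts.grad_tol:
            converged = True
            break

        def em_step() -> np.ndarray:
            new = theta + 2.0 * theta**2 / np.asarray(q) * grad
            return np.maximum(new, floor)

        if opts.algorithm == "em":
            new = em_step()
        else:
            def try_step(base: np.ndarray, idx: np.ndarray, delta: np.ndarray):
                for _ in range(6):  # AI step with halving, clamped at the floor
                    cand_theta = base.copy()
                    cand_theta[idx] = base[idx] + delta
                    cand_theta = np.maximum(cand_theta, floor)
                    cand = _reml_core(cand_theta[0] * ZGZ + cand_theta[1] * I, X, y)
                    if cand["ll"] >= core["ll"] - 1e-10:
                        return cand_theta
                    delta = delta / 2.0
                return None

            try:
                idx = np.flatnonzero(free)
                delta = np.linalg.solve(AI[np.ix_(idx, idx)], grad[idx])
                new = try_step(theta, idx, delta)
                if new is None:
                    # active set: pin components the AI step drives below
                    # zero at the floor and re-solve for the remainder —
                    # without this, boundary optima are approached by a
                    # geometrically slowing EM crawl
                    pinned = np.zeros_like(free)
                    pinned[idx] = theta[idx] + delta < floor
                    idx2 = np.flatnonzero(free & ~pinned)
                    if pinned.any() and idx2.size:
                        base = theta.copy()
                        base[pinned] = floor
                        delta2 = np.linalg.solve(AI[np.ix_(idx2, idx2)], grad[idx2])
                        new = try_step(base, idx2, delta2)
                if new is None:
                    new = em_step()
            except np.linalg.LinAlgError:
                new = em_step()
        new_core = _reml_core(new[0] * ZGZ + new[1] * I, X, y)
        rel = np.max(np.abs(new - theta) / np.maximum(theta, floor))
        theta, core = new, new_core
        if rel < opts.rel_tol:
            converged = True
            trace.append(core["ll"])
            break
    if not converged:
        raise RuntimeError(
            f"AI-REML did not converge in {opts.max_iter} iterations; "
            f"loglik trace tail: {trace[-5:]}"
        )

    grad, AI = _grad_and_ai(core, dVs, y)
    try:
        AIinv = np.linalg.inv(AI)
        se = np.sqrt(np.maximum(np.diag(AIinv), 0.0))
    except np.linalg.LinAlgError:
        AIinv = np.full((2, 2), np.nan)
        se = np.array([np.nan, np.nan])
    s2u, s2e = float(theta[0]), float(theta[1])
    h2 = heritability(s2u, s2e)
    d = np.array([s2e, -s2u]) / (s2u + s2e) ** 2
    h2_se = float(np.sqrt(max(d @ AIinv @ d, 0.0))) if np.isfinite(AIinv).all() else np.nan

    G = data.grm.matrix
    GZt_Py = G @ (Z.T @ core["Py"])
    u_hat = s2u * GZt_Py
    # reliability: 1 - PEV_i / (s2u * G_ii)
    ZG = Z @ G
    PZG = core["Vinv"] @ ZG - core["B"] @ (core["Cinv"] @ (core["B"].T @ ZG))
    pev = s2u * np.diag(G) - s2u**2 * np.einsum("ij,ij->j", ZG, PZG)
    with np.errstate(divide="ignore", invalid="ignore"):
        rel = 1.0 - pev / (s2u * np.diag(G))
    name = data.trait_names[trait]
    vc = VarianceComponents(
        sigma2_u=s2u,
        sigma2_e=s2e,
        se={"sigma2_u": float(se[0]), "sigma2_e": float(se[1])},
        h2={name: h2},
        h2_se={name: h2_se},
        loglik_trace=trace,
        converged=converged,
        n_iter=it,
    )
    gebv = GEBV(
        u_hat=pd.DataFrame({name: u_hat}, index=data.grm.individual_ids),
        reliability=pd.DataFrame({name: rel}, index=data.grm.individual_ids),
    )
    return vc, gebv


# ---------------------------------------------------------------------------
# Anchored bivariate fit


def _stack_bivariate(data: ModelData, H: np.ndarray, R: np.ndarray):
    if len(data.y) != 2:
        raise ValueError("bivariate model needs exactly 2 traits")
    y1, y2 = data.y
    X1, X2 = data.X
    Z1, Z2 = data.Z
    G = data.grm.matrix
    G11, G12, G22 = Z1 @ G @ Z1.T, Z1 @ G @ Z2.T, Z2 @ G @ Z2.T
    S = Z1 @ Z2.T  # shared-individual indicator
    n1, n2 = len(y1), len(y2)
    V = np.block(
        [
            [H[0, 0] * G11 + R[0, 0] * np.eye(n1), H[0, 1] * G12 + R[0, 1] * S],
            [(H[0, 1] * G12 + R[0, 1] * S).T, H[1, 1] * G22 + R[1, 1] * np.eye(n2)],
        ]
    )
    X = np.block(
        [[X1, np.zeros((n1, X2.shape[1]))], [np.zeros((n2, X1.shape[1])), X2]]
    )
    return np.concatenate([y1, y2]), X, V


def fit_bivariate_anchored(
    data: ModelData,
    anchor_components: tuple[float, float],
    opts: FitOptions | None = None,
) -> tuple[VarianceComponents, GEBV]:
    """Bivariate GBLUP with the first trait's components held fixed.

    ``anchor_components = (sigma2_u1, sigma2_e1)`` are frozen (typically the
    univariate estimates for the anchor trait); the free parameters are the
    genetic and residual covariances and the second trait's components,
    estimated by constrained AI-REML with the 2x2 H and R kept positive
    semi-definite.  When an AI step is infeasible or would lower the
    restricted log-likelihood the step is halved (down to a scaled-gradient
    direction), so the likelihood trace is non-decreasing.
    """
    opts = opts or FitOptions()
    h11, r11 = map(float, anchor_components)
    if h11 <= 0 or r11 <= 0:
        raise ValueError("anchor components must be positive")
    y1, y2 = data.y
    X1, X2 = data.X
    Z1, Z2 = data.Z
    G = data.grm.matrix
    n1, n2 = len(y1), len(y2)
    vary2 = float(np.var(y2, ddof=1))
    floor = 1e-10 * vary2
    slack = 1e-8

    G11, G12, G22 = Z1 @ G @ Z1.T, Z1 @ G @ Z2.T, Z2 @ G @ Z2.T
    S = Z1 @ Z2.T
    Zb1 = np.zeros((n1, n1))
    Zb2 = np.zeros((n2, n2))
    # derivative structures for theta = (h12, h22, r12, r22)
    dVs = [
        np.block([[Zb1, G12], [G12.T, Zb2]]),
        np.block([[Zb1, np.zeros((n1, n2))], [np.zeros((n2, n1)), G22]]),
        np.block([[Zb1, S], [S.T, Zb2]]),
        np.block([[Zb1, np.zeros((n1, n2))], [np.zeros((n2, n1)), np.eye(n2)]]),
    ]

    def hr(theta):
        h12, h22, r12, r22 = theta
        H = np.array([[h11, h12], [h12, h22]])
        R = np.array([[r11, r12], [r12, r22]])
        return H, R

    def clip_feasible(theta: np.ndarray) -> np.ndarray:
        """Project a proposal onto the feasible region: variance floors and
        PSD bounds on the covariances.  Clipping (rather than rejecting)
        lets iterates slide along the PSD boundary when the optimum is a
        pegged correlation."""
        h12, h22, r12, r22 = theta
        h22 = max(h22, floor)
        r22 = max(r22, floor)
        hb = np.sqrt(h11 * h22 * (1.0 - slack))
        rb = np.sqrt(r11 * r22 * (1.0 - slack))
        return np.array([np.clip(h12, -hb, hb), h22, np.clip(r12, -rb, rb), r22])

    def core_at(theta):
        H, R = hr(theta)
        y, X, V = _stack_bivariate(data, H, R)
        return _reml_core(V, X, y), y

    theta = np.array([0.0, vary2 / 2.0, 0.0, vary2 / 2.0])
    core, ystack = core_at(theta)
    trace: list[float] = []
    converged = False
    it = 0
    for it in range(1, opts.max_iter + 1):
        trace.append(core["ll"])
        grad, AI = _grad_and_ai(core, dVs, ystack)
        if np.linalg.norm(grad) < opts.grad_tol:
            converged = True
            break
        try:
            step = np.linalg.solve(AI, grad)
        except np.linalg.LinAlgError:
            step = grad / np.maximum(np.abs(np.diag(AI)), 1e-12)
        accepted = False
        for directions in (step, grad / np.maximum(np.abs(np.diag(AI)), 1e-12)):
            s = directions
            for _ in range(30):  # step halving, proposals clipped feasible
                new = clip_feasible(theta + s)
                cand, _ = core_at(new)
                if cand["ll"] >= core["ll"] - 1e-10:
                    accepted = True
                    break
                s = s / 2.0
            if accepted:
                break
        if not accepted:
            converged = True  # stuck at a (constrained) stationary point
            break
        rel = np.max(np.abs(new - theta) / np.maximum(np.abs(theta), floor))
        dll = cand["ll"] - core["ll"]
        theta, core = new, cand
        if rel < opts.rel_tol or dll < 1e-9 * (1.0 + abs(cand["ll"])):
            # parameter change or likelihood gain below tolerance: either a
            # converged interior point or a constrained boundary optimum
            converged = True
            trace.append(core["ll"])
            break
    if not converged:
        raise RuntimeError(
            f"anchored bivariate AI-REML did not converge in {opts.max_iter} iterations; "
            f"loglik trace tail: {trace[-5:]}"
        )

    grad, AI = _grad_and_ai(core, dVs, ystack)
    try:
        AIinv = np.linalg.inv(AI)
        se_vec = np.sqrt(np.maximum(np.diag(AIinv), 0.0))
    except np.linalg.LinAlgError:
        AIinv = np.full((4, 4), np.nan)
        se_vec = np.full(4, np.nan)
    H, R = hr(theta)
    h12, h22, r12, r22 = theta
    name1, name2 = data.trait_names
    h2_2 = heritability(h22, r22)
    # delta method for h2 of trait 2 over free params (h12, h22, r12, r22)
    d = np.array([0.0, r22 / (h22 + r22) ** 2, 0.0, -h22 / (h22 + r22) ** 2])
    h2_se = float(np.sqrt(max(d @ AIinv @ d, 0.0))) if np.isfinite(AIinv).all() else np.nan
    rg = h12 / np.sqrt(h11 * h22) if h22 > 0 else np.nan
    # delta method for rg = h12 / sqrt(h11 h22)
    if h22 > 0 and np.isfinite(AIinv).all():
        drg = np.array([1.0 / np.sqrt(h11 * h22), -0.5 * h12 / (np.sqrt(h11) * h22**1.5), 0.0, 0.0])
        rg_se = float(np.sqrt(max(drg @ AIinv @ drg, 0.0)))
    else:
        rg_se = np.nan

    Py = core["Py"]
    Py1, Py2 = Py[:n1], Py[n1:]
    u1 = H[0, 0] * (G @ (Z1.T @ Py1)) + H[0, 1] * (G @ (Z2.T @ Py2))
    u2 = H[0, 1] * (G @ (Z1.T @ Py1)) + H[1, 1] * (G @ (Z2.T @ Py2))
    vc = VarianceComponents(
        H=H,
        R=R,
        se={"H12": float(se_vec[0]), "H22": float(se_vec[1]),
            "R12": float(se_vec[2]), "R22": float(se_vec[3])},
        h2={name1: heritability(h11, r11), name2: h2_2},
        h2_se={name2: h2_se},
        genetic_corr=float(rg),
        genetic_corr_se=rg_se,
        loglik_trace=trace,
        converged=converged,
        n_iter=it,
    )
    gebv = GEBV(
        u_hat=pd.DataFrame({name1: u1, name2: u2}, index=data.grm.individual_ids)
    )
    return vc, gebv
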