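"""EM-REML variance components for the repeatability litter model.

Estimates (sigma2_a, sigma2_p, sigma2_l, sigma2_e) — additive genetic,
permanent environment, common birth litter and residual variances — together
with their ratios to the phenotypic variance (h2, p2, l2, e2).

The EM updates are the classical MME-based ones: with C the coefficient
matrix of the mixed-model equations on the variance-ratio scale and
u_t the solution block of random term t (q_t levels, B_t = I or A),

    sigma2_t+ = (u_t' B_t^{-1} u_t + sigma2_e * tr(B_t^{-1} C^{tt})) / q_t
    sigma2_e+ = (y'y - theta' W'y) / (n - rank(X))

Each iteration does one dense Cholesky factorization and inversion of C;
the restricted log-likelihood

    -2 lR = (n-p) ln sigma2_e + sum_t q_t ln(sigma2_t/sigma2_e) + ln|A|
            + ln|C| + (y'y - theta' W'y)/sigma2_e

is tracked and is non-decreasing along EM steps (a property the test suite
asserts).  This targets desk-scale systems (a few thousand equations); the
dimension is capped rather than silently degrading.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.linalg.lapack import dpotrf, dpotri

from .design import DesignMatrices

__all__ = ["VarianceComponents", "RemlTrace", "em_reml", "ratios"]

#: hard floor for variance components (boundary flag raised when hit)
COMPONENT_FLOOR = 1e-8

#: snap-to-floor threshold as a fraction of the phenotypic variance; EM decay
#: toward a zero component is sublinear, so components this small are treated
#: as boundary estimates rather than ground out over thousands of iterations
BOUNDARY_FRACTION = 1e-3

MAX_EQUATIONS = 6000


@dataclass
class VarianceComponents:
    """Variance components on the phenotypic (squared-piglet) scale."""

    sigma2_a: float
    sigma2_p: float = 0.0
    sigma2_l: float = 0.0
    sigma2_e: float = 0.0

    def __post_init__(self):
        for name in ("sigma2_a", "sigma2_p", "sigma2_l", "sigma2_e"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")

    @property
    def phenotypic(self) -> float:
        return self.sigma2_a + self.sigma2_p + self.sigma2_l + self.sigma2_e

    @property
    def h2(self) -> float:
        return self.sigma2_a / self.phenotypic

    @property
    def p2(self) -> float:
        return self.sigma2_p / self.phenotypic

    @property
    def l2(self) -> float:
        return self.sigma2_l / self.phenotypic

    @property
    def e2(self) -> float:
        return self.sigma2_e / self.phenotypic

    def as_dict(self) -> dict[str, float]:
        return {
            "var_a": self.sigma2_a, "var_p": self.sigma2_p,
            "var_l": self.sigma2_l, "var_e": self.sigma2_e,
            "var_ph": self.phenotypic,
            "h2": self.h2, "p2": self.p2, "l2": self.l2, "e2": self.e2,
        }

    def report(self) -> pd.DataFrame:
        """One-row table mirroring the usual Var(a)..e2 report layout."""
        return pd.DataFrame([self.as_dict()])


def ratios(vc: VarianceComponents) -> dict[str, float]:
    """Component-to-phenotypic ratios (h2, p2, l2, e2)."""
    if vc.phenotypic <= 0:
        raise ValueError("phenotypic variance must be positive")
    return {"h2": vc.h2, "p2": vc.p2, "l2": vc.l2, "e2": vc.e2}


@dataclass
class RemlTrace:
    history: pd.DataFrame
    converged: bool
    n_iter: int
    boundary: dict[str, bool] = field(default_factory=dict)

    @property
    def loglik(self) -> np.ndarray:
        return self.history["loglik"].to_numpy()


def _dense_chol_inverse(C: np.ndarray) -> tuple[np.ndarray, float, np.ndarray]:
    """(solve-factor, log|C|, full inverse) via LAPACK Cholesky."""
    U, info = dpotrf(C, lower=0, overwrite_a=0)
    if info != 0:
        raise np.linalg.LinAlgError(
            f"coefficient matrix not positive definite (dpotrf info={info}); "
            "likely confounded fixed effects"
        )
    logdet = 2.0 * float(np.sum(np.log(np.diag(U))))
    Uinv, info = dpotri(U, lower=0, overwrite_c=0)
    if info != 0:
        raise np.linalg.LinAlgError(f"dpotri failed (info={info})")
    Cinv = np.triu(Uinv) + np.triu(Uinv, k=1).T
    return U, logdet, Cinv


def em_reml(dm: DesignMatrices, y: np.ndarray, A_inv: sp.spmatrix,
            init: VarianceComponents | None = None, tol: float = 1e-6,
            max_iter: int = 500, *, random_terms: tuple[str, ...] = ("litter", "perm", "animal"),
            log_det_A: float = 0.0, accelerate: bool = True,
            callback=None) -> tuple[VarianceComponents, RemlTrace]:
    """Estimate variance components by EM-REML on the mixed-model equations.

    Parameters
    ----------
    dm, y:
        Design matrices and response from the design module.
    A_inv:
        Sparse inverse numerator relationship matrix matching ``dm.Za``.
    init:
        Starting values; defaults to 10/10/5/75 % of the raw variance of y.
    tol:
        Relative-change stopping criterion on all components.
    random_terms:
        Subset of ("litter", "perm", "animal") to include; "animal" is
        mandatory.
    log_det_A:
        log|A| (sum of log Mendelian-sampling variances); only shifts the
        reported restricted log-likelihood by a constant.
    accelerate:
        after every three consecutive plain EM steps, try a log-space Aitken
        extrapolation of the trajectory; the jump is kept only if its
        restricted likelihood at least matches the recent per-step progress,
        so the recorded likelihood stays monotone.  ``max_iter`` counts
        likelihood evaluations either way.
    """
    y = np.asarray(y, dtype=float)
    n = y.size
    if "animal" not in random_terms:
        raise ValueError("the additive-genetic term is mandatory")

    vary = float(np.var(y, ddof=1))
    if init is None:
        init = VarianceComponents(
            sigma2_a=0.10 * vary,
            sigma2_p=0.10 * vary if "perm" in random_terms else 0.0,
            sigma2_l=0.05 * vary if "litter" in random_terms else 0.0,
            sigma2_e=0.75 * vary,
        )
    comp = {"litter": init.sigma2_l, "perm": init.sigma2_p, "animal": init.sigma2_a}
    for t in random_terms:
        if comp[t] <= 0:
            raise ValueError(f"init variance for '{t}' must be strictly positive")
    se = init.sigma2_e
    if se <= 0:
        raise ValueError("init residual variance must be strictly positive")

    blocks = [("fixed", dm.X)]
    if "litter" in random_terms:
        blocks.append(("litter", dm.Zl))
    if "perm" in random_terms:
        blocks.append(("perm", dm.Zp))
    blocks.append(("animal", dm.Za))
    W = sp.hstack([m for _, m in blocks], format="csr")
    n_eq = W.shape[1]
    if n_eq > MAX_EQUATIONS:
        raise ValueError(f"{n_eq} equations exceed the EM-REML cap {MAX_EQUATIONS}")

    slices: dict[str, slice] = {}
    col = 0
    for name, m in blocks:
        slices[name] = slice(col, col + m.shape[1])
        col += m.shape[1]
    px = dm.X.shape[1]
    if n - px <= 0:
        raise ValueError("fewer records than fixed-effect columns")

    WtW = (W.T @ W).toarray()
    Wty = W.T @ y
    yty = float(y @ y)
    Acoo = A_inv.tocoo()
    a_off = slices["animal"].start
    a_rows = Acoo.row + a_off
    a_cols = Acoo.col + a_off
    a_vals = Acoo.data
    A_inv_csr = A_inv.tocsr()

    q = {t: slices[t].stop - slices[t].start for t in random_terms}
    hist: list[dict[str, float]] = []
    frozen: dict[str, bool] = {t: False for t in random_terms}
    order = list(random_terms) + ["e"]

    def em_step(comp: dict[str, float], se: float):
        """Restricted log-likelihood at (comp, se) and the EM update."""
        C = WtW.copy()
        lam = {t: se / comp[t] for t in random_terms}
        for t in ("litter", "perm"):
            if t in random_terms:
                idx = np.arange(slices[t].start, slices[t].stop)
                C[idx, idx] += lam[t]
        C[a_rows, a_cols] += lam["animal"] * a_vals

        _, logdetC, Cinv = _dense_chol_inverse(C)
        theta = Cinv @ Wty
        ypy = yty - float(theta @ Wty)
        m2ll = (
            (n - px) * np.log(se)
            + sum(q[t] * np.log(comp[t] / se) for t in random_terms)
            + log_det_A + logdetC + ypy / se
        )
        new = dict(comp)
        for t in random_terms:
            if frozen[t]:
                continue
            sl = slices[t]
            u = theta[sl]
            if t == "animal":
                quad = float(u @ (A_inv_csr @ u))
                tr = float(A_inv_csr.multiply(Cinv[sl, sl]).sum())
            else:
                quad = float(u @ u)
                tr = float(np.trace(Cinv[sl, sl]))
            new[t] = (quad + se * tr) / q[t]
        return -0.5 * m2ll, new, ypy / (n - px)

    def as_vec(comp, se):
        return np.array([comp[t] for t in random_terms] + [se])

    def aitken(v1, v2, v3):
        """Component-wise log-space Aitken extrapolation of three iterates.

        Only components on a stable geometric path (consistent step sign,
        contraction ratio in (0.2, 0.995)) are extrapolated; capped at
        e^3-fold moves so a bad jump cannot leave the basin.
        """
        l1, l2, l3 = np.log(v1), np.log(v2), np.log(v3)
        d1, d2 = l2 - l1, l3 - l2
        with np.errstate(divide="ignore", invalid="ignore"):
            r = np.where(np.abs(d1) > 1e-14, d2 / d1, 0.0)
        stable = (d1 * d2 > 0) & (r > 0.2) & (r < 0.9995)
        r = np.where(stable, r, 0.0)
        jump = np.clip(r / (1.0 - r) * d2, -3.0, 3.0)
        return np.exp(l3 + jump)

    converged = False
    last_ll = -np.inf
    prev_gain = 0.0
    plain_run: list[np.ndarray] = []  # consecutive plain-EM iterates
    it = 0
    n_steps = 0
    while n_steps < max_iter:
        it += 1
        took_accel = False
        if accelerate and len(plain_run) >= 3 and not any(frozen.values()):
            cand = aitken(*plain_run[-3:])
            cand = np.maximum(cand, COMPONENT_FLOOR)
            comp_c = {t: float(cand[i]) for i, t in enumerate(random_terms)}
            se_c = float(cand[-1])
            ll_c, new_c, se_new_c = em_step(comp_c, se_c)
            n_steps += 1
            # the jump must at least match the recent plain-step progress,
            # otherwise it only stalls the trajectory
            if ll_c >= last_ll + 0.5 * prev_gain:
                comp, se = comp_c, se_c
                loglik, new, se_new = ll_c, new_c, se_new_c
                took_accel = True
                plain_run = []
        if not took_accel:
            loglik, new, se_new = em_step(comp, se)
            n_steps += 1

        pheno = se_new + sum(new.values())
        for t in random_terms:
            if not frozen[t] and new[t] < BOUNDARY_FRACTION * pheno:
                new[t] = COMPONENT_FLOOR
                frozen[t] = True

        denom = max(pheno, 1e-300)
        rel = max(
            max(abs(new[t] - comp[t]) / max(comp[t], tol * denom) for t in random_terms),
            abs(se_new - se) / max(se, tol * denom),
        )
        prev_gain = max(loglik - last_ll, 0.0) if np.isfinite(last_ll) else 0.0
        last_ll = loglik
        comp, se = new, se_new
        if not took_accel:
            plain_run.append(as_vec(comp, se))
        hist.append({
            "iter": it, "sigma2_l": comp.get("litter", 0.0),
            "sigma2_p": comp.get("perm", 0.0), "sigma2_a": comp["animal"],
            "sigma2_e": se, "loglik": loglik, "rel_change": rel,
        })
        if callback is not None:
            callback(it, comp, se, loglik)
        if rel < tol:
            converged = True
            break

    vc = VarianceComponents(
        sigma2_a=comp["animal"],
        sigma2_p=comp.get("perm", 0.0),
        sigma2_l=comp.get("litter", 0.0),
        sigma2_e=se,
    )
    trace = RemlTrace(
        history=pd.DataFrame(hist), converged=converged, n_iter=it,
        boundary={t: bool(frozen[t]) for t in random_terms},
    )
    return vc, trace


def reml_loglik_dense(dm: DesignMatrices, y: np.ndarray, A: np.ndarray,
                      vc: VarianceComponents,
                      random_terms: tuple[str, ...] = ("litter", "perm", "animal"),
                      ) -> float:
    """Brute-force restricted log-likelihood via the record-level covariance.

    Independent oracle: V = sum_t Z_t B_t Z_t' sigma2_t + I sigma2_e,
    -2 lR = ln|V| + ln|X'V^{-1}X| + y' P y, computed densely.  Only for
    small instances.
    """
    y = np.asarray(y, dtype=float)
    n = y.size
    V = np.eye(n) * vc.sigma2_e
    if "litter" in random_terms and vc.sigma2_l > 0:
        Zl = dm.Zl.toarray()
        V += vc.sigma2_l * Zl @ Zl.T
    if "perm" in random_terms and vc.sigma2_p > 0:
        Zp = dm.Zp.toarray()
        V += vc.sigma2_p * Zp @ Zp.T
    Za = dm.Za.toarray()
    V += vc.sigma2_a * Za @ A @ Za.T
    X = dm.X.toarray()
    Vinv = np.linalg.inv(V)
    XtVinvX = X.T @ Vinv @ X
    b = np.linalg.solve(XtVinvX, X.T @ Vinv @ y)
    r = y - X @ b
    ypy = float(r @ Vinv @ y)
    sign1, logdetV = np.linalg.slogdet(V)
    sign2, logdetX = np.linalg.slogdet(XtVinvX)
    if sign1 <= 0 or sign2 <= 0:
        raise np.linalg.LinAlgError("V or X'V^-1X not positive definite")
    return -0.5 * (logdetV + logdetX + ypy)
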