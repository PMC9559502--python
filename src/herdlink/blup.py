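"""Mixed-model equations: assembly, direct solving, PEV and reliability.

The coefficient matrix is

    [ X'X    X'Zl              X'Zp              X'Za               ]
    [ Zl'X   Zl'Zl + I*ke_l    Zl'Zp             Zl'Za              ]
    [ Zp'X   Zp'Zl             Zp'Zp + I*ke_p    Zp'Za              ]
    [ Za'X   Za'Zl             Za'Zp             Za'Za + Ainv*ke_a  ]

with ke_t = sigma2_e / sigma2_t, and right-hand side W'y.  Systems at desk
scale are solved by direct sparse factorization; prediction-error variances
come from the animal-block diagonal of the inverse coefficient matrix:

    pev_i = sigma2_e * C^{-1}[i, i],    reliability_i = 1 - pev_i / sigma2_a
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .design import DesignMatrices
from .varcomp import VarianceComponents

__all__ = [
    "MixedModelSystem",
    "EvaluationResult",
    "assemble_mme",
    "solve_mme",
    "compute_pev_reliability",
    "summarize_reliability",
]

#: above this dimension the inverse diagonal is computed by chunked solves
DENSE_INVERSE_CAP = 4000


@dataclass
class MixedModelSystem:
    lhs: sp.csr_matrix
    rhs: np.ndarray
    index_map: dict[str, tuple[int, int, list[str]]]
    variance_ratios: dict[str, float]
    sigma2_e: float
    sigma2_a: float
    dm: DesignMatrices = field(repr=False)
    _lu: object | None = field(default=None, repr=False)

    @property
    def n_equations(self) -> int:
        return self.lhs.shape[0]

    def block(self, name: str) -> slice:
        lo, hi, _ = self.index_map[name]
        return slice(lo, hi)

    def factorize(self):
        if self._lu is None:
            self._lu = spla.splu(self.lhs.tocsc())
        return self._lu

    def inverse_diagonal(self, idx: np.ndarray) -> np.ndarray:
        """Selected diagonal entries of the inverse coefficient matrix."""
        n = self.n_equations
        if n <= DENSE_INVERSE_CAP:
            Cinv = np.linalg.inv(self.lhs.toarray())
            return np.diag(Cinv)[idx].copy()
        lu = self.factorize()
        out = np.empty(idx.size)
        chunk = max(1, int(2e8 / (8 * n)))  # ~200 MB of RHS columns at a time
        for lo in range(0, idx.size, chunk):
            sel = idx[lo: lo + chunk]
            E = np.zeros((n, sel.size))
            E[sel, np.arange(sel.size)] = 1.0
            cols = lu.solve(E)
            out[lo: lo + chunk] = cols[sel, np.arange(sel.size)]
        return out

    def inverse_block(self, idx: np.ndarray) -> np.ndarray:
        """Dense sub-block of the inverse over the given equation indices."""
        n = self.n_equations
        if n <= DENSE_INVERSE_CAP:
            Cinv = np.linalg.inv(self.lhs.toarray())
            return Cinv[np.ix_(idx, idx)].copy()
        lu = self.factorize()
        E = np.zeros((n, idx.size))
        E[idx, np.arange(idx.size)] = 1.0
        cols = lu.solve(E)
        return cols[idx, :].copy()


@dataclass
class EvaluationResult:
    fixed_solutions: pd.Series
    litter_solutions: pd.Series
    perm_solutions: pd.Series
    ebv: pd.Series  # indexed by animal id
    pev: pd.Series | None = None
    reliability: pd.Series | None = None


def assemble_mme(dm: DesignMatrices, y: np.ndarray, A_inv: sp.spmatrix,
                 vc: VarianceComponents) -> MixedModelSystem:
    """Build the sparse symmetric coefficient matrix and right-hand side.

    Random terms with (near-)zero variance are dropped from the system with
    a warning, mirroring analyses where e.g. the common-litter variance hits
    the boundary.
    """
    y = np.asarray(y, dtype=float)
    if y.size != dm.n_records:
        raise ValueError("response length does not match design matrices")
    if A_inv.shape[0] != dm.Za.shape[1]:
        raise ValueError("A_inv dimension does not match the pedigree")
    if vc.sigma2_e <= 0 or vc.sigma2_a <= 0:
        raise ValueError("residual and additive variances must be positive")

    parts: list[tuple[str, sp.spmatrix, sp.spmatrix | None]] = [
        ("fixed", dm.X, None)]
    eps = 1e-12
    if vc.sigma2_l > eps:
        parts.append(("litter", dm.Zl,
                      sp.identity(dm.Zl.shape[1]) * (vc.sigma2_e / vc.sigma2_l)))
    else:
        warnings.warn("sigma2_l ~ 0: common-litter term dropped from MME", stacklevel=2)
    if vc.sigma2_p > eps:
        parts.append(("perm", dm.Zp,
                      sp.identity(dm.Zp.shape[1]) * (vc.sigma2_e / vc.sigma2_p)))
    else:
        warnings.warn("sigma2_p ~ 0: permanent-environment term dropped", stacklevel=2)
    parts.append(("animal", dm.Za, A_inv * (vc.sigma2_e / vc.sigma2_a)))

    W = sp.hstack([m for _, m, _ in parts], format="csr")
    lhs = (W.T @ W).tolil()
    index_map: dict[str, tuple[int, int, list[str]]] = {}
    col = 0
    for name, m, aug in parts:
        hi = col + m.shape[1]
        if name == "fixed":
            labels = []
            for eff, (lo_e, hi_e, labs) in dm.column_map.items():
                labels += [f"{eff}:{l}" for l in labs]
        elif name == "litter":
            labels = [str(v) for v in dm.litter_ids]
        elif name == "perm":
            labels = [str(v) for v in dm.sow_ids]
        else:
            labels = [str(v) for v in dm.animal_ids]
        index_map[name] = (col, hi, labels)
        if aug is not None:
            lhs[col:hi, col:hi] = lhs[col:hi, col:hi] + aug
        col = hi
    # expose the herd equations directly for connectedness work
    if "herd" in dm.column_map:
        lo, hi, labels = dm.column_map["herd"]
        index_map["herd"] = (lo, hi, labels)

    rhs = W.T @ y
    ratios = {
        "litter": vc.sigma2_e / vc.sigma2_l if vc.sigma2_l > eps else np.inf,
        "perm": vc.sigma2_e / vc.sigma2_p if vc.sigma2_p > eps else np.inf,
        "animal": vc.sigma2_e / vc.sigma2_a,
    }
    return MixedModelSystem(
        lhs=lhs.tocsr(), rhs=rhs, index_map=index_map, variance_ratios=ratios,
        sigma2_e=vc.sigma2_e, sigma2_a=vc.sigma2_a, dm=dm,
    )


def solve_mme(sys: MixedModelSystem) -> EvaluationResult:
    """Solve the MME by direct sparse factorization."""
    lu = sys.factorize()
    theta = lu.solve(sys.rhs)
    if not np.all(np.isfinite(theta)):
        raise np.linalg.LinAlgError(
            "MME solve produced non-finite solutions: coefficient matrix is "
            "singular (confounded fixed effects?)"
        )

    def series(name: str) -> pd.Series:
        if name not in sys.index_map or name == "herd":
            return pd.Series(dtype=float)
        lo, hi, labels = sys.index_map[name]
        return pd.Series(theta[lo:hi], index=labels)

    lo, hi, labels = sys.index_map["animal"]
    ebv = pd.Series(theta[lo:hi], index=[int(x) for x in labels])
    return EvaluationResult(
        fixed_solutions=series("fixed"),
        litter_solutions=series("litter"),
        perm_solutions=series("perm"),
        ebv=ebv,
    )


def compute_pev_reliability(sys: MixedModelSystem,
                            res: EvaluationResult | None = None) -> EvaluationResult:
    """Fill PEV and reliability from the animal-block inverse diagonal."""
    if res is None:
        res = solve_mme(sys)
    lo, hi, labels = sys.index_map["animal"]
    diag = sys.inverse_diagonal(np.arange(lo, hi))
    pev = sys.sigma2_e * diag
    rel = 1.0 - pev / sys.sigma2_a
    clipped = np.clip(rel, 0.0, 1.0)
    if np.max(np.abs(clipped - rel)) > 1e-10:
        warnings.warn("reliability clipped to [0, 1] beyond numerical noise",
                      stacklevel=2)
    ids = [int(x) for x in labels]
    res.pev = pd.Series(pev, index=ids)
    res.reliability = pd.Series(clipped, index=ids)
    return res


def summarize_reliability(res: EvaluationResult, groups: pd.Series,
                          *, restrict_to: np.ndarray | None = None) -> pd.DataFrame:
    """Per-group and overall N / mean / SD / min / max of reliability.

    ``groups`` maps animal id -> herd (or contemporary-group) label.
    ``restrict_to`` optionally limits the summary to the given animal ids
    (e.g. sows with records).
    """
    if res.reliability is None:
        raise ValueError("reliability not computed; call compute_pev_reliability")
    rel = res.reliability
    if restrict_to is not None:
        rel = rel.loc[[int(a) for a in restrict_to if int(a) in rel.index]]
    groups = groups.reindex(rel.index)
    rows = []
    for label, vals in [*rel.groupby(groups), ("ALL", rel[groups.notna()])]:
        if len(vals) == 0:
            warnings.warn(f"group '{label}' empty; omitted", stacklevel=2)
            continue
        rows.append({
            "group": label,
            "N": int(len(vals)),
            "mean": float(vals.mean()),
            "sd": float(vals.std(ddof=1)) if len(vals) > 1 else 0.0,
            "min": float(vals.min()),
            "max": float(vals.max()),
        })
    return pd.DataFrame(rows)
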