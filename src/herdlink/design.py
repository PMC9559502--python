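"""Model frame and sparse design matrices for the repeatability litter model.

The observation model is

    y = X b + Zl l + Zp p + Za a + e

with fixed factors (parity, mating season as year-month, sow genotype, litter
sire, herd, weaning-to-conception class), an age-at-farrowing covariate
(linear + quadratic, centered, nested within parity), a previous-lactation
covariate, and random common-litter (l), permanent-environment (p) and
additive-genetic (a) terms.

Identifiability is handled in the coding, not by generalized inverses: every
fixed factor is reference-coded (first level dropped) *except* herd, which
keeps all its levels while the intercept is omitted — so the herd solutions
are directly comparable, which the connectedness rating requires.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.linalg as sla
import scipy.sparse as sp

from .pedigree import Pedigree

__all__ = [
    "ModelSpec",
    "ModelFrame",
    "DesignMatrices",
    "build_model_frame",
    "build_design_matrices",
    "assign_wci_class",
    "PHENOTYPE_COLUMNS",
    "WCI_NA",
]

PHENOTYPE_COLUMNS = [
    "sow", "parity", "year", "month", "genotype", "litter_sire", "herd",
    "age_days", "wci_days", "prev_lact_days", "birth_litter", "nba",
]

#: class label for records with no weaning-to-conception interval (parity 1)
WCI_NA = "na"

DEFAULT_WCI_BINS = (5, 20, 40)  # upper edges (days); above last edge -> "gt40"


@dataclass
class ModelSpec:
    """Which effects enter the model.

    ``fixed_factors`` are categorical; covariates are fixed regressions.
    ``nested_age`` adds per-parity centered linear and quadratic age terms;
    ``prev_lactation`` a single centered linear term (zero where not
    applicable).  ``include_herd`` keeps herd as a full-level factor without
    intercept (dropped automatically when only one herd is present).
    """

    fixed_factors: tuple[str, ...] = (
        "parity", "season", "genotype", "litter_sire", "wci_class",
    )
    include_herd: bool = True
    nested_age: bool = True
    prev_lactation: bool = True
    random_terms: tuple[str, ...] = ("litter", "perm", "animal")
    wci_bins: tuple[int, ...] = DEFAULT_WCI_BINS
    #: parities above this are lumped into one top level (keeps the nested
    #: age regressions estimable when high parities are sparse)
    max_parity_level: int = 8


@dataclass
class ModelFrame:
    """Encoded records: response, factor level codes and centered covariates."""

    y: np.ndarray
    factors: dict[str, pd.Categorical]
    covariates: dict[str, np.ndarray]
    sow: np.ndarray
    birth_litter: np.ndarray
    herd: np.ndarray
    spec: ModelSpec
    data: pd.DataFrame = field(repr=False)


@dataclass
class DesignMatrices:
    """Sparse X and incidence matrices, with a column map per effect."""

    X: sp.csr_matrix
    Zl: sp.csr_matrix
    Zp: sp.csr_matrix
    Za: sp.csr_matrix
    column_map: dict[str, tuple[int, int, list[str]]]  # effect -> (lo, hi, labels)
    litter_ids: np.ndarray
    sow_ids: np.ndarray
    animal_ids: np.ndarray
    herd_of_row: np.ndarray

    @property
    def n_records(self) -> int:
        return self.X.shape[0]


def assign_wci_class(wci_days: pd.Series, parity: pd.Series,
                     bins: tuple[int, ...] = DEFAULT_WCI_BINS) -> pd.Series:
    """Bin the weaning-to-conception interval; parity-1 records get WCI_NA."""
    edges = [-np.inf, *bins, np.inf]
    labels = []
    prev = 0
    for b in bins:
        labels.append(f"{prev}-{b}")
        prev = b + 1
    labels.append(f"gt{bins[-1]}")
    cls = pd.cut(wci_days.astype(float), bins=edges, labels=labels).astype(object)
    cls[parity.to_numpy() == 1] = WCI_NA
    cls[pd.isna(cls)] = WCI_NA
    return pd.Series(cls, index=wci_days.index, dtype=object)


def build_model_frame(phen: pd.DataFrame, spec: ModelSpec | None = None) -> ModelFrame:
    """Encode a phenotype table into factor levels and centered covariates.

    Factor levels are indexed lexicographically so the encoding is
    deterministic and independent of record order.  Covariates are centered
    on the mean of the analysed subset.
    """
    spec = spec or ModelSpec()
    df = phen.copy().reset_index(drop=True)
    missing = [c for c in ("sow", "parity", "herd", "birth_litter", "nba")
               if c not in df.columns]
    if missing:
        raise ValueError(f"phenotype table lacks column(s): {missing}")

    if "season" not in df.columns and {"year", "month"} <= set(df.columns):
        df["season"] = (
            df["year"].astype(int).astype(str) + "-"
            + df["month"].astype(int).astype(str).str.zfill(2)
        )
    if "wci_class" not in df.columns and "wci_days" in df.columns:
        df["wci_class"] = assign_wci_class(df["wci_days"], df["parity"], spec.wci_bins)

    if "parity" in df.columns:
        lumped = np.minimum(df["parity"].astype(int), spec.max_parity_level)
        df["parity_class"] = pd.Series(lumped, index=df.index).map("{:02d}".format)

    factors: dict[str, pd.Categorical] = {}
    for f in spec.fixed_factors:
        src = "parity_class" if f == "parity" else f
        if src not in df.columns:
            raise ValueError(f"model factor '{f}' not in phenotype table")
        levels = sorted(df[src].astype(str).unique())
        if f == "wci_class" and WCI_NA in levels:
            # make the not-applicable class the (dropped) reference level
            levels = [WCI_NA] + [x for x in levels if x != WCI_NA]
        factors[f] = pd.Categorical(df[src].astype(str), categories=levels)

    herd_levels = sorted(df["herd"].astype(str).unique())
    factors["herd"] = pd.Categorical(df["herd"].astype(str), categories=herd_levels)

    covariates: dict[str, np.ndarray] = {}
    if spec.nested_age:
        age = df["age_days"].to_numpy(dtype=float)
        if (age <= 0).any():
            raise ValueError("age_at_farrowing must be positive")
        # year scale keeps the quadratic term well conditioned
        covariates["age_c"] = (age - age.mean()) / 365.25
    if spec.prev_lactation:
        z = df["prev_lact_days"].to_numpy(dtype=float)
        applicable = df["parity"].to_numpy(dtype=int) > 1
        zc = np.zeros_like(z)
        if applicable.any():
            zc[applicable] = z[applicable] - z[applicable].mean()
        covariates["prev_lact_c"] = zc

    return ModelFrame(
        y=df["nba"].to_numpy(dtype=float),
        factors=factors,
        covariates=covariates,
        sow=df["sow"].to_numpy(dtype=np.int64),
        birth_litter=df["birth_litter"].to_numpy(),
        herd=df["herd"].astype(str).to_numpy(),
        spec=spec,
        data=df,
    )


def _factor_block(codes: np.ndarray, n_levels: int, drop_first: bool) -> sp.csr_matrix:
    n = codes.size
    if drop_first:
        keep = codes > 0
        mat = sp.csr_matrix(
            (np.ones(keep.sum()), (np.flatnonzero(keep), codes[keep] - 1)),
            shape=(n, n_levels - 1),
        )
    else:
        mat = sp.csr_matrix(
            (np.ones(n), (np.arange(n), codes)), shape=(n, n_levels)
        )
    return mat


def _drop_dependent_columns(X: sp.csr_matrix,
                            column_map: dict[str, tuple[int, int, list[str]]],
                            rtol: float = 1e-8):
    """Prune exactly collinear fixed-effect columns (rank-revealing).

    Strictly structured data can confound whole effects — e.g. under pure
    within-breed mating the sow-genotype dummy equals the sum of the
    same-breed sire dummies.  Dependent columns are dropped greedily with the
    intercept/herd block protected (processed first), so herd contrasts stay
    estimable for the connectedness rating.
    """
    p = X.shape[1]
    G = (X.T @ X).toarray()
    protected = [name for name in ("intercept", "herd") if name in column_map]
    order = []
    for name in protected:
        lo, hi, _ = column_map[name]
        order += list(range(lo, hi))
    order += [j for j in range(p) if j not in set(order)]

    L = np.zeros((p, p))
    kept: list[int] = []
    keep_mask = np.zeros(p, dtype=bool)
    for j in order:
        k = len(kept)
        gj = G[kept, j] if kept else np.empty(0)
        w = sla.solve_triangular(L[:k, :k], gj, lower=True) if k else gj
        r2 = G[j, j] - float(w @ w)
        if r2 > rtol * max(G[j, j], 1.0):
            L[k, :k] = w
            L[k, k] = np.sqrt(r2)
            kept.append(j)
            keep_mask[j] = True
    if keep_mask.all():
        return X, column_map

    labels_all: list[str] = []
    for eff, (lo, hi, labs) in column_map.items():
        labels_all += [f"{eff}:{l}" for l in labs]
    dropped = [labels_all[j] for j in range(p) if not keep_mask[j]]
    warnings.warn(
        f"dropping {len(dropped)} confounded fixed-effect column(s): "
        f"{dropped[:8]}", stacklevel=3)
    new_map: dict[str, tuple[int, int, list[str]]] = {}
    col = 0
    for eff, (lo, hi, labs) in column_map.items():
        keep_here = [i for i in range(lo, hi) if keep_mask[i]]
        if not keep_here:
            continue
        new_labs = [labs[i - lo] for i in keep_here]
        new_map[eff] = (col, col + len(keep_here), new_labs)
        col += len(keep_here)
    X_new = X[:, np.flatnonzero(keep_mask)]
    return X_new.tocsr(), new_map


def build_design_matrices(frame: ModelFrame, ped: Pedigree) -> DesignMatrices:
    """Assemble X, Zl, Zp, Za from an encoded frame.

    Za spans the full pedigree (animals without records get empty columns);
    Zp has one column per sow with records; Zl one per distinct birth litter.
    """
    spec = frame.spec
    n = frame.y.size
    blocks: list[sp.csr_matrix] = []
    column_map: dict[str, tuple[int, int, list[str]]] = {}
    col = 0

    herd_cat = frame.factors["herd"]
    use_herd = spec.include_herd and len(herd_cat.categories) > 1
    if not use_herd:
        blocks.append(sp.csr_matrix(np.ones((n, 1))))
        column_map["intercept"] = (0, 1, ["intercept"])
        col = 1

    for f in spec.fixed_factors:
        cat = frame.factors[f]
        codes = np.asarray(cat.codes)
        if (codes < 0).any():
            raise ValueError(f"unseen level in factor '{f}'")
        n_levels = len(cat.categories)
        observed = np.unique(codes)
        if n_levels < 2 or observed.size < 2:
            warnings.warn(f"factor '{f}' has a single level; dropped", stacklevel=2)
            continue
        if observed.size < n_levels:
            # re-index onto observed levels only (empty levels dropped)
            warnings.warn(f"factor '{f}': empty level(s) dropped", stacklevel=2)
            remap = {old: new for new, old in enumerate(observed)}
            codes = np.array([remap[c] for c in codes])
            cats = [cat.categories[i] for i in observed]
            n_levels = observed.size
        else:
            cats = list(cat.categories)
        blk = _factor_block(codes, n_levels, drop_first=True)
        blocks.append(blk)
        column_map[f] = (col, col + blk.shape[1], [str(c) for c in cats[1:]])
        col += blk.shape[1]

    if use_herd:
        codes = np.asarray(herd_cat.codes)
        blk = _factor_block(codes, len(herd_cat.categories), drop_first=False)
        blocks.append(blk)
        column_map["herd"] = (col, col + blk.shape[1],
                              [str(c) for c in herd_cat.categories])
        col += blk.shape[1]

    if spec.nested_age and "age_c" in frame.covariates:
        x = frame.covariates["age_c"]
        pcat = frame.factors.get("parity")
        if pcat is not None and "parity" in spec.fixed_factors:
            pcodes = np.asarray(pcat.codes)
            nlev = len(pcat.categories)
            cols_lin = sp.csr_matrix(
                (x, (np.arange(n), pcodes)), shape=(n, nlev))
            cols_quad = sp.csr_matrix(
                (x ** 2, (np.arange(n), pcodes)), shape=(n, nlev))
            blocks += [cols_lin, cols_quad]
            labels = [f"age_lin[parity={c}]" for c in pcat.categories] + \
                     [f"age_quad[parity={c}]" for c in pcat.categories]
            column_map["age"] = (col, col + 2 * nlev, labels)
            col += 2 * nlev
        else:
            blk = sp.csr_matrix(np.column_stack([x, x ** 2]))
            blocks.append(blk)
            column_map["age"] = (col, col + 2, ["age_lin", "age_quad"])
            col += 2

    if spec.prev_lactation and "prev_lact_c" in frame.covariates:
        z = frame.covariates["prev_lact_c"]
        blocks.append(sp.csr_matrix(z.reshape(-1, 1)))
        column_map["prev_lact"] = (col, col + 1, ["prev_lact_lin"])
        col += 1

    X = sp.hstack(blocks, format="csr")
    X, column_map = _drop_dependent_columns(X, column_map)

    litter_ids = np.array(sorted(set(frame.birth_litter.tolist())), dtype=object)
    lit_idx = {v: i for i, v in enumerate(litter_ids)}
    Zl = sp.csr_matrix(
        (np.ones(n), (np.arange(n), [lit_idx[v] for v in frame.birth_litter])),
        shape=(n, litter_ids.size),
    )

    sow_ids = np.unique(frame.sow)
    sow_idx = {int(v): i for i, v in enumerate(sow_ids)}
    Zp = sp.csr_matrix(
        (np.ones(n), (np.arange(n), [sow_idx[int(v)] for v in frame.sow])),
        shape=(n, sow_ids.size),
    )

    missing_sows = [int(s) for s in sow_ids if int(s) not in ped.order_index]
    if missing_sows:
        raise ValueError(f"sow(s) with records absent from pedigree: {missing_sows[:10]}")
    rows_pos = ped.positions(frame.sow)
    Za = sp.csr_matrix(
        (np.ones(n), (np.arange(n), rows_pos)), shape=(n, ped.n)
    )

    return DesignMatrices(
        X=X, Zl=Zl, Zp=Zp, Za=Za, column_map=column_map,
        litter_ids=litter_ids, sow_ids=sow_ids, animal_ids=ped.ids.copy(),
        herd_of_row=frame.herd.copy(),
    )
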