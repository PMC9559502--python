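"""Pedigree handling: validation, topological ordering, inbreeding and the
numerator relationship matrix.

The pedigree is the backbone of the whole evaluation: it supplies the additive
relationship matrix ``A`` (dense, brute-force, for oracle checks), its sparse
inverse ``A_inv`` (built directly from per-animal rules, used in the mixed
model equations) and the inbreeding coefficients that both require.

Conventions
-----------
* Animal ids are positive integers; parent id 0 means "unknown".
* A *base animal* has both parents unknown.
* A :class:`Pedigree` is always topologically ordered: every parent precedes
  its offspring.  All matrix routines index animals by pedigree position.
"""

from __future__ import annotations

import heapq
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp

__all__ = [
    "Pedigree",
    "PedigreeError",
    "read_pedigree",
    "write_pedigree",
    "compute_inbreeding",
    "build_A_tabular",
    "build_A_inverse",
    "mendelian_sampling_variances",
    "pedigree_summary",
]

PEDIGREE_COLUMNS = ["animal", "sire", "dam", "herd", "birth_year", "sex", "breed"]

#: dense-matrix cap for the brute-force tabular A (oracle path)
DEFAULT_TABULAR_CAP = 2000


class PedigreeError(ValueError):
    """Raised for structural pedigree violations (duplicates, cycles, ...)."""


@dataclass
class Pedigree:
    """Topologically ordered pedigree stored as parallel arrays.

    ``sire_pos``/``dam_pos`` hold the *position* of each parent in the
    ordering, or -1 for unknown.  ``order_index`` maps animal id -> position.
    """

    ids: np.ndarray
    sire_pos: np.ndarray
    dam_pos: np.ndarray
    herd: np.ndarray
    birth_year: np.ndarray
    sex: np.ndarray
    breed: np.ndarray
    order_index: dict[int, int] = field(repr=False)

    def __len__(self) -> int:
        return self.ids.size

    @property
    def n(self) -> int:
        return self.ids.size

    @property
    def is_base(self) -> np.ndarray:
        """Boolean mask of base animals (both parents unknown)."""
        return (self.sire_pos < 0) & (self.dam_pos < 0)

    def positions(self, animal_ids) -> np.ndarray:
        """Positions of the given animal ids (raises KeyError if absent)."""
        return np.array([self.order_index[int(a)] for a in np.asarray(animal_ids).ravel()])

    def to_frame(self) -> pd.DataFrame:
        sire_id = np.where(self.sire_pos >= 0, self.ids[np.maximum(self.sire_pos, 0)], 0)
        dam_id = np.where(self.dam_pos >= 0, self.ids[np.maximum(self.dam_pos, 0)], 0)
        return pd.DataFrame(
            {
                "animal": self.ids,
                "sire": sire_id,
                "dam": dam_id,
                "herd": self.herd,
                "birth_year": self.birth_year,
                "sex": self.sex,
                "breed": self.breed,
            }
        )

    @staticmethod
    def from_frame(df: pd.DataFrame, *, missing_parents: str = "insert") -> "Pedigree":
        """Validate and topologically order a pedigree table.

        Parameters
        ----------
        df:
            Table with columns ``animal, sire, dam`` and optionally
            ``herd, birth_year, sex, breed``.
        missing_parents:
            ``"insert"`` (default) adds parents referenced but absent from the
            table as base animals with a warning; ``"error"`` raises.
        """
        df = df.copy()
        for col, default in (
            ("herd", "?"),
            ("birth_year", 0),
            ("sex", "?"),
            ("breed", "?"),
        ):
            if col not in df.columns:
                df[col] = default

        animals = df["animal"].to_numpy(dtype=np.int64)
        if (animals <= 0).any():
            raise PedigreeError("animal ids must be positive integers")
        uniq, counts = np.unique(animals, return_counts=True)
        if (counts > 1).any():
            dup = uniq[counts > 1]
            raise PedigreeError(f"duplicate animal id(s): {dup[:10].tolist()}")

        sires = df["sire"].to_numpy(dtype=np.int64)
        dams = df["dam"].to_numpy(dtype=np.int64)
        if (sires == animals).any() or (dams == animals).any():
            bad = animals[(sires == animals) | (dams == animals)]
            raise PedigreeError(f"self-parentage for animal(s): {bad[:10].tolist()}")

        known = set(uniq.tolist())
        referenced = (set(sires[sires > 0].tolist()) | set(dams[dams > 0].tolist())) - known
        if referenced:
            if missing_parents == "error":
                raise PedigreeError(
                    f"parent id(s) absent from pedigree: {sorted(referenced)[:10]}"
                )
            warnings.warn(
                f"inserting {len(referenced)} referenced parent(s) as base animals",
                stacklevel=2,
            )
            missing = sorted(referenced)
            sex_of = {}
            for m in missing:
                sex_of[m] = "M" if m in set(sires.tolist()) else "F"
            extra = pd.DataFrame(
                {
                    "animal": missing,
                    "sire": 0,
                    "dam": 0,
                    "herd": "?",
                    "birth_year": 0,
                    "sex": [sex_of[m] for m in missing],
                    "breed": "?",
                }
            )
            df = pd.concat([extra, df], ignore_index=True)
            animals = df["animal"].to_numpy(dtype=np.int64)
            sires = df["sire"].to_numpy(dtype=np.int64)
            dams = df["dam"].to_numpy(dtype=np.int64)

        # sex consistency: anyone used as a sire must be male, as a dam female
        sex = df["sex"].astype(str).to_numpy()
        id_to_row = {int(a): i for i, a in enumerate(animals)}
        for pid in np.unique(sires[sires > 0]):
            if sex[id_to_row[int(pid)]] == "F":
                raise PedigreeError(f"animal {pid} is used as a sire but recorded female")
        for pid in np.unique(dams[dams > 0]):
            if sex[id_to_row[int(pid)]] == "M":
                raise PedigreeError(f"animal {pid} is used as a dam but recorded male")

        order = _topological_order(animals, sires, dams, id_to_row)
        df = df.iloc[order].reset_index(drop=True)
        animals = df["animal"].to_numpy(dtype=np.int64)
        order_index = {int(a): i for i, a in enumerate(animals)}
        sire_pos = np.array(
            [order_index[int(s)] if s > 0 else -1 for s in df["sire"]], dtype=np.int64
        )
        dam_pos = np.array(
            [order_index[int(d)] if d > 0 else -1 for d in df["dam"]], dtype=np.int64
        )
        return Pedigree(
            ids=animals,
            sire_pos=sire_pos,
            dam_pos=dam_pos,
            herd=df["herd"].astype(str).to_numpy(),
            birth_year=df["birth_year"].to_numpy(dtype=np.int64),
            sex=df["sex"].astype(str).to_numpy(),
            breed=df["breed"].astype(str).to_numpy(),
            order_index=order_index,
        )

    def subset(self, keep_pos: np.ndarray) -> "Pedigree":
        """Restrict to the given positions plus all their ancestors."""
        keep = np.zeros(self.n, dtype=bool)
        stack = list(np.asarray(keep_pos, dtype=np.int64))
        while stack:
            i = stack.pop()
            if keep[i]:
                continue
            keep[i] = True
            if self.sire_pos[i] >= 0:
                stack.append(self.sire_pos[i])
            if self.dam_pos[i] >= 0:
                stack.append(self.dam_pos[i])
        return Pedigree.from_frame(self.to_frame().loc[keep])


def _topological_order(animals, sires, dams, id_to_row) -> np.ndarray:
    """Kahn's algorithm over parent->offspring edges; detects cycles.

    Ties are broken by animal id so the result is independent of the input
    row order.
    """
    n = animals.size
    children: list[list[int]] = [[] for _ in range(n)]
    indeg = np.zeros(n, dtype=np.int64)
    for i in range(n):
        for p in (sires[i], dams[i]):
            if p > 0:
                children[id_to_row[int(p)]].append(i)
                indeg[i] += 1
    heap = [(int(animals[i]), i) for i in range(n) if indeg[i] == 0]
    heapq.heapify(heap)
    order = []
    while heap:
        _, i = heapq.heappop(heap)
        order.append(i)
        for c in children[i]:
            indeg[c] -= 1
            if indeg[c] == 0:
                heapq.heappush(heap, (int(animals[c]), c))
    if len(order) != n:
        cyc = animals[indeg > 0]
        raise PedigreeError(f"pedigree contains a cycle involving: {cyc[:10].tolist()}")
    return np.asarray(order, dtype=np.int64)


def read_pedigree(path, column_map: dict[str, str] | None = None, *,
                  missing_parents: str = "insert") -> Pedigree:
    """Read a pedigree CSV (columns animal,sire,dam,herd,birth_year,sex,breed)."""
    df = pd.read_csv(path)
    if column_map:
        df = df.rename(columns={v: k for k, v in column_map.items()})
    required = {"animal", "sire", "dam"}
    missing = required - set(df.columns)
    if missing:
        raise PedigreeError(f"pedigree file lacks required column(s): {sorted(missing)}")
    return Pedigree.from_frame(df, missing_parents=missing_parents)


def write_pedigree(ped: Pedigree, path) -> None:
    ped.to_frame().to_csv(path, index=False)


def compute_inbreeding(ped: Pedigree) -> np.ndarray:
    """Inbreeding coefficients by the Meuwissen & Luo recursion.

    For each animal the diagonal element 1 + F is accumulated over its
    ancestor set: processing ancestors from youngest to oldest, each ancestor
    j contributes L_j^2 * d_j where L_j is the expected genome fraction
    passed down and d_j its Mendelian-sampling variance.
    """
    n = ped.n
    F = np.zeros(n)
    d = np.empty(n)  # Mendelian sampling variance, filled in order
    sire, dam = ped.sire_pos, ped.dam_pos
    for i in range(n):
        s, dd = sire[i], dam[i]
        if s < 0 and dd < 0:
            d[i] = 1.0
            F[i] = 0.0
            continue
        if s < 0 or dd < 0:
            known = s if s >= 0 else dd
            d[i] = 0.75 - 0.25 * F[known]
            F[i] = 0.0
            continue
        d[i] = 0.5 - 0.25 * (F[s] + F[dd])
        # accumulate a_ii = 1 + F_i over ancestors of i
        L: dict[int, float] = {i: 1.0}
        heap = [-i]
        aii = 0.0
        while heap:
            j = -heapq.heappop(heap)
            lj = L.pop(j)
            aii += lj * lj * d[j]
            for p in (sire[j], dam[j]):
                if p >= 0:
                    if p in L:
                        L[p] += 0.5 * lj
                    else:
                        L[p] = 0.5 * lj
                        heapq.heappush(heap, -int(p))
        F[i] = aii - 1.0
    return F


def mendelian_sampling_variances(ped: Pedigree, F: np.ndarray | None = None) -> np.ndarray:
    """Diagonal of W in the A = T W T' decomposition.

    d_i = 1 (no parent known), 0.75 - F_known/4 (one known),
    0.5 - (F_s + F_d)/4 (both known).
    """
    if F is None:
        F = compute_inbreeding(ped)
    n = ped.n
    d = np.ones(n)
    s, dd = ped.sire_pos, ped.dam_pos
    both = (s >= 0) & (dd >= 0)
    d[both] = 0.5 - 0.25 * (F[s[both]] + F[dd[both]])
    only_s = (s >= 0) & (dd < 0)
    d[only_s] = 0.75 - 0.25 * F[s[only_s]]
    only_d = (s < 0) & (dd >= 0)
    d[only_d] = 0.75 - 0.25 * F[dd[only_d]]
    return d


def build_A_tabular(ped: Pedigree, cap: int = DEFAULT_TABULAR_CAP) -> np.ndarray:
    """Dense numerator relationship matrix by the tabular recursion.

    Brute-force oracle: a(i,j) = [a(j,s_i) + a(j,d_i)] / 2 applied in
    pedigree order; a(i,i) = 1 + a(s_i, d_i)/2.
    """
    n = ped.n
    if n > cap:
        raise PedigreeError(
            f"pedigree of {n} exceeds tabular cap {cap}; use build_A_inverse instead"
        )
    A = np.zeros((n, n))
    sire, dam = ped.sire_pos, ped.dam_pos
    for i in range(n):
        s, d = sire[i], dam[i]
        row = np.zeros(i)
        if s >= 0:
            row += 0.5 * A[:i, s]
        if d >= 0:
            row += 0.5 * A[:i, d]
        A[i, :i] = row
        A[:i, i] = row
        A[i, i] = 1.0 + (0.5 * A[s, d] if (s >= 0 and d >= 0) else 0.0)
    return A


def build_A_inverse(ped: Pedigree, F: np.ndarray | None = None) -> sp.csr_matrix:
    """Sparse inverse of A from per-animal contributions.

    Each animal contributes alpha_i = 1/d_i to its own diagonal, -alpha_i/2
    to (animal, parent), and alpha_i/4 to (parent, parent) cells, with d_i the
    Mendelian-sampling variance accounting for parental inbreeding.
    """
    if F is None:
        F = compute_inbreeding(ped)
    d = mendelian_sampling_variances(ped, F)
    alpha = 1.0 / d
    rows: list[int] = []
    cols: list[int] = []
    vals: list[float] = []
    sire, dam = ped.sire_pos, ped.dam_pos
    for i in range(ped.n):
        a = alpha[i]
        parents = [p for p in (sire[i], dam[i]) if p >= 0]
        rows.append(i)
        cols.append(i)
        vals.append(a)
        for p in parents:
            rows += [i, p]
            cols += [p, i]
            vals += [-0.5 * a, -0.5 * a]
        for p in parents:
            for q in parents:
                rows.append(p)
                cols.append(q)
                vals.append(0.25 * a)
    Ainv = sp.coo_matrix((vals, (rows, cols)), shape=(ped.n, ped.n))
    return Ainv.tocsr()


def pedigree_summary(ped: Pedigree, phen: pd.DataFrame | None = None) -> pd.DataFrame:
    """Per-herd and overall pedigree/data structure summary.

    Columns: n_animals, n_base, pct_base, and — when a phenotype table is
    given — n_with_records, n_litters and per-breed litter counts plus the
    response mean/SD.
    """
    base = ped.is_base
    herds = sorted(set(ped.herd.tolist()))
    rows = []
    for label, mask in [(h, ped.herd == h) for h in herds] + [
        ("ALL", np.ones(ped.n, dtype=bool))
    ]:
        row: dict[str, object] = {
            "herd": label,
            "n_animals": int(mask.sum()),
            "n_base": int((mask & base).sum()),
        }
        row["pct_base"] = 100.0 * row["n_base"] / row["n_animals"] if row["n_animals"] else np.nan
        if phen is not None:
            sub = phen if label == "ALL" else phen[phen["herd"] == label]
            ids_here = set(ped.ids[mask].tolist())
            row["n_with_records"] = int(
                len(set(sub["sow"].astype(int).tolist()) & ids_here)
                if label != "ALL"
                else sub["sow"].nunique()
            )
            row["n_litters"] = int(len(sub))
            row["nba_mean"] = float(sub["nba"].mean()) if len(sub) else np.nan
            row["nba_sd"] = float(sub["nba"].std(ddof=1)) if len(sub) > 1 else np.nan
            for g, cnt in sub.groupby("genotype").size().items():
                row[f"litters_{g}"] = int(cnt)
        rows.append(row)
    return pd.DataFrame(rows).fillna({c: 0 for c in rows[-1] if str(c).startswith("litters_")})
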