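"""Gene-flow accounting between herds.

Decomposes the additive relationship matrix as A = T W T' where T is lower
triangular under pedigree order (t[i, j] = expected fraction of animal i's
genome descending from ancestor j) and W is the diagonal of
Mendelian-sampling variances.  Restricting T to base-animal columns and
grouping base animals by herd of origin (the 0/1 incidence Q) gives, for any
group of animals, the average fraction of its genes that originates from each
herd's founders.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .pedigree import Pedigree, compute_inbreeding, mendelian_sampling_variances

__all__ = [
    "GeneFlowDecomposition",
    "GeneFlowResult",
    "build_T_W",
    "base_incidence",
    "base_contributions",
    "gene_flow_contributions",
    "gene_flow_report",
]

DEFAULT_T_CAP = 2000


@dataclass
class GeneFlowDecomposition:
    """Full dense T and diagonal W (small pedigrees; oracle checks)."""

    T: np.ndarray
    W: np.ndarray  # diagonal entries
    Q: np.ndarray  # base-animal (pedigree positions) x herd incidence
    base_pos: np.ndarray
    origin_herds: list[str]


@dataclass
class GeneFlowResult:
    """Group x origin-herd matrix of mean gene proportions."""

    contribution: pd.DataFrame  # index: group label, columns: origin herd
    group_spec: str


def build_T_W(ped: Pedigree, F: np.ndarray | None = None,
              cap: int = DEFAULT_T_CAP) -> GeneFlowDecomposition:
    """Dense gene-flow decomposition: row_i = (row_sire + row_dam)/2 + e_i."""
    n = ped.n
    if n > cap:
        raise ValueError(f"pedigree of {n} exceeds dense T cap {cap}")
    if F is None:
        F = compute_inbreeding(ped)
    W = mendelian_sampling_variances(ped, F)
    T = np.zeros((n, n))
    for i in range(n):
        s, d = ped.sire_pos[i], ped.dam_pos[i]
        if s >= 0:
            T[i, : i] += 0.5 * T[s, : i]
        if d >= 0:
            T[i, : i] += 0.5 * T[d, : i]
        T[i, i] = 1.0
    base_pos, Q, herds = base_incidence(ped)
    return GeneFlowDecomposition(T=T, W=W, Q=Q, base_pos=base_pos, origin_herds=herds)


def base_incidence(ped: Pedigree) -> tuple[np.ndarray, np.ndarray, list[str]]:
    """Base-animal positions and their 0/1 herd-of-origin incidence Q."""
    base_pos = np.flatnonzero(ped.is_base)
    herds = sorted(set(ped.herd[base_pos].tolist()))
    if "?" in herds:
        raise ValueError("base animal(s) with unknown herd of origin")
    col = {h: k for k, h in enumerate(herds)}
    Q = np.zeros((base_pos.size, len(herds)))
    for r, p in enumerate(base_pos):
        Q[r, col[ped.herd[p]]] = 1.0
    return base_pos, Q, herds


def base_contributions(ped: Pedigree) -> tuple[np.ndarray, list[str]]:
    """Per-animal herd-of-origin gene shares, i.e. the rows of T·Q.

    Computed by the downward recursion share_i = (share_sire + share_dam)/2
    without materialising T; a base animal is its own single origin.  Rows
    sum to 1 for every animal (all ancestry terminates in base animals).
    """
    base_pos, Q, herds = base_incidence(ped)
    n, k = ped.n, len(herds)
    share = np.zeros((n, k))
    is_base = ped.is_base
    col = {h: j for j, h in enumerate(herds)}
    for i in range(n):
        if is_base[i]:
            share[i, col[ped.herd[i]]] = 1.0
            continue
        s, d = ped.sire_pos[i], ped.dam_pos[i]
        # a single unknown parent is treated as an unrecorded base animal of
        # the animal's own herd (keeps rows summing to 1)
        for p in (s, d):
            if p >= 0:
                share[i] += 0.5 * share[p]
            else:
                share[i, col.get(ped.herd[i], 0)] += 0.5
    return share, herds


def gene_flow_contributions(ped: Pedigree, groups: pd.Series | dict,
                            *, group_spec: str = "herd") -> GeneFlowResult:
    """Mean origin-herd gene shares per group of animals.

    ``groups`` maps animal id -> group label (e.g. current herd, or
    "herd:year"); animals absent from the mapping are ignored.
    """
    share, herds = base_contributions(ped)
    if isinstance(groups, dict):
        groups = pd.Series(groups)
    groups = groups.dropna()
    if groups.empty:
        raise ValueError("empty group assignment")
    pos = ped.positions(groups.index.to_numpy())
    df = pd.DataFrame(share[pos], columns=herds)
    df["__group"] = groups.to_numpy()
    contrib = df.groupby("__group").mean()
    contrib.index.name = "group"
    return GeneFlowResult(contribution=contrib, group_spec=group_spec)


def gene_flow_report(res: GeneFlowResult, *, dataset_tag: str = "",
                     year_window: str = "all",
                     as_percent: bool = True) -> pd.DataFrame:
    """Long-format directional flow table: group_herd, origin_herd, proportion."""
    rows = []
    scale = 100.0 if as_percent else 1.0
    for g, row in res.contribution.iterrows():
        for origin, v in row.items():
            rows.append(
                {
                    "group_herd": g,
                    "origin_herd": origin,
                    "proportion": scale * float(v),
                    "dataset_tag": dataset_tag,
                    "year_window": year_window,
                }
            )
    return pd.DataFrame(rows)
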