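"""High-level analysis steps shared by the CLI and the test-bench.

Wires the stages together the way the study design is laid out: per-herd and
merged evaluations, purebred and purebred-plus-crossbred record subsets,
variance components either estimated in-run (EM-REML) or supplied, then
BLUP with reliability summaries, connectedness ratings and gene-flow tables.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .blup import (EvaluationResult, MixedModelSystem, assemble_mme,
                   compute_pev_reliability, solve_mme, summarize_reliability)
from .connectedness import ConnectednessMatrix, cr_from_system
from .design import DesignMatrices, ModelSpec, build_design_matrices, build_model_frame
from .geneflow import GeneFlowResult, gene_flow_contributions
from .pedigree import Pedigree, build_A_inverse, compute_inbreeding
from .varcomp import RemlTrace, VarianceComponents, em_reml

__all__ = [
    "Evaluation",
    "purebred_subset",
    "sow_herds",
    "evaluate",
    "cr_analysis",
    "geneflow_analysis",
    "cr_model_spec",
]

PURE_BREEDS = ("L", "LW")


def purebred_subset(phen: pd.DataFrame) -> pd.DataFrame:
    """Records of purebred sows only."""
    return phen[phen["genotype"].isin(PURE_BREEDS)].reset_index(drop=True)


def sow_herds(phen: pd.DataFrame) -> pd.Series:
    """Animal id -> herd for every sow with records."""
    return phen.groupby("sow")["herd"].first()


def cr_model_spec() -> ModelSpec:
    """Model used for connectedness ratings.

    Herd is the only fixed factor; remaining adjustment effects are left out
    so that herd-effect estimates are linked exclusively through shared
    genetics and shared random-effect levels — isolated herds then give an
    exactly block-diagonal system and a zero rating.
    """
    return ModelSpec(fixed_factors=(), include_herd=True,
                     nested_age=False, prev_lactation=False)


@dataclass
class Evaluation:
    """One complete evaluation run on a record subset."""

    ped: Pedigree
    dm: DesignMatrices
    vc: VarianceComponents
    system: MixedModelSystem
    result: EvaluationResult
    reml_trace: RemlTrace | None = None
    tag: str = ""
    extras: dict = field(default_factory=dict)

    def reliability_summary(self, *, sows_only: bool = True,
                            phen: pd.DataFrame | None = None) -> pd.DataFrame:
        groups = pd.Series(self.ped.herd, index=self.ped.ids)
        restrict = None
        if sows_only and phen is not None:
            restrict = phen["sow"].unique()
        return summarize_reliability(self.result, groups, restrict_to=restrict)


def evaluate(ped: Pedigree, phen: pd.DataFrame,
             vc: VarianceComponents | None = None,
             spec: ModelSpec | None = None, *,
             estimate_vc: bool = False,
             restrict_pedigree: bool = True,
             reml_tol: float = 1e-5, reml_max_iter: int = 300,
             tag: str = "") -> Evaluation:
    """Run design -> (REML) -> MME -> solutions -> PEV/reliability.

    With ``restrict_pedigree`` the pedigree is pruned to the phenotyped sows
    and their ancestors, as a per-herd analysis would see it.
    """
    spec = spec or ModelSpec()
    if restrict_pedigree:
        pos = ped.positions(phen["sow"].unique())
        ped = ped.subset(pos)
    frame = build_model_frame(phen, spec)
    dm = build_design_matrices(frame, ped)
    F = compute_inbreeding(ped)
    A_inv = build_A_inverse(ped, F)

    trace = None
    if estimate_vc or vc is None:
        vc, trace = em_reml(dm, frame.y, A_inv, init=vc, tol=reml_tol,
                            max_iter=reml_max_iter)
    system = assemble_mme(dm, frame.y, A_inv, vc)
    result = solve_mme(system)
    result = compute_pev_reliability(system, result)
    return Evaluation(ped=ped, dm=dm, vc=vc, system=system, result=result,
                      reml_trace=trace, tag=tag)


def cr_analysis(ped: Pedigree, phen: pd.DataFrame, vc: VarianceComponents,
                *, tag: str = "", restrict_pedigree: bool = True
                ) -> ConnectednessMatrix:
    """Connectedness ratings between the herds present in the records."""
    spec = cr_model_spec()
    if restrict_pedigree:
        ped = ped.subset(ped.positions(phen["sow"].unique()))
    frame = build_model_frame(phen, spec)
    dm = build_design_matrices(frame, ped)
    A_inv = build_A_inverse(ped)
    system = assemble_mme(dm, frame.y, A_inv, vc)
    return cr_from_system(system, dataset_tag=tag)


def geneflow_analysis(ped: Pedigree, phen: pd.DataFrame, *,
                      tag: str = "", per_year: bool = False) -> GeneFlowResult:
    """Origin-herd gene shares of the phenotyped sows, grouped by herd."""
    ped = ped.subset(ped.positions(phen["sow"].unique()))
    if per_year:
        g = phen.groupby("sow").agg(herd=("herd", "first"), year=("year", "min"))
        groups = pd.Series(
            g["herd"].astype(str) + ":" + g["year"].astype(str), index=g.index)
        spec = "herd:first_record_year"
    else:
        groups = sow_herds(phen)
        spec = "herd"
    res = gene_flow_contributions(ped, groups, group_spec=spec)
    res.contribution.attrs["dataset_tag"] = tag
    return res
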