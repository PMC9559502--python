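"""Connectedness rating (CR) between herds.

CR for a herd pair is the correlation between the estimated herd effects,

    cr(i, j) = cov(hi, hj) / sqrt(var(hi) var(hj))

where the variances and covariances are prediction-error (co)variances read
off the herd-rows/columns block of the inverse mixed-model coefficient
matrix, scaled by the residual variance.  Well-connected herds (shared AI
sires, traded gilts) have strongly correlated herd-effect estimates; herds
with no shared information have cr ~ 0.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .blup import MixedModelSystem

__all__ = [
    "ConnectednessMatrix",
    "herd_effect_precision",
    "connectedness_rating_matrix",
    "cr_report",
]

#: conventional minimum rating for across-herd genetic evaluation
DEFAULT_CR_THRESHOLD = 0.015


@dataclass
class ConnectednessMatrix:
    herds: list[str]
    cr: np.ndarray
    dataset_tag: str = ""

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.cr, index=self.herds, columns=self.herds)

    def pairs(self) -> pd.DataFrame:
        rows = []
        for i, hi in enumerate(self.herds):
            for j, hj in enumerate(self.herds):
                if i < j:
                    rows.append({
                        "dataset_tag": self.dataset_tag,
                        "herd_i": hi, "herd_j": hj,
                        "cr": float(self.cr[i, j]),
                    })
        return pd.DataFrame(rows)


def herd_effect_precision(sys: MixedModelSystem) -> tuple[np.ndarray, list[str]]:
    """PEV-covariance of the herd-effect estimates.

    Returns sigma2_e times the herd block of the inverse coefficient matrix,
    together with the herd labels.  Requires the design to have retained all
    herd levels (include_herd on, more than one herd present).
    """
    if "herd" not in sys.index_map:
        raise ValueError(
            "herd is not a fixed factor in this system; rebuild the design "
            "with include_herd=True and more than one herd"
        )
    lo, hi, labels = sys.index_map["herd"]
    idx = np.arange(lo, hi)
    block = sys.inverse_block(idx)
    block = 0.5 * (block + block.T)
    return sys.sigma2_e * block, [lbl.split(":", 1)[-1] for lbl in labels]


def connectedness_rating_matrix(cov: np.ndarray, herds: list[str],
                                dataset_tag: str = "") -> ConnectednessMatrix:
    """Correlation matrix of the herd-effect estimates from their PEV block."""
    d = np.diag(cov)
    if (d <= 0).any():
        bad = [herds[i] for i in np.flatnonzero(d <= 0)]
        raise ValueError(f"herd(s) with no information (zero PEV diagonal): {bad}")
    denom = np.sqrt(np.outer(d, d))
    cr = cov / denom
    np.fill_diagonal(cr, 1.0)
    return ConnectednessMatrix(herds=list(herds), cr=cr, dataset_tag=dataset_tag)


def cr_from_system(sys: MixedModelSystem, dataset_tag: str = "") -> ConnectednessMatrix:
    """Convenience: herd PEV block -> connectedness rating in one step."""
    cov, herds = herd_effect_precision(sys)
    return connectedness_rating_matrix(cov, herds, dataset_tag=dataset_tag)


def cr_report(crs: list[ConnectednessMatrix],
              threshold: float = DEFAULT_CR_THRESHOLD) -> pd.DataFrame:
    """Long-format CR table over datasets with below-threshold pairs flagged."""
    frames = []
    for cm in crs:
        df = cm.pairs()
        df["below_threshold"] = df["cr"] < threshold
        frames.append(df)
    out = pd.concat(frames, ignore_index=True) if frames else pd.DataFrame(
        columns=["dataset_tag", "herd_i", "herd_j", "cr", "below_threshold"])
    return out
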