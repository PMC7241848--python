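"""Partition of phenotypic variance into G and G-by-E contributions.

The replicate-mean growth of segregant i in environment j is decomposed by a
two-way factorial ANOVA

    ybar_ij = u + id_i + E_j + (id*E)_ij + e

on the complete segregant x environment grid of cell means.  Because the data
are deviations from a control medium the environment main effect is expected
to be null, but its sum of squares is computed and reported regardless.  The
replicate-level residual sum of squares (within-cell variation) is reported
as SS_resid.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .simulate import PhenotypeTable

logger = logging.getLogger(__name__)

__all__ = ["VarCompResult", "partition_gxe"]


@dataclass
class VarCompResult:
    grand_mean: float
    SS_G: float
    SS_E: float
    SS_GxE: float
    SS_resid: float
    SS_total: float
    n_segregants: int
    n_environments: int

    @property
    def fraction_G(self) -> float:
        return self.SS_G / self.SS_total if self.SS_total > 0 else 0.0

    @property
    def fraction_E(self) -> float:
        return self.SS_E / self.SS_total if self.SS_total > 0 else 0.0

    @property
    def fraction_GxE(self) -> float:
        return self.SS_GxE / self.SS_total if self.SS_total > 0 else 0.0

    def as_dict(self) -> dict:
        return {
            "grand_mean": self.grand_mean,
            "SS_G": self.SS_G,
            "SS_E": self.SS_E,
            "SS_GxE": self.SS_GxE,
            "SS_resid": self.SS_resid,
            "SS_total": self.SS_total,
            "fraction_G": self.fraction_G,
            "fraction_E": self.fraction_E,
            "fraction_GxE": self.fraction_GxE,
            "n_segregants": self.n_segregants,
            "n_environments": self.n_environments,
        }


def partition_gxe(pheno: PhenotypeTable) -> VarCompResult:
    """Two-way ANOVA of replicate-mean growth on segregant and environment.

    Unbalanced replicate counts are absorbed by averaging to cell means
    first; the factorial decomposition then runs on the balanced grid of
    means.  Segregants not observed in every environment are excluded with a
    warning (the interaction is undefined for a segregant seen in a single
    environment, and an incomplete grid breaks the orthogonal
    decomposition).

    The identity SS_G + SS_E + SS_GxE = SS of the cell means holds exactly;
    SS_resid (replicate scatter around the cell means) completes SS_total.
    """
    grid = pheno.cell_means()
    complete = grid.dropna(axis=0)
    dropped = len(grid) - len(complete)
    if dropped:
        logger.warning(
            "excluding %d segregant(s) not observed in every environment", dropped
        )
    n_seg, n_env = complete.shape
    if n_seg < 2 or n_env < 2:
        raise ValueError(
            f"need >=2 segregants and >=2 environments with complete data "
            f"(got {n_seg} x {n_env})"
        )
    y = complete.to_numpy()
    grand = y.mean()
    row = y.mean(axis=1)
    col = y.mean(axis=0)
    ss_g = n_env * float(np.sum((row - grand) ** 2))
    ss_e = n_seg * float(np.sum((col - grand) ** 2))
    inter = y - row[:, None] - col[None, :] + grand
    ss_gxe = float(np.sum(inter**2))
    # replicate-level scatter around the cell means (kept segregants only)
    rec = pheno.records[pheno.records["segregant"].isin(complete.index)]
    cell = rec.groupby(["segregant", "environment"])["growth"]
    ss_resid = float((cell.transform("mean") - rec["growth"]).pow(2).sum())
    # total computed directly from the data, not from the components, so the
    # factorial identity SS_G + SS_E + SS_GxE + SS_resid = SS_total is a
    # genuine check of the decomposition
    ss_total = float(np.sum((y - grand) ** 2)) + ss_resid
    return VarCompResult(
        grand_mean=float(grand),
        SS_G=ss_g,
        SS_E=ss_e,
        SS_GxE=ss_gxe,
        SS_resid=ss_resid,
        SS_total=ss_total,
        n_segregants=n_seg,
        n_environments=n_env,
    )
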