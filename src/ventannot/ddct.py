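"""Comparative-CT (ddCt) relative expression for qPCR confirmation.

Classic Livak quantification with amplification efficiency fixed at 2:
dCt = mean Ct(gene) - mean Ct(reference); ddCt = dCt(target) -
dCt(calibrator); fold = 2^(-ddCt). The dCt standard deviation combines
the replicate SDs in quadrature, the calibrator dCt is treated as the
fixed baseline, and the fold range maps 2^(-(ddCt +- SD)). An
efficiency-corrected mode (base = efficiency) is available.
"""
from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

import pandas as pd

from .errors import ConfigError, InputError

CT_COLUMNS = ["gene_id", "replicate", "ct"]


@dataclass
class CtTable:
    """Replicate threshold cycles with the designated reference
    (housekeeping, e.g. 28S rRNA) and calibrator genes."""

    data: pd.DataFrame  # gene_id, replicate, ct
    reference: str
    calibrator: str

    def __post_init__(self):
        missing = [c for c in CT_COLUMNS if c not in self.data.columns]
        if missing:
            raise InputError(f"Ct table lacks columns {missing}")
        if (self.data["ct"] <= 0).any():
            raise InputError("Ct values must be positive cycle counts")
        if self.reference not in set(self.data["gene_id"]):
            raise InputError(f"reference gene {self.reference!r} has no "
                             "replicates")
        if self.calibrator not in set(self.data["gene_id"]):
            raise InputError(f"calibrator gene {self.calibrator!r} has no "
                             "replicates")

    @classmethod
    def from_tsv(cls, path, reference: str, calibrator: str) -> "CtTable":
        return cls(pd.read_csv(path, sep="\t"), reference, calibrator)

    def genes(self) -> list[str]:
        return sorted(set(self.data["gene_id"]))

    def stats(self, gene: str) -> tuple[float, float, int]:
        grp = self.data.loc[self.data["gene_id"] == gene, "ct"]
        if grp.empty:
            raise InputError(f"gene {gene!r} has no replicates")
        n = len(grp)
        sd = float(grp.std(ddof=1)) if n > 1 else 0.0
        return float(grp.mean()), sd, n


@dataclass
class FoldResult:
    gene_id: str
    fold: float
    fold_low: float
    fold_high: float
    ddct: float
    ddct_sd: float
    n_replicates: int


def ddct_fold(table: CtTable, target_gene: str,
              reference_gene: Optional[str] = None,
              calibrator: Optional[str] = None,
              efficiency: float = 2.0) -> FoldResult:
    """Relative expression of ``target_gene`` vs the calibrator,
    normalised to the reference gene.

    SD(dCt) = sqrt(sd_target^2 + sd_reference^2); the fold interval is
    base^(-(ddCt ± SD)). fold(calibrator vs itself) is exactly 1.
    """
    if efficiency <= 1.0:
        raise ConfigError(f"efficiency must exceed 1, got {efficiency}")
    reference_gene = reference_gene or table.reference
    calibrator = calibrator or table.calibrator
    mean_t, sd_t, n_t = table.stats(target_gene)
    mean_r, sd_r, _ = table.stats(reference_gene)
    mean_c, sd_c, _ = table.stats(calibrator)

    dct_target = mean_t - mean_r
    dct_cal = mean_c - mean_r
    ddct = dct_target - dct_cal
    sd = 0.0 if target_gene == calibrator \
        else math.sqrt(sd_t ** 2 + sd_r ** 2)
    fold = efficiency ** (-ddct)
    return FoldResult(
        gene_id=target_gene,
        fold=fold,
        fold_low=efficiency ** (-(ddct + sd)),
        fold_high=efficiency ** (-(ddct - sd)),
        ddct=ddct,
        ddct_sd=sd,
        n_replicates=n_t,
    )


def fold_table(table: CtTable, efficiency: float = 2.0) -> pd.DataFrame:
    """ddCt folds for every gene (reference excluded) vs the calibrator."""
    rows = []
    for gene in table.genes():
        if gene == table.reference:
            continue
        r = ddct_fold(table, gene, efficiency=efficiency)
        rows.append((r.gene_id, r.fold, r.fold_low, r.fold_high, r.ddct,
                     r.ddct_sd, r.n_replicates))
    return pd.DataFrame(rows, columns=[
        "gene_id", "fold", "fold_low", "fold_high", "ddct", "ddct_sd",
        "n_replicates"])
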