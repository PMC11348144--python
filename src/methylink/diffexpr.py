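"""FPKM, per-tumor fold changes versus averaged controls, and a
(fold change, p) significance contract.

Each tumor is compared to the mean of the control columns:
``FC = (tumor_fpkm + eps) / (mean(control_fpkm) + eps)`` with a small
pseudocount (default 0.1) so zero-expression genes stay finite.  The
significance p can come from an imported differential-expression table
(e.g. a DESeq2 export) or from an internal z-score of the tumor's
log2(FPKM + eps) against the control replicate distribution — an
approximation for the single-tumor-versus-replicates design, not a
negative-binomial model.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats

from .io_formats import ExpressionMatrix

logger = logging.getLogger(__name__)


def compute_fpkm(counts: ExpressionMatrix) -> ExpressionMatrix:
    """Fragments per kilobase per million: count * 1e9 / (length * library size).

    The library size is the column sum of raw counts, so scaling a
    column's counts leaves its FPKM unchanged.
    """
    if counts.unit != "counts":
        raise ValueError("compute_fpkm expects a counts matrix")
    if counts.gene_lengths is None:
        raise ValueError("FPKM requires gene lengths")
    lengths = counts.gene_lengths.reindex(counts.values.index)
    if lengths.isna().any():
        missing = lengths.index[lengths.isna()][0]
        raise ValueError(f"no length for gene {missing!r}")
    lib = counts.values.sum(axis=0)
    fpkm = counts.values * 1e9
    fpkm = fpkm.div(lengths, axis=0).div(lib, axis=1)
    return ExpressionMatrix(
        values=fpkm, unit="fpkm", groups=dict(counts.groups),
        gene_lengths=counts.gene_lengths,
    )


def fold_changes(
    fpkm: ExpressionMatrix,
    pseudocount: float = 0.1,
) -> pd.DataFrame:
    """Per-gene, per-tumor fold change versus the control mean.

    Returns genes x tumor-samples of FC; log2 is just ``np.log2`` of it.
    """
    if fpkm.unit != "fpkm":
        raise ValueError("fold_changes expects an FPKM matrix")
    controls = fpkm.control_ids
    tumors = fpkm.tumor_ids
    if not controls:
        raise ValueError("at least one control column is required")
    ctrl_mean = fpkm.values[controls].mean(axis=1)
    fc = (fpkm.values[tumors] + pseudocount).div(ctrl_mean + pseudocount, axis=0)
    return fc


@dataclass
class DEResult:
    """Fold changes with significance per gene per tumor.

    ``fc``, ``p`` and ``significant`` are genes x tumors frames; the
    flag is FC >= fc_threshold or FC <= 1/fc_threshold with p < alpha.
    """

    fc: pd.DataFrame
    p: pd.DataFrame
    fc_threshold: float
    alpha: float

    @property
    def log2fc(self) -> pd.DataFrame:
        return np.log2(self.fc)

    @property
    def significant(self) -> pd.DataFrame:
        beyond = (self.fc >= self.fc_threshold) | (self.fc <= 1.0 / self.fc_threshold)
        return beyond & (self.p < self.alpha)

    @property
    def up(self) -> pd.DataFrame:
        return (self.fc >= self.fc_threshold) & (self.p < self.alpha)

    @property
    def down(self) -> pd.DataFrame:
        return (self.fc <= 1.0 / self.fc_threshold) & (self.p < self.alpha)


def de_table(
    fpkm: ExpressionMatrix,
    source: str = "internal",
    imported: pd.DataFrame | None = None,
    fc_threshold: float = 1.5,
    alpha: float = 0.05,
    pseudocount: float = 0.1,
) -> DEResult:
    """Assemble the differential-expression contract.

    ``internal``: p per tumor from a two-sided normal z of the tumor's
    log2(FPKM+eps) against the control replicates' log2 distribution
    (requires >= 2 controls).  ``imported``: a long table with columns
    gene_id, sample_id, log2fc, p passes its p-values through; FC is
    still computed from FPKM in both modes so the two routes agree on it.
    """
    fc = fold_changes(fpkm, pseudocount)
    tumors = list(fc.columns)
    if source == "internal":
        controls = fpkm.control_ids
        if len(controls) < 2:
            raise ValueError("internal test needs >= 2 control replicates")
        log_ctrl = np.log2(fpkm.values[controls] + pseudocount)
        mu = log_ctrl.mean(axis=1)
        sd = log_ctrl.std(axis=1, ddof=1)
        p = pd.DataFrame(index=fc.index, columns=tumors, dtype=float)
        for t in tumors:
            log_t = np.log2(fpkm.values[t] + pseudocount)
            with np.errstate(divide="ignore", invalid="ignore"):
                z = (log_t - mu) / sd
            pt = 2.0 * stats.norm.sf(np.abs(z))
            # zero control variance: significant only if the tumor moved at all
            pt = np.where(sd.to_numpy() == 0,
                          np.where(log_t.to_numpy() == mu.to_numpy(), 1.0, 0.0), pt)
            p[t] = pt
    elif source == "imported":
        if imported is None:
            raise ValueError("imported mode needs a DE table")
        p = pd.DataFrame(np.nan, index=fc.index, columns=tumors, dtype=float)
        wide = imported.pivot(index="gene_id", columns="sample_id", values="p")
        common = p.index.intersection(wide.index)
        missing = len(p.index) - len(common)
        if missing:
            logger.warning("imported DE table missing %d genes; flags left absent", missing)
        cols = [c for c in tumors if c in wide.columns]
        p.loc[common, cols] = wide.loc[common, cols]
    else:
        raise ValueError(f"unknown DE source {source!r}")
    return DEResult(fc=fc, p=p, fc_threshold=fc_threshold, alpha=alpha)


def read_de_table(path: str | Path) -> pd.DataFrame:
    """Read an externally produced DE table: TSV with columns
    gene_id, sample_id, log2fc, p."""
    df = pd.read_csv(path, sep="\t", comment="#")
    required = {"gene_id", "sample_id", "log2fc", "p"}
    if not required.issubset(df.columns):
        raise ValueError(f"DE table needs columns {sorted(required)}")
    return df


def select_expressed(
    fpkm: ExpressionMatrix,
    threshold: float = 5.0,
    group: str = "control",
) -> list[str]:
    """Genes whose mean FPKM across the designated group is >= threshold
    (inclusive)."""
    cols = [s for s in fpkm.values.columns if fpkm.groups.get(s) == group]
    if not cols:
        raise ValueError(f"no samples in group {group!r}")
    mean = fpkm.values[cols].mean(axis=1)
    return list(mean.index[mean >= threshold])
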