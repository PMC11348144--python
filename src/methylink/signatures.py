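"""Cross-tumor recurrence: core methylation/expression signatures,
promoter DMR frequencies, methylation-expression integration and the
gene-effect lethality screen.

Cross-tumor DMR identity is defined by >= 1 bp overlap with
single-linkage clustering: same-direction DMRs from different tumors
that form an overlap chain become one merged signature region whose
interval is their union.  A merged region enters the core signature
when it is supported by at least ``n_required`` distinct tumors.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .io_formats import DMR

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class SignatureRegion:
    """One merged recurrent region (BED coordinates)."""

    chrom: str
    start: int
    end: int
    direction: str
    support: tuple[str, ...]  # distinct contributing tumor ids
    mean_delta_by_tumor: Mapping[str, float]

    @property
    def n_support(self) -> int:
        return len(self.support)


@dataclass
class CoreSignature:
    hypo: list[SignatureRegion] = field(default_factory=list)
    hyper: list[SignatureRegion] = field(default_factory=list)

    @property
    def sizes(self) -> dict[str, int]:
        return {"hypo": len(self.hypo), "hyper": len(self.hyper)}


def _overlap_frac(a: DMR, b: DMR) -> float:
    inter = min(a.bed_end, b.bed_end) - max(a.bed_start, b.bed_start)
    if inter <= 0:
        return 0.0
    return inter / min(a.bed_end - a.bed_start, b.bed_end - b.bed_start)


def _cluster_direction(
    dmrs: list[DMR], n_required: int, min_reciprocal: float
) -> list[SignatureRegion]:
    """Single-linkage overlap clustering on a sorted sweep.

    Overlap chaining keeps each cluster's union contiguous, so one pass
    over (chrom, start)-sorted DMRs suffices: a DMR overlapping the
    running union extends the cluster, anything else starts a new one.
    """
    regions: list[SignatureRegion] = []
    dmrs = sorted(dmrs, key=lambda d: (d.chrom, d.bed_start, d.bed_end))
    cluster: list[DMR] = []

    def flush() -> None:
        if not cluster:
            return
        tumors = tuple(sorted({d.sample_id for d in cluster}))
        if len(tumors) >= n_required:
            deltas = {
                t: float(
                    np.mean([d.mean_delta for d in cluster if d.sample_id == t])
                )
                for t in tumors
            }
            regions.append(
                SignatureRegion(
                    chrom=cluster[0].chrom,
                    start=min(d.bed_start for d in cluster),
                    end=max(d.bed_end for d in cluster),
                    direction=cluster[0].direction,
                    support=tumors,
                    mean_delta_by_tumor=deltas,
                )
            )

    cur_chrom, cur_end = None, -1
    for d in dmrs:
        linked = d.chrom == cur_chrom and d.bed_start < cur_end
        if linked and min_reciprocal > 0:
            linked = any(
                _overlap_frac(d, other) >= min_reciprocal for other in cluster
            )
        if not linked:
            flush()
            cluster = []
            cur_chrom, cur_end = d.chrom, d.bed_end
        cluster.append(d)
        cur_end = max(cur_end, d.bed_end)
    flush()
    return regions


def recurrent_dmrs(
    dmr_sets: Mapping[str, Sequence[DMR]],
    n_required: int | None = None,
    min_reciprocal: float = 0.0,
) -> CoreSignature:
    """Merge per-tumor DMR sets into direction-matched recurrent regions.

    ``n_required`` defaults to the number of tumors (the core signature:
    recurrence in every tumor).  ``min_reciprocal`` optionally demands a
    reciprocal overlap fraction on top of the >= 1 bp rule.
    """
    if n_required is None:
        n_required = len(dmr_sets)
    sig = CoreSignature()
    for direction in ("hypo", "hyper"):
        pool = [
            d
            for tumor_dmrs in dmr_sets.values()
            for d in tumor_dmrs
            if d.direction == direction
        ]
        regions = _cluster_direction(pool, n_required, min_reciprocal)
        setattr(sig, direction, regions)
    logger.info("core signature sizes: %s (n_required=%d)", sig.sizes, n_required)
    return sig


def gene_dmr_frequency(
    dmr_sets: Mapping[str, Sequence[DMR]],
    promoters: pd.DataFrame,
) -> pd.DataFrame:
    """Per gene and direction, the number of tumors with >= 1 DMR of
    that direction overlapping the promoter (a tumor counts once).

    Returns a frame indexed by gene_id with columns hypo, hyper.
    """
    genes = promoters["name"].tolist()
    hits: dict[str, dict[str, set[str]]] = {
        g: {"hypo": set(), "hyper": set()} for g in genes
    }
    by_chrom = {chrom: grp for chrom, grp in promoters.groupby("chrom", sort=False)}
    for tumor_id, dmrs in dmr_sets.items():
        for d in dmrs:
            grp = by_chrom.get(d.chrom)
            if grp is None:
                continue
            sel = (grp["start"] < d.bed_end) & (grp["end"] > d.bed_start)
            for gene in grp.loc[sel, "name"]:
                hits[gene][d.direction].add(tumor_id)
    out = pd.DataFrame(
        {
            "hypo": [len(hits[g]["hypo"]) for g in genes],
            "hyper": [len(hits[g]["hyper"]) for g in genes],
        },
        index=pd.Index(genes, name="gene_id"),
    )
    return out


def core_expression_signature(
    fc: pd.DataFrame,
    fold: float = 2.0,
    n_required: int | None = None,
) -> tuple[list[str], list[str]]:
    """Genes moving at least ``fold`` in the same direction in at least
    ``n_required`` tumors (default: all tumors).

    Returns (up list, down list); up means FC >= fold, down FC <= 1/fold.
    """
    if n_required is None:
        n_required = fc.shape[1]
    up = (fc >= fold).sum(axis=1) >= n_required
    down = (fc <= 1.0 / fold).sum(axis=1) >= n_required
    return list(fc.index[up]), list(fc.index[down])


@dataclass(frozen=True)
class IntegrationProfile:
    """Threshold bundle for methylation-expression integration."""

    name: str
    fc_threshold: float
    alpha: float
    meth_min_tumors: int
    expr_min_tumors: int | None = None  # None -> majority of tumors


#: named profiles: "fig5a" follows the >=2-fold legend, "text25" the
#: >=1.5-fold in-text variant of the same analysis (the source analyses
#: report both thresholds).
PROFILES = {
    "fig5a": IntegrationProfile("fig5a", 2.0, 0.05, 6),
    "text25": IntegrationProfile("text25", 1.5, 0.05, 6),
}


def integrate(
    gene_freq: pd.DataFrame,
    de: "DEResult",
    meth_min_tumors: int = 6,
    fc_threshold: float = 2.0,
    alpha: float = 0.05,
    expr_min_tumors: int | None = None,
) -> pd.DataFrame:
    """Combine promoter-DMR recurrence with expression recurrence.

    hypo_up genes have a hypomethylated promoter in >= ``meth_min_tumors``
    tumors and pass FC >= fc_threshold with p < alpha in >=
    ``expr_min_tumors`` tumors (default: a majority); hyper_down is the
    mirror image.  Every gene gets a class in {hypo_up, hyper_down, none};
    a single run can never assign both classes to one gene unless its
    promoter recurs in both directions — ties resolve to none.
    """
    from .diffexpr import DEResult  # local import to avoid cycle at import time

    assert isinstance(de, DEResult)
    n_tumors = de.fc.shape[1]
    if expr_min_tumors is None:
        expr_min_tumors = n_tumors // 2 + 1
    common = gene_freq.index.intersection(de.fc.index)
    if len(common) < 0.5 * max(len(gene_freq), 1):
        logger.warning(
            "gene id namespaces overlap poorly: %d/%d", len(common), len(gene_freq)
        )
    up_counts = de.up.sum(axis=1)
    down_counts = de.down.sum(axis=1)
    rows = []
    for gene in common:
        hypo_n = int(gene_freq.loc[gene, "hypo"])
        hyper_n = int(gene_freq.loc[gene, "hyper"])
        n_up = int(up_counts.loc[gene])
        n_down = int(down_counts.loc[gene])
        is_hypo_up = hypo_n >= meth_min_tumors and n_up >= expr_min_tumors
        is_hyper_down = hyper_n >= meth_min_tumors and n_down >= expr_min_tumors
        if is_hypo_up and not is_hyper_down:
            cls = "hypo_up"
        elif is_hyper_down and not is_hypo_up:
            cls = "hyper_down"
        else:
            cls = "none"
        rows.append((gene, hypo_n, hyper_n, n_up, n_down, cls))
    return pd.DataFrame(
        rows,
        columns=[
            "gene_id", "hypo_promoter_count", "hyper_promoter_count",
            "up_count", "down_count", "class",
        ],
    ).set_index("gene_id")


def lethality_screen(
    gene_effect: pd.DataFrame,
    lineages: Mapping[str, str],
    threshold: float = -1.0,
    common_essential_frac: float = 0.9,
) -> pd.DataFrame:
    """Count cell lines per gene with effect score <= threshold
    (inclusive), split by lineage.

    ``gene_effect`` is genes x cell lines; ``lineages`` maps line ->
    {lymphoid, myeloid, other}.  A gene lethal in >=
    ``common_essential_frac`` of all lines is flagged common_essential.
    """
    lethal = gene_effect <= threshold
    lineage = pd.Series({c: lineages.get(c, "other") for c in gene_effect.columns})
    out = pd.DataFrame(index=gene_effect.index)
    for lin in ("lymphoid", "myeloid", "other"):
        cols = lineage.index[lineage == lin]
        out[f"n_{lin}"] = lethal[cols].sum(axis=1) if len(cols) else 0
    out["n_total"] = lethal.sum(axis=1)
    out["common_essential"] = out["n_total"] >= common_essential_frac * gene_effect.shape[1]
    return out
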