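"""Genomic-element annotation and promoter methylation summaries.

Promoters are the window from 1500 bp upstream to 500 bp downstream of
the TSS, strand-relative, with the TSS base itself counted as position
+1 of the downstream side.  Element classes are non-exclusive by
default (a region overlapping both a promoter and a repeat carries both
labels, matching ``bedtools intersect`` semantics); an exclusive
priority mode is available for distribution summaries.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Literal, Mapping, Sequence

import numpy as np
import pandas as pd
from intervaltree import IntervalTree
from scipy import stats

from .io_formats import DMR, MethylomeSample

ELEMENT_PRIORITY = ["promoter", "exon", "intron", "gene_body", "enhancer", "repeat"]

#: promoter-methylation bin labels and their half-open-above edges
BIN_LABELS = ["0-25", "26-50", "51-75", "76-100"]
BIN_EDGES = [0.0, 25.0, 50.0, 75.0, 100.0]


@dataclass
class AnnotationSet:
    """Strand-aware intervals by element class plus TSS records.

    ``intervals`` maps element class -> frame with columns chrom, start,
    end, name, strand (BED convention); ``tss`` has columns gene_id,
    chrom, pos (1-based TSS), strand.
    """

    intervals: dict[str, pd.DataFrame] = field(default_factory=dict)
    tss: pd.DataFrame | None = None
    _trees: dict[tuple[str, str], IntervalTree] = field(
        default_factory=dict, repr=False, compare=False
    )

    def add(self, element_class: str, frame: pd.DataFrame) -> None:
        if element_class in self.intervals:
            frame = pd.concat([self.intervals[element_class], frame], ignore_index=True)
        self.intervals[element_class] = frame.reset_index(drop=True)
        self._trees = {k: v for k, v in self._trees.items() if k[0] != element_class}

    def tree(self, element_class: str, chrom: str) -> IntervalTree:
        key = (element_class, chrom)
        if key not in self._trees:
            frame = self.intervals.get(element_class)
            tree = IntervalTree()
            if frame is not None:
                sub = frame[frame["chrom"] == chrom]
                for start, end, name in zip(sub["start"], sub["end"], sub["name"]):
                    tree.addi(int(start), int(end), name)
            self._trees[key] = tree
        return self._trees[key]

    @property
    def element_classes(self) -> list[str]:
        return list(self.intervals)


def make_promoters(
    tss: pd.DataFrame,
    upstream: int = 1500,
    downstream: int = 500,
) -> pd.DataFrame:
    """Build strand-relative promoter intervals around TSS records.

    For a plus-strand TSS at 1-based position t the promoter covers the
    bases t-upstream .. t+downstream-1, i.e. the BED interval
    [t-1-upstream, t-1+downstream); the mirror image for minus strand.
    Intervals are clipped at zero.
    """
    required = {"gene_id", "chrom", "pos", "strand"}
    if not required.issubset(tss.columns):
        raise ValueError(f"tss records need columns {sorted(required)}")
    if (~tss["strand"].isin(["+", "-"])).any():
        bad = tss.loc[~tss["strand"].isin(["+", "-"]), "gene_id"].iloc[0]
        raise ValueError(f"TSS record {bad!r} lacks a usable strand")
    t0 = tss["pos"].to_numpy() - 1  # 0-based TSS base
    plus = (tss["strand"] == "+").to_numpy()
    start = np.where(plus, t0 - upstream, t0 - downstream + 1)
    end = np.where(plus, t0 + downstream, t0 + upstream + 1)
    start = np.maximum(start, 0)
    return pd.DataFrame(
        {
            "chrom": tss["chrom"].to_numpy(),
            "start": start.astype(int),
            "end": end.astype(int),
            "name": tss["gene_id"].to_numpy(),
            "strand": tss["strand"].to_numpy(),
            "element_class": "promoter",
        }
    )


def _feature_frame(features) -> pd.DataFrame:
    """Normalize CpG tables / DMR lists to (chrom, start, end, direction)."""
    if isinstance(features, pd.DataFrame):
        df = features.copy()
        if "start" not in df.columns:  # per-CpG table with 1-based pos
            df["start"] = df["pos"] - 1
            df["end"] = df["pos"]
        if "direction" not in df.columns:
            df["direction"] = "."
        return df[["chrom", "start", "end", "direction"]]
    rows = [
        (f.chrom, f.bed_start, f.bed_end, f.direction) for f in features
    ]
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "direction"])


def annotate_features(
    features: Sequence[DMR] | pd.DataFrame,
    annotation: AnnotationSet,
    mode: Literal["multilabel", "exclusive"] = "multilabel",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Label features (CpGs or DMRs) with the genomic elements they
    overlap by >= 1 bp.

    In ``multilabel`` mode (the default, bedtools-intersect semantics) a
    feature receives every overlapped class; in ``exclusive`` mode only
    the highest-priority class (promoter > exon > intron > gene_body >
    enhancer > repeat).  Features overlapping nothing are intergenic.

    Returns (per-feature table with a ``classes`` column, per-class
    hypo/hyper/total count table).
    """
    df = _feature_frame(features)
    classes = [c for c in ELEMENT_PRIORITY if c in annotation.intervals] + [
        c for c in annotation.intervals if c not in ELEMENT_PRIORITY
    ]
    labels: list[list[str]] = []
    for chrom, start, end in zip(df["chrom"], df["start"], df["end"]):
        hit = [
            cls for cls in classes if annotation.tree(cls, chrom).overlap(start, end)
        ]
        if not hit:
            hit = ["intergenic"]
        elif mode == "exclusive":
            hit = [hit[0]]
        labels.append(hit)
    df["classes"] = labels

    all_classes = classes + ["intergenic"]
    counts = pd.DataFrame(
        0, index=all_classes, columns=["hypo", "hyper", "other", "total"], dtype=int
    )
    for lab, direction in zip(labels, df["direction"]):
        col = direction if direction in ("hypo", "hyper") else "other"
        for cls in lab:
            counts.loc[cls, col] += 1
            counts.loc[cls, "total"] += 1
    return df, counts


def assign_bin(mean_pct: float) -> str:
    """Bin a methylation percent with edges [0,25], (25,50], (50,75], (75,100]."""
    if not 0.0 <= mean_pct <= 100.0:
        raise ValueError(f"methylation percent out of range: {mean_pct}")
    for label, hi in zip(BIN_LABELS, BIN_EDGES[1:]):
        if mean_pct <= hi:
            return label
    return BIN_LABELS[-1]


def promoter_methylation(
    sample: MethylomeSample,
    promoters: pd.DataFrame,
    min_cpgs: int = 1,
) -> pd.DataFrame:
    """Mean promoter methylation per gene.

    For each promoter interval the covered CpG percents are averaged
    (unweighted); genes with fewer than ``min_cpgs`` covered CpGs are
    absent from the result.  Columns: gene_id, mean_meth_pct, n_cpgs, bin.
    """
    sites = sample.sites
    pct = sample.meth_pct.to_numpy()
    rows = []
    for chrom, grp in promoters.groupby("chrom", sort=False):
        sub = sites["chrom"] == chrom
        pos = sites.loc[sub, "pos"].to_numpy()  # 1-based
        vals = pct[sub.to_numpy()]
        if len(pos) == 0:
            continue
        # CpG at 1-based p lies in BED [start, end) iff start <= p-1 < end
        for start, end, gene in zip(grp["start"], grp["end"], grp["name"]):
            lo = np.searchsorted(pos, start + 1, side="left")
            hi = np.searchsorted(pos, end, side="right")
            member = vals[lo:hi]
            member = member[~np.isnan(member)]
            if len(member) >= min_cpgs:
                mean = float(member.mean())
                rows.append((gene, mean, len(member), assign_bin(mean)))
    return pd.DataFrame(rows, columns=["gene_id", "mean_meth_pct", "n_cpgs", "bin"])


def bin_counts(values: Iterable[float]) -> dict[str, int]:
    """Tabulate methylation percents into the four standard bins."""
    out = {label: 0 for label in BIN_LABELS}
    for v in values:
        out[assign_bin(float(v))] += 1
    return out


def pairwise_pearson(
    frame: pd.DataFrame,
    columns: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Pearson R for every pair of columns on their shared non-missing
    rows.  Returns a long table (a, b, r, n)."""
    cols = list(columns) if columns is not None else list(frame.columns)
    rows = []
    for i, a in enumerate(cols):
        for b in cols[i:]:
            pair = frame[[a, b]].dropna()
            n = len(pair)
            if a == b:
                r = 1.0
            elif n >= 2:
                r = float(stats.pearsonr(pair[a], pair[b])[0])
            else:
                r = float("nan")
            rows.append((a, b, r, n))
    return pd.DataFrame(rows, columns=["a", "b", "r", "n"])


def expression_by_bin(
    promoter_meth: pd.DataFrame,
    fpkm: pd.Series,
    equal_var: bool = False,
) -> tuple[pd.DataFrame, pd.DataFrame, bool]:
    """Mean +/- SEM FPKM per promoter-methylation bin with all pairwise
    two-tailed t-tests (Welch by default).

    Returns (per-bin summary, pairwise test table, monotone-decreasing
    flag for the bin means).  Bins with < 2 genes get NaN test results
    rather than an error.
    """
    merged = promoter_meth.merge(
        fpkm.rename("fpkm"), left_on="gene_id", right_index=True, how="inner"
    )
    groups = {label: merged.loc[merged["bin"] == label, "fpkm"] for label in BIN_LABELS}
    summary = pd.DataFrame(
        {
            "bin": BIN_LABELS,
            "n": [len(groups[b]) for b in BIN_LABELS],
            "mean_fpkm": [groups[b].mean() if len(groups[b]) else np.nan for b in BIN_LABELS],
            "sem_fpkm": [
                groups[b].sem() if len(groups[b]) > 1 else np.nan for b in BIN_LABELS
            ],
        }
    )
    tests = []
    for i, a in enumerate(BIN_LABELS):
        for b in BIN_LABELS[i + 1:]:
            ga, gb = groups[a], groups[b]
            if len(ga) >= 2 and len(gb) >= 2:
                t, p = stats.ttest_ind(ga, gb, equal_var=equal_var)
                tests.append((a, b, float(t), float(p)))
            else:
                tests.append((a, b, np.nan, np.nan))
    tests_df = pd.DataFrame(tests, columns=["bin_a", "bin_b", "t", "p"])
    means = summary["mean_fpkm"].dropna().to_numpy()
    monotone = bool(len(means) >= 2 and np.all(np.diff(means) < 0))
    return summary, tests_df, monotone
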