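"""Readers and writers for the formats the pipeline touches.

Coordinate conventions
----------------------
CpG positions are 1-based, as in Bismark cytosine reports; every genomic
interval is 0-based half-open, as in BED.  Conversion between the two
happens only at the CpG <-> interval boundary: a 1-based cytosine at
position ``p`` occupies the BED interval ``[p-1, p)``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

SITE_COLUMNS = ["chrom", "pos", "strand", "meth", "unmeth"]

#: contexts accepted as CpG in a Bismark cytosine report
_CPG_CONTEXTS = {"CpG", "CG"}


class FormatError(ValueError):
    """A malformed input file; the message names the offending line."""


@dataclass
class MethylomeSample:
    """Per-CpG methylated/unmethylated read counts for one specimen.

    ``sites`` has columns chrom, pos (1-based), strand, meth, unmeth,
    sorted by (chrom, pos) with no duplicate (chrom, pos).
    """

    sample_id: str
    group: str  # "control" or "tumor"
    sites: pd.DataFrame

    def __post_init__(self) -> None:
        if self.group not in ("control", "tumor"):
            raise ValueError(f"group must be control/tumor, got {self.group!r}")
        missing = [c for c in SITE_COLUMNS if c not in self.sites.columns]
        if missing:
            raise ValueError(f"sites missing columns {missing}")
        self.sites = self.sites.reset_index(drop=True)

    @property
    def coverage(self) -> pd.Series:
        return self.sites["meth"] + self.sites["unmeth"]

    @property
    def meth_pct(self) -> pd.Series:
        """Methylation percent per site; NaN where coverage is zero."""
        cov = self.coverage
        with np.errstate(invalid="ignore", divide="ignore"):
            pct = 100.0 * self.sites["meth"] / cov
        return pct.where(cov > 0)

    def __len__(self) -> int:
        return len(self.sites)


@dataclass
class ExpressionMatrix:
    """Genes x samples abundance (raw counts or FPKM)."""

    values: pd.DataFrame  # index: gene ids, columns: sample ids
    unit: str  # "counts" or "fpkm"
    groups: Mapping[str, str]  # sample id -> "control" / "tumor"
    gene_lengths: pd.Series | None = None  # bp, required when unit == counts

    def __post_init__(self) -> None:
        if self.unit not in ("counts", "fpkm"):
            raise ValueError(f"unit must be counts/fpkm, got {self.unit!r}")
        if (self.values.values < 0).any():
            raise ValueError("expression values must be non-negative")
        if self.values.index.duplicated().any():
            dup = self.values.index[self.values.index.duplicated()][0]
            raise ValueError(f"duplicate gene id {dup!r}")
        if self.unit == "counts" and self.gene_lengths is not None:
            if (self.gene_lengths <= 0).any():
                raise ValueError("gene lengths must be positive")

    @property
    def control_ids(self) -> list[str]:
        return [s for s in self.values.columns if self.groups.get(s) == "control"]

    @property
    def tumor_ids(self) -> list[str]:
        return [s for s in self.values.columns if self.groups.get(s) == "tumor"]


@dataclass(frozen=True)
class DMR:
    """A tested run of consecutive same-direction differential CpGs.

    ``start_pos``/``end_pos`` are the 1-based positions of the first and
    last member cytosine; the equivalent BED interval is
    ``[start_pos - 1, end_pos)``.
    """

    sample_id: str
    chrom: str
    start_pos: int
    end_pos: int
    positions: tuple[int, ...]
    direction: str  # "hypo" or "hyper"
    mean_delta: float
    p_value: float

    @property
    def n_cpgs(self) -> int:
        return len(self.positions)

    @property
    def bed_start(self) -> int:
        return self.start_pos - 1

    @property
    def bed_end(self) -> int:
        return self.end_pos


def _merge_strands(df: pd.DataFrame) -> pd.DataFrame:
    """Collapse symmetric CpGs onto the plus-strand cytosine.

    A minus-strand record at position p belongs to the CpG whose
    plus-strand cytosine sits at p-1; counts are summed.  Total read
    counts are conserved.
    """
    df = df.copy()
    minus = df["strand"] == "-"
    df.loc[minus, "pos"] = df.loc[minus, "pos"] - 1
    df["strand"] = "+"
    merged = (
        df.groupby(["chrom", "pos"], as_index=False, sort=False)
        .agg(meth=("meth", "sum"), unmeth=("unmeth", "sum"))
    )
    merged["strand"] = "+"
    return merged[SITE_COLUMNS]


def read_cytosine_report(
    path: str | Path,
    min_coverage: int = 5,
    merge_strands: bool = True,
    sample_id: str | None = None,
    group: str = "tumor",
) -> MethylomeSample:
    """Read per-CpG counts from a Bismark cytosine report or a
    6-column bedGraph-with-counts file.

    The dialect is auto-detected from the column count: 7 columns is the
    Bismark cytosine report (chrom, 1-based pos, strand, meth count,
    unmeth count, context, trinucleotide); 6 columns is bedGraph with
    counts (chrom, 0-based start, end, meth %, meth count, unmeth count).
    Only CpG-context records are kept; the coverage filter is applied
    after strand merging (when enabled).  The bedGraph dialect carries no
    strand, so merging is a no-op there.
    """
    path = Path(path)
    rows: list[tuple] = []
    skipped_context = 0
    ncols: int | None = None
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if ncols is None:
                if len(fields) not in (6, 7):
                    raise FormatError(
                        f"{path}:{lineno}: expected 6 or 7 tab-separated "
                        f"columns, got {len(fields)}"
                    )
                ncols = len(fields)
            if len(fields) != ncols:
                raise FormatError(
                    f"{path}:{lineno}: expected {ncols} columns, got {len(fields)}"
                )
            try:
                if ncols == 7:
                    chrom, pos, strand, meth, unmeth, context = (
                        fields[0], int(fields[1]), fields[2],
                        int(fields[3]), int(fields[4]), fields[5],
                    )
                    if context not in _CPG_CONTEXTS:
                        skipped_context += 1
                        continue
                else:
                    chrom = fields[0]
                    pos = int(fields[1]) + 1  # bedGraph start is 0-based
                    strand = "."
                    meth, unmeth = int(fields[4]), int(fields[5])
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: malformed line ({exc})") from exc
            if meth < 0 or unmeth < 0:
                raise FormatError(f"{path}:{lineno}: negative read count")
            if strand not in ("+", "-", "."):
                raise FormatError(f"{path}:{lineno}: bad strand {strand!r}")
            rows.append((chrom, pos, strand, meth, unmeth))
    if skipped_context:
        logger.info("%s: skipped %d non-CpG context records", path, skipped_context)

    df = pd.DataFrame(rows, columns=SITE_COLUMNS)
    if not df.empty:
        order = df.sort_values(["chrom", "pos"], kind="mergesort")
        if not order.index.equals(df.index):
            logger.warning("%s: positions not sorted; sorting internally", path)
            df = order.reset_index(drop=True)
        if merge_strands and (df["strand"] == "-").any():
            df = _merge_strands(df).sort_values(["chrom", "pos"]).reset_index(drop=True)
        cov = df["meth"] + df["unmeth"]
        df = df[cov >= min_coverage].reset_index(drop=True)
    return MethylomeSample(
        sample_id=sample_id or path.stem, group=group, sites=df
    )


def read_region_bed(path: str | Path, element_class: str) -> pd.DataFrame:
    """Read BED3/BED6 intervals and tag them with an element class.

    Returns a frame with columns chrom, start, end, name, strand,
    element_class.  BED coordinates (0-based half-open) are kept as-is;
    BED3 records get name '.' and strand '.'.
    """
    path = Path(path)
    rows = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(f"{path}:{lineno}: fewer than 3 BED columns")
            try:
                chrom, start, end = fields[0], int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: malformed line ({exc})") from exc
            if start >= end:
                raise FormatError(
                    f"{path}:{lineno}: empty or inverted interval [{start}, {end})"
                )
            name = fields[3] if len(fields) > 3 else "."
            strand = fields[5] if len(fields) > 5 else "."
            rows.append((chrom, start, end, name, strand, element_class))
    return pd.DataFrame(
        rows, columns=["chrom", "start", "end", "name", "strand", "element_class"]
    )


def read_expression_table(
    path: str | Path,
    groups: Mapping[str, str],
    unit: str = "counts",
) -> ExpressionMatrix:
    """Read a TSV expression table (first column gene id, optional
    'length' column, remaining columns one sample each)."""
    df = pd.read_csv(path, sep="\t", index_col=0, comment="#")
    lengths = None
    if "length" in df.columns:
        lengths = df.pop("length").astype(float)
    if df.isna().any().any():
        raise FormatError(f"{path}: missing values in expression table")
    if df.index.duplicated().any():
        dup = df.index[df.index.duplicated()][0]
        raise FormatError(f"{path}: duplicate gene id {dup!r}")
    if (df.values < 0).any():
        raise FormatError(f"{path}: negative expression value")
    return ExpressionMatrix(
        values=df.astype(float), unit=unit, groups=dict(groups), gene_lengths=lengths
    )


_DMR_BED_HEADER = (
    "#chrom\tstart\tend\tname\tscore\tstrand\tn_cpgs\tmean_delta\tp_value\tpositions"
)


def write_dmr_bed(dmrs: Sequence[DMR], path: str | Path, version: str = "0.1.0") -> None:
    """Write DMRs as BED6+ (name = sample:direction, score = round |mean delta|),
    ordered by (chrom, start)."""
    recs = sorted(dmrs, key=lambda d: (d.chrom, d.bed_start, d.bed_end))
    with open(path, "w") as fh:
        fh.write(f"# methylink {version} DMR export\n")
        fh.write(_DMR_BED_HEADER + "\n")
        for d in recs:
            fh.write(
                "\t".join(
                    [
                        d.chrom,
                        str(d.bed_start),
                        str(d.bed_end),
                        f"{d.sample_id}:{d.direction}",
                        str(int(round(abs(d.mean_delta)))),
                        ".",
                        str(d.n_cpgs),
                        repr(d.mean_delta),
                        repr(d.p_value),
                        ",".join(map(str, d.positions)),
                    ]
                )
                + "\n"
            )


def read_dmr_bed(path: str | Path) -> list[DMR]:
    """Inverse of :func:`write_dmr_bed`; round-trips all fields exactly."""
    out: list[DMR] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            f = line.split("\t")
            if len(f) < 10:
                raise FormatError(f"{path}:{lineno}: expected 10 DMR BED columns")
            sample_id, _, direction = f[3].rpartition(":")
            positions = tuple(int(p) for p in f[9].split(",")) if f[9] else ()
            out.append(
                DMR(
                    sample_id=sample_id,
                    chrom=f[0],
                    start_pos=int(f[1]) + 1,
                    end_pos=int(f[2]),
                    positions=positions,
                    direction=direction,
                    mean_delta=float(f[7]),
                    p_value=float(f[8]),
                )
            )
    return out


def write_methylome(sample: MethylomeSample, path: str | Path) -> None:
    """Write a sample as a 7-column Bismark-dialect cytosine report."""
    with open(path, "w") as fh:
        for chrom, pos, strand, meth, unmeth in sample.sites[SITE_COLUMNS].itertuples(
            index=False
        ):
            strand_out = "+" if strand == "." else strand
            fh.write(f"{chrom}\t{pos}\t{strand_out}\t{meth}\t{unmeth}\tCpG\tCGN\n")
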