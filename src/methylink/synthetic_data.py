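"""Synthetic mini-cohorts with planted, recorded truth.

The generator emulates the structure of a WGBS + RNA-seq tumor-cohort
study: a bimodal CpG methylation landscape (most CpGs highly
methylated), per-CpG binomial read sampling at Poisson coverage, normal
controls that share a latent methylation state up to small logit-normal
jitter, tumors that shift that state by a planted delta inside
differentially methylated blocks, and negative-binomial gene expression
in which a configurable subset of genes is coupled to the planted
promoter methylation change (promoter loss -> up, gain -> down).

Defaults mirror the profiled study design: 5 control and 7 tumor
methylomes, 4 control and 10 tumor expression libraries, ~30x coverage,
a 0.7/0.3 Beta(8,1)/Beta(1,8) background mixture and logit-normal
control jitter sigma = 0.3 (which puts control-control correlations in
the 0.7-0.9 range typical of real T-cell methylomes).

Everything is driven by one ``numpy`` Generator, so a fixed config and
seed reproduce the outputs byte for byte.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
import pandas as pd

from .annotation import AnnotationSet, make_promoters
from .io_formats import ExpressionMatrix, MethylomeSample, SITE_COLUMNS, write_methylome


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------

@dataclass
class PlantedDMRSpec:
    """One family of planted differential blocks.

    ``presence`` is "all", an integer k (a random k-of-n tumor subset),
    or an explicit tuple of 0-based tumor indices.
    """

    n_regions: int
    direction: Literal["hypo", "hyper"]
    delta: float  # percentage points, signed; sign must match direction
    n_cpgs: int = 6
    element_class: str = "promoter"
    cpg_spacing_bp: int = 50
    presence: object = "all"

    def __post_init__(self) -> None:
        if self.direction == "hypo" and self.delta >= 0:
            raise ValueError("hypo blocks need a negative delta")
        if self.direction == "hyper" and self.delta <= 0:
            raise ValueError("hyper blocks need a positive delta")
        if not 0 < abs(self.delta) <= 100:
            raise ValueError("delta must keep methylation within [0, 100]")


@dataclass
class ExpressionSpec:
    """Negative-binomial expression with planted fold changes."""

    mean_log10_range: tuple[float, float] = (1.3, 3.0)  # base mean counts
    dispersion: float = 0.1
    n_planted_up: int = 15  # universally up, FC = planted_fc_up
    n_planted_down: int = 5
    planted_fc_up: float = 4.0
    planted_fc_down: float = 0.25
    coupling_fraction_hypo: float = 0.6  # of hypo-promoter genes -> up
    coupling_fraction_hyper: float = 0.8  # of hyper-promoter genes -> down
    coupled_fc_up: float = 4.0
    coupled_fc_down: float = 0.25


@dataclass
class SimulationConfig:
    seed: int = 0
    n_chroms: int = 2
    chrom_length_bp: int = 1_000_000
    cpg_spacing_bp: float = 100.0
    n_genes: int = 300
    gene_length_bp: int = 3000
    repeat_fraction: float = 0.15
    repeat_length_bp: int = 300
    enhancers_per_chrom: int = 20
    n_controls: int = 5
    n_tumors: int = 7
    n_expr_controls: int = 4
    n_expr_tumors: int = 10
    coverage_mean: float = 30.0
    coverage_floor: int = 5
    bg_weight_high: float = 0.7
    bg_high: tuple[float, float] = (8.0, 1.0)
    bg_low: tuple[float, float] = (1.0, 8.0)
    jitter_sd: float = 0.3  # logit-normal inter-control variability
    noise_free: bool = False
    planted_dmrs: list[PlantedDMRSpec] = field(default_factory=list)
    expression: ExpressionSpec = field(default_factory=ExpressionSpec)

    @property
    def control_ids(self) -> list[str]:
        return [f"C{i+1}" for i in range(self.n_controls)]

    @property
    def tumor_ids(self) -> list[str]:
        return [f"T{i+1}" for i in range(self.n_tumors)]

    @property
    def expr_control_ids(self) -> list[str]:
        return [f"EC{i+1}" for i in range(self.n_expr_controls)]

    @property
    def expr_tumor_ids(self) -> list[str]:
        # first n_tumors expression tumors are the methylome-profiled ones
        return [f"T{i+1}" for i in range(self.n_expr_tumors)]


def default_config(seed: int = 0, **overrides) -> SimulationConfig:
    """Study-shaped default: 20 hypo + 10 hyper promoter blocks planted
    in every tumor, with 12 genes coupled up and 8 coupled down."""
    overrides.setdefault(
        "planted_dmrs",
        [
            PlantedDMRSpec(n_regions=20, direction="hypo", delta=-30.0),
            PlantedDMRSpec(n_regions=10, direction="hyper", delta=+30.0),
        ],
    )
    return SimulationConfig(seed=seed, **overrides)


# ---------------------------------------------------------------------------
# Truth containers
# ---------------------------------------------------------------------------

@dataclass
class SyntheticTruth:
    """Planted signal exactly as generated.

    ``dmrs`` columns: region_id, chrom, start_pos, end_pos (1-based
    first/last planted CpG), direction, delta, n_cpgs, element_class,
    gene_id (promoter blocks), tumors (comma-joined ids).
    ``expression`` columns: gene_id, fc, kind (planted_up, planted_down,
    coupled_hypo_up, coupled_hyper_down); untouched genes have FC 1 and
    are absent.
    """

    dmrs: pd.DataFrame
    expression: pd.DataFrame

    def coupled_genes(self) -> pd.DataFrame:
        return self.expression[self.expression["kind"].str.startswith("coupled")]


@dataclass
class SyntheticDataset:
    config: SimulationConfig
    annotation: AnnotationSet
    genes: pd.DataFrame  # gene_id, chrom, tss_pos, strand, length
    controls: list[MethylomeSample]
    tumors: list[MethylomeSample]
    expression: ExpressionMatrix
    truth: SyntheticTruth


# ---------------------------------------------------------------------------
# Annotation
# ---------------------------------------------------------------------------

def simulate_annotation(
    config: SimulationConfig, rng: np.random.Generator
) -> tuple[AnnotationSet, pd.DataFrame]:
    """Lay out gene models, enhancers and repeats on a mini-genome.

    Genes sit in fixed slots (one per 6 kb by default geometry) with
    alternating strand; each has two 500 bp exons at the body ends, the
    remainder intronic.  Repeats are tiled to cover ``repeat_fraction``
    of the genome; enhancers fall in the intergenic slack.
    """
    n_per = int(np.ceil(config.n_genes / config.n_chroms))
    slot = config.chrom_length_bp // max(n_per, 1)
    # slot must hold 2 kb of upstream space, the body, and a 1.5 kb
    # downstream promoter tail for minus-strand genes
    if slot < config.gene_length_bp + 3600:
        raise ValueError("chromosomes too short for the requested gene count")
    gene_rows = []
    body_rows, exon_rows, intron_rows, tss_rows = [], [], [], []
    gid = 0
    for ci in range(config.n_chroms):
        chrom = f"chr{ci + 1}"
        for si in range(n_per):
            if gid >= config.n_genes:
                break
            gene = f"gene{gid + 1:04d}"
            strand = "+" if gid % 2 == 0 else "-"
            body_start = si * slot + 2000  # BED
            body_end = body_start + config.gene_length_bp
            tss_pos = body_start + 1 if strand == "+" else body_end  # 1-based
            gene_rows.append((gene, chrom, tss_pos, strand, config.gene_length_bp))
            body_rows.append((chrom, body_start, body_end, gene, strand))
            exon_rows.append((chrom, body_start, body_start + 500, f"{gene}.e1", strand))
            exon_rows.append((chrom, body_end - 500, body_end, f"{gene}.e2", strand))
            intron_rows.append((chrom, body_start + 500, body_end - 500, f"{gene}.i1", strand))
            tss_rows.append((gene, chrom, tss_pos, strand))
            gid += 1

    genes = pd.DataFrame(
        gene_rows, columns=["gene_id", "chrom", "tss_pos", "strand", "length"]
    )
    tss = pd.DataFrame(tss_rows, columns=["gene_id", "chrom", "pos", "strand"])

    def frame(rows):
        return pd.DataFrame(rows, columns=["chrom", "start", "end", "name", "strand"])

    ann = AnnotationSet(tss=tss)
    ann.add("gene_body", frame(body_rows))
    ann.add("exon", frame(exon_rows))
    ann.add("intron", frame(intron_rows))
    ann.add("promoter", make_promoters(tss))

    enh_rows = []
    for ci in range(config.n_chroms):
        chrom = f"chr{ci + 1}"
        for _ in range(config.enhancers_per_chrom):
            s = int(rng.integers(0, config.chrom_length_bp - 400))
            enh_rows.append((chrom, s, s + 400, f"enh_{chrom}_{s}", "."))
    ann.add("enhancer", frame(enh_rows))

    rpt_rows = []
    n_rpt = int(
        round(config.repeat_fraction * config.chrom_length_bp / config.repeat_length_bp)
    )
    for ci in range(config.n_chroms):
        chrom = f"chr{ci + 1}"
        # evenly spaced anchors with jitter keep coverage near the target
        anchors = np.linspace(
            0, config.chrom_length_bp - config.repeat_length_bp, n_rpt, dtype=int
        )
        jitter = rng.integers(
            0, max(config.chrom_length_bp // max(n_rpt, 1) - config.repeat_length_bp, 1),
            size=n_rpt,
        )
        for k, (a, j) in enumerate(zip(anchors, jitter)):
            s = int(min(a + j, config.chrom_length_bp - config.repeat_length_bp))
            rpt_rows.append((chrom, s, s + config.repeat_length_bp, f"rpt_{chrom}_{k}", "."))
    ann.add("repeat", frame(rpt_rows))
    return ann, genes


# ---------------------------------------------------------------------------
# Methylomes
# ---------------------------------------------------------------------------

def _resolve_presence(spec: PlantedDMRSpec, n_tumors: int, rng: np.random.Generator):
    if spec.presence == "all":
        return tuple(range(n_tumors))
    if isinstance(spec.presence, int):
        k = spec.presence
        if not 1 <= k <= n_tumors:
            raise ValueError(f"presence {k} out of range for {n_tumors} tumors")
        return tuple(sorted(rng.choice(n_tumors, size=k, replace=False).tolist()))
    return tuple(int(i) for i in spec.presence)


def _logit_jitter(mu: np.ndarray, sd: float, rng: np.random.Generator) -> np.ndarray:
    if sd == 0:
        return mu
    clipped = np.clip(mu, 1e-3, 1 - 1e-3)
    logit = np.log(clipped / (1 - clipped))
    noisy = logit + rng.normal(0.0, sd, size=mu.shape)
    return 1.0 / (1.0 + np.exp(-noisy))


def simulate_methylomes(
    config: SimulationConfig,
    annotation: AnnotationSet,
    rng: np.random.Generator,
) -> tuple[list[MethylomeSample], list[MethylomeSample], pd.DataFrame]:
    """Draw control and tumor methylomes plus the planted-DMR truth table.

    Background CpG positions follow exponential spacing; every planted
    block contributes a dedicated run of ``n_cpgs`` CpGs inside its host
    element so segmentation is exercisable.  Planted baselines are drawn
    so baseline + delta stays inside [0, 100].
    """
    # -- choose host intervals for planted blocks ---------------------------
    truth_rows = []
    planted_pos: dict[str, list[int]] = {}  # chrom -> positions
    planted_info: list[dict] = []
    used_hosts: set[tuple[str, str, int]] = set()
    region_id = 0
    for spec in config.planted_dmrs:
        hosts = annotation.intervals.get(spec.element_class)
        if hosts is None or hosts.empty:
            raise ValueError(f"no intervals of class {spec.element_class!r} to plant in")
        span = (spec.n_cpgs - 1) * spec.cpg_spacing_bp
        candidates = hosts[(hosts["end"] - hosts["start"]) > span + 20]
        order = rng.permutation(len(candidates))
        taken = 0
        for idx in order:
            if taken >= spec.n_regions:
                break
            row = candidates.iloc[idx]
            key = (spec.element_class, row["chrom"], int(row["start"]))
            if key in used_hosts:
                continue
            used_hosts.add(key)
            start_bed = int(row["start"]) + 10
            positions = [start_bed + 1 + k * spec.cpg_spacing_bp for k in range(spec.n_cpgs)]
            tumors_idx = _resolve_presence(spec, config.n_tumors, rng)
            planted_pos.setdefault(row["chrom"], []).extend(positions)
            planted_info.append(
                {
                    "chrom": row["chrom"],
                    "positions": positions,
                    "delta": spec.delta,
                    "tumors": tumors_idx,
                }
            )
            gene_id = row["name"] if spec.element_class == "promoter" else ""
            truth_rows.append(
                (
                    f"pdmr{region_id:04d}", row["chrom"], positions[0], positions[-1],
                    spec.direction, spec.delta, spec.n_cpgs, spec.element_class,
                    gene_id, ",".join(f"T{i+1}" for i in tumors_idx),
                )
            )
            region_id += 1
            taken += 1
        if taken < spec.n_regions:
            raise ValueError(
                f"could only place {taken}/{spec.n_regions} blocks in "
                f"{spec.element_class!r} intervals"
            )
    truth = pd.DataFrame(
        truth_rows,
        columns=[
            "region_id", "chrom", "start_pos", "end_pos", "direction",
            "delta", "n_cpgs", "element_class", "gene_id", "tumors",
        ],
    )

    # -- CpG landscape ------------------------------------------------------
    chrom_pos: dict[str, np.ndarray] = {}
    for ci in range(config.n_chroms):
        chrom = f"chr{ci + 1}"
        gaps = rng.exponential(config.cpg_spacing_bp, size=int(
            2.0 * config.chrom_length_bp / config.cpg_spacing_bp
        ))
        gaps = np.maximum(gaps.astype(int), 2)
        pos = 1 + np.cumsum(gaps)
        pos = pos[pos <= config.chrom_length_bp]
        extra = np.array(sorted(set(planted_pos.get(chrom, []))), dtype=int)
        if len(extra):
            pos = np.unique(np.concatenate([pos, extra]))
        chrom_pos[chrom] = pos

    # -- latent baseline methylation ---------------------------------------
    baseline: dict[str, np.ndarray] = {}
    for chrom, pos in chrom_pos.items():
        high = rng.random(len(pos)) < config.bg_weight_high
        mu = np.where(
            high,
            rng.beta(*config.bg_high, size=len(pos)),
            rng.beta(*config.bg_low, size=len(pos)),
        )
        baseline[chrom] = mu
    # Planted blocks are regionally coherent: one baseline per region
    # (drawn so baseline + delta stays inside [0, 100]) shared by every
    # CpG falling in the block span, mirroring the local correlation of
    # real methylation domains.
    for info in planted_info:
        pos = chrom_pos[info["chrom"]]
        lo_p, hi_p = info["positions"][0], info["positions"][-1]
        idx = np.where((pos >= lo_p) & (pos <= hi_p))[0]
        d = info["delta"] / 100.0
        if d < 0:
            lo, hi = -d + 0.05, 0.97
        else:
            lo, hi = 0.03, 1.0 - d - 0.05
        baseline[info["chrom"]][idx] = rng.uniform(lo, hi)
        info["member_idx"] = idx

    # -- per-sample observed counts ----------------------------------------
    def draw_sample(sample_id: str, group: str, shift: dict[str, np.ndarray]) -> MethylomeSample:
        frames = []
        for chrom in sorted(chrom_pos):
            pos = chrom_pos[chrom]
            mu = np.clip(baseline[chrom] + shift.get(chrom, 0.0), 0.0, 1.0)
            if config.noise_free:
                cov = np.full(len(pos), 10_000, dtype=int)
                meth = np.round(mu * cov).astype(int)
            else:
                # inter-individual jitter models normal-control
                # variability; tumors deviate from the shared latent
                # state only through the planted shift + read sampling
                mu_s = (
                    _logit_jitter(mu, config.jitter_sd, rng)
                    if group == "control"
                    else mu
                )
                cov = rng.poisson(config.coverage_mean, size=len(pos))
                cov = np.maximum(cov, config.coverage_floor)
                meth = rng.binomial(cov, mu_s)
            frames.append(
                pd.DataFrame(
                    {
                        "chrom": chrom, "pos": pos, "strand": "+",
                        "meth": meth, "unmeth": cov - meth,
                    }
                )
            )
        sites = pd.concat(frames, ignore_index=True)[SITE_COLUMNS]
        return MethylomeSample(sample_id=sample_id, group=group, sites=sites)

    controls = [draw_sample(sid, "control", {}) for sid in config.control_ids]

    tumors = []
    for ti, sid in enumerate(config.tumor_ids):
        shift: dict[str, np.ndarray] = {}
        for chrom, pos in chrom_pos.items():
            shift[chrom] = np.zeros(len(pos))
        for info in planted_info:
            if ti not in info["tumors"]:
                continue
            shift[info["chrom"]][info["member_idx"]] += info["delta"] / 100.0
        tumors.append(draw_sample(sid, "tumor", shift))
    return controls, tumors, truth


# ---------------------------------------------------------------------------
# Expression
# ---------------------------------------------------------------------------

def simulate_expression(
    config: SimulationConfig,
    genes: pd.DataFrame,
    dmr_truth: pd.DataFrame,
    rng: np.random.Generator,
) -> tuple[ExpressionMatrix, pd.DataFrame]:
    """Draw the counts (or exact-FPKM, in noise-free mode) table.

    Planted-FC genes are drawn from genes without planted promoter
    blocks; coupled genes are a per-direction fraction of the genes that
    do carry one, with fold change matched to the promoter direction.
    The planted fold change applies in every tumor library.
    """
    spec = config.expression
    gene_ids = genes["gene_id"].tolist()
    lo, hi = spec.mean_log10_range
    base_mean = 10.0 ** rng.uniform(lo, hi, size=len(gene_ids))
    base_mean = pd.Series(base_mean, index=gene_ids)

    promoter_truth = dmr_truth[dmr_truth["element_class"] == "promoter"]
    hypo_genes = sorted(set(promoter_truth.loc[promoter_truth["direction"] == "hypo", "gene_id"]))
    hyper_genes = sorted(set(promoter_truth.loc[promoter_truth["direction"] == "hyper", "gene_id"]))
    free = [g for g in gene_ids if g not in set(hypo_genes) | set(hyper_genes)]
    if spec.n_planted_up + spec.n_planted_down > len(free):
        raise ValueError("not enough unplanted genes for the requested DE genes")
    pick = rng.choice(len(free), size=spec.n_planted_up + spec.n_planted_down, replace=False)
    planted_up = [free[i] for i in pick[: spec.n_planted_up]]
    planted_down = [free[i] for i in pick[spec.n_planted_up:]]

    def couple(pool: list[str], frac: float) -> list[str]:
        k = int(round(frac * len(pool)))
        if k == 0:
            return []
        idx = rng.choice(len(pool), size=k, replace=False)
        return [pool[i] for i in sorted(idx)]

    coupled_up = couple(hypo_genes, spec.coupling_fraction_hypo)
    coupled_down = couple(hyper_genes, spec.coupling_fraction_hyper)

    fc = pd.Series(1.0, index=gene_ids)
    truth_rows = []
    for g in planted_up:
        fc[g] = spec.planted_fc_up
        truth_rows.append((g, spec.planted_fc_up, "planted_up"))
    for g in planted_down:
        fc[g] = spec.planted_fc_down
        truth_rows.append((g, spec.planted_fc_down, "planted_down"))
    for g in coupled_up:
        fc[g] = spec.coupled_fc_up
        truth_rows.append((g, spec.coupled_fc_up, "coupled_hypo_up"))
    for g in coupled_down:
        fc[g] = spec.coupled_fc_down
        truth_rows.append((g, spec.coupled_fc_down, "coupled_hyper_down"))
    expr_truth = pd.DataFrame(truth_rows, columns=["gene_id", "fc", "kind"])

    samples = config.expr_control_ids + config.expr_tumor_ids
    groups = {s: ("control" if s.startswith("EC") else "tumor") for s in samples}
    lengths = genes.set_index("gene_id")["length"].astype(float)

    if config.noise_free:
        # infinite-coverage analog: exact per-gene abundances, FPKM units
        values = pd.DataFrame(index=gene_ids, columns=samples, dtype=float)
        for s in samples:
            mult = fc if groups[s] == "tumor" else 1.0
            values[s] = base_mean * mult
        return (
            ExpressionMatrix(values=values, unit="fpkm", groups=groups,
                             gene_lengths=lengths),
            expr_truth,
        )

    disp = spec.dispersion
    values = pd.DataFrame(index=gene_ids, columns=samples, dtype=float)
    for s in samples:
        mean = base_mean * (fc if groups[s] == "tumor" else 1.0)
        if disp > 0:
            shape = 1.0 / disp
            lam = rng.gamma(shape, mean / shape)
        else:
            lam = mean
        values[s] = rng.poisson(lam).astype(float)
    return (
        ExpressionMatrix(values=values, unit="counts", groups=groups,
                         gene_lengths=lengths),
        expr_truth,
    )


# ---------------------------------------------------------------------------
# Top level
# ---------------------------------------------------------------------------

def simulate(config: SimulationConfig | None = None) -> SyntheticDataset:
    """Generate a complete cohort (annotation, methylomes, expression)."""
    config = config if config is not None else default_config()
    rng = np.random.default_rng(config.seed)
    annotation, genes = simulate_annotation(config, rng)
    controls, tumors, dmr_truth = simulate_methylomes(config, annotation, rng)
    expression, expr_truth = simulate_expression(config, genes, dmr_truth, rng)
    return SyntheticDataset(
        config=config,
        annotation=annotation,
        genes=genes,
        controls=controls,
        tumors=tumors,
        expression=expression,
        truth=SyntheticTruth(dmrs=dmr_truth, expression=expr_truth),
    )


def write_dataset(dataset: SyntheticDataset, out_dir: str | Path) -> None:
    """Emit the dataset as plain-text files: Bismark-dialect cytosine
    reports, BED/TSV annotation, the expression table and truth tables."""
    out = Path(out_dir)
    (out / "methylomes").mkdir(parents=True, exist_ok=True)
    (out / "annotation").mkdir(exist_ok=True)
    (out / "truth").mkdir(exist_ok=True)
    for s in dataset.controls + dataset.tumors:
        write_methylome(s, out / "methylomes" / f"{s.sample_id}.cov.txt")
    ann = dataset.annotation
    ann.tss.rename(columns={"pos": "tss_pos"}).to_csv(
        out / "annotation" / "tss.tsv", sep="\t", index=False
    )
    for cls, frame in ann.intervals.items():
        bed = frame.copy()
        bed["score"] = 0
        bed[["chrom", "start", "end", "name", "score", "strand"]].to_csv(
            out / "annotation" / f"{cls}.bed", sep="\t", index=False, header=False
        )
    expr = dataset.expression.values.copy()
    if dataset.expression.gene_lengths is not None:
        expr.insert(0, "length", dataset.expression.gene_lengths)
    expr.to_csv(out / "counts.tsv", sep="\t", index_label="gene_id")
    pd.Series(dataset.expression.groups).rename("group").to_csv(
        out / "groups.tsv", sep="\t", index_label="sample_id"
    )
    dataset.truth.dmrs.to_csv(out / "truth" / "planted_dmrs.tsv", sep="\t", index=False)
    dataset.truth.expression.to_csv(
        out / "truth" / "planted_expression.tsv", sep="\t", index=False
    )
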