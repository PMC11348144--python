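"""Differential methylation against an averaged normal-control profile.

The comparison design is one tumor methylome versus a panel of normal
controls collapsed into a per-CpG profile (the unweighted mean of the
per-control methylation percents).  A differentially methylated cytosine
(DMC) is a CpG whose tumor-minus-control difference is at least
``delta_threshold`` percentage points (default 10, boundary inclusive).
A differentially methylated region (DMR) is a maximal run of at least
``min_cpgs`` consecutive same-direction DMCs with adjacent positions at
most ``max_gap`` bp apart (defaults 3 and 100), accepted when a
Mann-Whitney U test over the member CpGs — tumor percents versus
control mean percents — gives p <= alpha (default 0.05, one-sided in
the run's direction).

A per-site rank test is degenerate at these group sizes (1 tumor value
vs a handful of controls cannot reach p < 0.05), so the significance
criterion lives at the region level; an optional per-site Fisher exact
proportion test on read counts is available instead.
"""

from __future__ import annotations

import dataclasses
import itertools
import logging
import math
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .io_formats import DMR, MethylomeSample

logger = logging.getLogger(__name__)

DMC_COLUMNS = [
    "chrom", "pos", "tumor_meth_pct", "control_meth_pct",
    "delta", "direction", "p_value",
]


# ---------------------------------------------------------------------------
# Mann-Whitney U with exact (tie-aware) enumeration
# ---------------------------------------------------------------------------

def _midranks(values: np.ndarray) -> np.ndarray:
    return stats.rankdata(values, method="average")


def mannwhitney_u(x: Sequence[float], y: Sequence[float]) -> float:
    """U statistic for sample ``x`` versus ``y``, midranks for ties."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ranks = _midranks(np.concatenate([x, y]))
    r1 = ranks[: len(x)].sum()
    return r1 - len(x) * (len(x) + 1) / 2.0


def mannwhitney_exact_p(
    x: Sequence[float],
    y: Sequence[float],
    alternative: Literal["less", "greater", "two-sided"] = "two-sided",
) -> float:
    """Exact Mann-Whitney p by enumeration of all C(n1+n2, n1) splits.

    Handles ties by permuting the observed pooled values themselves
    (every assignment of the pooled multiset to the two groups is
    equally likely under the null), so the null distribution is exact
    even with duplicated values.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n1, n2 = len(x), len(y)
    pooled = np.concatenate([x, y])
    ranks = _midranks(pooled)
    offset = n1 * (n1 + 1) / 2.0
    u_obs = ranks[:n1].sum() - offset

    total = math.comb(n1 + n2, n1)
    n_le = 0
    n_ge = 0
    eps = 1e-9
    for combo in itertools.combinations(range(n1 + n2), n1):
        u = ranks[list(combo)].sum() - offset
        if u <= u_obs + eps:
            n_le += 1
        if u >= u_obs - eps:
            n_ge += 1
    p_less = n_le / total
    p_greater = n_ge / total
    if alternative == "less":
        return p_less
    if alternative == "greater":
        return p_greater
    return min(1.0, 2.0 * min(p_less, p_greater))


def mannwhitney_normal_p(
    x: Sequence[float],
    y: Sequence[float],
    alternative: Literal["less", "greater", "two-sided"] = "two-sided",
) -> float:
    """Normal approximation with midranks, tie-corrected variance and
    continuity correction."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n1, n2 = len(x), len(y)
    n = n1 + n2
    u = mannwhitney_u(x, y)
    mu = n1 * n2 / 2.0
    pooled = np.concatenate([x, y])
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = (counts**3 - counts).sum()
    var = n1 * n2 / 12.0 * ((n + 1) - tie_term / (n * (n - 1)))
    if var <= 0:  # all values identical
        return 1.0
    sd = math.sqrt(var)
    if alternative == "less":
        z = (u - mu + 0.5) / sd
        return float(stats.norm.cdf(z))
    if alternative == "greater":
        z = (u - mu - 0.5) / sd
        return float(stats.norm.sf(z))
    z = (u - mu - math.copysign(0.5, u - mu)) / sd if u != mu else 0.0
    return float(min(1.0, 2.0 * stats.norm.sf(abs(z))))


def mannwhitney_p(
    x: Sequence[float],
    y: Sequence[float],
    alternative: Literal["less", "greater", "two-sided"] = "two-sided",
    exact_max_n: int = 8,
) -> float:
    """Exact enumeration when both sides have <= ``exact_max_n`` values,
    tie-corrected normal approximation otherwise."""
    if len(x) <= exact_max_n and len(y) <= exact_max_n:
        return mannwhitney_exact_p(x, y, alternative)
    return mannwhitney_normal_p(x, y, alternative)


# ---------------------------------------------------------------------------
# Control profile
# ---------------------------------------------------------------------------

@dataclass
class ControlProfile:
    """Averaged normal-control methylation profile.

    ``table`` columns: chrom, pos, mean_meth_pct (unweighted mean of the
    per-control percents, not a pooled-count percent), n_controls,
    meth_sum / unmeth_sum (pooled read counts, for the optional Fisher
    site test) and one ``pct_<sample>`` column per control.
    """

    table: pd.DataFrame
    control_ids: list[str]

    @property
    def pct_columns(self) -> list[str]:
        return [f"pct_{s}" for s in self.control_ids]

    def __len__(self) -> int:
        return len(self.table)


def build_control_profile(
    controls: Sequence[MethylomeSample],
    min_coverage: int = 5,
    require_all: bool = True,
) -> ControlProfile:
    """Average control methylomes into a per-CpG profile.

    A CpG enters the profile when it is covered >= ``min_coverage`` in
    every control (``require_all``, the default) or in at least one.
    """
    if not controls:
        raise ValueError("at least one control sample is required")
    ids = [c.sample_id for c in controls]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate control sample ids")

    frames = []
    for c in controls:
        cov = c.coverage
        keep = c.sites[cov >= min_coverage]
        frames.append(
            pd.DataFrame(
                {
                    "chrom": keep["chrom"],
                    "pos": keep["pos"],
                    f"pct_{c.sample_id}": 100.0
                    * keep["meth"]
                    / (keep["meth"] + keep["unmeth"]),
                    f"meth_{c.sample_id}": keep["meth"],
                    f"unmeth_{c.sample_id}": keep["unmeth"],
                }
            )
        )
    how = "inner" if require_all else "outer"
    merged = frames[0]
    for f in frames[1:]:
        merged = merged.merge(f, on=["chrom", "pos"], how=how)

    pct_cols = [f"pct_{s}" for s in ids]
    merged["mean_meth_pct"] = merged[pct_cols].mean(axis=1)
    merged["n_controls"] = merged[pct_cols].notna().sum(axis=1)
    merged["meth_sum"] = merged[[f"meth_{s}" for s in ids]].sum(axis=1).astype(int)
    merged["unmeth_sum"] = merged[[f"unmeth_{s}" for s in ids]].sum(axis=1).astype(int)
    merged = merged.drop(columns=[f"meth_{s}" for s in ids] + [f"unmeth_{s}" for s in ids])
    merged = merged.sort_values(["chrom", "pos"]).reset_index(drop=True)
    return ControlProfile(table=merged, control_ids=ids)


# ---------------------------------------------------------------------------
# CpG classification and DMC calling
# ---------------------------------------------------------------------------

def classify_cpgs(
    tumor: MethylomeSample,
    profile: ControlProfile,
    delta_threshold: float = 10.0,
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Classify every CpG common to tumor and profile as hypo, hyper or
    unchanged (boundary inclusive: |delta| >= threshold is differential).

    Returns the per-CpG table and the three class counts; the counts
    always sum to the size of the common CpG set.
    """
    t = tumor.sites.copy()
    t["tumor_meth_pct"] = tumor.meth_pct
    merged = t.merge(
        profile.table, on=["chrom", "pos"], how="inner", suffixes=("", "_ctl")
    )
    if merged.empty:
        raise ValueError("tumor and control profile share no CpGs")
    merged["delta"] = merged["tumor_meth_pct"] - merged["mean_meth_pct"]
    direction = np.where(
        merged["delta"] <= -delta_threshold,
        "hypo",
        np.where(merged["delta"] >= delta_threshold, "hyper", "unchanged"),
    )
    merged["direction"] = direction
    counts = {
        "hypo": int((direction == "hypo").sum()),
        "hyper": int((direction == "hyper").sum()),
        "unchanged": int((direction == "unchanged").sum()),
    }
    return merged, counts


def call_dmcs(
    tumor: MethylomeSample,
    profile: ControlProfile,
    delta_threshold: float = 10.0,
    site_test: Literal["none", "proportion"] = "none",
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Call differentially methylated cytosines.

    With ``site_test='proportion'`` each candidate additionally needs a
    Fisher exact p < alpha comparing tumor (meth, unmeth) read counts
    against the pooled control counts.
    """
    table, _ = classify_cpgs(tumor, profile, delta_threshold)
    dmcs = table[table["direction"] != "unchanged"].copy()
    dmcs["control_meth_pct"] = dmcs["mean_meth_pct"]
    dmcs["p_value"] = np.nan
    if site_test == "proportion" and not dmcs.empty:
        pvals = [
            stats.fisher_exact(
                [[row.meth, row.unmeth], [row.meth_sum, row.unmeth_sum]]
            )[1]
            for row in dmcs.itertuples()
        ]
        dmcs["p_value"] = pvals
        dmcs = dmcs[dmcs["p_value"] < alpha]
    elif site_test != "none" and site_test != "proportion":
        raise ValueError(f"unknown site_test {site_test!r}")
    return dmcs[DMC_COLUMNS].reset_index(drop=True)


# ---------------------------------------------------------------------------
# DMR segmentation and testing
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CandidateRegion:
    chrom: str
    positions: tuple[int, ...]
    direction: str

    @property
    def n_cpgs(self) -> int:
        return len(self.positions)


def segment_dmrs(
    dmcs: pd.DataFrame,
    min_cpgs: int = 3,
    max_gap: int = 100,
) -> list[CandidateRegion]:
    """Split sorted DMCs into maximal same-direction runs.

    A run breaks at a chromosome change, a direction flip, or when the
    distance between adjacent DMC positions exceeds ``max_gap`` bp.
    Runs shorter than ``min_cpgs`` are dropped.
    """
    out: list[CandidateRegion] = []
    if dmcs.empty:
        return out
    dmcs = dmcs.sort_values(["chrom", "pos"])
    run_pos: list[int] = []
    run_chrom = run_dir = None
    for chrom, pos, direction in zip(dmcs["chrom"], dmcs["pos"], dmcs["direction"]):
        breaks = (
            chrom != run_chrom
            or direction != run_dir
            or (run_pos and pos - run_pos[-1] > max_gap)
        )
        if breaks:
            if len(run_pos) >= min_cpgs:
                out.append(CandidateRegion(run_chrom, tuple(run_pos), run_dir))
            run_pos, run_chrom, run_dir = [], chrom, direction
        run_pos.append(pos)
    if len(run_pos) >= min_cpgs:
        out.append(CandidateRegion(run_chrom, tuple(run_pos), run_dir))
    return out


def test_dmr(
    candidate: CandidateRegion,
    tumor: MethylomeSample,
    profile: ControlProfile,
    alpha: float = 0.05,
    sided: Literal["one", "two"] = "one",
    sample_id: str | None = None,
) -> DMR | None:
    """Mann-Whitney test of a candidate region.

    The two series are the tumor per-CpG percents and the control mean
    per-CpG percents over the k member CpGs.  One-sided in the
    candidate's direction by default, accepted at p <= alpha
    (inclusive, so a 3-CpG perfect separation at exactly p = 0.05
    passes).  Returns the DMR or None when rejected.
    """
    pos = list(candidate.positions)
    t = tumor.sites.set_index(["chrom", "pos"])
    key = [(candidate.chrom, p) for p in pos]
    try:
        tsub = t.loc[key]
    except KeyError as exc:
        raise KeyError(f"member CpG missing from tumor sample: {exc}") from exc
    tumor_pct = (100.0 * tsub["meth"] / (tsub["meth"] + tsub["unmeth"])).to_numpy()
    p_idx = profile.table.set_index(["chrom", "pos"])
    try:
        control_pct = p_idx.loc[key, "mean_meth_pct"].to_numpy()
    except KeyError as exc:
        raise KeyError(f"member CpG missing from control profile: {exc}") from exc

    if sided == "one":
        alternative = "less" if candidate.direction == "hypo" else "greater"
    else:
        alternative = "two-sided"
    p = mannwhitney_p(tumor_pct, control_pct, alternative)
    if p > alpha:
        return None
    delta = tumor_pct - control_pct
    return DMR(
        sample_id=sample_id or tumor.sample_id,
        chrom=candidate.chrom,
        start_pos=pos[0],
        end_pos=pos[-1],
        positions=tuple(pos),
        direction=candidate.direction,
        mean_delta=float(delta.mean()),
        p_value=float(p),
    )


@dataclass
class DMRParams:
    """Knobs for the DMC -> DMR pipeline (defaults are the study's)."""

    delta_threshold: float = 10.0
    min_cpgs: int = 3
    max_gap: int = 100
    alpha: float = 0.05
    sided: Literal["one", "two"] = "one"
    site_test: Literal["none", "proportion"] = "none"
    bh_correct: bool = False


def call_sample_dmrs(
    tumor: MethylomeSample,
    profile: ControlProfile,
    params: DMRParams | None = None,
) -> list[DMR]:
    """Call DMRs for one tumor: DMCs -> segmentation -> region test."""
    params = params or DMRParams()
    dmcs = call_dmcs(
        tumor, profile, params.delta_threshold, params.site_test, params.alpha
    )
    candidates = segment_dmrs(dmcs, params.min_cpgs, params.max_gap)

    # Resolve member percents in bulk (test_dmr per candidate would
    # re-index the sample each call).
    t = tumor.sites.set_index(["chrom", "pos"])
    tumor_pct_all = 100.0 * t["meth"] / (t["meth"] + t["unmeth"])
    ctl = profile.table.set_index(["chrom", "pos"])["mean_meth_pct"]

    tested: list[DMR] = []
    pvals: list[float] = []
    for cand in candidates:
        key = [(cand.chrom, p) for p in cand.positions]
        tumor_pct = tumor_pct_all.loc[key].to_numpy()
        control_pct = ctl.loc[key].to_numpy()
        if params.sided == "one":
            alternative = "less" if cand.direction == "hypo" else "greater"
        else:
            alternative = "two-sided"
        p = mannwhitney_p(tumor_pct, control_pct, alternative)
        delta = tumor_pct - control_pct
        tested.append(
            DMR(
                sample_id=tumor.sample_id,
                chrom=cand.chrom,
                start_pos=cand.positions[0],
                end_pos=cand.positions[-1],
                positions=cand.positions,
                direction=cand.direction,
                mean_delta=float(delta.mean()),
                p_value=float(p),
            )
        )
        pvals.append(p)

    if params.bh_correct and pvals:
        adj = stats.false_discovery_control(pvals, method="bh")
        dmrs = [
            dataclasses.replace(d, p_value=float(q))
            for d, q in zip(tested, adj)
            if q <= params.alpha
        ]
    else:
        dmrs = [d for d in tested if d.p_value <= params.alpha]

    dmrs.sort(key=lambda d: (d.chrom, d.start_pos))
    n_hypo = sum(d.direction == "hypo" for d in dmrs)
    logger.info(
        "%s: %d DMCs -> %d candidates -> %d DMRs (%d hypo / %d hyper)",
        tumor.sample_id, len(dmcs), len(candidates), len(dmrs),
        n_hypo, len(dmrs) - n_hypo,
    )
    return dmrs
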