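"""Recovery metrics against planted truth, for benchmarking the caller
on synthetic cohorts."""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .io_formats import DMR, MethylomeSample


def dmr_recovery(dmrs: Sequence[DMR], truth: pd.DataFrame) -> dict:
    """Score called DMRs against planted regions for one tumor.

    A planted region counts as recovered when any call overlaps it by
    >= 1 bp; direction accuracy is over calls overlapping planted
    regions; false positives are calls overlapping no planted region.
    """
    recovered = 0
    correct_dir = 0
    overlapping = 0
    for _, row in truth.iterrows():
        hits = [
            d for d in dmrs
            if d.chrom == row["chrom"]
            and d.start_pos <= row["end_pos"]
            and d.end_pos >= row["start_pos"]
        ]
        recovered += bool(hits)
        overlapping += len(hits)
        correct_dir += sum(d.direction == row["direction"] for d in hits)
    false_pos = 0
    for d in dmrs:
        inside = (
            (truth["chrom"] == d.chrom)
            & (truth["start_pos"] <= d.end_pos)
            & (truth["end_pos"] >= d.start_pos)
        ).any()
        false_pos += not inside
    return {
        "n_planted": len(truth),
        "n_recovered": recovered,
        "sensitivity": recovered / len(truth) if len(truth) else float("nan"),
        "direction_accuracy": correct_dir / overlapping if overlapping else float("nan"),
        "n_false_positive": false_pos,
        "n_calls": len(dmrs),
    }


def candidate_window_count(
    sample: MethylomeSample, min_cpgs: int = 3, max_gap: int = 100
) -> int:
    """Number of runs of ``min_cpgs`` consecutive covered CpGs whose
    adjacent gaps are all <= ``max_gap`` — the denominator for a
    genome-wide false-call rate."""
    total = 0
    for _, grp in sample.sites.groupby("chrom", sort=False):
        pos = np.sort(grp["pos"].to_numpy())
        gaps = np.diff(pos) <= max_gap
        k = min_cpgs - 1
        if len(gaps) >= k:
            window_ok = np.convolve(gaps.astype(int), np.ones(k, dtype=int), "valid") == k
            total += int(window_ok.sum())
    return total


def coupled_gene_recovery(integrated: pd.DataFrame, truth_expression: pd.DataFrame) -> dict:
    """Fraction of planted coupled genes assigned their own class, plus
    the count assigned the opposite class (direction errors)."""
    coupled = truth_expression[truth_expression["kind"].str.startswith("coupled")]
    up = set(coupled.loc[coupled["kind"] == "coupled_hypo_up", "gene_id"])
    down = set(coupled.loc[coupled["kind"] == "coupled_hyper_down", "gene_id"])
    cls = integrated["class"]
    got_up = set(integrated.index[cls == "hypo_up"])
    got_down = set(integrated.index[cls == "hyper_down"])
    n_truth = len(up) + len(down)
    n_rec = len(got_up & up) + len(got_down & down)
    return {
        "n_planted": n_truth,
        "n_recovered": n_rec,
        "recovery": n_rec / n_truth if n_truth else float("nan"),
        "n_direction_errors": len(got_up & down) + len(got_down & up),
    }
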