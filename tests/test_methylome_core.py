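import itertools
import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import methylink as ml
from methylink.methylome_core import (
    CandidateRegion,
    DMRParams,
    build_control_profile,
    call_dmcs,
    call_sample_dmrs,
    classify_cpgs,
    mannwhitney_exact_p,
    mannwhitney_normal_p,
    segment_dmrs,
)
from methylink.methylome_core import test_dmr as region_test  # avoid pytest collection

from conftest import make_sample


# ---------------------------------------------------------------------------
# Independent oracles
# ---------------------------------------------------------------------------

def mwu_p_by_pair_counting(x, y, alternative):
    """Oracle: U from pairwise win/tie counting, null from enumerating
    every assignment of the pooled values to the two groups."""
    def u_stat(a, b):
        wins = sum(1 for xi in a for yj in b if xi > yj)
        ties = sum(1 for xi in a for yj in b if xi == yj)
        return wins + 0.5 * ties

    u_obs = u_stat(x, y)
    pooled = list(x) + list(y)
    n1 = len(x)
    n_le = n_ge = total = 0
    for combo in itertools.combinations(range(len(pooled)), n1):
        xs = [pooled[i] for i in combo]
        ys = [pooled[i] for i in range(len(pooled)) if i not in combo]
        u = u_stat(xs, ys)
        total += 1
        n_le += u <= u_obs + 1e-9
        n_ge += u >= u_obs - 1e-9
    if alternative == "less":
        return n_le / total
    if alternative == "greater":
        return n_ge / total
    return min(1.0, 2 * min(n_le, n_ge) / total)


class TestMannWhitney:
    def test_complete_separation_3v3(self):
        """3-vs-3 perfect separation: one-sided exact p = 1/C(6,3) = 0.05."""
        p = mannwhitney_exact_p([10, 12, 15], [80, 85, 90], "less")
        assert p == pytest.approx(1 / 20)

    def test_complete_separation_4v4(self):
        p = mannwhitney_exact_p([1, 2, 3, 4], [10, 20, 30, 40], "less")
        assert p == pytest.approx(1 / 70)

    @pytest.mark.parametrize("alternative", ["less", "greater", "two-sided"])
    @pytest.mark.parametrize(
        "x,y",
        [
            ([10, 12, 15], [80, 85, 90]),
            ([5, 40, 60], [10, 30, 90, 95]),
            ([1, 1, 2, 3], [1, 2, 2, 4]),  # heavy ties
            ([50.0] * 3, [50.0] * 3),  # all identical
            ([7, 2, 9, 9, 4], [3, 9, 1]),
        ],
    )
    def test_exact_matches_enumeration_oracle(self, x, y, alternative):
        assert mannwhitney_exact_p(x, y, alternative) == pytest.approx(
            mwu_p_by_pair_counting(x, y, alternative)
        )

    @pytest.mark.parametrize("alternative", ["less", "greater", "two-sided"])
    def test_exact_matches_scipy_on_tie_free_input(self, alternative):
        rng = np.random.default_rng(0)
        for _ in range(5):
            perm = rng.permutation(100).astype(float)
            x, y = perm[:6], perm[50:56]
            ours = mannwhitney_exact_p(x, y, alternative)
            ref = stats.mannwhitneyu(x, y, alternative=alternative, method="exact")[1]
            assert ours == pytest.approx(ref)

    def test_normal_approximation_close_to_scipy(self):
        rng = np.random.default_rng(1)
        x = rng.normal(40, 10, size=25)
        y = rng.normal(55, 10, size=25)
        ours = mannwhitney_normal_p(x, y, "less")
        ref = stats.mannwhitneyu(x, y, alternative="less", method="asymptotic")[1]
        assert ours == pytest.approx(ref, rel=1e-6)

    def test_identical_series_uninformative(self):
        assert mannwhitney_exact_p([50, 60, 70], [50, 60, 70], "less") >= 0.5


class TestControlProfile:
    def test_mean_is_unweighted_mean_of_percents(self):
        # coverages differ, so a pooled-count mean would give 86.7 not 90
        controls = [
            make_sample([("chr1", 100, 8, 2)], "c1", "control"),   # 80%
            make_sample([("chr1", 100, 18, 2)], "c2", "control"),  # 90%
            make_sample([("chr1", 100, 40, 0)], "c3", "control"),  # 100%
        ]
        prof = build_control_profile(controls, min_coverage=5)
        assert prof.table["mean_meth_pct"].iloc[0] == pytest.approx(90.0)
        assert prof.table["n_controls"].iloc[0] == 3

    def test_require_all_drops_partially_covered_sites(self):
        controls = [
            make_sample([("chr1", 100, 8, 2), ("chr1", 200, 8, 2)], "c1", "control"),
            make_sample([("chr1", 100, 8, 2)], "c2", "control"),
        ]
        prof = build_control_profile(controls, min_coverage=5, require_all=True)
        assert list(prof.table["pos"]) == [100]
        prof_any = build_control_profile(controls, min_coverage=5, require_all=False)
        assert list(prof_any.table["pos"]) == [100, 200]

    def test_single_control_profile_is_identity(self):
        c = make_sample([("chr1", 100, 8, 2), ("chr1", 200, 1, 9)], "c1", "control")
        prof = build_control_profile([c], min_coverage=5)
        assert list(prof.table["mean_meth_pct"]) == pytest.approx([80.0, 10.0])

    def test_empty_control_list_rejected(self):
        with pytest.raises(ValueError):
            build_control_profile([])


class TestClassifyAndDmcs:
    @staticmethod
    def profile_at(percents):
        controls = [
            make_sample(
                [("chr1", 100 * (i + 1), int(p), 100 - int(p)) for i, p in enumerate(percents)],
                "c1", "control",
            )
        ]
        return build_control_profile(controls, min_coverage=5)

    def test_boundary_inclusive(self):
        prof = self.profile_at([50, 50, 50])
        tumor = make_sample(
            [("chr1", 100, 40, 60), ("chr1", 200, 599, 401), ("chr1", 300, 60, 40)]
        )
        # deltas: -10.0 (hypo, inclusive), +9.9 (unchanged), +10.0 (hyper)
        _, counts = classify_cpgs(tumor, prof)
        assert counts == {"hypo": 1, "hyper": 1, "unchanged": 1}

    def test_counts_conserve_common_set(self, default_dataset):
        prof = build_control_profile(default_dataset.controls)
        tumor = default_dataset.tumors[0]
        table, counts = classify_cpgs(tumor, prof)
        assert sum(counts.values()) == len(table)

    def test_planted_direction_counts(self):
        rng = np.random.default_rng(7)
        base = rng.uniform(30, 70, size=100)
        deltas = np.zeros(100)
        deltas[:30] = -25
        deltas[30:50] = +25
        controls = [
            make_sample(
                [("chr1", 10 * (i + 1), int(round(b)), 100 - int(round(b)))
                 for i, b in enumerate(base)],
                "c1", "control",
            )
        ]
        prof = build_control_profile(controls)
        tumor = make_sample(
            [("chr1", 10 * (i + 1), int(round(b + d)), 100 - int(round(b + d)))
             for i, (b, d) in enumerate(zip(base, deltas))]
        )
        _, counts = classify_cpgs(tumor, prof)
        assert counts == {"hypo": 30, "hyper": 20, "unchanged": 50}

    def test_site_proportion_test_matches_hypergeometric_enumeration(self):
        # tumor 12/8 (60%) vs pooled controls 80/20 (80%): delta -20 but
        # the Fisher exact p exceeds 0.05, so the site is excluded
        controls = [make_sample([("chr1", 100, 16, 4)], f"c{i}", "control") for i in range(5)]
        prof = build_control_profile(controls)
        tumor = make_sample([("chr1", 100, 12, 8)])
        no_test = call_dmcs(tumor, prof, site_test="none")
        assert len(no_test) == 1 and no_test["direction"].iloc[0] == "hypo"
        with_test = call_dmcs(tumor, prof, site_test="proportion")
        assert len(with_test) == 0
        # oracle: full hypergeometric enumeration of the 2x2 null
        M, n, N = 120, 92, 20  # reads total, meth total, tumor reads
        probs = {k: stats.hypergeom.pmf(k, M, n, N) for k in range(0, 21)}
        p_obs = probs[12]
        p_enum = sum(p for p in probs.values() if p <= p_obs + 1e-12)
        p_scipy = stats.fisher_exact([[12, 8], [80, 20]])[1]
        assert p_scipy == pytest.approx(p_enum)
        assert p_enum > 0.05

    def test_identical_tumor_yields_no_dmcs(self):
        controls = [make_sample([("chr1", 100, 8, 2), ("chr1", 200, 5, 5)], "c1", "control")]
        prof = build_control_profile(controls)
        tumor = make_sample([("chr1", 100, 8, 2), ("chr1", 200, 5, 5)])
        assert len(call_dmcs(tumor, prof)) == 0

    def test_large_delta_kept_without_site_test(self):
        controls = [make_sample([("chr1", 100, 9, 1)], "c1", "control")]
        prof = build_control_profile(controls)
        tumor = make_sample([("chr1", 100, 11, 9)])  # 55% vs 90% -> delta -35
        dmcs = call_dmcs(tumor, prof, site_test="none")
        assert list(dmcs["direction"]) == ["hypo"]


# ---------------------------------------------------------------------------
# Segmentation
# ---------------------------------------------------------------------------

def dmc_frame(entries):
    return pd.DataFrame(
        entries, columns=["chrom", "pos", "direction"]
    ).assign(tumor_meth_pct=0.0, control_meth_pct=0.0, delta=0.0, p_value=np.nan)


def brute_force_runs(dmcs, min_cpgs, max_gap):
    """Oracle: test every contiguous index range for run validity and
    maximality."""
    recs = sorted(
        dmcs[["chrom", "pos", "direction"]].itertuples(index=False), key=lambda r: (r.chrom, r.pos)
    )
    n = len(recs)

    def valid(i, j):  # inclusive range
        sub = recs[i: j + 1]
        if len({(r.chrom, r.direction) for r in sub}) != 1:
            return False
        return all(
            sub[k + 1].pos - sub[k].pos <= max_gap for k in range(len(sub) - 1)
        )

    out = []
    for i in range(n):
        for j in range(i + min_cpgs - 1, n):
            if not valid(i, j):
                continue
            if i > 0 and valid(i - 1, j):
                continue
            if j < n - 1 and valid(i, j + 1):
                continue
            out.append((recs[i].chrom, tuple(r.pos for r in recs[i: j + 1]),
                        recs[i].direction))
    return set(out)


class TestSegmentation:
    def test_three_cpgs_within_gap(self):
        cands = segment_dmrs(dmc_frame([("chr1", 10, "hypo"), ("chr1", 60, "hypo"),
                                        ("chr1", 140, "hypo")]))
        assert len(cands) == 1
        assert cands[0].positions == (10, 60, 140)

    def test_direction_flip_breaks_run(self):
        cands = segment_dmrs(dmc_frame([("chr1", 10, "hypo"), ("chr1", 60, "hypo"),
                                        ("chr1", 100, "hyper")]))
        assert cands == []

    def test_gap_boundary_101_breaks_run(self):
        cands = segment_dmrs(dmc_frame([("chr1", 10, "hypo"), ("chr1", 60, "hypo"),
                                        ("chr1", 161, "hypo")]))
        assert cands == []
        cands = segment_dmrs(dmc_frame([("chr1", 10, "hypo"), ("chr1", 60, "hypo"),
                                        ("chr1", 160, "hypo")]))
        assert len(cands) == 1

    def test_empty_input(self):
        assert segment_dmrs(dmc_frame([])) == []

    def test_matches_brute_force_on_random_inputs(self):
        """Segmentation equals exhaustive maximal-run search, 100 seeds."""
        for seed in range(100):
            rng = np.random.default_rng(seed)
            n = int(rng.integers(0, 51))
            chroms = rng.choice(["chr1", "chr2"], size=n)
            pos = {c: iter(sorted(rng.choice(2000, size=n, replace=False))) for c in ["chr1", "chr2"]}
            entries = sorted(
                (c, int(next(pos[c])), rng.choice(["hypo", "hyper"]))
                for c in chroms
            )
            df = dmc_frame(entries)
            got = {
                (c.chrom, c.positions, c.direction) for c in segment_dmrs(df)
            }
            assert got == brute_force_runs(df, 3, 100), f"seed {seed}"


class TestRegionTest:
    @staticmethod
    def cohort(tumor_pcts, control_pcts, positions=None):
        positions = positions or [100 + 50 * i for i in range(len(tumor_pcts))]
        controls = [
            make_sample(
                [("chr1", p, int(round(c * 10)), 1000 - int(round(c * 10)))
                 for p, c in zip(positions, control_pcts)],
                "c1", "control",
            )
        ]
        tumor = make_sample(
            [("chr1", p, int(round(t * 10)), 1000 - int(round(t * 10)))
             for p, t in zip(positions, tumor_pcts)],
            "T1",
        )
        prof = build_control_profile(controls)
        cand = CandidateRegion("chr1", tuple(positions), "hypo")
        return cand, tumor, prof

    def test_three_cpg_separation_accepted_at_inclusive_alpha(self):
        cand, tumor, prof = self.cohort([10, 12, 15], [80, 85, 90])
        dmr = region_test(cand, tumor, prof)
        assert dmr is not None
        assert dmr.p_value == pytest.approx(0.05)
        assert dmr.mean_delta == pytest.approx(np.mean([10 - 80, 12 - 85, 15 - 90]), abs=0.2)

    def test_four_cpg_separation_p_1_over_70(self):
        cand, tumor, prof = self.cohort([10, 12, 15, 20], [80, 85, 90, 95])
        dmr = region_test(cand, tumor, prof)
        assert dmr.p_value == pytest.approx(1 / 70)

    def test_identical_series_rejected(self):
        cand, tumor, prof = self.cohort([50, 60, 70], [50, 60, 70])
        assert region_test(cand, tumor, prof) is None

    def test_two_sided_mode_doubles_p(self):
        cand, tumor, prof = self.cohort([10, 12, 15], [80, 85, 90])
        dmr = region_test(cand, tumor, prof, alpha=0.2, sided="two")
        assert dmr.p_value == pytest.approx(0.1)


class TestCallSampleDmrs:
    def test_tumor_equal_to_control_sample_yields_no_dmrs(self):
        records = [("chr1", 100 + 10 * i, 8, 2) for i in range(50)]
        control = make_sample(records, "c1", "control")
        tumor = make_sample(records, "T1")
        prof = build_control_profile([control])
        assert call_sample_dmrs(tumor, prof) == []

    def test_planted_block_recovery_with_read_noise(self):
        """50 planted hypo blocks (delta -30, 6 CpGs, coverage 30) are
        nearly all recovered with the right direction."""
        cfg = ml.default_config(
            seed=21,
            planted_dmrs=[ml.PlantedDMRSpec(n_regions=50, direction="hypo", delta=-30.0)],
            n_tumors=1,
        )
        ds = ml.simulate(cfg)
        prof = build_control_profile(ds.controls)
        dmrs = call_sample_dmrs(ds.tumors[0], prof)
        truth = ds.truth.dmrs
        recovered = 0
        for _, row in truth.iterrows():
            hits = [
                d for d in dmrs
                if d.chrom == row.chrom and d.start_pos <= row.end_pos
                and d.end_pos >= row.start_pos
            ]
            recovered += bool(hits)
            assert all(d.direction == "hypo" for d in hits)
        assert recovered >= 45
        # no hyper call may fall inside a hypo block
        for d in dmrs:
            if d.direction == "hyper":
                inside = (
                    (truth["chrom"] == d.chrom)
                    & (truth["start_pos"] <= d.end_pos)
                    & (truth["end_pos"] >= d.start_pos)
                ).any()
                assert not inside

    def test_doubling_max_gap_never_loses_member_cpgs(self, default_dataset):
        prof = build_control_profile(default_dataset.controls)
        tumor = default_dataset.tumors[0]
        narrow = call_sample_dmrs(tumor, prof, DMRParams(max_gap=100))
        wide = call_sample_dmrs(tumor, prof, DMRParams(max_gap=200))
        for d in narrow:
            containing = [
                w for w in wide
                if w.chrom == d.chrom and w.start_pos <= d.end_pos and w.end_pos >= d.start_pos
                and w.direction == d.direction
            ]
            assert sum(w.n_cpgs for w in containing) >= d.n_cpgs

    def test_dmr_invariants(self, default_analysis):
        """Members are DMCs, p <= alpha, gaps within bound."""
        for dmrs in default_analysis.dmrs.values():
            for d in dmrs:
                assert d.p_value <= 0.05
                assert d.n_cpgs >= 3
                gaps = np.diff(d.positions)
                assert (gaps <= 100).all()
                sign = -1 if d.direction == "hypo" else 1
                assert sign * d.mean_delta > 0
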