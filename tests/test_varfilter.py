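"""Filter-cascade tests: scoring, consensus, orientation, trajectories, oracle parity."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import stats

from _oracles import (
    oracle_cascade_keep,
    oracle_qual,
    random_pileup_table,
)
from degensim.seqsim import PileupSite, SeqParams, simulate_pileup_batch
from degensim.varfilter import (
    AlleleTrajectory,
    FilterParams,
    MultiallelicPileup,
    StructureError,
    consensus_call,
    orientation_filter,
    run_filter_cascade,
    score_site,
    split_multiallelic,
    trajectory_filter,
)


def site(fwd_ref, fwd_alt, rev_ref, rev_alt, bq=30.0, pos=100):
    return PileupSite("chrom", pos, "C", "A", fwd_ref, fwd_alt, rev_ref, rev_alt, bq)


class TestScoreSite:
    def test_zero_alt_scores_zero(self):
        assert score_site(site(100, 0, 100, 0), 0.001) == 0.0

    def test_matches_exact_binomial_oracle_and_exceeds_100(self):
        """Depth 400 / alt 40 at e=0.003: survival-function oracle agrees and
        clears the QUAL>=100 bar."""
        s = site(180, 20, 180, 20)
        got = score_site(s, 0.003)
        expected = oracle_qual(40, 400, 0.003)
        assert got == pytest.approx(expected, rel=1e-6)
        assert got > 100

    def test_monotone_nondecreasing_in_alt(self):
        quals = [
            score_site(site(200 - a, a, 200, 0), 0.001) for a in range(0, 60, 3)
        ]
        assert all(b >= a for a, b in zip(quals, quals[1:]))

    def test_zero_depth_is_an_error(self):
        with pytest.raises(ValueError):
            score_site(site(0, 0, 0, 0), 0.001)

    def test_cap_applies(self):
        assert score_site(site(0, 500, 0, 500), 0.001) == 5000.0


class TestConsensusCall:
    def test_zero_alt_flagged_low_qual(self):
        call = consensus_call(site(184, 0, 184, 0), FilterParams(), 0.001)
        assert "low_qual" in call.filters

    def test_clean_half_af_site_passes_both_criteria(self):
        call = consensus_call(site(92, 92, 92, 92), FilterParams(), 0.001)
        assert call.filters == set()
        assert call.qual >= 100

    def test_strand_biased_site_retained_with_label(self):
        """Criterion A can pass while criterion B fails; the call is labelled,
        never dropped."""
        call = consensus_call(site(10, 40, 150, 0), FilterParams(), 0.001)
        assert "no_consensus" in call.filters
        assert call.qual >= 100
        assert call.chrom == "chrom"


class TestOrientationFilter:
    def test_passes_above_threshold_both_strata(self):
        call = consensus_call(site(45, 5, 54, 6), FilterParams(), 0.001)
        call = orientation_filter(call, FilterParams())
        assert "low_orientation_af" not in call.filters
        assert "low_reads" not in call.filters

    def test_one_stratum_below_threshold_fails(self):
        call = orientation_filter(
            consensus_call(site(95, 5, 97, 3), FilterParams(), 0.001), FilterParams()
        )
        assert "low_orientation_af" in call.filters

    def test_exactly_at_threshold_fails_strict_rule(self):
        # 4/100 = 0.04 exactly: the rule requires strictly above 0.04
        call = orientation_filter(
            consensus_call(site(96, 4, 90, 10), FilterParams(), 0.001), FilterParams()
        )
        assert "low_orientation_af" in call.filters

    def test_shallow_stratum_fails_min_reads(self):
        call = orientation_filter(
            consensus_call(site(1, 2, 100, 50), FilterParams(), 0.001), FilterParams()
        )
        assert "low_reads" in call.filters

    def test_total_mode_counts_pooled_depth(self):
        params = FilterParams(min_reads_mode="total")
        call = orientation_filter(
            consensus_call(site(1, 2, 100, 50), params, 0.001), params
        )
        assert "low_reads" not in call.filters

    def test_low_base_quality_fails(self):
        call = orientation_filter(
            consensus_call(site(45, 5, 54, 6, bq=15.0), FilterParams(), 0.001),
            FilterParams(),
        )
        assert "low_reads" in call.filters


class TestSplitMultiallelic:
    def test_single_alt_identity(self):
        rec = MultiallelicPileup("chrom", 10, "C", ("A",), 50, 50, (5,), (6,))
        calls = split_multiallelic(rec)
        assert len(calls) == 1
        assert calls[0].alt == "A" and calls[0].fwd_alt == 5

    def test_two_alts_preserve_counts_and_af_sum(self):
        rec = MultiallelicPileup("chrom", 10, "C", ("A", "T"), 40, 40, (5, 10), (5, 10))
        calls = split_multiallelic(rec)
        assert [c.alt for c in calls] == ["A", "T"]
        assert calls[0].pos == calls[1].pos == 10
        af_sum = sum((c.fwd_alt + c.rev_alt) for c in calls)
        assert af_sum == 30

    def test_round_trip_recovers_alt_set(self):
        rec = MultiallelicPileup("chrom", 7, "G", ("T", "A", "C"), 30, 30, (1, 2, 3), (4, 5, 6))
        calls = split_multiallelic(rec)
        regrouped = {}
        for c in calls:
            regrouped.setdefault((c.chrom, c.pos, c.ref), set()).add(c.alt)
        assert regrouped == {("chrom", 7, "G"): {"T", "A", "C"}}


class TestTrajectoryFilter:
    @staticmethod
    def traj(afs, subs=None, depths=None, pos=500):
        subs = subs if subs is not None else list(range(len(afs)))
        depths = depths or [368] * len(afs)
        return AlleleTrajectory("chrom", pos, "C", "A", "rep1", subs, afs, depths)

    def test_three_recurrences_keep(self):
        keep, labels = trajectory_filter(self.traj([0.01, 0.09, 0.12, 0.30]), FilterParams())
        assert keep and not labels

    def test_two_recurrences_drop(self):
        keep, labels = trajectory_filter(self.traj([0.09, 0.09, 0.05, 0.02]), FilterParams())
        assert not keep and labels == {"insufficient_recurrence"}

    def test_starter_background(self):
        keep, labels = trajectory_filter(self.traj([0.6, 0.2, 0.3, 0.4]), FilterParams())
        assert "starter_background" in labels

    def test_rrna_exclusion(self):
        keep, labels = trajectory_filter(
            self.traj([0.1, 0.2, 0.3, 0.4], pos=500),
            FilterParams(),
            exclusions=[("chrom", 400, 600)],
        )
        assert "rrna" in labels

    def test_depth_artifact_screen(self):
        """AF tracking depth across >=6 subcultures flags the generalized
        depth-correlation artifact rule."""
        depths = [100, 150, 200, 250, 300, 350, 400]
        afs = [0.10, 0.12, 0.15, 0.18, 0.22, 0.26, 0.30]
        keep, labels = trajectory_filter(
            self.traj(afs, depths=depths), FilterParams()
        )
        assert "depth_artifact" in labels
        keep2, labels2 = trajectory_filter(
            self.traj(afs, depths=depths), FilterParams(depth_corr_threshold=None)
        )
        assert "depth_artifact" not in labels2

    def test_consecutive_mode(self):
        afs = [0.1, 0.0, 0.1, 0.0, 0.1]
        assert trajectory_filter(self.traj(afs), FilterParams())[0]
        keep, labels = trajectory_filter(
            self.traj(afs), FilterParams(require_consecutive=True)
        )
        assert not keep and "insufficient_recurrence" in labels

    def test_label_accumulation_is_monotone(self):
        """Each violated rule appends its own label; keep iff the set is empty."""
        keep, labels = trajectory_filter(
            self.traj([0.6, 0.05, 0.02, 0.01], pos=450),
            FilterParams(),
            exclusions=[("chrom", 400, 600)],
        )
        assert not keep
        assert labels == {"insufficient_recurrence", "rrna", "starter_background"}

    @given(st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=1, max_size=10))
    def test_keep_iff_no_labels(self, afs):
        keep, labels = trajectory_filter(self.traj(afs), FilterParams())
        assert keep == (not labels)


class TestCascade:
    def test_empty_input(self):
        res = run_filter_cascade(pd.DataFrame(columns=["chrom"]).iloc[0:0])
        assert res.calls.empty and res.variants.empty and res.trajectories.empty

    def test_duplicate_rows_are_structural_error(self, rng):
        df = random_pileup_table(rng, 2, 3)
        dup = pd.concat([df, df.iloc[[0]]], ignore_index=True)
        with pytest.raises(StructureError):
            run_filter_cascade(dup)

    def test_cascade_equals_bruteforce_rule_oracle(self, rng):
        """Keep-set and label sets match an independent rule-by-rule evaluation."""
        df = random_pileup_table(rng, 60, 6)
        exclusions = [("chrom", 1, 50_000)]
        res = run_filter_cascade(df, error_rate=0.001, exclusions=exclusions)
        expected = oracle_cascade_keep(df, 0.001, exclusions)
        got = {
            (r.replicate, r.chrom, r.pos, r.ref, r.alt): set(
                r.labels.split(",")
            ) - {""}
            for r in res.variants.itertuples()
        }
        assert got == expected
        for key, labels in expected.items():
            keep = res.variants[
                (res.variants["pos"] == key[2]) & (res.variants["replicate"] == key[0])
            ]["keep"].iloc[0]
            assert keep == (not labels)

    def test_site_pass_iff_no_labels(self, rng):
        df = random_pileup_table(rng, 30, 4)
        res = run_filter_cascade(df)
        assert (res.calls["site_pass"] == (res.calls["labels"] == "")).all()

    def test_deterministic(self, rng):
        df = random_pileup_table(rng, 20, 4)
        a = run_filter_cascade(df)
        b = run_filter_cascade(df)
        pd.testing.assert_frame_equal(a.variants, b.variants)

    def test_high_af_variant_survives_cascade(self):
        """A true 50% variant at default depth across subcultures 1-5 is kept
        in >=99% of seeded runs (binomial power oracle regime)."""
        params = SeqParams(error_rate=0.001)
        kept = 0
        n_runs = 300
        rng = np.random.default_rng(77)
        for _ in range(n_runs):
            batch = simulate_pileup_batch(np.full(5, 0.5), params, rng)
            batch["chrom"] = "chrom"
            batch["pos"] = 1234
            batch["ref"] = "C"
            batch["alt"] = "A"
            batch["subculture"] = range(1, 6)
            batch["replicate"] = "rep1"
            res = run_filter_cascade(batch, error_rate=params.error_rate)
            kept += int(res.variants["keep"].iloc[0])
        assert kept / n_runs >= 0.99

    def test_detection_limit_orientation_stage(self, rng):
        """Pass rate of the orientation filter: <5% at true AF 0.02, >95% at 0.10."""
        from degensim.varfilter import VariantCall

        params = SeqParams(error_rate=0.001)
        fp = FilterParams()
        for af, low, high in [(0.02, 0.0, 0.05), (0.10, 0.95, 1.0)]:
            batch = simulate_pileup_batch(np.full(3000, af), params, rng)
            passes = 0
            for row in batch.itertuples():
                call = VariantCall(
                    "chrom", 1, "C", "A",
                    fwd_ref=row.fwd_ref, fwd_alt=row.fwd_alt,
                    rev_ref=row.rev_ref, rev_alt=row.rev_alt,
                    mean_bq=row.mean_bq,
                )
                passes += int(not orientation_filter(call, fp).filters)
            rate = passes / len(batch)
            assert low <= rate <= high
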