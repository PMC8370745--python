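"""Gate-by-gate behavior of the translation caller and the consensus logic."""

import math

import numpy as np
import pandas as pd
import pytest

from smorfkit import (
    CallThresholds,
    SimulationConfig,
    call_orfs,
    condition_consensus,
    condition_sets,
    enumerate_transcriptome,
    generate_transcriptome,
    multimap_filter,
    orf_psite_stats,
    replicate_pass,
    select_start,
    simulate_reads,
)
from smorfkit.psite_calibration import assign_psites_calibrated, calibrate
from smorfkit.synthetic_data import control_lncRNAs
from smorfkit.translation_calling import ReplicateORFStats


def exact_binom_tail(k, n, p=1 / 3):
    """Independent oracle: P(X >= k) by direct enumeration."""
    return sum(
        math.comb(n, j) * p**j * (1 - p) ** (n - j) for j in range(k, n + 1)
    )


def stats_for(rel_offsets, start=0, end=300, multimapping=None):
    pos = np.asarray([start + o for o in rel_offsets])
    mm = np.asarray(multimapping) if multimapping is not None else None
    return orf_psite_stats(start, end, pos, mm)


class TestORFPsiteStats:
    def test_all_in_frame(self):
        s = stats_for([0, 3, 6, 9])
        assert (s.n_psites, s.in_frame_fraction) == (4, 1.0)

    def test_half_in_frame(self):
        s = stats_for([0, 3, 1, 2])
        assert (s.n_psites, s.in_frame_fraction) == (4, 0.5)

    def test_none_in_frame(self):
        s = stats_for([1, 2])
        assert (s.n_psites, s.in_frame_fraction) == (2, 0.0)

    def test_zero_psites_flagged_undefined(self):
        s = stats_for([])
        assert s.n_psites == 0 and math.isnan(s.in_frame_fraction)

    def test_psites_outside_span_ignored(self):
        s = stats_for([-3, 0, 3, 300])
        assert s.n_psites == 2

    def test_coverage_and_multimap_only_positions(self):
        # positions 0 and 3 covered; 3 supported only by multimapping reads
        s = stats_for([0, 0, 3, 3], multimapping=[False, True, True, True])
        assert s.covered_positions == 2
        assert s.multimap_only_positions == 1


class TestReplicatePass:
    @pytest.mark.parametrize(
        "n, k, expect",
        [
            (6, 5, True),    # p ~ 0.018: periodic, passes all three gates
            (4, 4, False),   # fails the more-than-five count gate
            (12, 5, False),  # 5/12 < 0.5 fails the framing gate
            (6, 3, False),   # 0.5 framing but binomial p ~ 0.32: not periodic
        ],
    )
    def test_stated_examples(self, n, k, expect):
        rel = [3 * i for i in range(k)] + [3 * i + 1 for i in range(n - k)]
        s = stats_for(rel)
        assert replicate_pass(s) is expect
        if s.n_psites >= 6 and s.in_frame_fraction >= 0.5:
            # decision must match the independent exact tail
            assert (exact_binom_tail(k, n) <= 0.05) is expect

    def test_pvalue_matches_enumeration_oracle(self):
        for n, k in [(6, 5), (6, 6), (10, 7), (20, 10), (30, 15)]:
            rel = [3 * i for i in range(k)] + [3 * i + 1 for i in range(n - k)]
            s = stats_for(rel)
            replicate_pass(s)
            assert s.periodicity_p == pytest.approx(exact_binom_tail(k, n), rel=1e-9)


class TestMultimapFilter:
    def make(self, covered, mm_only):
        return ReplicateORFStats("o", "r", "c", 10, 0.8, covered, mm_only)

    def test_above_threshold_discarded(self):
        assert multimap_filter(self.make(10, 4)) is False  # 0.4 > 0.3

    def test_boundary_is_retained_strict_inequality(self):
        assert multimap_filter(self.make(10, 3)) is True  # exactly 0.30

    def test_no_multimap_retained(self):
        assert multimap_filter(self.make(10, 0)) is True


class TestSelectStart:
    def test_upstream_start_with_enough_support(self):
        assert select_start([0, 30], np.arange(0, 18, 3)) == 0  # 6 P-sites in [0, 30)

    def test_upstream_start_without_support_skipped(self):
        assert select_start([0, 30], np.array([0, 3, 6])) == 30

    def test_single_atg_unconditional(self):
        assert select_start([12], np.array([])) == 12

    def test_no_qualifying_atg_returns_most_downstream(self):
        assert select_start([0, 30, 60], np.array([1, 2])) == 60


class TestConsensus:
    @pytest.mark.parametrize(
        "passes, called, n", [((True, True, False), True, 2),
                              ((True, False, False), False, 1),
                              ((True, True, True), True, 3)]
    )
    def test_at_least_two_of_three(self, passes, called, n):
        per_rep = [(f"rep{i}", 10, p) for i, p in enumerate(passes)]
        call = condition_consensus(per_rep, min_replicates=2)
        assert call.called is called and call.n_replicates_passing == n

    def test_consensus_start_is_most_upstream_passing(self):
        per_rep = [("rep1", 30, True), ("rep2", 0, True), ("rep3", 12, False)]
        assert condition_consensus(per_rep).selected_start == 0


class TestConditionSets:
    def calls_frame(self, a_ids, b_ids):
        rows = []
        for cond, ids in [("Control", a_ids), ("RA", b_ids)]:
            for i in ids:
                rows.append(
                    dict(
                        orf_id=f"T{i}_0_90",
                        transcript_id=f"T{i}",
                        selected_start=0,
                        end=90,
                        frame=0,
                        condition=cond,
                        category="lncRNA_smORF",
                        length_codons=29,
                        n_replicates_passing=3,
                        called=True,
                    )
                )
        return pd.DataFrame(rows)

    def test_union_by_inclusion_exclusion(self):
        # 28 in one condition, 23 in the other, 6 shared -> union 45
        calls = self.calls_frame(range(28), list(range(6)) + list(range(28, 45)))
        sets = condition_sets(calls)
        assert sets.sizes == {"Control": 28, "RA": 23}
        assert sets.intersection == 6
        assert sets.union == 45
        assert sets.union == 28 + 23 - sets.intersection

    def test_disjoint_and_identical_sets(self):
        sets = condition_sets(self.calls_frame(range(3), range(3, 7)))
        assert (sets.union, sets.intersection) == (7, 0)
        sets = condition_sets(self.calls_frame(range(5), range(5)))
        assert sets.union == sets.intersection == 5

    def test_category_tally_shape(self):
        sets = condition_sets(self.calls_frame(range(2), range(1)))
        assert sets.category_counts.loc["lncRNA_smORF", "Control"] == 2
        assert sets.category_counts.loc["lncRNA_smORF", "RA"] == 1


def _pipeline(seed, **config_kwargs):
    config = SimulationConfig(seed=seed, **config_kwargs)
    txs, manifest = generate_transcriptome(config)
    reads = simulate_reads(txs, manifest, config)
    ribo = reads[reads["assay"] == "ribo"]
    psites = assign_psites_calibrated(ribo, calibrate(ribo, txs), txs)
    orfs = enumerate_transcriptome(txs)
    return config, txs, manifest, psites, orfs


class TestEndToEnd:
    def test_planted_smorfs_recovered_controls_clean(self):
        config, txs, manifest, psites, orfs = _pipeline(31)
        calls, repstats = call_orfs(orfs, psites)
        called = calls[calls["called"]]
        keys = set(
            map(tuple, called[["transcript_id", "end", "condition"]].itertuples(index=False))
        )
        smorfs = manifest[manifest["category"] == "lncRNA_smORF"]
        hits = total = 0
        for row in smorfs.itertuples():
            for cond in row.conditions.split(";"):
                total += 1
                hits += (row.transcript_id, row.end, cond) in keys
        assert hits / total >= 0.9
        controls = set(control_lncRNAs(txs, manifest))
        assert called[called["transcript_id"].isin(controls)].empty

    def test_every_call_auditable_from_replicate_table(self):
        _, _, _, psites, orfs = _pipeline(32, n_protein_coding=6, n_lncRNA=10)
        th = CallThresholds()
        calls, repstats = call_orfs(orfs, psites, th)
        merged = repstats.groupby(["transcript_id", "end", "condition"])["passes"].sum()
        for row in calls[calls["called"]].itertuples():
            assert merged[(row.transcript_id, row.end, row.condition)] >= th.min_replicates
        # audit every passing replicate against the stated gates
        passing = repstats[repstats["passes"]]
        assert (passing["n_psites"] > 5).all()
        assert (passing["in_frame_fraction"] >= 0.5).all()
        assert (passing["periodicity_p"] <= 0.05).all()
        frac = passing["multimap_only_positions"] / passing["covered_positions"]
        assert (frac <= 0.30).all()

    def test_relaxing_consensus_only_grows_called_set(self):
        _, _, _, psites, orfs = _pipeline(33, n_protein_coding=6, n_lncRNA=10)
        strict, _ = call_orfs(orfs, psites, CallThresholds(min_replicates=2))
        loose, _ = call_orfs(orfs, psites, CallThresholds(min_replicates=1))
        key = ["transcript_id", "end", "frame", "condition"]
        s = set(map(tuple, strict[strict["called"]][key].itertuples(index=False)))
        l = set(map(tuple, loose[loose["called"]][key].itertuples(index=False)))
        assert s <= l

    def test_call_rate_monotone_in_depth_and_framing(self):
        def call_rate(depth, p_if, seed=34):
            from smorfkit import PlantedTranslation

            config, txs, manifest, psites, orfs = None, None, None, None, None
            cfg = SimulationConfig(
                seed=seed, n_protein_coding=6, n_lncRNA=24, n_translated_lncRNA=24,
                conditions=("Control",),
                planted=PlantedTranslation(depth=depth, in_frame_prob=p_if),
            )
            txs, manifest = generate_transcriptome(cfg)
            reads = simulate_reads(txs, manifest, cfg)
            ribo = reads[reads["assay"] == "ribo"]
            psites = assign_psites_calibrated(ribo, calibrate(ribo, txs), txs)
            orfs = enumerate_transcriptome(txs)
            calls, _ = call_orfs(orfs, psites)
            called = set(
                map(tuple, calls[calls["called"]][["transcript_id", "end"]].itertuples(index=False))
            )
            smorfs = manifest[manifest["category"] == "lncRNA_smORF"]
            return np.mean(
                [(r.transcript_id, r.end) in called for r in smorfs.itertuples()]
            )

        by_depth = [call_rate(d, 0.85) for d in (5, 25, 100)]
        assert by_depth == sorted(by_depth)
        by_framing = [call_rate(50, p) for p in (0.40, 0.60, 0.95)]
        assert by_framing == sorted(by_framing)
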