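import numpy as np
import pytest

from tandemcall import align_core as ac
from tandemcall import consensus_profile as cp
from tandemcall import synthetic_locus as sl
from tandemcall.io_formats import AlignmentRow
from conftest import mini_preset, random_seq


def perfect_row(read_id, ref_len, start=0):
    n = ref_len - start
    return AlignmentRow(read_id, "ref", 0, n, start, ref_len, "+",
                        float(n), 1.0, 0.0, f"{n}=")


def map_all(reads, locus, model, seed=0):
    idx = ac.KmerIndex(locus.sequence)
    rng = np.random.default_rng(seed)
    alns, seqs = [], {}
    for r in reads:
        row = ac.map_read(r.sequence, locus.sequence, model, index=idx,
                          rng=rng, query_id=r.read_id)
        if row is not None:
            alns.append(row)
            seqs[r.read_id] = r.sequence
    return alns, seqs


class TestPileup:
    def test_unanimous_columns(self):
        ref = "ACGTT" * 20
        rows = [perfect_row(f"r{i}", len(ref)) for i in range(5)]
        reads = {f"r{i}": ref for i in range(5)}
        pile = cp.build_pileup(rows, reads, ref)
        assert (pile.depth == 5).all()
        assert (pile.counts.max(axis=1) == 5).all()

    def test_deletion_tally(self):
        ref = "A" * 120 + "C" + "G" * 120
        read = ref[:100] + ref[101:]  # drop ref position 100
        row = AlignmentRow("r", "ref", 0, len(read), 0, len(ref), "+",
                           200.0, 0.99, 0.0, "100=1D140=")
        pile = cp.build_pileup([row], {"r": read}, ref)
        assert pile.counts[100, cp.DEL] == 1
        assert pile.depth[100] == 1

    def test_unknown_read_id_rejected(self):
        with pytest.raises(cp.PileupError):
            cp.build_pileup([perfect_row("ghost", 10)], {}, "ACGTACGTAC")

    def test_tallies_match_ledger_on_sub_only_reads(self, model, mini_locus):
        """Substitution-only reads align unambiguously, so pileup tallies
        must equal the simulator's ledger counts per column."""
        spec = sl.ErrorSpec(p_sub=0.08, p_ins=0, p_del=0, seed=13)
        reads = sl.simulate_reads(mini_locus, spec, mode="coverage",
                                  coverage=6, length_median=900)
        alns, seqs = map_all(reads, mini_locus, model)
        assert len(alns) == len(reads)
        pile = cp.build_pileup(alns, seqs, mini_locus.sequence)
        L = len(mini_locus.sequence)
        cov = np.zeros(L, int)
        subs = np.zeros((L, 4), int)
        for r in reads:
            cov[r.true_start:r.true_end] += 1
            for pos, typ, ref, alt in r.edits:
                subs[pos, "ACGT".index(alt)] += 1
        assert (pile.depth == cov).all()
        for b in range(4):
            ref_is_b = np.frombuffer(mini_locus.sequence.encode(),
                                     np.uint8) == ord("ACGT"[b])
            expected = np.where(ref_is_b, cov - subs.sum(axis=1) + subs[:, b],
                                subs[:, b])
            assert (pile.counts[:, b] == expected).all()

    def test_depth_conservation(self, model, mini_locus):
        spec = sl.ErrorSpec(p_sub=0.10, p_ins=0.01, p_del=0.01, seed=14)
        reads = sl.simulate_reads(mini_locus, spec, mode="coverage",
                                  coverage=5, length_median=800)
        alns, seqs = map_all(reads, mini_locus, model)
        pile = cp.build_pileup(alns, seqs, mini_locus.sequence)
        expected = 0
        for a in alns:
            for n, op in ac.expand_ops(a.edit_string):
                if op in "=XD":
                    expected += n
        assert int(pile.depth.sum()) == expected


class TestConsensusCalling:
    def _pile(self, tallies):
        counts = np.array(tallies, np.int32)
        return cp.Pileup(counts=counts, insertions={},
                         ref="A" * len(counts))

    def test_majority_picks_plurality(self):
        pile = self._pile([[2, 0, 3, 0, 0]])
        assert cp.call_consensus(pile, "majority").sequence == "G"

    def test_majority_tie_break_order(self):
        pile = self._pile([[2, 0, 2, 0, 0]])
        assert cp.call_consensus(pile, "majority").sequence == "A"

    def test_zero_depth_is_n(self):
        pile = self._pile([[0, 0, 0, 0, 0], [3, 0, 0, 0, 0]])
        res = cp.call_consensus(pile, "majority")
        assert res.sequence == "NA"
        assert res.zero_depth[0] and not res.zero_depth[1]

    def test_weighted_overrides_biased_majority(self, model):
        """If true A is observed as G far more often than true G as A, an
        A:2/G:3 column should still be called A by the weighted mode."""
        m = ac.ScoreModel.default()
        sp = np.full((4, 4), 0.01)
        np.fill_diagonal(sp, 0.97)
        sp[0, 2] = 0.45   # P(G obs | A true): strong A->G error channel
        sp[0, 0] = 0.53
        sp[2, 0] = 0.001  # P(A obs | G true): tiny
        sp[2, 2] = 0.989
        sp /= sp.sum(axis=1, keepdims=True)
        m.subst_probs = sp
        m.gap_probs = {"open": 0.01, "extend": 0.1}
        pile = self._pile([[2, 0, 3, 0, 0]])
        weighted = cp.call_consensus(pile, "weighted", model=m)
        assert weighted.sequence == "A"
        assert cp.call_consensus(pile, "majority").sequence == "G"
        # hand-computed posterior check
        logp = cp._weighted_logpost(np.array([2, 0, 3, 0, 0]), m, 0.02)
        by_hand_a = np.log(0.25 * 0.98) + 2 * np.log(0.99 * sp[0, 0]) \
            + 3 * np.log(0.99 * sp[0, 2])
        assert logp[0] == pytest.approx(by_hand_a)

    def test_weighted_requires_trained_model(self):
        pile = self._pile([[1, 0, 0, 0, 0]])
        with pytest.raises(ValueError):
            cp.call_consensus(pile, "weighted", model=ac.ScoreModel.default())


class TestIdentity:
    def test_identical_sequences(self):
        s = "ACGT" * 250
        assert cp.compute_identity(s, s) == pytest.approx(100.0)

    def test_75_mismatches_in_49877(self):
        rng = np.random.default_rng(15)
        truth = random_seq(rng, 49877)
        pos = rng.choice(49877, size=75, replace=False)
        cons = list(truth)
        for p in pos:
            cons[p] = "ACGT"[("ACGT".index(cons[p]) + 1) % 4]
        ident = cp.compute_identity("".join(cons), truth)
        assert round(ident, 2) == 99.85

    def test_single_deletion_in_1000(self):
        rng = np.random.default_rng(16)
        truth = random_seq(rng, 1000)
        cons = truth[:500] + truth[501:]
        assert cp.compute_identity(cons, truth) == pytest.approx(99.90,
                                                                 abs=0.005)

    def test_region_restriction(self, mini_locus):
        truth = mini_locus.sequence
        cons = list(truth)
        cons[50] = "A" if truth[50] != "A" else "C"   # flank5 error
        cons = "".join(cons)
        f3 = (mini_locus.flank3_iv.start, mini_locus.flank3_iv.end)
        assert cp.compute_identity(cons, truth, region=f3) == 100.0
        assert cp.compute_identity(cons, truth) < 100.0

    def test_region_outside_truth_rejected(self):
        with pytest.raises(ValueError):
            cp.compute_identity("ACGT", "ACGT", region=(0, 10))


class TestDifferenceTaxonomy:
    def test_classes(self, mini_locus):
        truth = mini_locus.sequence
        cons = list(truth)
        # find an A in unit 1 and a C in unit 2 to mutate
        u1 = mini_locus.unit_ivs[1]
        a_pos = truth.index("A", u1.start + 10)
        c_pos = truth.index("C", mini_locus.unit_ivs[2].start + 10)
        cons[a_pos] = "G"   # transition
        cons[c_pos] = "A"   # transversion
        recs = cp.classify_differences("".join(cons), truth, mini_locus)
        by_pos = {r.ref_pos: r for r in recs}
        assert by_pos[a_pos].diff_class == "transition"
        assert by_pos[c_pos].diff_class == "transversion"
        assert by_pos[a_pos].unit_index == 1
        assert by_pos[a_pos].unit_offset == a_pos - u1.start
        assert by_pos[a_pos].context == truth[a_pos - 2:a_pos + 3]

    def test_indel_records(self, mini_locus):
        truth = mini_locus.sequence
        cons = truth[:700] + truth[701:]          # deletion at 700
        cons = cons[:100] + "A" + cons[100:]      # insertion after 99
        recs = cp.classify_differences(cons, truth, mini_locus)
        classes = {r.diff_class for r in recs}
        assert "deletion" in classes and "insertion" in classes

    def test_recurrent_grouping(self, mini_locus):
        truth = mini_locus.sequence
        offset = 57
        cons = list(truth)
        units = [0, 2, 4]
        for u in units:
            pos = mini_locus.unit_ivs[u].start + offset
            cons[pos] = "G" if truth[pos] in "ACT" else "A"
        recs = cp.classify_differences("".join(cons), truth, mini_locus)
        groups = cp.find_recurrent(recs, 200, min_units=3)
        assert len(groups) == 1
        g = groups[0]
        assert g.unit_offset == offset and g.unit_count == 3
        assert cp.find_recurrent([], 200) == []

    def test_random_errors_rarely_recur(self, mini_locus):
        """Birthday-problem check: 75 uniform errors over 13x3306 offsets
        essentially never hit the same offset with the same change in >= 3
        units."""
        rng = np.random.default_rng(17)
        total_groups = 0
        for _ in range(100):
            recs = []
            for pos in rng.choice(13 * 3306, size=75, replace=False):
                unit, off = divmod(int(pos), 3306)
                ref = "ACGT"[int(rng.integers(0, 4))]
                alt = [b for b in "ACGT" if b != ref][int(rng.integers(0, 3))]
                recs.append(cp.DifferenceRecord(int(pos), ref, alt, unit,
                                                off, "NNNNN", "transition"))
            total_groups += len(cp.find_recurrent(recs, 3306, min_units=3))
        assert total_groups <= 1

    def test_motif_stats_iupac(self):
        truth = "CCAGG" + "ATATAT" + "CCTGG"  # motif centers at 2 and 13
        groups = [cp.RecurrentGroup(0, "A", "G", 3, (2,)),
                  cp.RecurrentGroup(1, "T", "C", 3, (13,))]
        n_in, n_rec, frac = cp.motif_stats(groups, truth)
        assert (n_in, n_rec) == (2, 2)
        bad = [cp.RecurrentGroup(0, "A", "G", 3, (2,))]
        n_in, _, _ = cp.motif_stats(bad, "ACAGT")
        assert n_in == 0

    def test_error_summary_worked_examples(self):
        rng = np.random.default_rng(18)
        recs = []
        for i in range(75):
            cls = "transition" if i < 53 else "transversion"
            recs.append(cp.DifferenceRecord(i, "A", "G" if cls == "transition"
                                            else "T", 0, i, "NNNNN", cls))
        prof = cp.error_summary(recs, 49877)
        assert f"{prof.error_rate_pct:.2f}" == "0.15"
        assert f"{prof.transition_pct:.1f}" == "70.7"
        assert prof.n_subs == 75 and prof.n_transitions == 53

    def test_error_summary_empty(self):
        prof = cp.error_summary([], 1000)
        assert prof.error_rate_pct == 0.0
        assert prof.transition_pct is None
        assert "NA" in prof.report()


class TestConsensusProperties:
    def test_weighted_beats_majority_with_biased_errors(self, mini_locus):
        """Mean weighted-consensus identity >= mean majority identity over
        50 seeded simulations with transition-biased, hotspot-enriched
        errors."""
        base_spec = sl.ErrorSpec(p_sub=0.12, ts_fraction=0.8, p_ins=0.01,
                                 p_del=0.01, hotspot_multiplier=20, seed=0)
        reads0 = sl.simulate_reads(mini_locus, base_spec, mode="coverage",
                                   coverage=20, length_median=800)
        model = ac.train_error_model([r.sequence for r in reads0],
                                     mini_locus.sequence, max_iters=4)
        w_ids, m_ids = [], []
        for seed in range(1, 51):
            spec = sl.ErrorSpec(p_sub=0.12, ts_fraction=0.8, p_ins=0.01,
                                p_del=0.01, hotspot_multiplier=20, seed=seed)
            reads = sl.simulate_reads(mini_locus, spec, mode="coverage",
                                      coverage=20, length_median=800)
            alns, seqs = map_all(reads, mini_locus, model, seed=seed)
            pile = cp.build_pileup(alns, seqs, mini_locus.sequence)
            w = cp.call_consensus(pile, "weighted", model=model)
            mj = cp.call_consensus(pile, "majority")
            w_ids.append(cp.compute_identity(w.sequence, mini_locus.sequence))
            m_ids.append(cp.compute_identity(mj.sequence, mini_locus.sequence))
        assert np.mean(w_ids) >= np.mean(m_ids)

    def test_identity_improves_with_coverage(self, mini_locus, mini_trained):
        def mean_ident(cov, seeds=(21, 22, 23)):
            vals = []
            for s in seeds:
                spec = sl.ErrorSpec(p_sub=0.12, p_ins=0.01, p_del=0.01,
                                    seed=s)
                reads = sl.simulate_reads(mini_locus, spec, mode="coverage",
                                          coverage=cov, length_median=800)
                alns, seqs = map_all(reads, mini_locus, mini_trained, seed=s)
                pile = cp.build_pileup(alns, seqs, mini_locus.sequence)
                res = cp.call_consensus(pile, "majority")
                vals.append(cp.compute_identity(res.sequence,
                                                mini_locus.sequence))
            return np.mean(vals)

        assert mean_ident(60) >= mean_ident(10)

    def test_hotspot_recovery_in_consensus_errors(self, mini_locus, model):
        """Planted CCNGG hotspots: the recurrent-error motif fraction beats
        the background motif-center density (one-sided binomial, alpha=.01)."""
        from scipy.stats import binomtest
        spec = sl.ErrorSpec(p_sub=0.04, ts_fraction=0.7, p_ins=0.005,
                            p_del=0.005, hotspot_multiplier=20, seed=30)
        reads = sl.simulate_reads(mini_locus, spec, mode="coverage",
                                  coverage=20, length_median=800)
        alns, seqs = map_all(reads, mini_locus, model, seed=30)
        pile = cp.build_pileup(alns, seqs, mini_locus.sequence)
        res = cp.call_consensus(pile, "majority")
        recs = cp.classify_differences(res.sequence, mini_locus.sequence,
                                       mini_locus)
        groups = cp.find_recurrent(recs, 200, min_units=3)
        assert groups, "hotspots should produce recurrent consensus errors"
        n_in, n_rec, frac = cp.motif_stats(groups, mini_locus.sequence)
        background = len(sl.find_motif_centers(mini_locus.unit_seq)) / 200
        assert binomtest(n_in, n_rec, background,
                         alternative="greater").pvalue < 0.01
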