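import numpy as np
import pytest

from conftest import random_dna
from oracles import oracle_frame_category

from crispramp.align import align_glocal
from crispramp.classify import (
    FRAMESHIFT,
    IN_FRAME,
    SUBSTITUTION,
    UNASSIGNED,
    WT,
    ClassifyPolicy,
    SequenceClassifier,
    assign_locus,
    classify_read,
    classify_sequence,
    cohort_means,
    compare_tissues,
    summarize_locus,
)
from crispramp.refdata import QuantWindow, make_quant_window
from crispramp.simulate import EditAllele, IndelOp, apply_allele


def _classify_string(read: str, ref: str, window=None, policy=None):
    aln = align_glocal(read, ref)
    window = window or QuantWindow(span=(0, len(ref)), mode="full_amplicon")
    return classify_read(aln, window, policy)


class TestClassifyRead:
    def test_perfect_match_is_wt(self, amp_a):
        w = make_quant_window(amp_a, "cut_centered", 30)
        aln = align_glocal(amp_a.sequence, amp_a)
        assert classify_read(aln, w).category == WT

    def test_three_nt_deletion_at_cut_is_in_frame(self, amp_a):
        w = make_quant_window(amp_a, "cut_centered", 30)
        read = apply_allele(amp_a, EditAllele(ops=(IndelOp(amp_a.cut_pos, "del", 3),)))
        aln = align_glocal(read, amp_a)
        c = classify_read(aln, w)
        assert c.category == IN_FRAME and c.net_indel == -3 and c.n_indel_events == 1

    def test_one_nt_insertion_is_frameshift(self, amp_a):
        w = make_quant_window(amp_a, "cut_centered", 30)
        read = apply_allele(amp_a, EditAllele(ops=(IndelOp(amp_a.cut_pos, "ins", 1, "A"),)))
        c = classify_read(align_glocal(read, amp_a), w)
        assert c.category == FRAMESHIFT and c.net_indel == 1

    def test_read_not_spanning_window_is_unassigned(self, amp_a):
        w = make_quant_window(amp_a, "full_amplicon")
        read = amp_a.sequence[:120]  # stops before the window end
        assert classify_read(align_glocal(read, amp_a), w).category == UNASSIGNED

    def test_substitution_only_policies(self, amp_a):
        w = make_quant_window(amp_a, "cut_centered", 30)
        cut = amp_a.cut_pos
        read = list(amp_a.sequence)
        read[cut] = "A" if read[cut] != "A" else "C"
        read = "".join(read)
        aln = align_glocal(read, amp_a)
        assert classify_read(aln, w).category == IN_FRAME  # default routes to in-frame
        assert classify_read(aln, w, ClassifyPolicy(substitution_policy="wt")).category == WT
        assert (
            classify_read(aln, w, ClassifyPolicy(substitution_policy="separate")).category
            == SUBSTITUTION
        )
        assert classify_read(aln, w, ClassifyPolicy(max_subs=1)).category == WT

    def test_substitutions_outside_window_do_not_count(self, amp_a):
        w = make_quant_window(amp_a, "cut_centered", 30)
        read = list(amp_a.sequence)
        read[40] = "A" if read[40] != "A" else "C"  # far from the cut
        c = classify_read(align_glocal("".join(read), amp_a), w)
        assert c.category == WT and c.n_substitutions == 0

    def test_category_matches_frame_oracle_on_planted_indels(self, rng):
        """Planted 0-2 interior indels (<=4 nt) classify by net length mod 3."""
        from crispramp.simulate import sample_toy_indel_case

        for _ in range(150):
            ref, read, allele, wspan = sample_toy_indel_case(rng)
            c = _classify_string(read, ref, window=QuantWindow(span=wspan, mode="full_amplicon"))
            assert c.category == oracle_frame_category(allele.net_len, len(allele.ops))

    def test_net_zero_two_event_read_is_in_frame(self, rng):
        ref = random_dna(rng, 30)
        ops = (IndelOp(8, "del", 3), IndelOp(20, "ins", 3, "ACG"))
        read = apply_allele(ref, EditAllele(ops=ops))
        c = _classify_string(read, ref)
        assert c.category == IN_FRAME


def _random_indel(rng, pos):
    length = int(rng.integers(1, 5))
    if rng.random() < 0.5:
        return IndelOp(pos, "del", length)
    return IndelOp(pos, "ins", length, "".join("ACGT"[b] for b in rng.integers(0, 4, length)))


class TestAssignLocus:
    def test_reads_assign_to_their_own_locus(self, amps):
        for amp in amps:
            read = amp.sequence[20:320]
            locus, _ = assign_locus(read, amps)
            assert locus == amp.locus_id

    def test_identical_references_tie_to_unassigned(self, amp_a):
        import dataclasses

        twin = dataclasses.replace(amp_a, locus_id="twin")
        locus, _ = assign_locus(amp_a.sequence[20:320], [amp_a, twin])
        assert locus is None

    def test_random_sequences_fall_below_score_floor(self, amps, rng):
        for _ in range(20):
            locus, _ = assign_locus(random_dna(rng, 150), amps)
            assert locus is None

    def test_classify_sequence_unassigned_category(self, amps, rng):
        windows = {a.locus_id: make_quant_window(a, "cut_centered", 30) for a in amps}
        c = classify_sequence(random_dna(rng, 150), amps, windows)
        assert c.category == UNASSIGNED and c.assigned_locus is None


class TestSummaries:
    def _mk(self, n_wt, n_if, n_fs, ind="IgM_01", tissue="fin", locus="IgM_A"):
        from crispramp.classify import ReadClassification

        cls = (
            [ReadClassification(WT, 0, 0, 0, locus)] * n_wt
            + [ReadClassification(IN_FRAME, 3, 1, 0, locus)] * n_if
            + [ReadClassification(FRAMESHIFT, 1, 1, 0, locus)] * n_fs
        )
        return summarize_locus(cls, ind, tissue, locus)

    def test_fractions_sum_to_one_and_match_counts(self):
        s = self._mk(2, 19, 79)
        assert s.n_classified == 100
        assert s.f_mutated == pytest.approx(0.98)
        assert s.f_wt + s.f_inframe + s.f_frameshift == pytest.approx(1.0, abs=1e-9)

    def test_all_wt(self):
        s = self._mk(50, 0, 0)
        assert (s.f_wt, s.f_inframe, s.f_frameshift) == (1.0, 0.0, 0.0)

    def test_empty_group_raises(self):
        with pytest.raises(ValueError):
            summarize_locus([], "IgM_01", "fin", "IgM_A")

    def test_unassigned_excluded_from_denominator(self):
        from crispramp.classify import ReadClassification

        cls = [ReadClassification(WT, 0, 0, 0, "IgM_A")] * 10 + [
            ReadClassification(UNASSIGNED, 0, 0, 0, None)
        ] * 5
        s = summarize_locus(cls, "IgM_01", "fin", "IgM_A")
        assert s.n_classified == 10 and s.n_unassigned == 5 and s.f_wt == 1.0

    def test_cohort_means_are_unweighted_across_individuals(self):
        a = self._mk(0, 0, 100, ind="IgM_01")
        b = self._mk(30, 0, 70, ind="IgM_02")  # different depth weighting check
        df = cohort_means([a, b])
        row = df.iloc[0]
        assert row["f_frameshift"] == pytest.approx((1.0 + 0.7) / 2)
        assert row["n_individuals"] == 2

    def test_compare_tissues_matches_printed_example(self):
        wbc = self._mk(24, 16, 60, tissue="WBC", locus="IgM_B")
        fin = self._mk(4, 16, 80, tissue="fin", locus="IgM_B")
        diff = compare_tissues(wbc, fin)
        assert diff[WT] == pytest.approx(0.24 - 0.04)
        identical = compare_tissues(fin, fin)
        assert all(v == 0 for v in identical.values())

    def test_compare_tissues_key_mismatch_raises(self):
        a = self._mk(1, 1, 1, ind="IgM_01", locus="IgM_A")
        b = self._mk(1, 1, 1, ind="IgM_02", locus="IgM_A")
        with pytest.raises(ValueError):
            compare_tissues(a, b)


class TestTissueDiscordanceRecovery:
    def test_simulated_discordant_spectra_recover_truth_differences(self, amps):
        """Fin/WBC differences estimated from reads match the truth table."""
        from crispramp.pipeline import PipelineConfig, analyze_sample
        from crispramp.simulate import SimConfig, simulate_dataset

        sim = SimConfig(seed=77, n_individuals=2, tissues=("fin", "WBC"), read_depth=1500)
        config = PipelineConfig(seed=77, sim=sim, window_mode="cut_centered")
        windows = config.windows(amps)
        summaries, truths = {}, {}
        for sample in simulate_dataset(amps, sim):
            clf = SequenceClassifier(amps, windows, config.classify, config.scoring)
            s, _ = analyze_sample(sample, config, clf)
            key = (sample.individual, sample.locus)
            summaries.setdefault(key, {})[sample.tissue] = s
            truths.setdefault(key, {})[sample.tissue] = sample.truth
        for key, per_tissue in summaries.items():
            diff = compare_tissues(per_tissue["fin"], per_tissue["WBC"])
            t = truths[key]
            truth_diff = {
                WT: t["fin"]["frac_wt"] - t["WBC"]["frac_wt"],
                IN_FRAME: t["fin"]["frac_inframe"] - t["WBC"]["frac_inframe"],
                FRAMESHIFT: t["fin"]["frac_frameshift"] - t["WBC"]["frac_frameshift"],
            }
            for cat in diff:
                assert diff[cat] == pytest.approx(truth_diff[cat], abs=0.04)


class TestErrorRobustness:
    def test_wt_misclassification_matches_analytic_substitution_rate(self, amps):
        """Strict perfect-match WT: substitution errors relabel WT reads at
        the analytic rate 1-(1-e)^w for a window of w covered bases."""
        from crispramp.pipeline import PipelineConfig, analyze_sample
        from crispramp.simulate import SimConfig, simulate_dataset

        e = 0.005
        sim = SimConfig(
            seed=13,
            n_individuals=1,
            read_depth=5000,
            editing_rate=0.0,
            error_rate=e,
            tail_length=0,
        )
        config = PipelineConfig(
            seed=13, sim=sim, window_mode="cut_centered", window_halfwidth=30, pairing="r1_only"
        )
        amp = amps[0]
        windows = config.windows(amps)
        w = windows[amp.locus_id]
        sample = next(s for s in simulate_dataset(amps, sim) if s.locus == amp.locus_id)
        clf = SequenceClassifier(amps, windows, config.classify, config.scoring)
        summary, _ = analyze_sample(sample, config, clf)
        p_analytic = 1.0 - (1.0 - e) ** (w.end - w.start)
        p_hat = 1.0 - summary.f_wt
        se = np.sqrt(p_analytic * (1 - p_analytic) / summary.n_classified)
        assert abs(p_hat - p_analytic) < 4 * se
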