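"""End-calling semantics: templated/non-templated splits and summaries."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from racemap import (ConstructAnnotation, EndCall3, EndCall5, cap_fraction,
                     call_3prime_end, call_5prime_end, classify_tail,
                     collapse_top_n, end_distribution, modification_spectrum,
                     prep_reads)
from racemap.simulate import SimConfig3, SimConfig5, simulate_race3, simulate_race5


class TestCollapseTopN:
    def test_top_twenty_of_25(self):
        inserts = []
        for i in range(25):
            inserts += [f"SEQ{i:02d}"] * (i + 1)  # counts 1..25
        ranked = collapse_top_n(inserts, n=20)
        assert len(ranked) == 20
        assert ranked[0].insert == "SEQ24" and ranked[0].count == 25
        assert [r.rank for r in ranked] == list(range(1, 21))
        assert ranked[-1].count == 6  # counts 25..6 retained

    def test_single_class(self):
        ranked = collapse_top_n(["AAA"] * 7)
        assert ranked == [type(ranked[0])("AAA", 7, 1)]

    def test_tie_at_rank_boundary_lexicographic(self):
        # 19 distinct high-count sequences + two tied at the boundary
        inserts = []
        for i in range(19):
            inserts += [f"HI{i:02d}"] * (30 - i)
        inserts += ["TTTT"] * 2 + ["AAAA"] * 2
        ranked = collapse_top_n(inserts, n=20)
        assert ranked[-1].insert == "AAAA"  # lexicographically smaller kept
        assert "TTTT" not in [r.insert for r in ranked]

    @settings(max_examples=50, deadline=None)
    @given(st.lists(st.sampled_from(["A", "C", "G", "T", "AC", "GT"]), max_size=60),
           st.integers(min_value=1, max_value=5))
    def test_matches_full_sort_oracle(self, inserts, n):
        from collections import Counter
        ranked = collapse_top_n(inserts, n=n)
        oracle = sorted(Counter(inserts).items(), key=lambda kv: (-kv[1], kv[0]))[:n]
        assert [(r.insert, r.count) for r in ranked] == oracle


class TestCall3Prime:
    def test_act_extension_is_templated(self, construct):
        insert = construct.seq[construct.anchor5:construct.crrna_end] + "ACT"
        call = call_3prime_end(insert, construct)
        assert call == EndCall3(3, "", "none")

    def test_act_plus_diU_tail(self, construct):
        insert = construct.seq[construct.anchor5:construct.crrna_end] + "ACTTT"
        call = call_3prime_end(insert, construct)
        # first T after ACT is the templated +4?  No: base at +3 is C, so both
        # trailing Ts are non-templated
        assert call == EndCall3(3, "TT", "diU")

    def test_exact_crrna_boundary(self, construct):
        insert = construct.seq[construct.anchor5:construct.crrna_end]
        call = call_3prime_end(insert, construct)
        assert call.end_offset == 0 and call.tail_class == "none"

    def test_short_anchor_unassigned(self, construct):
        assert call_3prime_end("ACGTACGT", construct) is None
        assert call_3prime_end("C" * 40, construct) is None

    def test_templated_polyT_terminator(self):
        """On a Pol III (U6-style) toy construct the terminator-derived run of
        Ts is templated: ends are placed after the poly-T with an empty tail."""
        # 60-nt toy: 10 nt leader, crRNA 20 nt, then TTTT terminator, then GC-rich
        leader = "CATGCATGCA"
        crrna = "GACCGGAACCTTGGCAGCAC"
        seq = leader + crrna + "TTTT" + "GCGCGGCCGCGGCCGCGGCCGCGGCC"
        toy = ConstructAnnotation(
            seq=seq, plus_one=len(leader),
            crrna_span=(len(leader), len(leader) + 20),
            dr_span=(len(leader), len(leader) + 10),
            spacer_span=(len(leader) + 10, len(leader) + 20),
            box3_span=(len(seq) - 5, len(seq)), anchor5=len(leader),
            name="U6-toy")
        # hand-computed: crRNA + TTTT is fully templated -> offset +4, no tail
        call = call_3prime_end(crrna + "TTTT", toy)
        assert call == EndCall3(4, "", "none")
        # two extra Ts beyond the templated four (template continues with G):
        # offset stays +4 and the surplus is a diU tail
        call = call_3prime_end(crrna + "TTTTTT", toy)
        assert call == EndCall3(4, "TT", "diU")

    def test_ambiguous_tail_base_goes_to_template(self, construct):
        """A tail base equal to the next template base is called templated
        (longest templated match wins)."""
        # base at +0 is 'A': an insert ending ...crRNA + 'A' is offset +1
        insert = construct.seq[construct.anchor5:construct.crrna_end] + "A"
        assert construct.seq[construct.crrna_end] == "A"
        call = call_3prime_end(insert, construct)
        assert call.end_offset == 1 and call.tail == ""


class TestClassifyTail:
    @pytest.mark.parametrize("tail,cls", [
        ("", "none"), ("T", "monoU"), ("TT", "diU"), ("TTT", "oligoU"),
        ("TTTTT", "oligoU"), ("A", "other"), ("TA", "other"), ("CT", "other")])
    def test_classes(self, tail, cls):
        assert classify_tail(tail) == cls


class TestCall5Prime:
    def insert(self, construct, g, offset=0):
        return "G" * g + construct.seq[construct.plus_one + offset:]

    def test_three_g_uncapped(self, construct):
        call = call_5prime_end(self.insert(construct, 3), construct)
        assert call == EndCall5(0, 3, "uncapped")

    def test_four_g_capped(self, construct):
        call = call_5prime_end(self.insert(construct, 4), construct)
        assert call == EndCall5(0, 4, "capped")

    def test_upstream_start(self, construct):
        call = call_5prime_end(self.insert(construct, 3, offset=-1), construct)
        assert call.start_offset == -1 and call.leading_g == 3

    def test_plus_one_g_split_by_maximal_templated_match(self):
        """+1 G construct: of four observed guanosines one is templated, so
        the leader is 3 G and the start offset 0 (enumeration oracle)."""
        leader = "CATCATCATCATCATCATC"
        body = "GTACCGGTTCACGCATTCACGGTACAGCATC"  # +1 base is G
        toy = ConstructAnnotation(
            seq=leader + body, plus_one=len(leader),
            crrna_span=(len(leader) + 1, len(leader) + 25),
            dr_span=(len(leader) + 1, len(leader) + 10),
            spacer_span=(len(leader) + 10, len(leader) + 25),
            box3_span=(len(leader) + 28, len(leader) + 31),
            anchor5=len(leader) + 1, name="plus1G")
        insert = "GGG" + body  # 3 non-templated G + templated G at +1 = 4 observed
        assert insert.startswith("GGGG")
        call = call_5prime_end(insert, toy)
        assert call == EndCall5(0, 3, "uncapped")
        # independent oracle: enumerate all split points, keep the one with
        # the maximal templated span
        best = None
        run = len(insert) - len(insert.lstrip("G"))
        for k in range(run + 1):
            pos = toy.seq.find(insert[k:])
            if pos >= 0 and len(insert[k:]) >= 15:
                best = (k, pos - toy.plus_one)
                break
        assert best == (call.leading_g, call.start_offset)

    def test_unassigned_without_template_match(self, construct):
        assert call_5prime_end("G" * 40, construct) is None
        assert call_5prime_end("GGGCCCCCCCCCCCCCCCCCCC", construct) is None


class TestSummaries:
    def test_degenerate_distribution(self):
        calls = [(EndCall3(3, "", "none"), 2.0), (EndCall3(3, "", "none"), 5.0)]
        dist = end_distribution(calls, window=(-5, 10))
        assert dist.proportions[3] == pytest.approx(1.0)
        assert sum(dist.proportions.values()) == pytest.approx(1.0, abs=1e-9)

    def test_unassigned_and_out_of_window_pooled(self):
        calls = [(EndCall3(3, "", "none"), 1.0), (None, 1.0),
                 (EndCall3(99, "", "none"), 2.0)]
        dist = end_distribution(calls, window=(-5, 10))
        assert dist.proportions["other"] == pytest.approx(0.75)

    def test_empty_calls_error(self):
        with pytest.raises(ValueError):
            end_distribution([])
        with pytest.raises(ValueError):
            modification_spectrum([])

    def test_all_unmodified_spectrum(self):
        spec = modification_spectrum([(EndCall3(0, "", "none"), 3.0)])
        assert spec.proportions["none"] == pytest.approx(1.0)
        assert set(spec.proportions) == {"none", "monoU", "diU", "oligoU", "other"}

    def test_cap_fraction_degenerate_and_symmetric(self):
        all4 = [(EndCall5(0, 4, "capped"), 5.0)]
        assert cap_fraction(all4).estimate == pytest.approx(1.0)
        even = [(EndCall5(0, 4, "capped"), 7.0), (EndCall5(0, 3, "uncapped"), 7.0)]
        cf = cap_fraction(even)
        assert cf.estimate == pytest.approx(0.5)
        assert cf.ci_low < 0.5 < cf.ci_high
        with pytest.raises(ValueError):
            cap_fraction([(EndCall5(0, 2, "other"), 1.0)])

    def test_weighting_equivalence(self, construct):
        """Distributions computed from collapsed weighted sequences equal those
        from the corresponding uncollapsed read list."""
        cfg = SimConfig3(construct=construct, end_offset_probs={0: 0.3, 3: 0.7},
                         tail_probs={"": 0.6, "T": 0.4}, n_reads=300, seed=21)
        reads, _ = simulate_race3(cfg)
        trimmed, _ = prep_reads(reads, adapter3=cfg.adapter_seq)
        inserts = [t.insert for t in trimmed]
        ranked = collapse_top_n(inserts, n=20)
        kept = {r.insert for r in ranked}
        weighted = [(call_3prime_end(r.insert, construct), float(r.count))
                    for r in ranked]
        unweighted = [(call_3prime_end(s, construct), 1.0)
                      for s in inserts if s in kept]
        d1 = end_distribution(weighted)
        d2 = end_distribution(unweighted)
        for k in d1.proportions:
            assert d1.proportions[k] == pytest.approx(d2.proportions[k], abs=1e-12)

    def test_simulated_proportions_recovered(self, construct):
        """Per-read calls on clean simulator output recover the configured end
        and tail distributions within 3-sigma binomial bounds."""
        n = 5000
        cfg = SimConfig3(construct=construct, end_offset_probs={0: 0.2, 3: 0.8},
                         tail_probs={"": 0.5, "T": 0.3, "TT": 0.2},
                         n_reads=n, seed=17)
        reads, truth = simulate_race3(cfg)
        trimmed, _ = prep_reads(reads, adapter3=cfg.adapter_seq)
        calls = [(call_3prime_end(t.insert, construct), 1.0) for t in trimmed]
        dist = end_distribution(calls)
        for off, p in cfg.end_offset_probs.items():
            bound = 3 * math.sqrt(p * (1 - p) / n)
            assert abs(dist.proportions[off] - p) <= bound
        spec = modification_spectrum(calls)
        for cls, p in [("none", 0.5), ("monoU", 0.3), ("diU", 0.2)]:
            assert abs(spec.proportions[cls] - p) <= 3 * math.sqrt(p * (1 - p) / n)

    def test_error_rate_never_increases_unmodified_fraction(self, construct):
        """Raising the substitution error rate cannot inflate the "none"
        class: errors convert clean tails into mismatched ones."""
        def none_fraction(err):
            cfg = SimConfig3(construct=construct, end_offset_probs={3: 1.0},
                             tail_probs={"": 0.7, "T": 0.3}, n_reads=800,
                             subst_error_rate=err, seed=23)
            reads, _ = simulate_race3(cfg)
            trimmed, _ = prep_reads(reads, adapter3=cfg.adapter_seq)
            if not trimmed:
                return 0.0
            calls = [(call_3prime_end(t.insert, construct), 1.0) for t in trimmed]
            return modification_spectrum(calls).proportions["none"]

        assert none_fraction(0.05) <= none_fraction(0.0)

    def test_simulated_cap_fraction_recovered(self, construct):
        cfg = SimConfig5(construct=construct, cap_fraction=0.5, n_reads=2000, seed=19)
        reads, _ = simulate_race5(cfg)
        trimmed, _ = prep_reads(reads, adapter5=cfg.tso_adapter_seq)
        calls = [(call_5prime_end(t.insert, construct), 1.0) for t in trimmed]
        cf = cap_fraction(calls)
        assert abs(cf.estimate - 0.5) <= 0.03
        assert cf.ci_low <= cf.estimate <= cf.ci_high
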