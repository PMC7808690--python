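"""Trinucleotide-motif enrichment: counts, statistic, test, load."""

import math

import numpy as np
import pytest
from scipy import stats

from clonemut.catalog_io import Reference
from clonemut.motif_enrichment import (
    IUPAC,
    SIG_CPG,
    SIG_UV,
    MotifSignature,
    bh_correct,
    class_windows,
    count_cc_tt,
    count_motif_and_base,
    enrichment,
    enrichment_test,
    exclude_complex,
    minimum_mutation_load,
    run_panel,
)
from clonemut.records import COMPLEMENT, MutationRecord, revcomp


def snv(pos, ref="C", alt="T", sample="s", chrom="chr1"):
    return MutationRecord(sample, chrom, pos, ref, alt, 0.5)


# ---------------------------------------------------------------------------
# complex-mutation exclusion
# ---------------------------------------------------------------------------

class TestExcludeComplex:
    def test_close_pair_both_excluded(self):
        assert exclude_complex([snv(100), snv(105)]) == []

    def test_distance_ten_both_kept(self):
        recs = [snv(100), snv(110)]
        assert sorted(r.pos for r in exclude_complex(recs)) == [100, 110]

    def test_singleton_kept(self):
        assert len(exclude_complex([snv(100)])) == 1

    def test_other_sample_does_not_exclude(self):
        recs = [snv(100, sample="a"), snv(105, sample="b")]
        assert len(exclude_complex(recs)) == 2

    def test_chain_of_close_mutations_all_go(self):
        recs = [snv(100), snv(108), snv(116), snv(200)]
        assert [r.pos for r in exclude_complex(recs)] == [200]


# ---------------------------------------------------------------------------
# counting oracle
# ---------------------------------------------------------------------------

def oracle_counts(window_strings, signature):
    """Independent position-by-position scan of the window population.

    The unconstrained symbol n matches anything (including N and off-window
    positions); every other symbol matches only concrete bases.
    """
    m0, _, m2 = (s.upper() for s in signature.motif)
    b = signature.from_base
    cb = COMPLEMENT[b]

    def sym(symbol, base):
        if symbol == "N":
            return True
        return base in "ACGT" and base in IUPAC[symbol]

    def neighbors(w, i):
        left = w[i - 1] if i - 1 >= 0 else "N"
        right = w[i + 1] if i + 1 < len(w) else "N"
        return left, right

    def fwd(w, i):
        left, right = neighbors(w, i)
        return w[i] == b and sym(m0, left) and sym(m2, right)

    def rev(w, i):
        left, right = neighbors(w, i)
        comp = lambda x: COMPLEMENT[x] if x in "ACGT" else "N"
        return w[i] == cb and sym(m0, comp(right)) and sym(m2, comp(left))

    mm = mc = cm = ctx = 0
    for w in window_strings:
        c = len(w) // 2
        mc += 1
        if fwd(w, c) or rev(w, c):
            mm += 1
        for i in range(len(w)):
            if i == c:
                continue
            if w[i] == b or w[i] == cb:
                ctx += 1
                if fwd(w, i) or rev(w, i):
                    cm += 1
    return mm, mc, cm, ctx


def windows_array(strings):
    arr = np.frombuffer("".join(strings).encode(), dtype=np.uint8)
    return arr.reshape(len(strings), len(strings[0])).copy()


class TestCountMotifAndBase:
    def test_single_window_hand_count(self):
        # center C of TTCGA; motif nCg: center tCg matches.
        w = ["TTCGA"]
        sig = MotifSignature("nCg>nTg", "nCg", "T")
        mm, mc, cm, cb = count_motif_and_base(windows_array(w), sig)
        assert (mm, mc) == (1, 1)
        # context bases: T,T,G,A -> only G (reverse-strand C); its motif on
        # the opposite strand is c(C)g -> needs reference ..C G C.., here CGA
        # -> opposite strand trinucleotide TCG = nCg? complement of A is T
        # (5' n ok), complement of C is G -> G at 3' position: matches.
        assert (cm, cb) == (1, 1)

    def test_degenerate_ncn_motif_enrichment_is_one(self, rng):
        from conftest import random_sequence
        sig = MotifSignature("nCn>nTn", "nCn", "T")
        wins = [random_sequence(rng, 9) [:4] + "C" + random_sequence(rng, 4)
                for _ in range(50)]
        mm, mc, cm, cb = count_motif_and_base(windows_array(wins), sig)
        assert mm == mc and cm == cb
        assert enrichment(mm, mc, cm, cb)[0] == pytest.approx(1.0)

    @pytest.mark.parametrize("motif,to", [("yCn", "T"), ("nCg", "T"),
                                          ("nTt", "C"), ("rGa", "C")])
    def test_randomized_windows_match_bruteforce(self, rng, motif, to):
        sig = MotifSignature(f"{motif}>x", motif, to)
        alphabet = list("ACGT" * 10 + "N")
        wins = ["".join(rng.choice(alphabet, size=11)) for _ in range(300)]
        # force center to be a concrete base sometimes matching the class
        wins = [w[:5] + rng.choice(list("ACGT")) + w[6:] for w in wins]
        got = count_motif_and_base(windows_array(wins), sig)
        assert got == oracle_counts(wins, sig)

    def test_bad_symbols_rejected(self):
        with pytest.raises(ValueError, match="symbols"):
            count_motif_and_base(windows_array(["TTXGA"]), SIG_CPG)


class TestClassWindows:
    def test_reverse_complement_records_normalized(self):
        ref = Reference({"c": "AATTCGGATC"})
        # G>A at pos 7 is the C>T class on the other strand
        recs = [snv(5, "C", "T", chrom="c"), snv(7, "G", "A", chrom="c")]
        wins = class_windows(recs, ref, "C", "T", flank=2, guard=0)
        assert wins.shape == (2, 5)
        # windows: pos 5 +/-2 = TTCGG; pos 7 +/-2 = CGGAT, reverse-complemented
        assert wins.tobytes().decode() == "TTCGG" + revcomp("CGGAT")

    def test_non_class_records_ignored(self):
        ref = Reference({"c": "AATTCGGATC"})
        wins = class_windows([snv(5, "C", "A", chrom="c")], ref, "C", "T", 2, guard=0)
        assert wins.shape == (0, 5)


# ---------------------------------------------------------------------------
# statistic, test, correction, load
# ---------------------------------------------------------------------------

class TestEnrichment:
    def test_direct_formula(self):
        assert enrichment(10, 20, 50, 200) == (2.0, False)

    def test_null_case(self):
        assert enrichment(5, 20, 50, 200)[0] == pytest.approx(1.0)

    def test_zero_ctx_motif_flagged_infinite(self):
        val, undef = enrichment(3, 10, 0, 200)
        assert undef and math.isinf(val)

    def test_zero_class_flagged(self):
        val, undef = enrichment(0, 0, 50, 200)
        assert undef and math.isnan(val)

    def test_random_counts_match_arithmetic(self, rng):
        for _ in range(50):
            mc = int(rng.integers(1, 100))
            mm = int(rng.integers(0, mc + 1))
            cb = int(rng.integers(1, 1000))
            cm = int(rng.integers(1, cb + 1))
            assert enrichment(mm, mc, cm, cb)[0] == pytest.approx(
                (mm * cb) / (mc * cm))


def hypergeom_p_greater(a, b, c, d):
    """P(X >= a) for X ~ Hypergeom drawing (a+b) from (a+c) successes of
    (a+b+c+d): full enumeration oracle."""
    N, K, n = a + b + c + d, a + c, a + b
    return sum(stats.hypergeom.pmf(k, N, K, n)
               for k in range(a, min(K, n) + 1))


class TestFisher:
    def test_no_signal_p_one(self):
        assert enrichment_test(0, 10, 100, 1000) == pytest.approx(1.0)

    def test_matches_enumeration_oracle(self, rng):
        for _ in range(30):
            a, b = int(rng.integers(0, 10)), int(rng.integers(0, 10))
            c, d = int(rng.integers(0, 12)), int(rng.integers(0, 12))
            if (a + b) == 0 or (c + d) == 0:
                continue
            got = enrichment_test(a, a + b, c, c + d)
            want = hypergeom_p_greater(a, b, c, d)
            assert got == pytest.approx(want, abs=1e-12)

    def test_specific_table_vs_oracle(self):
        got = enrichment_test(10, 20, 50, 200)
        assert got == pytest.approx(hypergeom_p_greater(10, 10, 50, 150),
                                    abs=1e-12)

    def test_negative_cell_rejected(self):
        with pytest.raises(ValueError):
            enrichment_test(10, 5, 50, 200)


class TestBH:
    def test_textbook_example(self):
        assert bh_correct([0.01, 0.02, 0.03]) == pytest.approx([0.03, 0.03, 0.03])

    def test_single_p(self):
        assert bh_correct([0.2]) == pytest.approx([0.2])

    def test_random_vectors_match_stepup_formula(self, rng):
        for _ in range(20):
            p = rng.uniform(0, 1, int(rng.integers(1, 40)))
            m = p.size
            order = np.argsort(p)
            q_sorted = p[order] * m / np.arange(1, m + 1)
            q_sorted = np.minimum.accumulate(q_sorted[::-1])[::-1]
            want = np.empty(m)
            want[order] = np.minimum(q_sorted, 1)
            assert bh_correct(p) == pytest.approx(want)

    def test_monotone_and_dominates_p(self, rng):
        p = np.sort(rng.uniform(0, 1, 30))
        q = bh_correct(p)
        assert np.all(np.diff(q) >= -1e-12) and np.all(q >= p - 1e-12)


class TestMinLoad:
    def test_formula(self):
        assert minimum_mutation_load(10, 2.0, 0.001) == pytest.approx(5.0)

    def test_gate_on_enrichment(self):
        assert minimum_mutation_load(10, 0.8, 0.001) == 0.0

    def test_gate_on_q(self):
        assert minimum_mutation_load(10, 2.0, 0.05) == 0.0

    def test_bounds_and_monotonicity(self, rng):
        for _ in range(100):
            mm = int(rng.integers(1, 50))
            e1, e2 = sorted(rng.uniform(1.01, 30, 2))
            l1 = minimum_mutation_load(mm, float(e1), 0.01)
            l2 = minimum_mutation_load(mm, float(e2), 0.01)
            assert 0 <= l1 <= l2 <= mm


class TestCcTt:
    def test_adjacent_pair(self):
        assert count_cc_tt([snv(100), snv(101)]) == 1

    def test_reverse_complement_pair(self):
        assert count_cc_tt([snv(100, "G", "A"), snv(101, "G", "A")]) == 1

    def test_non_adjacent_not_counted(self):
        assert count_cc_tt([snv(100), snv(103)]) == 0

    def test_mixed_strand_adjacent_not_counted(self):
        # C>T next to G>A is not a CC or GG dinucleotide change
        assert count_cc_tt([snv(100, "C", "T"), snv(101, "G", "A")]) == 0

    def test_triple_counts_two_pairs(self):
        assert count_cc_tt([snv(100), snv(101), snv(102)]) == 2


# ---------------------------------------------------------------------------
# panel
# ---------------------------------------------------------------------------

class TestRunPanel:
    def test_uniform_background_gives_zero_min_load(self, rng):
        from conftest import random_sequence
        seq = random_sequence(rng, 60_000)
        ref = Reference({"c": seq})
        c_positions = [i + 1 for i, b in enumerate(seq) if b in "CG"]
        picks = rng.choice(len(c_positions), size=150, replace=False)
        recs = []
        for i in picks:
            pos = c_positions[int(i)]
            b = seq[pos - 1]
            recs.append(snv(pos, b, "T" if b == "C" else "A", chrom="c"))
        results, _ = run_panel(recs, ref, signatures=[SIG_UV, SIG_CPG])
        assert all(r.min_load == 0 for r in results
                   if not (r.q < 0.05 and r.enrichment > 1.2))
        # uniform placement: enrichment should hover near 1
        for r in results:
            assert 0.5 < r.enrichment < 1.6

    def test_duplicate_sample_identical_results(self, small_cohort, small_reference):
        _, cohort = small_cohort
        sample = cohort.meta[0].sample_id
        recs = [r for r in cohort.snvs if r.sample_id == sample][:400]
        dup = [MutationRecord("copy", r.chrom, r.pos, r.ref, r.alt, r.vaf)
               for r in recs]
        results, _ = run_panel(recs + dup, small_reference)
        by = {(r.sample_id, r.signature): r for r in results}
        for sig in ("nCg>nTg", "yCn>yTn", "nTt>nCt"):
            a, b = by[(sample, sig)], by[("copy", sig)]
            assert (a.mut_in_motif, a.mut_in_class, a.ctx_motif, a.ctx_base) \
                == (b.mut_in_motif, b.mut_in_class, b.ctx_motif, b.ctx_base)
            assert a.min_load == pytest.approx(b.min_load)
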