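"""SV hotspot chaining, CFS annotation, breakpoint microhomology, tests."""

import numpy as np
import pytest

from clonemut.catalog_io import GenomeIntervals, Reference
from clonemut.records import SVRecord, revcomp
from clonemut.sv_analysis import (
    annotate_all,
    annotate_cfs,
    breakpoint_microhomology,
    call_hotspots,
    mh_cfs_fisher,
    svtype_cfs_chisq,
)

MB = 1_000_000


def sv(sample, pos1, pos2=None, chrom="chr1", sv_type="DEL", chrom2=None):
    pos2 = pos2 if pos2 is not None else pos1 + 10_000
    return SVRecord(sample, sv_type, chrom, pos1, chrom2 or chrom, pos2,
                    junction_reads_variant=5, junction_reads_total=10)


def hotspot_oracle(svs, max_gap=MB):
    """O(n^2) pairwise single-linkage chaining over breakpoints."""
    pts = []
    for i, s in enumerate(svs):
        for chrom, pos in s.breakpoints:
            pts.append((chrom, pos, i))
    parent = list(range(len(pts)))

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for a in range(len(pts)):
        for b in range(a + 1, len(pts)):
            if pts[a][0] == pts[b][0] and abs(pts[a][1] - pts[b][1]) <= max_gap:
                parent[find(a)] = find(b)
    clusters = {}
    for idx, (chrom, pos, i) in enumerate(pts):
        clusters.setdefault(find(idx), set()).add(i)
    flags = [False] * len(svs)
    for members in clusters.values():
        samples = {svs[i].sample_id for i in members}
        if len(members) >= 2 and len(samples) >= 2:
            for i in members:
                flags[i] = True
    return flags


class TestHotspots:
    def test_two_samples_half_mb_apart(self):
        svs = [sv("a", 10 * MB), sv("b", int(10.5 * MB))]
        hotspots, flags = call_hotspots(svs)
        assert len(hotspots) == 1 and flags == [True, True]
        assert hotspots[0].n_samples == 2

    def test_same_sample_only_is_not_hotspot(self):
        svs = [sv("a", 10 * MB), sv("a", int(10.5 * MB))]
        hotspots, flags = call_hotspots(svs)
        assert hotspots == [] and flags == [False, False]

    def test_beyond_gap_not_chained(self):
        svs = [sv("a", 10 * MB, 10 * MB + 100),
               sv("b", 12 * MB, 12 * MB + 100)]
        assert call_hotspots(svs)[0] == []

    def test_random_sets_match_pairwise_oracle(self, rng):
        for _ in range(200):
            n = int(rng.integers(2, 15))
            svs = []
            for i in range(n):
                t = ["DEL", "DUP", "INV", "TRA"][int(rng.integers(0, 4))]
                c1 = f"chr{int(rng.integers(1, 3))}"
                p1 = int(rng.integers(1, 30 * MB))
                if t == "TRA":
                    c2 = f"chr{int(rng.integers(1, 3))}"
                    while c2 == c1:
                        c2 = f"chr{int(rng.integers(1, 4))}"
                    svs.append(sv(f"s{int(rng.integers(0, 4))}", p1,
                                  int(rng.integers(1, 30 * MB)), c1, t, c2))
                else:
                    svs.append(sv(f"s{int(rng.integers(0, 4))}", p1,
                                  p1 + int(rng.integers(100, 5 * MB)), c1, t))
            _, flags = call_hotspots(svs)
            assert flags == hotspot_oracle(svs)

    def test_invariance_to_order_and_shift(self, rng):
        svs = [sv(f"s{i % 3}", int(p), int(p) + 50_000)
               for i, p in enumerate(rng.integers(1, 40 * MB, 20))]
        _, flags = call_hotspots(svs)
        perm = rng.permutation(len(svs))
        _, flags_perm = call_hotspots([svs[i] for i in perm])
        assert [flags[i] for i in perm] == flags_perm
        shifted = [SVRecord(s.sample_id, s.sv_type, s.chrom1, s.pos1 + 777,
                            s.chrom2, s.pos2 + 777) for s in svs]
        assert call_hotspots(shifted)[1] == flags

    def test_every_member_has_partner_within_gap(self, rng):
        svs = [sv(f"s{i % 4}", int(p), int(p) + 10_000)
               for i, p in enumerate(rng.integers(1, 60 * MB, 40))]
        hotspots, _ = call_hotspots(svs)
        for hs in hotspots:
            for m in hs.members:
                ok = False
                for other in hs.members:
                    if other.sample_id == m.sample_id:
                        continue
                    for c1, p1 in m.breakpoints:
                        for c2, p2 in other.breakpoints:
                            if c1 == c2 and abs(p1 - p2) <= MB * len(hs.members):
                                ok = True
                assert ok


class TestCfsAnnotation:
    def cfs(self):
        iv = GenomeIntervals()
        iv.add("chr1", 5 * MB, 6 * MB, "FRA1")
        return iv

    def test_one_bp_overlap_flagged(self):
        rec = sv("a", 6 * MB, 7 * MB)
        assert annotate_cfs([rec], self.cfs())[0].overlaps_cfs

    def test_no_overlap(self):
        rec = sv("a", 6 * MB + 1, 7 * MB)
        assert not annotate_cfs([rec], self.cfs())[0].overlaps_cfs

    def test_tra_window_rule(self):
        near = SVRecord("a", "TRA", "chr1", 6 * MB + 9_999, "chr2", 1000)
        far = SVRecord("a", "TRA", "chr1", 6 * MB + 10_001, "chr2", 1000)
        annos = annotate_cfs([near, far], self.cfs())
        assert annos[0].overlaps_cfs and annos[0].rule_used == "breakpoint_window"
        assert not annos[1].overlaps_cfs

    def test_random_sets_match_bruteforce(self, rng):
        iv = GenomeIntervals()
        intervals = []
        for _ in range(5):
            s = int(rng.integers(1, 50 * MB))
            e = s + int(rng.integers(100_000, 2 * MB))
            iv.add("chr1", s, e, None)
            intervals.append((s, e))
        for _ in range(300):
            p1 = int(rng.integers(1, 55 * MB))
            rec = sv("a", p1, p1 + int(rng.integers(1000, 3 * MB)))
            got = annotate_cfs([rec], iv)[0].overlaps_cfs
            want = any(not (rec.pos2 < s or rec.pos1 > e) for s, e in intervals)
            assert got == want


class TestBreakpointMH:
    def test_engineered_deletion_junction(self):
        # deleted segment begins CA and right flank begins CA -> MH 2
        left = "AAGGAC"
        deleted = "CAGGGGGGTT"
        right = "CATTAATT"
        seq = left + deleted + right
        rec = SVRecord("s", "DEL", "c", len(left), "c", len(left) + len(deleted) + 1)
        assert breakpoint_microhomology(rec, Reference({"c": seq})) == 2

    def test_simulated_mh_lengths_recovered(self, rng):
        from conftest import random_sequence
        # engineer junctions with known MH by copying k bases
        for k in (0, 2, 3):
            hits = 0
            trials = 30
            for _ in range(trials):
                seq = list(random_sequence(rng, 4000))
                p1, p2 = 1000, 3000
                # make deleted prefix equal right-flank prefix for k bases
                for j in range(k):
                    seq[p1 + j] = seq[p2 - 1 + j]
                if k < 4:  # spoil the (k+1)-th base
                    seq[p1 + k] = "A" if seq[p2 - 1 + k] != "A" else "C"
                    # and spoil the left-side suffix match
                    seq[p1 - 1] = "G" if seq[p2 - 2] != "G" else "T"
                rec = SVRecord("s", "DEL", "c", p1, "c", p2)
                got = breakpoint_microhomology(rec, Reference({"c": "".join(seq)}))
                hits += got == k
            assert hits >= trials - 2  # rare accidental extra homology allowed

    def test_random_flanks_follow_quarter_power_law(self, rng):
        from conftest import random_sequence
        n = 2000
        mhs = []
        seq = random_sequence(rng, 300_000)
        ref = Reference({"c": seq})
        for _ in range(n):
            p1 = int(rng.integers(100, 140_000))
            p2 = int(rng.integers(150_000, 290_000))
            mhs.append(breakpoint_microhomology(
                SVRecord("s", "TRA", "c", p1, "c2", p2,), RefPair(ref)))
        mhs = np.array(mhs)
        for k in (1, 2):
            expected = 0.25 ** k
            observed = (mhs >= k).mean()
            se = np.sqrt(expected * (1 - expected) / n)
            assert abs(observed - expected) < 4 * se


class RefPair:
    """Present one sequence under two chromosome names (TRA test helper)."""

    def __init__(self, ref):
        self._ref = ref
        self.chroms = ["c", "c2"]

    def fetch(self, chrom, start, end):
        return self._ref.fetch("c", start, end)


class TestAssociationTests:
    def test_observed_cohort_table_fisher(self):
        """15 of 120 junctions used microhomology (6 in CFSs of 63; 9 in
        the 57 outside): no significant bias, p ~ 0.41."""
        mh = [True] * 6 + [False] * 57 + [True] * 9 + [False] * 48
        cfs = [True] * 63 + [False] * 57
        table, p = mh_cfs_fisher(mh, cfs)
        assert table.tolist() == [[6, 57], [9, 48]]
        assert p == pytest.approx(0.41, abs=0.005)

    def test_identical_proportions_p_one(self):
        mh = [True] * 5 + [False] * 5 + [True] * 5 + [False] * 5
        cfs = [True] * 10 + [False] * 10
        assert mh_cfs_fisher(mh, cfs)[1] == pytest.approx(1.0)

    def test_fisher_matches_enumeration(self, rng):
        from scipy import stats
        for _ in range(50):
            flags = rng.random(20) < 0.4
            cfs = rng.random(20) < 0.5
            table, p = mh_cfs_fisher(flags, cfs)
            assert p == pytest.approx(
                float(stats.fisher_exact(table, "two-sided")[1]), abs=1e-12)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            mh_cfs_fisher([], [])

    def test_chisq_identical_distributions(self):
        types = ["DEL", "DUP"] * 20
        cfs = [True] * 20 + [False] * 20
        stat, p, _ = svtype_cfs_chisq(types, cfs)
        assert stat == pytest.approx(0.0) and p == pytest.approx(1.0)

    def test_chisq_hand_computed_2x2(self):
        # table [[10, 5], [5, 10]]; chi2 = 30*(10*10-5*5)^2/(15*15*15*15)
        types = ["DEL"] * 15 + ["DUP"] * 15
        cfs = [True] * 10 + [False] * 5 + [True] * 5 + [False] * 10
        stat, p, exp = svtype_cfs_chisq(types, cfs)
        want = 30 * (100 - 25) ** 2 / (15 ** 4)
        assert stat == pytest.approx(want)
        assert exp.to_numpy() == pytest.approx(np.full((2, 2), 7.5))

    def test_chisq_random_matches_scipy(self, rng):
        from scipy import stats
        import pandas as pd
        for _ in range(20):
            types = rng.choice(["DEL", "DUP", "INV"], 60).tolist()
            cfs = (rng.random(60) < 0.5).tolist()
            if len(set(types)) < 2 or len(set(cfs)) < 2:
                continue
            stat, p, _ = svtype_cfs_chisq(types, cfs)
            tab = pd.crosstab(pd.Series(types), pd.Series(cfs)).to_numpy()
            want = stats.chi2_contingency(tab, correction=False)
            assert stat == pytest.approx(want[0]) and p == pytest.approx(want[1])


def test_annotate_all_end_to_end(small_cohort):
    _, cohort = small_cohort
    from clonemut.filters import filter_sv_clonality
    svs = filter_sv_clonality(cohort.svs)
    cfs = GenomeIntervals()
    for chrom, start, end in cohort.truth.fragile_intervals:
        cfs.add(chrom, start, end, "FRA")
    table = annotate_all(svs, cfs)
    assert len(table) == len(svs)
    assert set(table.columns) >= {"in_hotspot", "overlaps_cfs", "mh_present"}
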