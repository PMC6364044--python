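import itertools

import pytest

from hicforge.digest import LEFT, RIGHT, build_fend_table
from hicforge.enzymes import BUILTIN_ENZYMES
from hicforge.pairfilter import (
    AlignedMate,
    FragmentIndex,
    classify_pair,
    filter_mapq,
    pair_mates,
    read_pairs,
    remove_duplicates,
    run_pair_filter,
    write_pairs,
)
from hicforge.simulate import SimConfig, simulate_genome, simulate_pairs, simulate_sam

HINDIII = BUILTIN_ENZYMES["HindIII"]


def _mate(rid="r", chrom="c", pos=0, strand="+", mapq=60, alen=10, mapped=True):
    return AlignedMate(rid, chrom, pos, strand, mapq, alen, mapped)


class TestMapqFilter:
    @pytest.mark.parametrize("mapq,kept", [(30, True), (29, False), (0, False), (60, True)])
    def test_threshold_boundary(self, mapq, kept):
        out = list(filter_mapq([_mate(mapq=mapq)], 30))
        assert bool(out) == kept

    def test_unmapped_dropped_regardless_of_mapq(self):
        assert list(filter_mapq([_mate(mapq=60, mapped=False)], 30)) == []


class TestPairing:
    def test_intersection_semantics(self):
        m1 = [_mate(rid=x) for x in "abc"]
        m2 = [_mate(rid=x) for x in "bcd"]
        pairs, singles = pair_mates(m1, m2)
        assert sorted(p[0].read_id for p in pairs) == ["b", "c"]
        assert singles == 2

    def test_disjoint_sets_no_pairs(self):
        pairs, singles = pair_mates([_mate(rid="a")], [_mate(rid="b")])
        assert pairs == [] and singles == 2

    def test_identical_sets_full_pairing(self):
        ids = [f"r{i}" for i in range(5)]
        pairs, singles = pair_mates(
            [_mate(rid=i) for i in ids], [_mate(rid=i) for i in ids]
        )
        assert len(pairs) == 5 and singles == 0

    def test_duplicate_read_id_errors(self):
        with pytest.raises(ValueError, match="duplicate read id"):
            pair_mates([_mate(rid="a"), _mate(rid="a")], [])


@pytest.fixture(scope="module")
def toy_index():
    """Fragments [0,4), [4,13), [13,20) on one chromosome."""
    genome = {"c": "TTTAAGCTTGGGAAGCTTCC"}
    fends = build_fend_table(genome, HINDIII, gc_window=4, map_k=3, map_window=4)
    return FragmentIndex(fends), fends


class TestFragmentAssignment:
    def test_plus_strand_faces_downstream_end(self, toy_index):
        index, fends = toy_index
        frag, fend = index.assign(_mate(pos=5, strand="+", alen=1))
        assert frag == 1
        assert (fends[fend].fragment_index, fends[fend].side) == (1, RIGHT)

    def test_minus_strand_faces_upstream_end(self, toy_index):
        index, fends = toy_index
        frag, fend = index.assign(_mate(pos=0, strand="-", alen=1))
        assert frag == 0
        assert (fends[fend].fragment_index, fends[fend].side) == (0, LEFT)

    def test_last_base_containment(self, toy_index):
        index, _ = toy_index
        frag, _ = index.assign(_mate(pos=19, strand="+", alen=1))
        assert frag == 2

    def test_five_prime_of_minus_read_is_rightmost(self, toy_index):
        index, _ = toy_index
        # leftmost pos 10, aligned length 5 -> 5' end at 14, fragment 2
        frag, _ = index.assign(_mate(pos=10, strand="-", alen=5))
        assert frag == 2

    def test_beyond_chromosome_errors(self, toy_index):
        index, _ = toy_index
        with pytest.raises(ValueError, match="beyond"):
            index.assign(_mate(pos=25, strand="+", alen=1))


def _oracle_classify(m1, m2, f1, f2):
    """Independent rule-table enumeration of the artifact taxonomy."""
    if m1.chrom != m2.chrom:
        return "valid"
    if f1 == f2:
        if m1.strand == m2.strand:
            return "self_circle"
        plus = m1 if m1.strand == "+" else m2
        minus = m2 if m1.strand == "+" else m1
        return "dangling_end" if plus.pos5 <= minus.pos5 else "self_circle"
    if abs(f1 - f2) == 1:
        return "re_ligation"
    return "valid"


class TestClassification:
    def test_dangling_end_convergent_same_fragment(self):
        m1 = _mate(pos=10, strand="+")
        m2 = _mate(pos=30, strand="-", alen=10)
        assert classify_pair(m1, m2, 5, 5) == "dangling_end"

    def test_adjacent_fragments_are_religation(self):
        assert classify_pair(_mate(), _mate(strand="-"), 5, 6) == "re_ligation"

    def test_distant_fragments_valid(self):
        assert classify_pair(_mate(), _mate(strand="-"), 2, 9) == "valid"

    def test_matches_exhaustive_oracle(self, rng):
        """Classification equals an independently written rule table over
        random strand/fragment/position combinations."""
        for _ in range(300):
            f1, f2 = rng.integers(0, 4, 2)
            m1 = _mate(pos=int(rng.integers(0, 50)), strand="+-"[rng.integers(2)])
            m2 = _mate(pos=int(rng.integers(0, 50)), strand="+-"[rng.integers(2)])
            assert classify_pair(m1, m2, int(f1), int(f2)) == _oracle_classify(
                m1, m2, int(f1), int(f2)
            )


class TestDeduplication:
    def test_identical_pairs_collapse(self):
        p = (_mate(pos=5), _mate(pos=9, strand="-"))
        out, removed = remove_duplicates([p, p])
        assert len(out) == 1 and removed == 1

    def test_swapped_mates_still_duplicates(self):
        a = (_mate(pos=5), _mate(pos=9, strand="-"))
        b = (_mate(pos=9, strand="-"), _mate(pos=5))
        out, removed = remove_duplicates([a, b])
        assert len(out) == 1 and removed == 1

    def test_near_miss_positions_survive(self):
        a = (_mate(pos=5), _mate(pos=9, strand="-"))
        b = (_mate(pos=5), _mate(pos=10, strand="-"))
        out, removed = remove_duplicates([a, b])
        assert len(out) == 2 and removed == 0

    def test_idempotent_and_order_insensitive(self, rng):
        pairs = [
            (_mate(pos=int(rng.integers(0, 5))), _mate(pos=int(rng.integers(0, 5)), strand="-"))
            for _ in range(40)
        ]
        once, _ = remove_duplicates(pairs)
        twice, removed = remove_duplicates(once)
        assert twice == once and removed == 0
        for perm_seed in range(3):
            shuffled = list(pairs)
            rng.shuffle(shuffled)
            out, _ = remove_duplicates(shuffled)
            assert len(out) == len(once)


class TestRunPairFilter:
    def _write_sam(self, path, records, chrom_len=20):
        lines = ["@HD\tVN:1.6", f"@SQ\tSN:c\tLN:{chrom_len}"]
        for rid, flag, pos, mapq in records:
            alen = 3
            lines.append(
                f"{rid}\t{flag}\tc\t{pos + 1}\t{mapq}\t{alen}M\t*\t0\t0\tAAA\tIII"
            )
        path.write_text("\n".join(lines) + "\n")

    def test_hand_constructed_fixture(self, toy_index, tmp_path):
        """10 pairs with 2 planted duplicates, 1 self-circle, 1 low-MAPQ
        mate: 6 valid pairs survive."""
        _, fends = toy_index
        # valid pairs: fragment 0 (+ strand) vs fragment 2 (- strand),
        # distinct coordinates so none are mutual duplicates
        v1 = [(f"v{i}", 0, i % 4, 60) for i in range(6)]
        v2 = [(f"v{i}", 16, 12 + i, 60) for i in range(6)]
        # duplicates of v0
        v1 += [("d1", 0, 0, 60), ("d2", 0, 0, 60)]
        v2 += [("d1", 16, 12, 60), ("d2", 16, 12, 60)]
        # self-circle: same fragment 1, + downstream of -
        v1 += [("s1", 0, 10, 60)]
        v2 += [("s1", 16, 5, 60)]  # minus leftmost 5 -> 5' at 7 < 10
        # low MAPQ mate 1
        v1 += [("m1", 0, 0, 5)]
        v2 += [("m1", 16, 14, 60)]
        sam1, sam2 = tmp_path / "1.sam", tmp_path / "2.sam"
        self._write_sam(sam1, v1)
        self._write_sam(sam2, v2)
        valid, report = run_pair_filter(sam1, sam2, fends)
        assert len(valid) == 6
        assert report.category_counts["duplicate"] == 2
        assert report.category_counts["self_circle"] == 1
        assert report.singletons == 1  # low-MAPQ mate's partner

    def test_all_low_mapq_gives_empty(self, toy_index, tmp_path):
        _, fends = toy_index
        sam1, sam2 = tmp_path / "1.sam", tmp_path / "2.sam"
        self._write_sam(sam1, [("a", 0, 0, 0)])
        self._write_sam(sam2, [("a", 16, 14, 0)])
        valid, report = run_pair_filter(sam1, sam2, fends)
        assert valid == []
        assert report.mapq_pass_1 == 0 and report.mapq_pass_2 == 0

    def test_unknown_chromosome_errors(self, toy_index, tmp_path):
        _, fends = toy_index
        sam1, sam2 = tmp_path / "1.sam", tmp_path / "2.sam"
        lines = ["@HD\tVN:1.6", "@SQ\tSN:other\tLN:50",
                 "x\t0\tother\t1\t60\t3M\t*\t0\t0\tAAA\tIII"]
        sam1.write_text("\n".join(lines) + "\n")
        sam2.write_text("\n".join(lines) + "\n")
        with pytest.raises(KeyError, match="other"):
            run_pair_filter(sam1, sam2, fends)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_simulated_truth_recovered_exactly(self, seed, tmp_path):
        """FilterReport category counts equal the planted truth on simulated
        SAM files carrying every artifact class."""
        cfg = SimConfig(seed=seed, n_chroms=2, chrom_length=100_000,
                        sites_per_chrom=40, n_pairs=3000, dup_rate=0.04,
                        low_mapq_rate=0.05, self_circle_rate=0.03,
                        dangling_rate=0.02, religation_rate=0.02)
        genome, _ = simulate_genome(cfg)
        fends = build_fend_table(genome, cfg.get_enzyme(), map_k=20, map_window=100)
        pairs, _ = simulate_pairs(cfg, fends)
        s1, s2 = tmp_path / "1.sam", tmp_path / "2.sam"
        truth = simulate_sam(pairs, cfg, fends, s1, s2)
        valid, report = run_pair_filter(s1, s2, fends)
        assert report.category_counts == truth["category_counts"]
        assert report.singletons == truth["singletons"]
        assert report.paired == truth["paired"]
        assert len(valid) == truth["n_valid"]
        # conservation: categories partition the paired input
        assert sum(report.category_counts.values()) == report.paired

    def test_pairs_table_round_trip(self, toy_index, tmp_path):
        _, fends = toy_index
        from hicforge.pairfilter import PairRecord

        pairs = [PairRecord("c", 1, "+", 0, "c", 15, "-", 4)]
        path = tmp_path / "pairs.tsv"
        write_pairs(pairs, path)
        back = read_pairs(path)
        assert [(p.chrom1, p.pos1, p.strand1, p.fend1) for p in back] == [
            ("c", 1, "+", 0)
        ]
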