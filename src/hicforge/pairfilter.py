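"""Filtering of independently aligned Hi-C mates into valid read pairs.

The two mates of a Hi-C pair are mapped independently (no proximity
constraint), so pairing and artifact removal happen here: low-MAPQ and
unmapped mates are dropped, mates are re-paired by read id, PCR duplicates
are collapsed, and non-informative ligation products are classified and
removed. The artifact taxonomy is the standard one:

* ``dangling_end`` — both mates on one fragment, strands convergent: an
  unligated (or re-filled) fragment sequenced from both sides.
* ``self_circle`` — both mates on one fragment, strands divergent or
  identical: the fragment circularized on itself.
* ``re_ligation`` — mates on adjacent fragments: religation of a cut that
  carries no spatial information.
* ``valid`` — everything else; only these enter normalization.
"""

from __future__ import annotations

import gzip
import json
from bisect import bisect_right
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Sequence

import pysam

from .digest import LEFT, RIGHT, Fragment, FragmentEnd, fragments_from_fends

CATEGORIES = ("valid", "self_circle", "dangling_end", "re_ligation", "duplicate")


@dataclass(frozen=True)
class AlignedMate:
    read_id: str
    chrom: str
    pos: int  # 0-based leftmost mapped coordinate
    strand: str  # "+" or "-"
    mapq: int
    aligned_length: int = 1
    is_mapped: bool = True

    @property
    def pos5(self) -> int:
        """5' (ligation-proximal) position: leftmost base for ``+`` reads,
        rightmost for ``-`` reads."""
        if self.strand == "+":
            return self.pos
        return self.pos + self.aligned_length - 1


@dataclass
class PairRecord:
    chrom1: str
    pos1: int
    strand1: str
    fend1: int
    chrom2: str
    pos2: int
    strand2: str
    fend2: int
    frag1: int = -1
    frag2: int = -1


@dataclass
class FilterReport:
    """Read accounting at every stage; categories partition the paired input."""

    total_mates_1: int = 0
    total_mates_2: int = 0
    mapq_pass_1: int = 0
    mapq_pass_2: int = 0
    singletons: int = 0
    paired: int = 0
    category_counts: dict = field(default_factory=lambda: {c: 0 for c in CATEGORIES})

    def to_json(self, path: str) -> None:
        with open(path, "w") as fh:
            json.dump(self.__dict__, fh, indent=2)


def filter_mapq(
    mates: Iterable[AlignedMate], threshold: int = 30
) -> Iterator[AlignedMate]:
    """Keep mapped mates with ``mapq >= threshold``, preserving order."""
    for m in mates:
        if m.is_mapped and m.mapq >= threshold:
            yield m


def pair_mates(
    mates1: Iterable[AlignedMate], mates2: Iterable[AlignedMate]
) -> tuple[list[tuple[AlignedMate, AlignedMate]], int]:
    """Match mates by read id; returns (pairs, singleton count).

    Raises on a duplicated read id within one file.
    """
    by_id: dict[str, AlignedMate] = {}
    for m in mates1:
        if m.read_id in by_id:
            raise ValueError(f"duplicate read id {m.read_id!r} in mate-1 input")
        by_id[m.read_id] = m
    pairs = []
    seen2: set[str] = set()
    matched: set[str] = set()
    for m in mates2:
        if m.read_id in seen2:
            raise ValueError(f"duplicate read id {m.read_id!r} in mate-2 input")
        seen2.add(m.read_id)
        mate1 = by_id.get(m.read_id)
        if mate1 is not None:
            pairs.append((mate1, m))
            matched.add(m.read_id)
    singletons = (len(by_id) - len(matched)) + (len(seen2) - len(matched))
    return pairs, singletons


class FragmentIndex:
    """Per-chromosome fragment lookup and FEND-id resolution."""

    def __init__(self, fends: Sequence[FragmentEnd]):
        self.fend_ids = {
            (f.chrom, f.fragment_index, f.side): i for i, f in enumerate(fends)
        }
        self.fragments: dict[str, list[Fragment]] = {}
        for chrom in sorted({f.chrom for f in fends}):
            self.fragments[chrom] = fragments_from_fends(fends, chrom)
        self._starts = {
            chrom: [fr.start for fr in frs] for chrom, frs in self.fragments.items()
        }

    def chrom_length(self, chrom: str) -> int:
        return self.fragments[chrom][-1].end

    def assign(self, mate: AlignedMate) -> tuple[int, int]:
        """Fragment index containing the mate's 5' position, and the id of
        the fragment end the read points toward (downstream end for ``+``,
        upstream end for ``-``)."""
        if mate.chrom not in self.fragments:
            raise KeyError(f"chromosome {mate.chrom!r} absent from FEND table")
        pos = mate.pos5
        if pos < 0 or pos >= self.chrom_length(mate.chrom):
            raise ValueError(
                f"{mate.read_id}: position {pos} beyond {mate.chrom} "
                f"length {self.chrom_length(mate.chrom)}"
            )
        idx = bisect_right(self._starts[mate.chrom], pos) - 1
        side = RIGHT if mate.strand == "+" else LEFT
        return idx, self.fend_ids[(mate.chrom, idx, side)]


def classify_pair(
    mate1: AlignedMate, mate2: AlignedMate, frag1: int, frag2: int
) -> str:
    """Artifact taxonomy; see module docstring for the rule table."""
    if mate1.chrom == mate2.chrom and frag1 == frag2:
        if mate1.strand == mate2.strand:
            return "self_circle"
        plus, minus = (mate1, mate2) if mate1.strand == "+" else (mate2, mate1)
        if plus.pos5 <= minus.pos5:
            return "dangling_end"
        return "self_circle"
    if mate1.chrom == mate2.chrom and abs(frag1 - frag2) == 1:
        return "re_ligation"
    return "valid"


def _canonical_key(m1: AlignedMate, m2: AlignedMate):
    k1 = (m1.chrom, m1.pos5, m1.strand)
    k2 = (m2.chrom, m2.pos5, m2.strand)
    return (k1, k2) if k1 <= k2 else (k2, k1)


def remove_duplicates(
    pairs: Sequence[tuple[AlignedMate, AlignedMate]]
) -> tuple[list[tuple[AlignedMate, AlignedMate]], int]:
    """Collapse pairs sharing both 5' coordinates/strands (mates put in
    canonical order first, so swapped mates still count as duplicates).
    The first-encountered pair survives."""
    seen: set = set()
    out = []
    removed = 0
    for m1, m2 in pairs:
        key = _canonical_key(m1, m2)
        if key in seen:
            removed += 1
        else:
            seen.add(key)
            out.append((m1, m2))
    return out, removed


def read_sam_mates(path: str) -> Iterator[AlignedMate]:
    """Primary alignments from a SAM/BAM file (unmapped records included,
    flagged unmapped; secondary/supplementary skipped)."""
    mode = "rb" if str(path).endswith(".bam") else "r"
    with pysam.AlignmentFile(path, mode, check_sq=False) as fh:
        for rec in fh:
            if rec.is_secondary or rec.is_supplementary:
                continue
            if rec.is_unmapped:
                yield AlignedMate(rec.query_name, "*", 0, "+", 0, 1, is_mapped=False)
                continue
            yield AlignedMate(
                rec.query_name,
                rec.reference_name,
                rec.reference_start,
                "-" if rec.is_reverse else "+",
                rec.mapping_quality,
                rec.reference_length or len(rec.query_sequence or "") or 1,
            )


def run_pair_filter(
    sam1: str,
    sam2: str,
    fends: Sequence[FragmentEnd],
    mapq: int = 30,
    drop_religation: bool = True,
) -> tuple[list[PairRecord], FilterReport]:
    """MAPQ filter -> pairing -> fragment assignment -> dedup -> classify."""
    report = FilterReport()
    index = FragmentIndex(fends)

    mates1 = list(read_sam_mates(sam1))
    mates2 = list(read_sam_mates(sam2))
    report.total_mates_1 = len(mates1)
    report.total_mates_2 = len(mates2)
    kept1 = list(filter_mapq(mates1, mapq))
    kept2 = list(filter_mapq(mates2, mapq))
    report.mapq_pass_1 = len(kept1)
    report.mapq_pass_2 = len(kept2)

    pairs, singletons = pair_mates(kept1, kept2)
    report.singletons = singletons
    report.paired = len(pairs)

    deduped, n_dup = remove_duplicates(pairs)
    report.category_counts["duplicate"] = n_dup

    valid: list[PairRecord] = []
    for m1, m2 in deduped:
        frag1, fend1 = index.assign(m1)
        frag2, fend2 = index.assign(m2)
        category = classify_pair(m1, m2, frag1, frag2)
        if category == "re_ligation" and not drop_religation:
            category = "valid"
        report.category_counts[category] += 1
        if category == "valid":
            valid.append(
                PairRecord(
                    m1.chrom, m1.pos5, m1.strand, fend1,
                    m2.chrom, m2.pos5, m2.strand, fend2,
                    frag1, frag2,
                )
            )
    return valid, report


# ---------------------------------------------------------------------------
# Valid-pairs table I/O (tab-separated, optional gzip)

_PAIR_HEADER = "#chrom1\tpos1\tstrand1\tfend1\tchrom2\tpos2\tstrand2\tfend2"


def _open(path: str, mode: str):
    if str(path).endswith(".gz"):
        return gzip.open(path, mode)
    return open(path, mode)


def write_pairs(pairs: Iterable[PairRecord], path: str) -> None:
    with _open(path, "wt") as fh:
        fh.write(_PAIR_HEADER + "\n")
        for p in pairs:
            fh.write(
                f"{p.chrom1}\t{p.pos1}\t{p.strand1}\t{p.fend1}\t"
                f"{p.chrom2}\t{p.pos2}\t{p.strand2}\t{p.fend2}\n"
            )


def read_pairs(path: str) -> list[PairRecord]:
    out = []
    with _open(path, "rt") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 8:
                raise ValueError(f"{path}:{lineno}: expected 8 columns")
            c1, p1, s1, f1, c2, p2, s2, f2 = parts
            out.append(
                PairRecord(c1, int(p1), s1, int(f1), c2, int(p2), s2, int(f2))
            )
    return out
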