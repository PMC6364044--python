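"""In-silico restriction digestion and fragment-end (FEND) annotation.

The FEND table is the unit of bias correction: every restriction fragment
contributes two ends, each annotated with the features the explicit-factor
model corrects for — fragment length, local GC content, and local
mappability. Coordinates are 0-based half-open throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable, Mapping, Sequence

from Bio import SeqIO

from .enzymes import RestrictionEnzyme, reverse_complement

#: gc value for FENDs whose GC window is entirely N.
GC_SENTINEL = -1.0

LEFT = "L"  # FEND at the left (upstream) end of its fragment
RIGHT = "R"  # FEND at the right (downstream) end of its fragment


@dataclass(frozen=True)
class Fragment:
    """A restriction fragment; fragments tile each chromosome exactly."""

    chrom: str
    start: int
    end: int
    index: int

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(f"fragment {self.chrom}:{self.start}-{self.end} empty")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class FragmentEnd:
    """One end of a restriction fragment with its bias features.

    ``coord`` is the cut-site position the end abuts: fragment start for a
    left end, fragment end for a right end. ``gc`` and ``mappability`` are
    fractions in [0, 1]; ``gc`` may be the all-N sentinel ``-1``.
    """

    chrom: str
    coord: int
    side: str  # LEFT or RIGHT
    fragment_index: int
    fragment_length: int
    gc: float = 0.0
    mappability: float = 0.0


def digest_sequence(
    seq: str, enzyme: RestrictionEnzyme, chrom: str
) -> list[Fragment]:
    """Cut ``seq`` at every occurrence of the enzyme's recognition site.

    Scanning is top-strand only and case-insensitive; palindromy of the
    site (enforced at enzyme construction) makes that exhaustive. Cut
    positions are ``site_start + cut_offset``. A sequence with no site
    yields a single fragment covering it.
    """
    if not seq:
        raise ValueError(f"{chrom}: empty sequence")
    upper = seq.upper()
    site = enzyme.site
    cuts: list[int] = []
    pos = upper.find(site)
    while pos != -1:
        cut = pos + enzyme.cut_offset
        if 0 < cut < len(seq):
            cuts.append(cut)
        pos = upper.find(site, pos + 1)
    bounds = [0, *cuts, len(seq)]
    return [
        Fragment(chrom, a, b, i)
        for i, (a, b) in enumerate(zip(bounds[:-1], bounds[1:]))
    ]


def fragment_ends(fragments: Sequence[Fragment]) -> list[FragmentEnd]:
    """Two FENDs per fragment (features not yet annotated)."""
    out = []
    for frag in fragments:
        out.append(FragmentEnd(frag.chrom, frag.start, LEFT, frag.index, frag.length))
        out.append(FragmentEnd(frag.chrom, frag.end, RIGHT, frag.index, frag.length))
    return out


def _interior_window(seq: str, frag_start: int, frag_end: int, fend: FragmentEnd,
                     window: int) -> str:
    """Bases interior to the fragment, starting at the FEND coordinate."""
    if fend.side == LEFT:
        return seq[frag_start : min(frag_start + window, frag_end)]
    return seq[max(frag_end - window, frag_start) : frag_end]


def compute_gc(window_seq: str) -> float:
    """GC fraction over non-N bases; sentinel ``-1`` if every base is N."""
    up = window_seq.upper()
    informative = sum(1 for b in up if b != "N")
    if informative == 0:
        return GC_SENTINEL
    gc = sum(1 for b in up if b in "GC")
    return gc / informative


def _kmer_counts(genome: Mapping[str, str], k: int) -> dict[str, int]:
    counts: dict[str, int] = {}
    for seq in genome.values():
        up = seq.upper()
        for i in range(len(up) - k + 1):
            kmer = up[i : i + k]
            counts[kmer] = counts.get(kmer, 0) + 1
    return counts


class MappabilityIndex:
    """Exact k-mer uniqueness index over both strands of a genome.

    A k-mer is unique iff it occurs exactly once in the genome counting
    occurrences on both strands (so a palindromic k-mer is never unique,
    and any k-mer shared between two chromosomes is not either). k-mers
    containing N count as non-unique.
    """

    def __init__(self, genome: Mapping[str, str], k: int):
        self.k = k
        self._counts = _kmer_counts(genome, k)

    def is_unique(self, kmer: str) -> bool:
        kmer = kmer.upper()
        if "N" in kmer or len(kmer) != self.k:
            return False
        total = self._counts.get(kmer, 0)
        rc = reverse_complement(kmer)
        if rc != kmer:
            total += self._counts.get(rc, 0)
        else:
            total *= 2  # palindrome: each locus carries it on both strands
        return total == 1

    def window_fraction(self, seq: str, start: int, end: int) -> float:
        """Fraction of unique k-mers among those starting in [start, end)."""
        starts = range(start, min(end, len(seq) - self.k + 1))
        n = 0
        unique = 0
        for i in starts:
            n += 1
            if self.is_unique(seq[i : i + self.k]):
                unique += 1
        return unique / n if n else 0.0


def compute_mappability(
    genome: Mapping[str, str],
    fend: FragmentEnd,
    frag_start: int,
    frag_end: int,
    index: MappabilityIndex,
    window: int,
) -> float:
    """Unique-k-mer fraction over the window interior to the fragment."""
    seq = genome[fend.chrom]
    if fend.side == LEFT:
        lo, hi = frag_start, min(frag_start + window, frag_end)
    else:
        lo, hi = max(frag_end - window, frag_start), frag_end
    return index.window_fraction(seq, lo, hi)


def build_fend_table(
    genome: Mapping[str, str],
    enzyme: RestrictionEnzyme,
    gc_window: int = 200,
    map_k: int = 50,
    map_window: int = 500,
) -> list[FragmentEnd]:
    """Digest every chromosome and annotate all FENDs.

    Output order is normalized (chromosome name, then coordinate, then
    side), so the table is identical however chromosomes are scheduled.
    """
    if not genome:
        raise ValueError("empty genome")
    index = MappabilityIndex(genome, map_k)
    table: list[FragmentEnd] = []
    for chrom in sorted(genome):
        seq = genome[chrom]
        frags = digest_sequence(seq, enzyme, chrom)
        for fend in fragment_ends(frags):
            frag = frags[fend.fragment_index]
            win = _interior_window(seq, frag.start, frag.end, fend, gc_window)
            gc = compute_gc(win)
            mapp = compute_mappability(
                genome, fend, frag.start, frag.end, index, map_window
            )
            table.append(replace(fend, gc=gc, mappability=mapp))
    table.sort(key=lambda f: (f.chrom, f.coord, f.side))
    return table


# ---------------------------------------------------------------------------
# FASTA / BED I/O

def read_fasta(path: str) -> dict[str, str]:
    """Multi-record FASTA (wrapped or not, lowercase tolerated) -> dict."""
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(path, "fasta")}


_FEND_HEADER = "#chrom\tstart\tend\tfend_id\tfragment_length\tgc\tmappability\tside\tfragment_index"


def write_fend_bed(fends: Iterable[FragmentEnd], path: str) -> None:
    """BED-style FEND table: 0-based half-open single-base intervals."""
    with open(path, "w") as fh:
        fh.write(_FEND_HEADER + "\n")
        for i, f in enumerate(fends):
            # the FEND occupies the base adjacent to its cut site
            start = f.coord if f.side == LEFT else f.coord - 1
            fh.write(
                f"{f.chrom}\t{start}\t{start + 1}\tfend_{i}\t"
                f"{f.fragment_length}\t{f.gc!r}\t{f.mappability!r}\t"
                f"{f.side}\t{f.fragment_index}\n"
            )


def read_fend_bed(path: str) -> list[FragmentEnd]:
    fends = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 9:
                raise ValueError(f"{path}:{lineno}: expected 9 columns, got {len(parts)}")
            try:
                chrom, start, _end, _fid, frag_len, gc, mapp, side, frag_idx = parts
                if side not in (LEFT, RIGHT):
                    raise ValueError(f"bad side {side!r}")
                start_i = int(start)
                coord = start_i if side == LEFT else start_i + 1
                fends.append(
                    FragmentEnd(
                        chrom, coord, side, int(frag_idx), int(frag_len),
                        float(gc), float(mapp),
                    )
                )
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: malformed FEND line: {exc}") from exc
    return fends


def fragments_from_fends(fends: Sequence[FragmentEnd], chrom: str) -> list[Fragment]:
    """Reconstruct the fragment tiling of one chromosome from its FENDs."""
    per = sorted(
        (f for f in fends if f.chrom == chrom), key=lambda f: (f.fragment_index, f.side)
    )
    frags: dict[int, list[FragmentEnd]] = {}
    for f in per:
        frags.setdefault(f.fragment_index, []).append(f)
    out = []
    for idx in sorted(frags):
        ends = {f.side: f for f in frags[idx]}
        out.append(Fragment(chrom, ends[LEFT].coord, ends[RIGHT].coord, idx))
    return out
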