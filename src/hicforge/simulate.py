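"""Synthetic Hi-C data with known ground truth.

Every upstream input of the pipeline can be generated at desk scale with
its truth recorded: a small multi-chromosome genome with planted
restriction sites (and none elsewhere), FASTQ reads with ligation
junctions planted at known offsets, aligned mate files with planted PCR
duplicates / low-MAPQ mates / self-circles / dangling ends / re-ligations,
read pairs drawn from a distance-decaying contact model with planted TAD
blocks and multiplicative per-FEND biases, and directly sampled Poisson
contact matrices with planted domains. All generators are pure functions
of a seeded configuration.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .digest import LEFT, RIGHT, FragmentEnd, digest_sequence
from .enzymes import BUILTIN_ENZYMES, RestrictionEnzyme
from .matrix import ContactMatrix
from .pairfilter import PairRecord

_BASES = np.array(list("ACGT"))


@dataclass
class SimConfig:
    seed: int = 0
    n_chroms: int = 2
    chrom_length: int = 100_000
    sites_per_chrom: int = 40
    enzyme: str = "HindIII"
    n_pairs: int = 20_000
    decay_exponent: float = 1.0
    bin_size: int = 5_000
    tad_blocks: dict = field(default_factory=dict)  # chrom -> [(start_bin, end_bin)]
    tad_enrichment: float = 1.0
    fend_bias: dict = field(default_factory=dict)  # feature -> list of group effects
    junction_rate: float = 0.15
    read_length: int = 75
    dup_rate: float = 0.0
    low_mapq_rate: float = 0.0
    self_circle_rate: float = 0.0
    dangling_rate: float = 0.0
    religation_rate: float = 0.0

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)

    def get_enzyme(self) -> RestrictionEnzyme:
        return BUILTIN_ENZYMES[self.enzyme]


def _random_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(_BASES[rng.integers(0, 4, n)])


def _scrub(seq: list[str], motif: str, rng: np.random.Generator,
           protected: set[int]) -> None:
    """Mutate bases until ``motif`` occurs nowhere outside protected sites."""
    m = len(motif)
    while True:
        text = "".join(seq)
        pos = text.find(motif)
        dirty = []
        while pos != -1:
            if pos not in protected:
                dirty.append(pos)
            pos = text.find(motif, pos + 1)
        if not dirty:
            return
        for p in dirty:
            # mutate one base of the occurrence that is not inside any
            # protected site occurrence
            for off in range(m):
                i = p + off
                if not any(s <= i < s + m for s in protected):
                    current = seq[i]
                    choices = [b for b in "ACGT" if b != current]
                    seq[i] = choices[int(rng.integers(0, 3))]
                    break


def simulate_genome(config: SimConfig) -> tuple[dict[str, str], dict]:
    """Random genome with enzyme sites planted at recorded positions only."""
    rng = config.rng()
    enzyme = config.get_enzyme()
    site = enzyme.site
    genome: dict[str, str] = {}
    truth: dict = {"site_positions": {}, "cut_positions": {}}
    for c in range(config.n_chroms):
        chrom = f"chr{c + 1}"
        L = config.chrom_length
        seq = list(_random_seq(rng, L))
        # plant sites away from the chromosome ends, min spacing 2*site len
        usable = np.arange(len(site), L - 2 * len(site))
        positions = np.sort(
            rng.choice(usable[:: 2 * len(site)], config.sites_per_chrom, replace=False)
        )
        for p in positions:
            seq[p : p + len(site)] = list(site)
        _scrub(seq, site, rng, set(int(p) for p in positions))
        genome[chrom] = "".join(seq)
        truth["site_positions"][chrom] = [int(p) for p in positions]
        truth["cut_positions"][chrom] = [
            int(p) + enzyme.cut_offset for p in positions
        ]
        frags = digest_sequence(genome[chrom], enzyme, chrom)
        assert [f.start for f in frags[1:]] == truth["cut_positions"][chrom]
    return genome, truth


# ---------------------------------------------------------------------------
# Contact model at fend level

def _fend_biases(
    fends: Sequence[FragmentEnd], config: SimConfig
) -> tuple[np.ndarray, dict]:
    """Per-FEND multiplicative bias from quantile-group effects."""
    bias = np.ones(len(fends))
    groups: dict[str, list[int]] = {}
    for feature, effects in config.fend_bias.items():
        if feature == "length":
            vals = np.array([f.fragment_length for f in fends], dtype=float)
        elif feature == "gc":
            vals = np.array([f.gc for f in fends])
        else:
            vals = np.array([f.mappability for f in fends])
        B = len(effects)
        qs = np.quantile(vals, np.linspace(0, 1, B + 1))
        lab = np.searchsorted(np.unique(qs)[1:-1], vals, side="right")
        lab = np.minimum(lab, B - 1)
        bias *= np.asarray(effects, dtype=float)[lab]
        groups[feature] = lab.tolist()
    return bias, groups


def _block_of_bin(blocks: Sequence[tuple[int, int]], b: int) -> int:
    for k, (s, e) in enumerate(blocks):
        if s <= b < e:
            return k
    return -1


def simulate_pairs(
    config: SimConfig, fends: Sequence[FragmentEnd]
) -> tuple[list[PairRecord], dict]:
    """Sample intra-chromosomal read pairs from the planted contact model.

    Pair probability is proportional to
    ``(1 + d_bins)^-alpha * enrichment^[same TAD block] * bias(p) * bias(q)``.
    """
    rng = config.rng()
    bias, groups = _fend_biases(fends, config)
    coords = np.array([f.coord for f in fends])
    chrom_of = np.array([f.chrom for f in fends])
    frag_of = np.array([f.fragment_index for f in fends])

    ps, qs = [], []
    for chrom in sorted(set(chrom_of)):
        idx = np.flatnonzero(chrom_of == chrom)
        a, b = np.triu_indices(len(idx), k=1)
        # only informative products: fragments farther apart than adjacent
        keep = np.abs(frag_of[idx[a]] - frag_of[idx[b]]) > 1
        ps.append(idx[a][keep])
        qs.append(idx[b][keep])
    P = np.concatenate(ps)
    Q = np.concatenate(qs)
    d_bins = np.abs(coords[P] - coords[Q]) // config.bin_size
    w = (1.0 + d_bins) ** (-config.decay_exponent)
    w *= bias[P] * bias[Q]
    if config.tad_enrichment != 1.0 and config.tad_blocks:
        for i, (p, q) in enumerate(zip(P, Q)):
            blocks = config.tad_blocks.get(chrom_of[p], [])
            bp = _block_of_bin(blocks, coords[p] // config.bin_size)
            bq = _block_of_bin(blocks, coords[q] // config.bin_size)
            if bp != -1 and bp == bq:
                w[i] *= config.tad_enrichment
    w = w / w.sum()
    chosen = rng.choice(len(P), size=config.n_pairs, p=w)

    # chromosome lengths for position clipping
    chrom_len = {c: int(coords[chrom_of == c].max()) for c in set(chrom_of)}

    def _read_for(fi: int) -> tuple[str, int, str]:
        f = fends[fi]
        max_off = min(49, f.fragment_length - 1)
        off = int(rng.integers(0, max_off + 1))
        if f.side == RIGHT:  # + read pointing downstream toward the cut
            return f.chrom, min(f.coord - 1 - off, chrom_len[f.chrom] - 1), "+"
        return f.chrom, min(f.coord + off, chrom_len[f.chrom] - 1), "-"

    pairs: list[PairRecord] = []
    used_keys: set = set()
    counts_by_fendpair: dict[tuple[int, int], int] = {}
    for k in chosen:
        p, q = int(P[k]), int(Q[k])
        key_fp = (min(p, q), max(p, q))
        counts_by_fendpair[key_fp] = counts_by_fendpair.get(key_fp, 0) + 1
        for _attempt in range(200):
            c1, pos1, s1 = _read_for(p)
            c2, pos2, s2 = _read_for(q)
            key = tuple(sorted([(c1, pos1, s1), (c2, pos2, s2)]))
            if key not in used_keys:
                used_keys.add(key)
                break
        pairs.append(
            PairRecord(c1, pos1, s1, p, c2, pos2, s2, q,
                       fends[p].fragment_index, fends[q].fragment_index)
        )
    truth = {
        "bias": bias.tolist(),
        "groups": groups,
        "counts_by_fendpair": counts_by_fendpair,
        "chrom_lengths": chrom_len,
    }
    return pairs, truth


# ---------------------------------------------------------------------------
# FASTQ with planted ligation junctions

def simulate_fastq(
    pairs: Sequence[PairRecord], config: SimConfig, out1: str, out2: str
) -> dict:
    """Write the two mate files; junctions planted in mate-1 reads only.

    Exactly ``round(junction_rate * n)`` mate-1 reads carry the junction,
    at recorded offsets; no read contains a spurious junction.
    """
    rng = config.rng()
    enzyme = config.get_enzyme()
    junction = enzyme.ligation_junction()
    n = len(pairs)
    n_junc = round(config.junction_rate * n)
    junc_idx = set(int(i) for i in rng.choice(n, size=n_junc, replace=False))
    L = config.read_length
    qual = "I" * L
    truth: dict = {"n_reads": n, "n_junction": n_junc, "offsets": {}}

    def _junction_free(length: int) -> str:
        while True:
            s = _random_seq(rng, length)
            if junction not in s:
                return s

    with open(out1, "w") as f1, open(out2, "w") as f2:
        for i in range(n):
            rid = f"read_{i}"
            if i in junc_idx:
                off = int(rng.integers(5, L - len(junction) - 5))
                while True:
                    seq = _junction_free(off) + junction + _junction_free(
                        L - off - len(junction)
                    )
                    if seq.find(junction) == off:
                        break
                truth["offsets"][rid] = off
            else:
                seq = _junction_free(L)
            f1.write(f"@{rid}\n{seq}\n+\n{qual}\n")
            f2.write(f"@{rid}\n{_junction_free(L)}\n+\n{qual}\n")
    return truth


# ---------------------------------------------------------------------------
# SAM with planted filtering artifacts

def _sam_record(
    rid: str, chrom: str, pos5: int, strand: str, mapq: int, alen: int,
    chrom_len: int,
) -> str:
    alen = max(1, alen)
    if strand == "+":
        left = pos5
        alen = min(alen, chrom_len - left)
        flag = 0
    else:
        left = max(pos5 - (alen - 1), 0)
        alen = pos5 - left + 1
        flag = 16
    seq = "A" * alen
    return (
        f"{rid}\t{flag}\t{chrom}\t{left + 1}\t{mapq}\t{alen}M\t*\t0\t0\t"
        f"{seq}\t{'I' * alen}"
    )


def simulate_sam(
    pairs: Sequence[PairRecord],
    config: SimConfig,
    fends: Sequence[FragmentEnd],
    out1: str,
    out2: str,
    alen: int = 36,
) -> dict:
    """Two mate SAM files: the given valid pairs plus planted artifacts.

    Artifact counts are ``round(rate * n_pairs)`` each; truth records the
    expected filter accounting exactly.
    """
    rng = config.rng()
    chrom_len = {}
    frag_by_chrom: dict[str, list[tuple[int, int, int]]] = {}
    for f in fends:
        chrom_len[f.chrom] = max(chrom_len.get(f.chrom, 0), f.coord)
    for f in fends:
        if f.side == LEFT:
            frag_by_chrom.setdefault(f.chrom, []).append(
                (f.fragment_index, f.coord, f.coord + f.fragment_length)
            )
    for c in frag_by_chrom:
        frag_by_chrom[c].sort()

    n = len(pairs)
    n_dup = round(config.dup_rate * n)
    n_low = round(config.low_mapq_rate * n)
    n_sc = round(config.self_circle_rate * n)
    n_de = round(config.dangling_rate * n)
    n_rl = round(config.religation_rate * n)

    records1: list[tuple[str, str, int, str, int]] = []
    records2: list[tuple[str, str, int, str, int]] = []
    rid_counter = 0

    def _add(c1, p1, s1, c2, p2, s2, mapq1=60, mapq2=60):
        nonlocal rid_counter
        rid = f"sim_{rid_counter}"
        rid_counter += 1
        records1.append((rid, c1, p1, s1, mapq1))
        records2.append((rid, c2, p2, s2, mapq2))

    for p in pairs:
        _add(p.chrom1, p.pos1, p.strand1, p.chrom2, p.pos2, p.strand2)

    # PCR duplicates: exact coordinate copies of existing valid pairs
    dup_of = rng.choice(n, size=n_dup, replace=False) if n_dup else []
    for k in dup_of:
        p = pairs[int(k)]
        _add(p.chrom1, p.pos1, p.strand1, p.chrom2, p.pos2, p.strand2)

    # low-MAPQ mate-1 pairs: dropped at the MAPQ stage, mate 2 singleton
    chroms = sorted(frag_by_chrom)
    big_frags = [
        (c, fi, s, e)
        for c in chroms
        for (fi, s, e) in frag_by_chrom[c]
        if e - s >= 12
    ]

    def _pick_frag():
        return big_frags[int(rng.integers(0, len(big_frags)))]

    used: set = set()

    def _unique(c1, p1, s1, c2, p2, s2) -> bool:
        key = tuple(sorted([(c1, p1, s1), (c2, p2, s2)]))
        if key in used:
            return False
        used.add(key)
        return True

    for p in pairs:
        used.add(tuple(sorted([(p.chrom1, p.pos1, p.strand1),
                               (p.chrom2, p.pos2, p.strand2)])))

    for _ in range(n_low):
        c, fi, s, e = _pick_frag()
        while True:
            p1 = int(rng.integers(s, e))
            p2 = int(rng.integers(s, e))
            if _unique(c, p1, "+", c, p2, "-"):
                break
        _add(c, p1, "+", c, p2, "-", mapq1=10)

    for _ in range(n_sc):  # same fragment, + strictly downstream of -
        while True:
            c, fi, s, e = _pick_frag()
            plus = int(rng.integers(s + (e - s) // 2, e))
            minus = int(rng.integers(s, s + (e - s) // 2))
            if plus > minus and _unique(c, plus, "+", c, minus, "-"):
                break
        _add(c, plus, "+", c, minus, "-")

    for _ in range(n_de):  # same fragment, convergent
        while True:
            c, fi, s, e = _pick_frag()
            plus = int(rng.integers(s, s + (e - s) // 2))
            minus = int(rng.integers(s + (e - s) // 2, e))
            if plus <= minus and _unique(c, plus, "+", c, minus, "-"):
                break
        _add(c, plus, "+", c, minus, "-")

    for _ in range(n_rl):  # adjacent fragments
        while True:
            c, fi, s, e = _pick_frag()
            nxt = [t for t in frag_by_chrom[c] if t[0] == fi + 1]
            if not nxt:
                continue
            _fi2, s2, e2 = nxt[0]
            p1 = int(rng.integers(s, e))
            p2 = int(rng.integers(s2, e2))
            if _unique(c, p1, "+", c, p2, "-"):
                break
        _add(c, p1, "+", c, p2, "-")

    header = "\n".join(
        ["@HD\tVN:1.6\tSO:unsorted"]
        + [f"@SQ\tSN:{c}\tLN:{chrom_len[c]}" for c in chroms]
    )
    for path, records in ((out1, records1), (out2, records2)):
        with open(path, "w") as fh:
            fh.write(header + "\n")
            for rid, c, pos5, strand, mapq in records:
                fh.write(
                    _sam_record(rid, c, pos5, strand, mapq, alen, chrom_len[c])
                    + "\n"
                )

    truth = {
        "n_valid": n,
        "category_counts": {
            "valid": n,
            "duplicate": n_dup,
            "self_circle": n_sc,
            "dangling_end": n_de,
            "re_ligation": n_rl,
        },
        "n_low_mapq": n_low,
        "paired": n + n_dup + n_sc + n_de + n_rl,
        "singletons": n_low,
    }
    return truth


# ---------------------------------------------------------------------------
# Direct contact-matrix simulation with planted domains

def plant_blocks(
    n_bins: int, rng: np.random.Generator, min_size: int = 10, max_size: int = 30
) -> list[tuple[int, int]]:
    """Tile [0, n_bins) with consecutive blocks of random size."""
    blocks = []
    pos = 0
    while pos < n_bins:
        size = int(rng.integers(min_size, max_size + 1))
        end = min(pos + size, n_bins)
        if n_bins - end < min_size:
            end = n_bins
        blocks.append((pos, end))
        pos = end
    return blocks


def simulate_contact_matrix(
    n_bins: int,
    seed: int,
    bin_size: int = 40_000,
    depth: float = 100.0,
    alpha: float = 1.0,
    enrichment: float = 5.0,
    blocks: list[tuple[int, int]] | None = None,
    chrom: str = "chrSim",
) -> tuple[ContactMatrix, list[tuple[int, int]]]:
    """Poisson observed matrix over a decay background with planted blocks.

    ``lambda[i,j] = depth * (1+|i-j|)^-alpha * enrichment^[same block]``.
    Returns the matrix and the planted block intervals (bin units).
    """
    rng = np.random.default_rng(seed)
    if blocks is None:
        blocks = plant_blocks(n_bins, rng)
    i, j = np.indices((n_bins, n_bins))
    lam = depth * (1.0 + np.abs(i - j)) ** (-alpha)
    member = np.full(n_bins, -1)
    for k, (s, e) in enumerate(blocks):
        member[s:e] = k
    same = (member[i] == member[j]) & (member[i] >= 0)
    lam = np.where(same, lam * enrichment, lam)
    upper = np.triu(rng.poisson(lam))
    vals = upper + np.triu(upper, 1).T
    return ContactMatrix(chrom, bin_size, vals.astype(float), "observed"), blocks
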