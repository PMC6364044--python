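"""Explicit-factor normalization of intra-chromosomal contact matrices.

The observed matrix O bins valid read pairs; systematic biases from
fragment length, GC content and mappability are corrected with an
explicit-factor model: fragment ends (FENDs) are partitioned into quantile
groups per feature, and a symmetric multiplicative correction table C_f is
learned for every feature so that the weight of a fend pair (p, q) is

    w(p, q) = decay(d_pq) * prod_f C_f[g_f(p), g_f(q)]

with ``decay`` the empirical distance-dependence profile estimated from
the data before normalization. Learning uses only pairs separated by more
than 500 kb, so that short-range biological structure (TSS/CTCF-driven
contacts) does not contaminate the technical correction. The learned
corrections give the per-bin-pair correction matrix E and the normalized
map N = O / E, plus the distance-aware observed-over-expected log2 map.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from sklearn.isotonic import IsotonicRegression

from .digest import GC_SENTINEL, FragmentEnd
from .matrix import (
    SENT_NO_EXPECTED,
    SENT_NO_OBSERVED,
    ContactMatrix,
    n_bins_for,
)
from .pairfilter import PairRecord

logger = logging.getLogger(__name__)

FEATURES = ("length", "gc", "mappability")
EXCLUDED_LABEL = -1


# ---------------------------------------------------------------------------
# Observed matrix

def bin_pairs(
    pairs: Sequence[PairRecord], bin_size: int, chrom_length: int, chrom: str
) -> ContactMatrix:
    """Bin intra-chromosomal pairs of one chromosome into an observed matrix.

    Both [i, j] and [j, i] are incremented for off-diagonal pairs; a pair
    with both ends in one bin counts once on the diagonal.
    """
    n = n_bins_for(chrom_length, bin_size)
    O = np.zeros((n, n))
    for p in pairs:
        if p.chrom1 != chrom or p.chrom2 != chrom:
            continue
        if p.pos1 >= chrom_length or p.pos2 >= chrom_length:
            raise ValueError(
                f"pair position beyond {chrom} length {chrom_length}"
            )
        i, j = p.pos1 // bin_size, p.pos2 // bin_size
        O[i, j] += 1
        if i != j:
            O[j, i] += 1
    return ContactMatrix(chrom, bin_size, O, "observed")


# ---------------------------------------------------------------------------
# Distance decay

@dataclass
class ExpectedProfile:
    """Mean contact count per genomic-distance bin (distance in bin units).

    ``raw`` is the direct average of O[i, j] over all bin pairs at each
    distance, pooled across chromosomes; ``smoothed`` is its isotonic
    (non-increasing beyond distance 1) regression, with zero-count
    distances imputed from the nearest positive smoothed neighbor.
    """

    raw: np.ndarray
    smoothed: np.ndarray

    def value(self, d: int | np.ndarray) -> np.ndarray:
        d = np.clip(np.asarray(d, dtype=int), 0, len(self.smoothed) - 1)
        return self.smoothed[d]


def estimate_distance_decay(matrices: Sequence[ContactMatrix]) -> ExpectedProfile:
    """Pool per-distance averages over chromosomes and smooth monotonically."""
    max_n = max(m.n_bins for m in matrices)
    sums = np.zeros(max_n)
    counts = np.zeros(max_n)
    for m in matrices:
        v = m.values
        for d in range(m.n_bins):
            sums[d] += np.trace(v, offset=d)
            counts[d] += m.n_bins - d
    if sums.sum() == 0:
        raise ValueError("no contacts: cannot estimate distance decay")
    raw = np.divide(sums, counts, out=np.zeros(max_n), where=counts > 0)

    smoothed = raw.copy()
    if max_n > 1:
        d = np.arange(1, max_n)
        iso = IsotonicRegression(increasing=False, out_of_bounds="clip")
        smoothed[1:] = iso.fit_transform(d, raw[1:], sample_weight=counts[1:])
    # impute zero-rate distances from the nearest positive smoothed neighbor
    pos = np.flatnonzero(smoothed > 0)
    zero = np.flatnonzero(smoothed <= 0)
    if len(pos) and len(zero):
        nearest = pos[np.argmin(np.abs(zero[:, None] - pos[None, :]), axis=1)]
        smoothed[zero] = smoothed[nearest]
    return ExpectedProfile(raw=raw, smoothed=smoothed)


# ---------------------------------------------------------------------------
# Feature binning

@dataclass
class FeatureBinning:
    """Quantile partition of FENDs per feature; label -1 excludes a FEND."""

    edges: dict[str, np.ndarray]
    labels: dict[str, np.ndarray]  # per-FEND group index, aligned with table

    def n_groups(self, feature: str) -> int:
        return max(len(self.edges[feature]) - 1, 1)


def _feature_values(fends: Sequence[FragmentEnd], feature: str) -> np.ndarray:
    if feature == "length":
        return np.array([f.fragment_length for f in fends], dtype=float)
    if feature == "gc":
        return np.array([f.gc for f in fends])
    return np.array([f.mappability for f in fends])


def partition_fend_features(
    fends: Sequence[FragmentEnd],
    n_groups: Mapping[str, int] | int = 20,
) -> FeatureBinning:
    """Quantile-bin each feature into (up to) ``n_groups`` groups.

    FENDs with the all-N GC sentinel are excluded (label -1) from every
    feature. Ties at quantile edges fall in the left-closed right-open
    group. Features with fewer distinct values than requested groups are
    collapsed to the available number, with a logged warning.
    """
    if isinstance(n_groups, int):
        n_groups = {f: n_groups for f in FEATURES}
    gc_vals = _feature_values(fends, "gc")
    excluded = gc_vals <= GC_SENTINEL + 1e-12
    edges: dict[str, np.ndarray] = {}
    labels: dict[str, np.ndarray] = {}
    for feature in FEATURES:
        vals = _feature_values(fends, feature)
        valid = vals[~excluded]
        if valid.size == 0:
            raise ValueError("no FENDs with valid features")
        B = n_groups[feature]
        qs = np.quantile(valid, np.linspace(0, 1, B + 1))
        e = np.unique(qs)
        if len(e) - 1 < B:
            logger.warning(
                "feature %s: only %d distinct quantile edges for %d groups",
                feature, len(e), B,
            )
        if len(e) == 1:  # all values identical: one group
            e = np.array([e[0], e[0]])
        lab = np.searchsorted(e[1:-1], vals, side="right")
        lab[excluded] = EXCLUDED_LABEL
        edges[feature] = e
        labels[feature] = lab
    return FeatureBinning(edges=edges, labels=labels)


# ---------------------------------------------------------------------------
# Correction model

@dataclass
class CorrectionModel:
    """Per-feature symmetric multiplicative correction tables.

    ``scale`` is the global rate multiplier absorbing the overall ratio of
    observed counts to the decay-based expectation, so each C_f can obey
    the log-mean-zero identifiability constraint.
    """

    tables: dict[str, np.ndarray]
    binning: FeatureBinning
    scale: float = 1.0
    iterations: int = 0
    final_delta: float = float("nan")
    min_distance: int = 500_000

    def pair_correction(self, fend_p: int, fend_q: int) -> float:
        """Product of feature corrections for one fend pair; a pair with an
        excluded-label fend contributes 1."""
        c = 1.0
        for feature in FEATURES:
            la = self.binning.labels[feature][fend_p]
            lb = self.binning.labels[feature][fend_q]
            if la == EXCLUDED_LABEL or lb == EXCLUDED_LABEL:
                return 1.0
            c *= self.tables[feature][la, lb]
        return c


class _FendUniverse:
    """Observable intra-chromosomal fend pairs with distances and labels.

    Pairs on the same or on adjacent fragments are excluded: the pair
    filter removes such products (self-circles, dangling ends,
    re-ligations), so they can never contribute observed counts and must
    not contribute expectation either.
    """

    def __init__(self, fends: Sequence[FragmentEnd], bin_size: int):
        self.fends = fends
        self.bin_size = bin_size
        self.coords = np.array([f.coord for f in fends])
        frag_of = np.array([f.fragment_index for f in fends])
        self.chroms = sorted({f.chrom for f in fends})
        self.chrom_lengths = {
            c: max(f.coord for f in fends if f.chrom == c) for c in self.chroms
        }
        idx_by_chrom = {
            c: np.flatnonzero(np.array([f.chrom == c for f in fends]))
            for c in self.chroms
        }
        ps, qs, bp, bq = [], [], [], []
        for c in self.chroms:
            idx = idx_by_chrom[c]
            a, b = np.triu_indices(len(idx), k=1)
            keep = np.abs(frag_of[idx[a]] - frag_of[idx[b]]) > 1
            pa, qa = idx[a][keep], idx[b][keep]
            ps.append(pa)
            qs.append(qa)
            nb = n_bins_for(self.chrom_lengths[c], bin_size)
            bp.append(np.minimum(self.coords[pa] // bin_size, nb - 1))
            bq.append(np.minimum(self.coords[qa] // bin_size, nb - 1))
        self.p = np.concatenate(ps) if ps else np.array([], dtype=int)
        self.q = np.concatenate(qs) if qs else np.array([], dtype=int)
        self.bin_p = np.concatenate(bp) if bp else np.array([], dtype=int)
        self.bin_q = np.concatenate(bq) if bq else np.array([], dtype=int)
        self.dist_bp = np.abs(self.coords[self.p] - self.coords[self.q])
        # distance in bin-index units: consistent with how both the decay
        # profile and the expectation mass are accumulated per bin pair
        self.dist_bins = np.abs(self.bin_p - self.bin_q)

    def fend_pair_rate(self, decay: ExpectedProfile) -> np.ndarray:
        """Per-distance expected count per observable fend pair.

        Restriction sites are unevenly spaced, so the number of fend
        pairs per bin pair fluctuates with distance and the bin-level
        profile is not monotone in expectation. The monotone decay
        assumption holds for the per-fend-pair contact rate: convert the
        raw bin-pair average to counts per fend pair, isotonically smooth
        that, and impute empty distances from the nearest positive
        neighbor.
        """
        max_d = len(decay.raw)
        nfend = np.bincount(
            np.minimum(self.dist_bins, max_d - 1).astype(int), minlength=max_d
        )
        nbinpairs = np.zeros(max_d)
        for c in self.chroms:
            nb = n_bins_for(self.chrom_lengths[c], self.bin_size)
            d = np.arange(min(nb, max_d))
            nbinpairs[d] += nb - d
        rate = np.zeros(max_d)
        ok = nfend > 0
        rate[ok] = decay.raw[ok] * nbinpairs[ok] / nfend[ok]
        if max_d > 1:
            iso = IsotonicRegression(increasing=False, out_of_bounds="clip")
            d = np.arange(1, max_d)
            rate[1:] = iso.fit_transform(
                d, rate[1:], sample_weight=np.maximum(nfend[1:], 1e-12)
            )
        pos = np.flatnonzero(rate > 0)
        zero = np.flatnonzero(rate <= 0)
        if len(pos) and len(zero):
            nearest = pos[np.argmin(np.abs(zero[:, None] - pos[None, :]), axis=1)]
            rate[zero] = rate[nearest]
        return rate


def learn_corrections(
    pairs: Sequence[PairRecord],
    fends: Sequence[FragmentEnd],
    binning: FeatureBinning,
    decay: ExpectedProfile,
    bin_size: int,
    min_distance: int = 500_000,
    max_iter: int = 100,
    tol: float = 1e-4,
) -> CorrectionModel:
    """Cyclic multiplicative (iterative-proportional-fitting) learning.

    For each feature f and group pair (a, b) the table entry is scaled by
    the ratio of observed pair counts to the model expectation summed over
    all fend pairs in that combination, using only pairs separated by more
    than ``min_distance``; each sweep ends with renormalization to the
    log-mean-zero constraint over occupied group pairs.
    """
    uni = _FendUniverse(fends, bin_size)
    rate = uni.fend_pair_rate(decay)

    # enumerated fend-pair universe beyond the exclusion distance
    far = uni.dist_bp > min_distance
    if not far.any():
        raise ValueError(
            f"no fend pairs farther than {min_distance} bp; "
            "use a smaller min_distance for small genomes"
        )
    up, uq = uni.p[far], uni.q[far]
    u_rate = rate[np.minimum(uni.dist_bins[far], len(rate) - 1).astype(int)]
    u_lab = {f: (binning.labels[f][up], binning.labels[f][uq]) for f in FEATURES}
    u_valid = np.ones(len(up), dtype=bool)
    for f in FEATURES:
        u_valid &= (u_lab[f][0] != EXCLUDED_LABEL) & (u_lab[f][1] != EXCLUDED_LABEL)
    up, uq = up[u_valid], uq[u_valid]
    u_rate = u_rate[u_valid]
    u_lab = {f: (u_lab[f][0][u_valid], u_lab[f][1][u_valid]) for f in FEATURES}

    # observed pairs beyond the exclusion distance
    coords = uni.coords
    op, oq = [], []
    for p in pairs:
        if p.chrom1 != p.chrom2:
            continue
        if abs(coords[p.fend1] - coords[p.fend2]) > min_distance:
            op.append(p.fend1)
            oq.append(p.fend2)
    op = np.array(op, dtype=int)
    oq = np.array(oq, dtype=int)
    if op.size == 0:
        raise ValueError(
            f"no observed pairs farther than {min_distance} bp; "
            "use a smaller min_distance for small genomes"
        )
    o_lab = {f: (binning.labels[f][op], binning.labels[f][oq]) for f in FEATURES}
    o_valid = np.ones(len(op), dtype=bool)
    for f in FEATURES:
        o_valid &= (o_lab[f][0] != EXCLUDED_LABEL) & (o_lab[f][1] != EXCLUDED_LABEL)
    o_lab = {f: (o_lab[f][0][o_valid], o_lab[f][1][o_valid]) for f in FEATURES}
    n_obs = int(o_valid.sum())

    tables = {
        f: np.ones((binning.n_groups(f), binning.n_groups(f))) for f in FEATURES
    }

    def _sym_accumulate(B, la, lb, weights=None):
        a = np.minimum(la, lb)
        b = np.maximum(la, lb)
        M = np.zeros((B, B))
        if weights is None:
            np.add.at(M, (a, b), 1.0)
        else:
            np.add.at(M, (a, b), weights)
        return M + np.triu(M, 1).T

    obs_tables = {
        f: _sym_accumulate(binning.n_groups(f), *o_lab[f]) for f in FEATURES
    }

    def _pair_products():
        w = u_rate.copy()
        for f in FEATURES:
            w *= tables[f][u_lab[f][0], u_lab[f][1]]
        return w

    scale = 1.0
    delta = float("inf")
    it = 0
    for it in range(1, max_iter + 1):
        old = {f: tables[f].copy() for f in FEATURES}
        for f in FEATURES:
            w = scale * _pair_products()
            exp_table = _sym_accumulate(
                binning.n_groups(f), u_lab[f][0], u_lab[f][1], w
            )
            obs = obs_tables[f]
            ratio = np.ones_like(exp_table)
            ok = (obs > 0) & (exp_table > 0)
            ratio[ok] = obs[ok] / exp_table[ok]
            tables[f] = tables[f] * ratio
            # identifiability: mean log correction over occupied pairs = 0
            occ = obs > 0
            if occ.any():
                g = np.exp(np.mean(np.log(tables[f][occ])))
                tables[f] /= g
        total_exp = float((scale * _pair_products()).sum())
        if total_exp > 0:
            scale *= n_obs / total_exp
        delta = max(
            float(np.max(np.abs(tables[f] - old[f]) / old[f])) for f in FEATURES
        )
        if delta < tol:
            break

    return CorrectionModel(
        tables=tables,
        binning=binning,
        scale=scale,
        iterations=it,
        final_delta=delta,
        min_distance=min_distance,
    )


# ---------------------------------------------------------------------------
# Correction / normalized / O-E matrices

def correction_matrix(
    model: CorrectionModel,
    pairs: Sequence[PairRecord],
    bin_size: int,
    chrom_length: int,
    chrom: str,
    statistic: str = "mean",
) -> ContactMatrix:
    """E[i, j]: per-pair corrections of the observed read pairs in each bin
    pair, aggregated by mean (default) or sum; zero exactly where O is zero.

    The mean keeps E ≡ 1 under an identity model, so N = O/E reduces to
    the observed counts when there is nothing to correct and otherwise
    rescales each bin pair by the average bias of the pairs that produced
    it. The raw sum (the count-weighted variant) is available via
    ``statistic="sum"``.
    """
    if statistic not in ("mean", "sum"):
        raise ValueError(f"unknown statistic {statistic!r}")
    n = n_bins_for(chrom_length, bin_size)
    E = np.zeros((n, n))
    counts = np.zeros((n, n))
    for p in pairs:
        if p.chrom1 != chrom or p.chrom2 != chrom:
            continue
        i, j = p.pos1 // bin_size, p.pos2 // bin_size
        c = model.pair_correction(p.fend1, p.fend2)
        E[i, j] += c
        counts[i, j] += 1
        if i != j:
            E[j, i] += c
            counts[j, i] += 1
    if statistic == "mean":
        E = np.divide(E, counts, out=np.zeros_like(E), where=counts > 0)
    return ContactMatrix(chrom, bin_size, E, "correction")


def normalize_matrix(O: ContactMatrix, E: ContactMatrix) -> ContactMatrix:
    """N = O / E on the support; 0 where both are 0."""
    if O.values.shape != E.values.shape:
        raise ValueError("O and E shapes differ")
    if np.any((E.values == 0) & (O.values > 0)):
        raise ValueError("E is zero where O is positive: invalid correction matrix")
    N = np.divide(
        O.values, E.values, out=np.zeros_like(O.values), where=E.values > 0
    )
    return ContactMatrix(O.chrom, O.bin_size, N, "normalized")


def expected_matrix(
    model: CorrectionModel,
    decay: ExpectedProfile,
    fends: Sequence[FragmentEnd],
    bin_size: int,
    chrom: str,
) -> ContactMatrix:
    """Full expectation: sum over *all* fend pairs mapping to each bin pair
    of decay(d) * corrections, on the observed-count scale."""
    uni = _FendUniverse(fends, bin_size)
    rate = uni.fend_pair_rate(decay)
    sel = np.array([fends[p].chrom == chrom for p in uni.p])
    p, q = uni.p[sel], uni.q[sel]
    bins_p, bins_q = uni.bin_p[sel], uni.bin_q[sel]
    d = np.minimum(uni.dist_bins[sel], len(rate) - 1).astype(int)
    w = model.scale * rate[d]
    corr = np.ones(len(p))
    valid = np.ones(len(p), dtype=bool)
    for f in FEATURES:
        la = model.binning.labels[f][p]
        lb = model.binning.labels[f][q]
        valid &= (la != EXCLUDED_LABEL) & (lb != EXCLUDED_LABEL)
        safe_a = np.where(la == EXCLUDED_LABEL, 0, la)
        safe_b = np.where(lb == EXCLUDED_LABEL, 0, lb)
        corr *= model.tables[f][safe_a, safe_b]
    w = w * np.where(valid, corr, 1.0)

    n = n_bins_for(uni.chrom_lengths[chrom], bin_size)
    Ef = np.zeros((n, n))
    np.add.at(Ef, (bins_p, bins_q), w)
    np.add.at(Ef, (bins_q, bins_p), np.where(bins_p != bins_q, w, 0.0))
    return ContactMatrix(chrom, bin_size, Ef, "correction")


def observed_over_expected(
    O: ContactMatrix,
    model: CorrectionModel,
    decay: ExpectedProfile,
    fends: Sequence[FragmentEnd],
) -> ContactMatrix:
    """log2(O / expected) with sentinels where either side is empty."""
    Ef = expected_matrix(model, decay, fends, O.bin_size, O.chrom)
    if Ef.n_bins != O.n_bins:
        raise ValueError("expected/observed bin count mismatch")
    exp = Ef.values
    obs = O.values
    vals = np.zeros_like(obs)
    sent = np.zeros(obs.shape, dtype=np.int8)
    sent[exp <= 0] = SENT_NO_EXPECTED
    sent[(exp > 0) & (obs == 0)] = SENT_NO_OBSERVED
    ok = (exp > 0) & (obs > 0)
    vals[ok] = np.log2(obs[ok] / exp[ok])
    return ContactMatrix(O.chrom, O.bin_size, vals, "oe_log2", sent)


def model_to_json(model: CorrectionModel) -> dict:
    return {
        "scale": model.scale,
        "iterations": model.iterations,
        "final_delta": model.final_delta,
        "min_distance": model.min_distance,
        "features": {
            f: {
                "edges": model.binning.edges[f].tolist(),
                "table": model.tables[f].tolist(),
            }
            for f in FEATURES
        },
    }
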