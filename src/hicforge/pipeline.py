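"""End-to-end orchestration: preprocessing, normalization, TAD analysis.

Each stage consumes files, writes its outputs plus a machine-readable JSON
log, and is independent per chromosome; threaded and serial runs produce
byte-identical outputs because every per-chromosome computation is a pure
function of its inputs.
"""

from __future__ import annotations

import json
import os
from concurrent.futures import ThreadPoolExecutor
from dataclasses import dataclass, field

from . import normalize as nz
from . import store, tad
from .digest import FragmentEnd, read_fend_bed
from .enzymes import get_enzyme
from .pairfilter import PairRecord, run_pair_filter, write_pairs
from .truncate import pretruncate_fastq


@dataclass
class RunConfig:
    enzyme: str = "HindIII"
    bin_size: int = 40_000
    mapq: int = 30
    min_distance: int = 500_000
    di_window: int = 2_000_000
    seed: int = 0
    threads: int = 1
    chromosomes: list = field(default_factory=list)  # empty = all


def run_preprocess(fastq1: str, fastq2: str, enzyme_name: str, outdir: str,
                   force: bool = False) -> dict:
    os.makedirs(outdir, exist_ok=True)
    enzyme = get_enzyme(enzyme_name)
    logs = {}
    for label, path in (("mate1", fastq1), ("mate2", fastq2)):
        out = os.path.join(outdir, f"{label}.trunc.fastq")
        if os.path.exists(out) and not force:
            raise FileExistsError(f"{out} exists; use force to overwrite")
        report = pretruncate_fastq(path, out, enzyme)
        report.to_json(os.path.join(outdir, f"{label}.trunc.json"))
        logs[label] = {
            "total_reads": report.total_reads,
            "truncated_reads": report.truncated_reads,
            "percent_truncated": report.percent_truncated,
        }
    return logs


def _chrom_lengths(fends: list[FragmentEnd]) -> dict[str, int]:
    lengths: dict[str, int] = {}
    for f in fends:
        lengths[f.chrom] = max(lengths.get(f.chrom, 0), f.coord)
    return lengths


def normalize_chromosome(
    chrom: str,
    pairs: list[PairRecord],
    fends: list[FragmentEnd],
    model: nz.CorrectionModel,
    decay: nz.ExpectedProfile,
    bin_size: int,
    outdir: str,
) -> dict:
    """Write the four per-chromosome matrices (O, E, N, O/E)."""
    length = _chrom_lengths(fends)[chrom]
    cpairs = [p for p in pairs if p.chrom1 == chrom and p.chrom2 == chrom]
    O = nz.bin_pairs(cpairs, bin_size, length, chrom)
    E = nz.correction_matrix(model, cpairs, bin_size, length, chrom)
    N = nz.normalize_matrix(O, E)
    OE = nz.observed_over_expected(O, model, decay, fends)
    paths = {}
    for m, tag in ((O, "observed"), (E, "correction"), (N, "normalized"), (OE, "oe")):
        path = os.path.join(outdir, f"{chrom}.{tag}.matrix.txt")
        store.write_matrix(m, path)
        paths[tag] = path
    return paths


def run_normalize(
    sam1: str,
    sam2: str,
    fend_path: str,
    outdir: str,
    config: RunConfig | None = None,
) -> dict:
    config = config or RunConfig()
    os.makedirs(outdir, exist_ok=True)
    fends = read_fend_bed(fend_path)
    valid, report = run_pair_filter(sam1, sam2, fends, mapq=config.mapq)
    report.to_json(os.path.join(outdir, "filter.json"))
    write_pairs(valid, os.path.join(outdir, "valid_pairs.tsv"))
    return normalize_from_pairs(valid, fends, outdir, config)


def normalize_from_pairs(
    valid: list[PairRecord],
    fends: list[FragmentEnd],
    outdir: str,
    config: RunConfig | None = None,
) -> dict:
    config = config or RunConfig()
    os.makedirs(outdir, exist_ok=True)
    lengths = _chrom_lengths(fends)
    chroms = config.chromosomes or sorted(lengths)
    for p in valid:
        for c in (p.chrom1, p.chrom2):
            if c not in lengths:
                raise KeyError(f"chromosome {c!r} absent from FEND table")

    observed = [
        nz.bin_pairs(
            [p for p in valid if p.chrom1 == c and p.chrom2 == c],
            config.bin_size, lengths[c], c,
        )
        for c in chroms
    ]
    decay = nz.estimate_distance_decay(observed)
    binning = nz.partition_fend_features(fends)
    model = nz.learn_corrections(
        valid, fends, binning, decay, config.bin_size,
        min_distance=config.min_distance,
    )
    with open(os.path.join(outdir, "model.json"), "w") as fh:
        json.dump(nz.model_to_json(model), fh, indent=2)

    def _one(chrom: str) -> tuple[str, dict]:
        return chrom, normalize_chromosome(
            chrom, valid, fends, model, decay, config.bin_size, outdir
        )

    if config.threads > 1:
        with ThreadPoolExecutor(max_workers=config.threads) as pool:
            results = dict(pool.map(_one, chroms))
    else:
        results = dict(_one(c) for c in chroms)
    log = {"chromosomes": results, "model_iterations": model.iterations,
           "model_delta": model.final_delta}
    with open(os.path.join(outdir, "normalize.json"), "w") as fh:
        json.dump(log, fh, indent=2)
    return log


def run_tad(matrix_paths: list[str], outdir: str, config: RunConfig | None = None) -> dict:
    """DI, decoded states and TAD coordinates per normalized matrix file."""
    config = config or RunConfig()
    os.makedirs(outdir, exist_ok=True)
    log = {}
    for path in matrix_paths:
        N = store.read_matrix(path)
        chrom = N.chrom or os.path.basename(path).split(".")[0]
        di = tad.directionality_index(N, window=config.di_window)
        model = tad.fit_hmm(di, seed=config.seed)
        states = tad.decode_states(model, di)
        tads = tad.call_tads(states)
        store.write_track(di.di, os.path.join(outdir, f"{chrom}.di.txt"))
        store.write_track(states.states, os.path.join(outdir, f"{chrom}.states.txt"))
        store.write_tads(tads, os.path.join(outdir, f"{chrom}.tads.txt"))
        log[chrom] = {"n_tads": len(tads),
                      "n_boundaries": len(tad.tad_boundaries(tads))}
    with open(os.path.join(outdir, "tad.json"), "w") as fh:
        json.dump(log, fh, indent=2)
    return log
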