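"""Pre-truncation of Hi-C reads that run through a ligation junction.

A read sequenced across the ligation junction continues into the partner
fragment and would align poorly (or chimerically). Before mapping, each
read is searched for the reconstructed junction sequence and, if found,
truncated so that only the portion derived from the read's own fragment —
up to and including that fragment's restriction half-site — is kept.
"""

from __future__ import annotations

import gzip
import json
from collections import Counter
from dataclasses import dataclass, field

from Bio.SeqIO.QualityIO import FastqGeneralIterator

from .enzymes import RestrictionEnzyme

make_ligation_junction = RestrictionEnzyme.ligation_junction


@dataclass
class TruncationReport:
    """QC statistics for one pre-truncated FASTQ file."""

    total_reads: int = 0
    truncated_reads: int = 0
    length_histogram: Counter = field(default_factory=Counter)

    @property
    def percent_truncated(self) -> float:
        if self.total_reads == 0:
            return 0.0
        return 100.0 * self.truncated_reads / self.total_reads

    def to_json(self, path: str) -> None:
        with open(path, "w") as fh:
            json.dump(
                {
                    "total_reads": self.total_reads,
                    "truncated_reads": self.truncated_reads,
                    "percent_truncated": self.percent_truncated,
                    "length_histogram": dict(
                        sorted(self.length_histogram.items())
                    ),
                },
                fh,
                indent=2,
            )


def truncate_read(
    seq: str, qual: str, junction: str, enzyme: RestrictionEnzyme
) -> tuple[str, str, bool]:
    """Truncate at the first junction occurrence (case-insensitive).

    The kept prefix has length ``p + (len(site) - cut_offset)`` where ``p``
    is the junction start: the read retains its own fragment's filled-in
    half of the junction, so re-truncating a truncated read is a no-op.
    """
    if len(seq) != len(qual):
        raise ValueError("sequence/quality length mismatch")
    p = seq.upper().find(junction.upper())
    if p == -1:
        return seq, qual, False
    keep = p + (len(enzyme.site) - enzyme.cut_offset)
    return seq[:keep], qual[:keep], True


def _open_maybe_gzip(path: str, mode: str):
    if str(path).endswith(".gz"):
        return gzip.open(path, mode)
    return open(path, mode)


def pretruncate_fastq(
    in_path: str, out_path: str, enzyme: RestrictionEnzyme
) -> TruncationReport:
    """Stream a FASTQ (plain or gzip) through :func:`truncate_read`.

    Record count is preserved; reads without a junction pass unchanged.
    """
    junction = enzyme.ligation_junction()
    report = TruncationReport()
    with _open_maybe_gzip(in_path, "rt") as ih, _open_maybe_gzip(out_path, "wt") as oh:
        for title, seq, qual in FastqGeneralIterator(ih):
            if len(seq) != len(qual):
                raise ValueError(
                    f"record {title!r}: sequence/quality length mismatch"
                )
            new_seq, new_qual, was_truncated = truncate_read(
                seq, qual, junction, enzyme
            )
            report.total_reads += 1
            report.truncated_reads += int(was_truncated)
            report.length_histogram[len(new_seq)] += 1
            oh.write(f"@{title}\n{new_seq}\n+\n{new_qual}\n")
    return report
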