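"""Square symmetric per-chromosome contact matrices.

A binned Hi-C map is symmetric, so one array plus a role tag is enough to
carry the observed counts (integers), the per-pair correction sums, the
normalized map N = O/E, or the log2 observed-over-expected map. O/E maps
additionally carry a sentinel mask distinguishing bins with no expected
signal (no fragment ends) from bins with expected but no observed contacts.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

ROLES = ("observed", "correction", "normalized", "oe_log2")

#: sentinel codes for the O/E mask
SENT_NONE = 0
SENT_NO_EXPECTED = 1  # bin pair with zero expected signal (e.g. no FENDs)
SENT_NO_OBSERVED = 2  # expected > 0 but zero observed contacts


def n_bins_for(chrom_length: int, bin_size: int) -> int:
    return math.ceil(chrom_length / bin_size)


@dataclass
class ContactMatrix:
    chrom: str
    bin_size: int
    values: np.ndarray
    role: str = "observed"
    sentinels: np.ndarray | None = None  # int8 mask, oe_log2 role only

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape[0] != self.values.shape[1]:
            raise ValueError("contact matrix must be square")
        if self.role not in ROLES:
            raise ValueError(f"unknown role {self.role!r}")
        if self.sentinels is not None:
            self.sentinels = np.asarray(self.sentinels, dtype=np.int8)
            if self.sentinels.shape != self.values.shape:
                raise ValueError("sentinel mask shape mismatch")

    @property
    def n_bins(self) -> int:
        return self.values.shape[0]

    def check_symmetric(self, rtol: float = 1e-9) -> None:
        v = self.values
        if not np.allclose(v, v.T, rtol=rtol, atol=0):
            raise ValueError(f"{self.chrom}: matrix is not symmetric")
        if self.sentinels is not None and not np.array_equal(
            self.sentinels, self.sentinels.T
        ):
            raise ValueError(f"{self.chrom}: sentinel mask is not symmetric")

    def copy(self) -> "ContactMatrix":
        return ContactMatrix(
            self.chrom,
            self.bin_size,
            self.values.copy(),
            self.role,
            None if self.sentinels is None else self.sentinels.copy(),
        )
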