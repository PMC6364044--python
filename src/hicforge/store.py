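"""Compact text storage for symmetric sparse contact matrices.

Only the upper triangle (diagonal included) is stored, row-major, with
every maximal run of ``k`` consecutive zeros collapsed to the single
integer ``-k``. For a typical 40-kb map, whose entries are mostly zero
away from the diagonal, this cuts the stored line count to a small
fraction of the full n(n+1)/2 triangle. Observed matrices are written as
integers; float matrices at a configurable number of significant digits
(default 6). O/E sentinels are written as the reserved tokens
``na_expected`` / ``na_observed``.

Also provides the one-value-per-line writers for DI / state tracks and
the two-column tab-separated TAD coordinate files.
"""

from __future__ import annotations

import gzip
import math
from typing import Iterable, Sequence

import numpy as np

from .matrix import SENT_NO_EXPECTED, SENT_NO_OBSERVED, SENT_NONE, ContactMatrix

TOKEN_NO_EXPECTED = "na_expected"
TOKEN_NO_OBSERVED = "na_observed"

_HEADER_PREFIX = "#hicforge triangular"


def _open(path, mode: str):
    if str(path).endswith(".gz"):
        return gzip.open(path, mode)
    return open(path, mode)


def _format_value(x: float, integer: bool, precision: int) -> str:
    if integer:
        return str(int(round(x)))
    tok = f"{x:.{precision}g}"
    # a float that formats as a bare integer would collide with run tokens
    if tok.lstrip("+-").isdigit():
        tok += ".0"
    return tok


def encode_triangular(
    matrix: ContactMatrix, precision: int = 6
) -> list[str]:
    """Upper-triangle run-length stream of a symmetric matrix.

    Raises if the matrix (or its sentinel mask) is not symmetric.
    """
    matrix.check_symmetric()
    integer = matrix.role == "observed"
    v = matrix.values
    s = matrix.sentinels
    n = matrix.n_bins
    tokens: list[str] = []
    run = 0

    def flush():
        nonlocal run
        if run:
            tokens.append(str(-run))
            run = 0

    for i in range(n):
        row = v[i, i:]
        srow = None if s is None else s[i, i:]
        for k, x in enumerate(row):
            code = SENT_NONE if srow is None else srow[k]
            if code == SENT_NO_EXPECTED:
                flush()
                tokens.append(TOKEN_NO_EXPECTED)
            elif code == SENT_NO_OBSERVED:
                flush()
                tokens.append(TOKEN_NO_OBSERVED)
            elif x == 0:
                run += 1
            else:
                flush()
                tokens.append(_format_value(x, integer, precision))
    flush()
    return tokens


def _n_from_triangle(length: int) -> int:
    n = int((math.isqrt(8 * length + 1) - 1) // 2)
    if n * (n + 1) // 2 != length:
        raise ValueError(f"expanded stream length {length} is not triangular")
    return n


def decode_triangular(
    tokens: Sequence[str],
    expect_n: int | None = None,
    chrom: str = "",
    bin_size: int = 1,
    role: str = "observed",
) -> ContactMatrix:
    """Inverse of :func:`encode_triangular`."""
    flat: list[float] = []
    codes: list[int] = []
    prev_negative = False
    for tok in tokens:
        tok = tok.strip()
        if not tok:
            continue
        if tok == TOKEN_NO_EXPECTED:
            flat.append(0.0)
            codes.append(SENT_NO_EXPECTED)
            prev_negative = False
            continue
        if tok == TOKEN_NO_OBSERVED:
            flat.append(0.0)
            codes.append(SENT_NO_OBSERVED)
            prev_negative = False
            continue
        is_run = False
        try:
            iv = int(tok)
            if iv < 0:
                is_run = True
        except ValueError:
            pass
        if is_run:
            if prev_negative:
                raise ValueError("two consecutive zero-run tokens")
            flat.extend([0.0] * (-iv))
            codes.extend([SENT_NONE] * (-iv))
            prev_negative = True
        else:
            flat.append(float(tok))
            codes.append(SENT_NONE)
            prev_negative = False

    n = _n_from_triangle(len(flat))
    if expect_n is not None and n != expect_n:
        raise ValueError(f"decoded size {n} != expected {expect_n}")
    values = np.zeros((n, n))
    sent = np.zeros((n, n), dtype=np.int8)
    pos = 0
    for i in range(n):
        m = n - i
        values[i, i:] = flat[pos : pos + m]
        sent[i, i:] = codes[pos : pos + m]
        pos += m
    values = values + np.triu(values, 1).T
    sent = sent + np.triu(sent, 1).T
    mask = sent if sent.any() else None
    return ContactMatrix(chrom, bin_size, values, role, mask)


def write_matrix(
    matrix: ContactMatrix,
    path,
    precision: int = 6,
    headerless: bool = False,
) -> None:
    tokens = encode_triangular(matrix, precision)
    with _open(path, "wt") as fh:
        if not headerless:
            fh.write(
                f"{_HEADER_PREFIX} n={matrix.n_bins} bin={matrix.bin_size} "
                f"chrom={matrix.chrom} role={matrix.role}\n"
            )
        fh.write("\n".join(tokens))
        if tokens:
            fh.write("\n")


def read_matrix(path, expect_n: int | None = None, **meta) -> ContactMatrix:
    with _open(path, "rt") as fh:
        lines = fh.read().splitlines()
    if lines and lines[0].startswith(_HEADER_PREFIX):
        fields = dict(
            kv.split("=", 1) for kv in lines[0][len(_HEADER_PREFIX):].split() if "=" in kv
        )
        meta.setdefault("chrom", fields.get("chrom", ""))
        meta.setdefault("bin_size", int(fields.get("bin", 1)))
        meta.setdefault("role", fields.get("role", "observed"))
        expect_n = expect_n if expect_n is not None else int(fields["n"])
        lines = lines[1:]
    return decode_triangular(lines, expect_n=expect_n, **meta)


# ---------------------------------------------------------------------------
# TAD coordinate and per-bin track files


def write_tads(tads: Iterable[tuple[int, int]], path) -> None:
    """One TAD per line: ``start<TAB>end`` in bp; sorted, non-overlapping."""
    sorted_tads = sorted(tads)
    for (s1, e1), (s2, _e2) in zip(sorted_tads, sorted_tads[1:]):
        if s2 < e1:
            raise ValueError(f"overlapping TADs ({s1},{e1}) and ({s2},{_e2})")
    with open(path, "w") as fh:
        for s, e in sorted_tads:
            fh.write(f"{s}\t{e}\n")


def read_tads(path) -> list[tuple[int, int]]:
    out = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise ValueError(f"{path}:{lineno}: expected 'start<TAB>end'")
            out.append((int(parts[0]), int(parts[1])))
    return out


def write_track(values: Iterable[float], path, precision: int = 6) -> None:
    """One value per line, bin-ordered; NaN marks masked bins."""
    with open(path, "w") as fh:
        for x in values:
            if isinstance(x, float) and math.isnan(x):
                fh.write("nan\n")
            else:
                fh.write(f"{x:.{precision}g}\n")


def read_track(path) -> np.ndarray:
    vals = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            try:
                vals.append(float(line))
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: non-numeric value {line!r}") from exc
    return np.array(vals)
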