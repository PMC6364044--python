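"""Restriction enzyme definitions and ligation-junction construction.

A Hi-C library is built by digesting chromatin with a restriction enzyme,
filling in the 5' overhangs and blunt-ligating the resulting fragment ends.
Everything downstream (fragment tables, junction pre-truncation) derives
from the enzyme's recognition site and its cut offset.
"""

from __future__ import annotations

from dataclasses import dataclass

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class RestrictionEnzyme:
    """A palindromic type-II restriction enzyme.

    Parameters
    ----------
    name : str
        Enzyme name (e.g. ``"HindIII"``).
    site : str
        Recognition site, uppercase ACGT only. Must be its own reverse
        complement: top-strand scanning then finds every site on both
        strands.
    cut_offset : int
        0-based position on the top strand after which the enzyme cuts,
        in ``[0, len(site) // 2]``. HindIII (A^AGCTT) has offset 1,
        MboI (^GATC) has offset 0.
    """

    name: str
    site: str
    cut_offset: int

    def __post_init__(self) -> None:
        if not self.site or set(self.site) - set("ACGT"):
            raise ValueError(
                f"{self.name}: recognition site must be non-empty uppercase "
                f"ACGT (ambiguity codes are not supported), got {self.site!r}"
            )
        if self.site != reverse_complement(self.site):
            raise ValueError(
                f"{self.name}: site {self.site!r} is not palindromic; only "
                "palindromic cutters are supported"
            )
        if not 0 <= self.cut_offset <= len(self.site) // 2:
            raise ValueError(
                f"{self.name}: cut_offset {self.cut_offset} outside "
                f"[0, {len(self.site) // 2}]"
            )

    def ligation_junction(self) -> str:
        """Sequence created by fill-in and blunt ligation of two cut ends.

        The 5' overhang left by cutting at ``cut_offset`` is filled in, so
        the junction reads ``site[:len-cut_offset] + site[cut_offset:]``
        and has length ``2 * (len(site) - cut_offset)``. A read that runs
        through this chimera into its ligation partner must be truncated
        before alignment.
        """
        n = len(self.site)
        return self.site[: n - self.cut_offset] + self.site[self.cut_offset :]


#: The four cutters commonly used for Hi-C libraries.
BUILTIN_ENZYMES = {
    "HindIII": RestrictionEnzyme("HindIII", "AAGCTT", 1),
    "NcoI": RestrictionEnzyme("NcoI", "CCATGG", 1),
    "DpnII": RestrictionEnzyme("DpnII", "GATC", 0),
    "MboI": RestrictionEnzyme("MboI", "GATC", 0),
}


def get_enzyme(name_or_spec: str) -> RestrictionEnzyme:
    """Look up a built-in enzyme, or parse a custom ``SITE^OFFSET`` spec.

    A custom enzyme is written as the site with a caret at the cut
    position, e.g. ``A^AGCTT``.
    """
    if name_or_spec in BUILTIN_ENZYMES:
        return BUILTIN_ENZYMES[name_or_spec]
    if "^" in name_or_spec:
        offset = name_or_spec.index("^")
        site = name_or_spec.replace("^", "").upper()
        return RestrictionEnzyme("custom", site, offset)
    raise KeyError(
        f"unknown enzyme {name_or_spec!r}; built-ins: "
        f"{sorted(BUILTIN_ENZYMES)} or custom 'SI^TE' spec"
    )
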