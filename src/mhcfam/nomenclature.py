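"""HLA allele nomenclature: parsing, resolution truncation, and comparison.

Classical HLA allele names follow the colon-delimited IMGT/HLA convention,
``HLA-B*58:01:01:01``: a locus symbol, an asterisk marking molecular typing,
and one to four numeric fields (allele group, specific protein, synonymous
coding variant, non-coding variant).  All downstream statistics in this
package operate at two-field ("protein level") resolution, while reports keep
the maximum resolution that was typed.

Leading zeros in fields are preserved as text but carry no meaning: ``B*07:02``
and ``B*7:2`` denote the same allele, so equality and hashing use the integer
value of each field.  Expression-suffix letters (N, L, S, C, A, Q) are accepted
and kept in :attr:`HLAAllele.raw` but ignored in comparisons; none occur in
classical family data at the resolutions handled here.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from functools import total_ordering
from typing import Sequence

#: The eight classical loci handled by this package, in the fixed map order
#: used for all haplotype rendering (telomeric HLA-A to centromeric HLA-DPB1).
PANEL: tuple[str, ...] = ("A", "C", "B", "DRB1", "DQA1", "DQB1", "DPA1", "DPB1")

#: The five-locus core spanned by conserved extended haplotypes (HLA-C to
#: HLA-DQB1, ~2.7 Mb).
CEH_LOCI: tuple[str, ...] = ("C", "B", "DRB1", "DQA1", "DQB1")


class NomenclatureError(ValueError):
    """Raised when an allele name cannot be interpreted."""


_ALLELE_RE = re.compile(
    r"^(?:HLA-)?([A-Z]+[0-9]*)\*(\d{1,4}(?::\d{1,4}){0,3})([NLSCAQ]?)$"
)


@total_ordering
@dataclass(frozen=True)
class HLAAllele:
    """A parsed HLA allele name.

    Parameters
    ----------
    locus :
        Locus symbol from :data:`PANEL`.
    fields :
        One to four numeric field strings, leading zeros preserved.
    raw :
        The original string as supplied (including any ``HLA-`` prefix or
        expression suffix).
    """

    locus: str
    fields: tuple[str, ...]
    raw: str

    def __post_init__(self) -> None:
        if self.locus not in PANEL:
            raise NomenclatureError(f"unknown HLA locus {self.locus!r}")
        if not 1 <= len(self.fields) <= 4:
            raise NomenclatureError(f"expected 1-4 fields, got {self.fields!r}")
        for f in self.fields:
            if not f or not f.isdigit():
                raise NomenclatureError(f"non-numeric field {f!r} in {self.raw!r}")

    # -- comparison uses integer field values so that "07" == "7" -------------
    @property
    def key(self) -> tuple[str, tuple[int, ...]]:
        return (self.locus, tuple(int(f) for f in self.fields))

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, HLAAllele):
            return NotImplemented
        return self.key == other.key

    def __hash__(self) -> int:
        return hash(self.key)

    def __lt__(self, other: "HLAAllele") -> bool:
        return self.key < other.key

    def render(self, prefix: bool = False) -> str:
        """Canonical string form, ``<locus>*<f1>:<f2>...`` (no suffix)."""
        name = f"{self.locus}*{':'.join(self.fields)}"
        return f"HLA-{name}" if prefix else name

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.render()

    @property
    def resolution(self) -> int:
        """Number of typed fields (1-4)."""
        return len(self.fields)


def parse_allele(name: str) -> HLAAllele:
    """Parse an IMGT/HLA colon-delimited allele name.

    Accepts an optional ``HLA-`` prefix and an optional expression-suffix
    letter.  Raises :class:`NomenclatureError` for unknown loci, missing
    asterisks, or non-numeric fields.

    >>> parse_allele("HLA-C*07:02:01:01").fields
    ('07', '02', '01', '01')
    """
    if not isinstance(name, str) or not name.strip():
        raise NomenclatureError("empty allele name")
    m = _ALLELE_RE.match(name.strip())
    if m is None:
        raise NomenclatureError(f"malformed HLA allele name {name!r}")
    locus, body, _suffix = m.groups()
    return HLAAllele(locus=locus, fields=tuple(body.split(":")), raw=name.strip())


def truncate(allele: HLAAllele, n_fields: int) -> HLAAllele:
    """Reduce an allele to at most ``n_fields`` fields of resolution.

    Idempotent; an allele typed at lower resolution than requested passes
    through unchanged.
    """
    if not 1 <= n_fields <= 4:
        raise ValueError(f"n_fields must be in 1..4, got {n_fields}")
    if len(allele.fields) <= n_fields:
        return allele
    kept = allele.fields[:n_fields]
    return HLAAllele(locus=allele.locus, fields=kept, raw=f"{allele.locus}*{':'.join(kept)}")


def same_at_resolution(a: HLAAllele, b: HLAAllele, n_fields: int) -> bool:
    """True iff both alleles are at the same locus and agree once truncated."""
    return a.locus == b.locus and truncate(a, n_fields) == truncate(b, n_fields)


def panel_index(locus: str, panel: Sequence[str] = PANEL) -> int:
    try:
        return list(panel).index(locus)
    except ValueError:
        raise KeyError(f"locus {locus!r} not in panel {tuple(panel)}") from None
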