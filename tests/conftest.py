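"""Shared fixtures and pedigree-building helpers."""

from __future__ import annotations

import pytest

from mhcfam import Individual, Pedigree, parse_allele
from mhcfam.nomenclature import PANEL


def geno(spec: dict[str, tuple[str, str] | None]) -> dict:
    """Build a genotype dict from allele-string pairs; loci not mentioned
    are missing."""
    out = {l: None for l in PANEL}
    for locus, pair in spec.items():
        out[locus] = None if pair is None else (parse_allele(pair[0]), parse_allele(pair[1]))
    return out


def family(
    fid: str,
    father: dict | None,
    mother: dict | None,
    children: list[dict],
) -> Pedigree:
    """Two-generation pedigree; a None parent genotype means ungenotyped."""
    members = [
        Individual(fid, "F", None, None, father if father is not None else {l: None for l in PANEL}),
        Individual(fid, "M", None, None, mother if mother is not None else {l: None for l in PANEL}),
    ]
    for i, kid in enumerate(children):
        members.append(Individual(fid, f"C{i + 1}", "F", "M", kid))
    return Pedigree(fid, members)


def uniform_geno(pair: tuple[str, str], loci=PANEL) -> dict:
    """Same allele-group pair replicated across loci (locus symbol swapped in)."""
    out = {}
    for locus in loci:
        a = pair[0].split("*", 1)[1]
        b = pair[1].split("*", 1)[1]
        out[locus] = (parse_allele(f"{locus}*{a}"), parse_allele(f"{locus}*{b}"))
    return out


@pytest.fixture
def informative_trio() -> Pedigree:
    """Fully informative family: every locus distinguishes all four parental
    haplotypes."""
    father = uniform_geno(("X*01:01", "X*02:01"))
    mother = uniform_geno(("X*03:01", "X*11:01"))
    child1 = uniform_geno(("X*01:01", "X*03:01"))
    child2 = uniform_geno(("X*02:01", "X*11:01"))
    return family("T1", father, mother, [child1, child2])
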