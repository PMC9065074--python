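"""Conserved extended haplotype (CEH) detection, naming, and profiling.

A CEH is a multi-locus allele combination spanning HLA-C to HLA-DQB1 (~2.7 Mb)
that recurs among unrelated founders of a population.  Detection follows the
established frequency procedure: count five-locus C-B-DRB1-DQA1-DQB1 blocks
over the founder pool at two-field resolution and keep blocks at or above a
frequency cutoff.  The literature convention for a common CEH is 0.005; small
cohorts require a stricter cutoff and 0.02 is the default here.

Named CEHs follow the serological-lineage convention: the HLA-B lineage label
followed by a sequential discovery number (8.1, 8.2, 58.1, 60.4...).  A block
absent from the registry is assigned the next free number for its B lineage
and flagged novel.

Extension profiling tabulates, among pool haplotypes carrying the full
five-locus block, the HLA-A alleles and DPA1-DPB1 blocks flanking it, as
percentages of the CEH's count.  Most-probable ancestry (MPA) assigns the
continental group(s) in which the CEH is common (reference frequency above a
threshold, default 0.10).
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Mapping, Sequence

import pandas as pd

from .familyio import load_data_table
from .nomenclature import CEH_LOCI, PANEL, HLAAllele, parse_allele, truncate
from .phasing import HaplotypePool

#: literature convention for a common CEH; the study cutoff is 0.02
DEFAULT_CUTOFF = 0.02
LITERATURE_CUTOFF = 0.005

AlleleTuple = tuple  # tuple of HLAAllele or None (None = wildcard in queries)


@dataclass
class BlockCount:
    loci: tuple[str, ...]
    alleles: AlleleTuple
    count: int
    n_known: int

    @property
    def frequency(self) -> float:
        return self.count / self.n_known

    def render(self) -> str:
        return "-".join(a.render() for a in self.alleles)


@dataclass
class CEHRecord:
    alleles: AlleleTuple  # C, B, DRB1, DQA1, DQB1 at 2-field resolution
    count: int
    n_known: int
    name: str | None = None
    novel: bool = False
    a_profile: dict[str, float] = field(default_factory=dict)
    dp_profile: dict[str, float] = field(default_factory=dict)
    mpa: tuple[str, ...] = ()

    @property
    def frequency(self) -> float:
        return self.count / self.n_known

    def render(self) -> str:
        return "-".join(a.render() for a in self.alleles)


def _hap_block(hap, loci: Sequence[str], resolution: int = 2):
    out = []
    for locus in loci:
        a = hap.alleles.get(locus)
        if a is None:
            return None
        out.append(truncate(a, resolution))
    return tuple(out)


def count_blocks(
    pool: HaplotypePool, loci_subset: Sequence[str], resolution: int = 2
) -> list[BlockCount]:
    """Haplotype block counts over a locus subset, two-field resolution.

    Haplotypes with an unknown allele at any subset locus are excluded from
    both numerator and denominator.  Sorted by count descending, then by
    allele tuple.
    """
    loci = tuple(loci_subset)
    if not loci:
        raise ValueError("empty locus subset")
    for locus in loci:
        if locus not in pool.panel:
            raise KeyError(f"locus {locus!r} not in panel")
    counts: Counter = Counter()
    for hap in pool:
        block = _hap_block(hap, loci, resolution)
        if block is not None:
            counts[block] += 1
    n_known = sum(counts.values())
    blocks = [
        BlockCount(loci=loci, alleles=t, count=c, n_known=n_known)
        for t, c in counts.items()
    ]
    blocks.sort(key=lambda b: (-b.count, tuple(a.key for a in b.alleles)))
    return blocks


def block_matches(query: AlleleTuple, target: AlleleTuple, resolution: int = 2) -> bool:
    """Compare two allele tuples; ``None`` in the query is a wildcard."""
    if len(query) != len(target):
        return False
    for q, t in zip(query, target):
        if q is None:
            continue
        if t is None:
            return False
        if truncate(q, resolution) != truncate(t, resolution):
            return False
    return True


# ---------------------------------------------------------------------------
# naming registry


class CEHRegistry:
    """Known CEH names: five-locus compositions and per-lineage numbering.

    Seeded from the packaged table of historically named CEHs (8.1, 8.2, 58.1,
    60.1-60.3; lineage 51 reserves 51.1 whose published composition is not
    carried here).  The B-allele serological lineage map assigns the numeric
    label used in CEH names (B*40:06 -> "60" and so on); unmapped B alleles
    fall back to field 1 of the allele.
    """

    def __init__(self, entries=None, serotypes: Mapping[str, str] | None = None):
        self._entries: list[tuple[AlleleTuple | None, str, str]] = []
        self._serotypes: dict[str, str] = dict(serotypes or {})
        for tup, name, ancestry in entries or []:
            self.add(tup, name, ancestry)

    @classmethod
    def default(cls) -> "CEHRegistry":
        reg_df = load_data_table("ceh_registry.tsv")
        sero_df = load_data_table("b_serotype.tsv")
        entries = []
        for _, row in reg_df.iterrows():
            if row["B"]:
                tup = tuple(parse_allele(row[l]) for l in CEH_LOCI)
            else:
                tup = None  # name reserved without a recorded composition
            entries.append((tup, row["name"], row["ancestry"]))
        sero = {row["b_allele"]: row["lineage"] for _, row in sero_df.iterrows()}
        return cls(entries, sero)

    def add(self, alleles: AlleleTuple | None, name: str, ancestry: str = "") -> None:
        if any(name == n for _, n, _ in self._entries):
            raise ValueError(f"duplicate CEH name {name!r}")
        self._entries.append((alleles, name, ancestry))

    def lookup(self, alleles: AlleleTuple) -> tuple[str, str] | None:
        for tup, name, ancestry in self._entries:
            if tup is not None and block_matches(alleles, tup):
                return name, ancestry
        return None

    def lineage(self, b_allele: HLAAllele) -> str:
        key = truncate(b_allele, 2).render()
        if key in self._serotypes:
            return self._serotypes[key]
        return str(int(b_allele.fields[0]))

    def next_index(self, lineage: str) -> int:
        used = [
            int(name.split(".", 1)[1])
            for _, name, _ in self._entries
            if name.split(".", 1)[0] == lineage and "." in name
        ]
        return (max(used) + 1) if used else 1


def name_ceh(record: CEHRecord, registry: CEHRegistry) -> CEHRecord:
    """Assign a registry name or mint the next sequential name for the B
    lineage; novel names are registered so later records continue the series."""
    hit = registry.lookup(record.alleles)
    if hit is not None:
        record.name, _ = hit
        record.novel = False
        return record
    b_allele = record.alleles[CEH_LOCI.index("B")]
    lineage = registry.lineage(b_allele)
    record.name = f"{lineage}.{registry.next_index(lineage)}"
    record.novel = True
    registry.add(record.alleles, record.name)
    return record


# ---------------------------------------------------------------------------
# detection and profiling


def identify_cehs(
    pool: HaplotypePool,
    freq_cutoff: float = DEFAULT_CUTOFF,
    min_count: int = 0,
    registry: CEHRegistry | None = None,
    reference: pd.DataFrame | None = None,
    mpa_threshold: float = 0.10,
    resolution: int = 2,
) -> list[CEHRecord]:
    """Five-locus blocks at or above the frequency cutoff, named and profiled.

    Output is sorted by count descending and is invariant to pool row order.
    ``min_count`` exposes the optional minimum-observations pre-filter.
    """
    if not 0.0 < freq_cutoff <= 1.0:
        raise ValueError(f"cutoff must be in (0, 1], got {freq_cutoff}")
    blocks = count_blocks(pool, CEH_LOCI, resolution)
    registry = registry if registry is not None else CEHRegistry.default()
    records = []
    for b in blocks:
        if b.frequency >= freq_cutoff and b.count >= min_count:
            rec = CEHRecord(alleles=b.alleles, count=b.count, n_known=b.n_known)
            name_ceh(rec, registry)
            a_prof, dp_prof = extension_profile(pool, rec.alleles, resolution)
            rec.a_profile, rec.dp_profile = a_prof, dp_prof
            if reference is not None:
                rec.mpa = assign_mpa(rec.alleles, reference, mpa_threshold, resolution)
            records.append(rec)
    return records


def extension_profile(
    pool: HaplotypePool, alleles: AlleleTuple, resolution: int = 2
) -> tuple[dict[str, float], dict[str, float]]:
    """HLA-A and DPA1-DPB1 flank percentages among carriers of the block.

    Percentages use the CEH count as denominator and are rounded to 1 dp.
    A carrier with an unknown flank allele is tallied under ``"?"``.
    """
    carriers = [
        hap
        for hap in pool
        if (b := _hap_block(hap, CEH_LOCI, resolution)) is not None
        and block_matches(alleles, b, resolution)
    ]
    if not carriers:
        return {}, {}
    n = len(carriers)
    a_counts: Counter = Counter()
    dp_counts: Counter = Counter()
    for hap in carriers:
        a = hap.alleles.get("A")
        a_counts[truncate(a, resolution).render() if a else "?"] += 1
        dp = _hap_block(hap, ("DPA1", "DPB1"), resolution)
        dp_counts["-".join(x.render() for x in dp) if dp else "?"] += 1
    a_prof = {k: _pct(v, n) for k, v in a_counts.most_common()}
    dp_prof = {k: _pct(v, n) for k, v in dp_counts.most_common()}
    return a_prof, dp_prof


def _pct(count: int, total: int) -> float:
    """Percentage at 1 dp, half-up (the convention of printed tables:
    5/16 -> 31.3, not banker's 31.2)."""
    return float(
        (Decimal(100 * count) / Decimal(total)).quantize(
            Decimal("0.1"), rounding=ROUND_HALF_UP
        )
    )


def load_mpa_reference() -> pd.DataFrame:
    """The packaged synthetic continental reference table (region, five-locus
    composition, frequency).  A stand-in encoding the study's own ancestry
    assignments; real analyses should supply published reference frequencies."""
    return load_data_table("mpa_reference_synthetic.tsv")


def assign_mpa(
    alleles: AlleleTuple,
    reference: pd.DataFrame,
    threshold: float = 0.10,
    resolution: int = 2,
) -> tuple[str, ...]:
    """Continental group(s) where the CEH's reference frequency exceeds the
    threshold; empty tuple when unassigned, multiple entries on ties."""
    required = {"region", "freq", *CEH_LOCI}
    if not required.issubset(reference.columns):
        raise ValueError(f"reference table must have columns {sorted(required)}")
    regions = []
    for _, row in reference.iterrows():
        tup = tuple(parse_allele(row[l]) if row[l] else None for l in CEH_LOCI)
        if block_matches(alleles, tup, resolution) and float(row["freq"]) > threshold:
            regions.append(row["region"])
    return tuple(dict.fromkeys(regions))


def ceh_table(records: Sequence[CEHRecord]) -> pd.DataFrame:
    """Result table mirroring the study's CEH summary layout."""
    rows = [
        {
            "ceh": r.render(),
            "name": r.name,
            "novel": r.novel,
            "count": r.count,
            "freq": round(r.frequency, 3),
            "mpa": ";".join(r.mpa),
        }
        for r in records
    ]
    return pd.DataFrame(rows, columns=["ceh", "name", "novel", "count", "freq", "mpa"])
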