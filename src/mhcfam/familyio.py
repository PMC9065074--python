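"""Pedigree-genotype tables, phased-haplotype tables, and packaged fixtures.

The cohort dialect is a PED-like TSV, one row per individual::

    family_id  individual_id  father_id  mother_id  A_1  A_2  C_1  C_2 ...

with two allele columns per locus in panel order.  ``0`` or an empty cell
means a missing/absent parent id or a missing allele; loci are multi-allelic
IMGT/HLA strings, so strict PLINK PED is deliberately not used.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field
from pathlib import Path
from typing import IO, Iterable, Sequence

import pandas as pd

from .nomenclature import PANEL, HLAAllele, NomenclatureError, parse_allele, truncate

MISSING = ("", "0", "NA", "na", None)

FIXTURES = tuple(f"table{i}" for i in range(1, 11))


class FormatError(ValueError):
    """Malformed cohort table (duplicate ids, bad columns...)."""


class PedigreeError(ValueError):
    """Structurally invalid pedigree (unknown parent, cycle...)."""


GenotypePair = tuple[HLAAllele, HLAAllele]


@dataclass
class Individual:
    family_id: str
    individual_id: str
    father_id: str | None
    mother_id: str | None
    # locus -> unordered allele pair, or None when the locus was not typed
    genotypes: dict[str, GenotypePair | None] = field(default_factory=dict)

    @property
    def is_founder(self) -> bool:
        return self.father_id is None and self.mother_id is None

    @property
    def is_genotyped(self) -> bool:
        return any(g is not None for g in self.genotypes.values())

    def genotype_at(self, locus: str, resolution: int = 4) -> GenotypePair | None:
        g = self.genotypes.get(locus)
        if g is None:
            return None
        a, b = (truncate(x, resolution) for x in g)
        return (a, b) if a <= b else (b, a)


@dataclass
class Pedigree:
    family_id: str
    members: list[Individual]

    def __post_init__(self) -> None:
        ids = [m.individual_id for m in self.members]
        if len(set(ids)) != len(ids):
            raise FormatError(f"duplicate individual id in family {self.family_id}")
        self._by_id = {m.individual_id: m for m in self.members}
        for m in self.members:
            for pid in (m.father_id, m.mother_id):
                if pid is not None and pid not in self._by_id:
                    raise PedigreeError(
                        f"family {self.family_id}: {m.individual_id} names "
                        f"unknown parent {pid!r}"
                    )
        self._check_acyclic()

    def _check_acyclic(self) -> None:
        state: dict[str, int] = {}

        def visit(iid: str) -> None:
            if state.get(iid) == 1:
                raise PedigreeError(f"family {self.family_id}: parent cycle at {iid}")
            if state.get(iid) == 2:
                return
            state[iid] = 1
            m = self._by_id[iid]
            for pid in (m.father_id, m.mother_id):
                if pid is not None:
                    visit(pid)
            state[iid] = 2

        for m in self.members:
            visit(m.individual_id)

    def member(self, individual_id: str) -> Individual:
        return self._by_id[individual_id]

    def founders(self) -> list[Individual]:
        return [m for m in self.members if m.is_founder]

    def children_of(self, father_id: str | None, mother_id: str | None) -> list[Individual]:
        return [
            m
            for m in self.members
            if (m.father_id, m.mother_id) == (father_id, mother_id)
            and not m.is_founder
        ]

    def nuclear_families(self) -> list[tuple[str | None, str | None, list[Individual]]]:
        """Unique (father_id, mother_id) couples with their children, in row order."""
        seen: dict[tuple[str | None, str | None], list[Individual]] = {}
        for m in self.members:
            if m.is_founder:
                continue
            seen.setdefault((m.father_id, m.mother_id), []).append(m)
        return [(f, mo, kids) for (f, mo), kids in seen.items()]


@dataclass
class Cohort:
    pedigrees: list[Pedigree]
    panel: tuple[str, ...] = PANEL

    def __post_init__(self) -> None:
        fids = [p.family_id for p in self.pedigrees]
        if len(set(fids)) != len(fids):
            raise FormatError("duplicate family id in cohort")

    def __iter__(self) -> Iterable[Pedigree]:
        return iter(self.pedigrees)

    def __len__(self) -> int:
        return len(self.pedigrees)


# ---------------------------------------------------------------------------
# cohort TSV


def _norm_id(value: object) -> str | None:
    s = "" if value is None or pd.isna(value) else str(value).strip()
    return None if s in ("", "0") else s


def read_cohort(path: str | Path | IO[str], panel: Sequence[str] = PANEL) -> Cohort:
    """Read a PED-like cohort TSV into a :class:`Cohort`.

    Row order is preserved so repeated runs produce identical output.  Raises
    :class:`FormatError` for structural problems and :class:`NomenclatureError`
    (with row/column context) for unparseable alleles.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    required = ["family_id", "individual_id", "father_id", "mother_id"]
    if list(df.columns[:4]) != required:
        raise FormatError(f"first four columns must be {required}, got {list(df.columns[:4])}")
    families: dict[str, list[Individual]] = {}
    order: list[str] = []
    for idx, row in df.iterrows():
        genos: dict[str, GenotypePair | None] = {}
        for locus in panel:
            raw1, raw2 = row.get(f"{locus}_1", ""), row.get(f"{locus}_2", "")
            if raw1 in MISSING or raw2 in MISSING:
                genos[locus] = None
                continue
            try:
                genos[locus] = (parse_allele(raw1), parse_allele(raw2))
            except NomenclatureError as exc:
                raise NomenclatureError(
                    f"row {idx + 2}, locus {locus}: {exc}"
                ) from exc
        ind = Individual(
            family_id=str(row["family_id"]),
            individual_id=str(row["individual_id"]),
            father_id=_norm_id(row["father_id"]),
            mother_id=_norm_id(row["mother_id"]),
            genotypes=genos,
        )
        if ind.family_id not in families:
            order.append(ind.family_id)
        families.setdefault(ind.family_id, []).append(ind)
    return Cohort(pedigrees=[Pedigree(fid, families[fid]) for fid in order], panel=tuple(panel))


def write_cohort(cohort: Cohort, path: str | Path) -> None:
    """Write a cohort back to the TSV dialect (inverse of :func:`read_cohort`)."""
    cols = ["family_id", "individual_id", "father_id", "mother_id"]
    for locus in cohort.panel:
        cols += [f"{locus}_1", f"{locus}_2"]
    rows = []
    for ped in cohort.pedigrees:
        for m in ped.members:
            row = {
                "family_id": m.family_id,
                "individual_id": m.individual_id,
                "father_id": m.father_id or "0",
                "mother_id": m.mother_id or "0",
            }
            for locus in cohort.panel:
                g = m.genotypes.get(locus)
                row[f"{locus}_1"] = g[0].render() if g else "0"
                row[f"{locus}_2"] = g[1].render() if g else "0"
            rows.append(row)
    pd.DataFrame(rows, columns=cols).to_csv(path, sep="\t", index=False)


def write_haplotypes(pool, path: str | Path) -> None:
    """Write a founder :class:`~mhcfam.phasing.HaplotypePool` as TSV.

    One row per founder haplotype instance with the family id, founder id, the
    per-family label (a, b, c, d...), full-resolution alleles per locus, and a
    two-field-truncated rendering for statistics.
    """
    cols = ["family_id", "founder_id", "label"]
    cols += list(pool.panel) + [f"{locus}_2f" for locus in pool.panel]
    rows = []
    for hap in pool.haplotypes:
        fam, founder, label = hap.origin
        row = {"family_id": fam, "founder_id": founder, "label": label}
        for locus in pool.panel:
            a = hap.alleles.get(locus)
            row[locus] = a.render() if a else "0"
            row[f"{locus}_2f"] = truncate(a, 2).render() if a else "0"
        rows.append(row)
    pd.DataFrame(rows, columns=cols).to_csv(path, sep="\t", index=False)


def read_haplotypes(path: str | Path, panel: Sequence[str] = PANEL):
    """Read a haplotype TSV written by :func:`write_haplotypes` back to a pool."""
    from .phasing import Haplotype, HaplotypePool

    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    haps = []
    for _, row in df.iterrows():
        alleles = {
            locus: (parse_allele(row[locus]) if row[locus] not in MISSING else None)
            for locus in panel
        }
        haps.append(
            Haplotype(
                alleles=alleles,
                origin=(row["family_id"], row["founder_id"], row["label"]),
            )
        )
    return HaplotypePool(haplotypes=haps, panel=tuple(panel))


# ---------------------------------------------------------------------------
# packaged fixtures


def _data_path(name: str):
    return importlib.resources.files("mhcfam.data").joinpath(name)


def load_fixture(name: str) -> pd.DataFrame:
    """Load one of the packaged result tables (``table1`` ... ``table10``).

    ``table1``/``table2`` are per-locus allele counts and frequencies;
    ``table3``-``table6`` are multi-locus block counts; ``table7``-``table10``
    are per-family haplotype listings with assigned CEH names and ancestry.
    Duplicate printed rows are preserved verbatim and flagged in ``dup``.
    """
    if name not in FIXTURES:
        raise KeyError(f"unknown fixture {name!r}; expected one of {FIXTURES}")
    with _data_path(f"{name}.tsv").open("r", encoding="utf-8") as fh:
        df = pd.read_csv(fh, sep="\t", dtype=str, keep_default_na=False)
    for col in ("count", "dup"):
        if col in df.columns:
            df[col] = df[col].astype(int)
    if "freq" in df.columns:
        df["freq"] = df["freq"].astype(float)
    return df


def load_data_table(name: str) -> pd.DataFrame:
    """Load an auxiliary packaged table (registry, serotype map, reference)."""
    with _data_path(name).open("r", encoding="utf-8") as fh:
        return pd.read_csv(fh, sep="\t", dtype=str, keep_default_na=False)


def fixture_pool(name: str, panel: Sequence[str] = PANEL):
    """Build a :class:`~mhcfam.phasing.HaplotypePool` from a table7-10 fixture."""
    from .phasing import Haplotype, HaplotypePool

    df = load_fixture(name)
    haps = []
    for _, row in df.iterrows():
        alleles = {
            locus: (parse_allele(row[locus]) if row.get(locus, "") not in MISSING else None)
            for locus in panel
        }
        haps.append(
            Haplotype(alleles=alleles, origin=(row["family"], row["family"], row["label"]))
        )
    return HaplotypePool(haplotypes=haps, panel=tuple(panel))
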