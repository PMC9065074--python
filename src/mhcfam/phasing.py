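"""Mendelian segregation phasing of family multi-locus HLA genotypes.

Within a nuclear family, each child inherits one whole parental haplotype per
parent (MHC haplotypes are treated as identical-by-descent blocks; no
recombination by default).  The phase of a family is therefore a joint
assignment of

* the four parental haplotypes (per-locus allele placement), and
* one transmission label per child per parent (which of the parent's two
  haplotypes that child received), constant across loci.

The solver performs an exact constraint-satisfaction search: child label
assignments are enumerated (the within-parent relabelling symmetry is removed
by fixing the first genotyped child's labels), and per locus the compatible
allele placements are derived by constraint propagation.  Loci where several
placement classes survive are flagged ``ambiguous_phase`` and left unknown;
recorded parental homozygotes that conflict with offspring but are explainable
by one hidden allele (allelic dropout) are repaired and flagged
``dropout_resolved``; irreparable conflicts yield ``recombination_candidate``
(a single label flip at one locus would rescue the family) or ``mendel_error``.

Founder haplotypes are collected into a :class:`HaplotypePool`, the denominator
of all downstream frequency estimates.  In a multi-generation pedigree only
grandparents and marry-in spouses are founders; middle-generation haplotypes
are copies and are excluded.
"""

from __future__ import annotations

import string
from dataclasses import dataclass, field
from itertools import product
from typing import Iterable, Sequence

import pandas as pd

from .familyio import Cohort, Individual, Pedigree
from .nomenclature import PANEL, HLAAllele

DIAG_KINDS = (
    "mendel_error",
    "dropout_resolved",
    "ambiguous_phase",
    "recombination_candidate",
    "unresolved",
)


class PhasingError(ValueError):
    """Raised when a family cannot be submitted to phasing at all."""


@dataclass(frozen=True)
class Haplotype:
    """One founder haplotype: per-locus allele (or unknown) plus provenance."""

    alleles: dict
    origin: tuple[str, str, str]  # (family_id, founder_id, label)

    def __post_init__(self) -> None:
        if all(v is None for v in self.alleles.values()):
            raise ValueError("an all-unknown haplotype is invalid")

    def render(self, panel: Sequence[str] = PANEL) -> tuple[str, ...]:
        return tuple(
            self.alleles[l].render() if self.alleles.get(l) else "?" for l in panel
        )

    def __hash__(self) -> int:
        return hash((self.origin, self.render()))


@dataclass
class Diagnostic:
    family_id: str
    locus: str
    kind: str
    detail: str = ""


@dataclass
class PhasedFamily:
    """Result of phasing one nuclear family."""

    family_id: str
    father_id: str | None
    mother_id: str | None
    # per-locus allele dicts; None entries are unknown/ambiguous
    father_haplotypes: tuple[dict, dict] | None
    mother_haplotypes: tuple[dict, dict] | None
    transmissions: dict[str, tuple[int, int]]
    diagnostics: list[Diagnostic] = field(default_factory=list)
    eligible: bool = True
    father_is_founder: bool = True
    mother_is_founder: bool = True

    @property
    def consistent(self) -> bool:
        return not any(
            d.kind in ("mendel_error", "recombination_candidate") for d in self.diagnostics
        )


# ---------------------------------------------------------------------------
# per-locus constraint solving

_FREE = object()  # marker: a repair slot whose hidden allele must be inferred


def _orientations(pair):
    if pair is None:
        return [(None, None)]
    a, b = pair
    if a == b:
        return [(a, a)]
    return [(a, b), (b, a)]


def _repair_orientations(pair):
    # a recorded homozygote may hide its second allele (allelic dropout)
    if pair is None or pair[0] != pair[1]:
        return []
    a = pair[0]
    return [(a, _FREE), (_FREE, a)]


def _pair_key(x: HLAAllele) -> tuple:
    return x.key


def _solve_locus(fpair, mpair, kids, allow_repair: bool):
    """All allele placements (f1, f2, m1, m2) consistent with the children.

    ``kids`` is a list of ``(pair_or_None, pf, pm)``.  Returns a list of
    ``(placement, repairs)`` where ``placement`` entries may be None (unknown)
    and ``repairs`` lists ``(slot, recorded, hidden)`` dropout resolutions.
    """
    f_opts = [(o, False) for o in _orientations(fpair)]
    m_opts = [(o, False) for o in _orientations(mpair)]
    if allow_repair:
        f_opts += [(o, True) for o in _repair_orientations(fpair)]
        m_opts += [(o, True) for o in _repair_orientations(mpair)]
    out = []
    seen = set()
    for fo, frep in f_opts:
        for mo, mrep in m_opts:
            slots = {"f1": fo[0], "f2": fo[1], "m1": mo[0], "m2": mo[1]}
            repair_slots = [k for k, v in slots.items() if v is _FREE]
            for k in repair_slots:
                slots[k] = None
            ok = True
            changed = True
            while changed and ok:
                changed = False
                for pair, pf, pm in kids:
                    if pair is None:
                        continue
                    a, b = pair
                    fs, ms = f"f{pf}", f"m{pm}"
                    tf, tm = slots[fs], slots[ms]
                    if tf is not None and tm is not None:
                        if sorted([tf.key, tm.key]) != sorted([a.key, b.key]):
                            ok = False
                            break
                    elif tf is not None:
                        if tf == a:
                            other = b
                        elif tf == b:
                            other = a
                        else:
                            ok = False
                            break
                        slots[ms] = other
                        changed = True
                    elif tm is not None:
                        if tm == a:
                            other = b
                        elif tm == b:
                            other = a
                        else:
                            ok = False
                            break
                        slots[fs] = other
                        changed = True
                    elif a == b:
                        slots[fs] = a
                        slots[ms] = a
                        changed = True
            if not ok:
                continue
            repairs = []
            skip = False
            for k in repair_slots:
                recorded = (fpair if k.startswith("f") else mpair)[0]
                hidden = slots[k]
                if hidden is None or hidden == recorded:
                    # no child revealed a second allele: identical to the
                    # strict orientation, so not a repair
                    skip = True
                    break
                repairs.append((k, recorded, hidden))
            if skip and (frep or mrep):
                continue
            placement = tuple(slots[k] for k in ("f1", "f2", "m1", "m2"))
            key = (
                tuple(x.key if x is not None else None for x in placement),
                tuple((k, h.key) for k, _, h in repairs),
            )
            if key not in seen:
                seen.add(key)
                out.append((placement, repairs))
    return out


# ---------------------------------------------------------------------------
# nuclear-family solver


def _genotype_maps(ind: Individual | None, panel, resolution):
    if ind is None or not ind.is_genotyped:
        return None
    return {locus: ind.genotype_at(locus, resolution) for locus in panel}


def _label_assignments(n_children: int):
    labels = [(1, 1), (1, 2), (2, 1), (2, 2)]
    for rest in product(labels, repeat=n_children - 1):
        yield ((1, 1),) + rest


def _hap_sort_key(hap: dict, panel) -> tuple:
    return tuple(hap[l].key if hap.get(l) is not None else ("~",) for l in panel)


def _phase_nuclear(
    family_id: str,
    father: Individual | None,
    mother: Individual | None,
    children: list[Individual],
    panel: Sequence[str],
    resolution: int,
) -> PhasedFamily:
    fmap = _genotype_maps(father, panel, resolution)
    mmap = _genotype_maps(mother, panel, resolution)
    kids = [
        (c.individual_id, {l: c.genotype_at(l, resolution) for l in panel})
        for c in children
        if c.is_genotyped
    ]
    if not kids:
        raise PhasingError(f"family {family_id}: no genotyped children")

    def base(eligible: bool, diags=()) -> PhasedFamily:
        return PhasedFamily(
            family_id=family_id,
            father_id=father.individual_id if father else None,
            mother_id=mother.individual_id if mother else None,
            father_haplotypes=None,
            mother_haplotypes=None,
            transmissions={},
            diagnostics=list(diags),
            eligible=eligible,
            father_is_founder=father.is_founder if father else True,
            mother_is_founder=mother.is_founder if mother else True,
        )

    if fmap is None and mmap is None:
        return base(False, [Diagnostic(family_id, "*", "unresolved", "both parents ungenotyped")])
    if fmap is None or mmap is None:
        # missing-parent eligibility: at least two children that are not
        # HLA-identical to each other are required
        sigs = [
            tuple(
                tuple(sorted((a.key, b.key))) if (g := geno.get(l)) and (a := g[0]) and (b := g[1]) else None
                for l in panel
            )
            for _, geno in kids
        ]
        if len(kids) < 2 or len(set(sigs)) < 2:
            return base(
                False,
                [
                    Diagnostic(
                        family_id,
                        "*",
                        "unresolved",
                        "ineligible: missing parent with fewer than two "
                        "non-HLA-identical genotyped children",
                    )
                ],
            )

    # enumerate transmission label assignments (first genotyped child fixed)
    viable = []  # (cost, assignment, {locus: [(placement, repairs)]})
    failures = []  # (n_failed, assignment, per_locus, failed_loci)
    for assignment in _label_assignments(len(kids)):
        per_locus: dict[str, list] = {}
        failed: list[str] = []
        cost = 0
        for locus in panel:
            kid_info = [
                (geno.get(locus), pf, pm)
                for (_, geno), (pf, pm) in zip(kids, assignment)
            ]
            placements = _solve_locus(
                fmap.get(locus) if fmap else None,
                mmap.get(locus) if mmap else None,
                kid_info,
                allow_repair=False,
            )
            if not placements:
                placements = _solve_locus(
                    fmap.get(locus) if fmap else None,
                    mmap.get(locus) if mmap else None,
                    kid_info,
                    allow_repair=True,
                )
                if placements:
                    nmin = min(len(r) for _, r in placements)
                    placements = [(p, r) for p, r in placements if len(r) == nmin]
                    cost += nmin
            if placements:
                per_locus[locus] = placements
            else:
                failed.append(locus)
        if failed:
            failures.append((len(failed), assignment, per_locus, failed))
        else:
            viable.append((cost, assignment, per_locus))

    diags: list[Diagnostic] = []
    if viable:
        min_cost = min(v[0] for v in viable)
        chosen = [v for v in viable if v[0] == min_cost]
        merged: dict[str, list] = {}
        for locus in panel:
            seen = set()
            plist = []
            for _, _, per_locus in chosen:
                for placement, repairs in per_locus[locus]:
                    key = tuple(x.key if x else None for x in placement)
                    if key not in seen:
                        seen.add(key)
                        plist.append((placement, repairs))
            merged[locus] = plist
        f1: dict = {}
        f2: dict = {}
        m1: dict = {}
        m2: dict = {}
        for locus in panel:
            plist = merged[locus]
            if len(plist) > 1:
                diags.append(Diagnostic(family_id, locus, "ambiguous_phase"))
                # keep slots on which every surviving placement agrees
                slots = []
                for i in range(4):
                    vals = {p[i].key if p[i] else None for p, _ in plist}
                    slots.append(plist[0][0][i] if len(vals) == 1 else None)
            else:
                placement, repairs = plist[0]
                slots = list(placement)
                for slot, recorded, hidden in repairs:
                    parent = "father" if slot.startswith("f") else "mother"
                    diags.append(
                        Diagnostic(
                            family_id,
                            locus,
                            "dropout_resolved",
                            f"{parent} recorded {recorded.render()}, "
                            f"hidden allele {hidden.render()}",
                        )
                    )
            parent_known = {
                0: fmap is not None and fmap.get(locus) is not None,
                2: mmap is not None and mmap.get(locus) is not None,
            }
            for i, target in enumerate((f1, f2, m1, m2)):
                target[locus] = slots[i]
                if slots[i] is None and not parent_known[i // 2 * 2] and len(plist) == 1:
                    if not any(
                        d.locus == locus and d.kind == "unresolved" for d in diags
                    ):
                        diags.append(Diagnostic(family_id, locus, "unresolved"))
        transmissions = dict(zip((cid for cid, _ in kids), chosen[0][1]))
        # deterministic within-parent order: lexicographic by rendered haplotype
        if _hap_sort_key(f2, panel) < _hap_sort_key(f1, panel):
            f1, f2 = f2, f1
            transmissions = {c: (3 - pf, pm) for c, (pf, pm) in transmissions.items()}
        if _hap_sort_key(m2, panel) < _hap_sort_key(m1, panel):
            m1, m2 = m2, m1
            transmissions = {c: (pf, 3 - pm) for c, (pf, pm) in transmissions.items()}
        result = base(True, diags)
        result.father_haplotypes = (f1, f2)
        result.mother_haplotypes = (m1, m2)
        result.transmissions = transmissions
        return result

    # no viable assignment: diagnose the least-broken one
    failures.sort(key=lambda t: t[0])
    _, assignment, per_locus, failed = failures[0]
    for locus in failed:
        rescued = False
        for k in range(len(kids)):
            for alt in ((1, 1), (1, 2), (2, 1), (2, 2)):
                if alt == assignment[k]:
                    continue
                kid_info = [
                    (geno.get(locus), *(alt if i == k else assignment[i]))
                    for i, (_, geno) in enumerate(kids)
                ]
                if _solve_locus(
                    fmap.get(locus) if fmap else None,
                    mmap.get(locus) if mmap else None,
                    kid_info,
                    allow_repair=True,
                ):
                    rescued = True
                    break
            if rescued:
                break
        kind = "recombination_candidate" if rescued else "mendel_error"
        diags.append(Diagnostic(family_id, locus, kind))
    result = base(True, diags)
    # salvage the consistent loci for reporting (pool extraction skips the
    # family by default anyway)
    f1 = {l: None for l in panel}
    f2 = dict(f1)
    m1 = dict(f1)
    m2 = dict(f1)
    for locus in panel:
        if locus in failed or locus not in per_locus:
            continue
        plist = per_locus[locus]
        if len(plist) == 1:
            placement, _ = plist[0]
            f1[locus], f2[locus], m1[locus], m2[locus] = placement
    result.father_haplotypes = (f1, f2)
    result.mother_haplotypes = (m1, m2)
    result.transmissions = dict(zip((cid for cid, _ in kids), assignment))
    return result


# ---------------------------------------------------------------------------
# public API


def phase_pedigree(
    ped: Pedigree, panel: Sequence[str] = PANEL, resolution: int = 4
) -> list[PhasedFamily]:
    """Phase every nuclear family of a pedigree (one result per couple)."""
    results = []
    for father_id, mother_id, kids in ped.nuclear_families():
        father = ped.member(father_id) if father_id else None
        mother = ped.member(mother_id) if mother_id else None
        results.append(
            _phase_nuclear(ped.family_id, father, mother, kids, panel, resolution)
        )
    return results


def phase_family(
    ped: Pedigree, panel: Sequence[str] = PANEL, resolution: int = 4
) -> PhasedFamily:
    """Phase a two-generation pedigree (exactly one nuclear family)."""
    results = phase_pedigree(ped, panel, resolution)
    if len(results) != 1:
        raise PhasingError(
            f"family {ped.family_id} has {len(results)} nuclear families; "
            "use phase_pedigree"
        )
    return results[0]


def phase_with_missing_parent(
    ped: Pedigree, panel: Sequence[str] = PANEL, resolution: int = 4
) -> PhasedFamily:
    """Phase a nuclear family in which exactly one parent is ungenotyped.

    The genotyped parent is phased against the children and the missing
    parent's haplotypes are reconstructed per child as the child allele minus
    the genotyped parent's contribution.  Requires at least two children that
    are not HLA-identical to each other; otherwise the family is marked
    ineligible and contributes nothing to the founder pool.
    """
    result = phase_family(ped, panel, resolution)
    return result


def phase_cohort(
    cohort: Cohort, resolution: int = 4
) -> list[PhasedFamily]:
    """Phase every nuclear family of every pedigree in the cohort."""
    out: list[PhasedFamily] = []
    for ped in cohort.pedigrees:
        out.extend(phase_pedigree(ped, cohort.panel, resolution))
    return out


@dataclass
class HaplotypePool:
    """Founder haplotype instances; duplicates kept (counts are the point)."""

    haplotypes: list[Haplotype]
    panel: tuple[str, ...] = PANEL

    @property
    def total_count(self) -> int:
        return len(self.haplotypes)

    def known_count(self, locus: str) -> int:
        return sum(1 for h in self.haplotypes if h.alleles.get(locus) is not None)

    def __len__(self) -> int:
        return len(self.haplotypes)

    def __iter__(self):
        return iter(self.haplotypes)


def extract_founder_pool(
    phased: Iterable[PhasedFamily],
    panel: Sequence[str] = PANEL,
    keep_recombinants: bool = False,
) -> HaplotypePool:
    """Collect two haplotypes per genotyped-or-reconstructed founder.

    Families flagged with ``mendel_error`` or ``recombination_candidate`` are
    excluded unless ``keep_recombinants`` (flagged loci are then unknown).
    Labels a, b, c, d... are assigned per family: father's two, then mother's
    two, then marry-in spouses, in table order.
    """
    by_family: dict[str, list[PhasedFamily]] = {}
    order: list[str] = []
    for pf in phased:
        if pf.family_id not in by_family:
            order.append(pf.family_id)
        by_family.setdefault(pf.family_id, []).append(pf)

    haps: list[Haplotype] = []
    for fid in order:
        labels = iter(string.ascii_lowercase)
        for unit_idx, pf in enumerate(by_family[fid]):
            if not pf.eligible:
                continue
            if not pf.consistent and not keep_recombinants:
                continue
            bad_loci = {
                d.locus
                for d in pf.diagnostics
                if d.kind in ("mendel_error", "recombination_candidate")
            }
            pairs = [
                (pf.father_id, pf.father_is_founder, pf.father_haplotypes, "father"),
                (pf.mother_id, pf.mother_is_founder, pf.mother_haplotypes, "mother"),
            ]
            for pid, is_founder, hap_pair, role in pairs:
                if not is_founder or hap_pair is None:
                    # middle-generation parents carry copies of founder
                    # haplotypes; skip them
                    if not is_founder:
                        continue
                    continue
                founder_id = pid if pid is not None else f"{role}.{unit_idx}"
                for hap in hap_pair:
                    alleles = {
                        l: (None if l in bad_loci else hap.get(l)) for l in panel
                    }
                    if all(v is None for v in alleles.values()):
                        continue  # nothing reconstructable for this founder slot
                    haps.append(
                        Haplotype(
                            alleles=alleles,
                            origin=(fid, founder_id, next(labels)),
                        )
                    )
    return HaplotypePool(haplotypes=haps, panel=tuple(panel))


def mendel_report(phased: Iterable[PhasedFamily]) -> pd.DataFrame:
    """One row per diagnostic: family, locus, kind, detail."""
    rows = [
        {
            "family_id": d.family_id,
            "locus": d.locus,
            "kind": d.kind,
            "detail": d.detail,
        }
        for pf in phased
        for d in pf.diagnostics
    ]
    return pd.DataFrame(rows, columns=["family_id", "locus", "kind", "detail"])
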