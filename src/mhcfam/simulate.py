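"""Synthetic family cohorts with known haplotype ground truth.

The generator emulates the design of a family segregation study: a founder
haplotype pool drawn from per-locus allele frequency spectra, two-generation
nuclear families (founder couple plus children who each inherit one whole
parental haplotype per parent), one optional three-generation pedigree with
marry-in spouses, and typing artefacts layered on the observed genotypes only
(the ground truth is untouched):

* ``missing_parent_rate`` — one parent of a family wholly ungenotyped,
* ``locus_missing_rate`` — a single locus genotype dropped,
* ``dropout_rate`` — allelic dropout: a founder heterozygote recorded as
  homozygous for one of its alleles,
* ``crossover_rate`` — per-meiosis single crossover (off by default; MHC
  blocks are transmitted intact, the switch exists to exercise the phaser's
  recombination diagnostics).

Per-locus spectra default to a geometric series with ratio 0.8 (one dominant
allele and a long tail, the shape seen in outbred HLA cohorts) with the allele
counts observed in the study cohort (31, 29, 41, 30, 13, 15, 8, 20 across the
panel).  Linkage between loci arises from transmission; an optional "CEH
seeding" repeats a fixed five-locus block in a stated fraction of pool draws
to emulate conserved extended haplotypes.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .familyio import Cohort, Individual, Pedigree
from .nomenclature import CEH_LOCI, PANEL, HLAAllele, parse_allele

#: distinct allele counts per locus in the study cohort (Tables of record)
STUDY_ALLELE_COUNTS: dict[str, int] = {
    "A": 31,
    "C": 29,
    "B": 41,
    "DRB1": 30,
    "DQA1": 13,
    "DQB1": 15,
    "DPA1": 8,
    "DPB1": 20,
}


def geometric_spectrum(k: int, ratio: float = 0.8) -> np.ndarray:
    """Normalized geometric frequency vector p_i proportional to ratio**i."""
    if k < 1:
        raise ValueError("need at least one allele")
    w = np.power(ratio, np.arange(k))
    return w / w.sum()


def default_pool_spec(
    panel: Sequence[str] = PANEL, ratio: float = 0.8
) -> dict[str, tuple[list[HLAAllele], np.ndarray]]:
    """Per-locus ``(alleles, frequencies)`` with study-like allele counts."""
    spec = {}
    for locus in panel:
        k = STUDY_ALLELE_COUNTS[locus]
        alleles = [parse_allele(f"{locus}*{g:02d}:01") for g in range(1, k + 1)]
        spec[locus] = (alleles, geometric_spectrum(k, ratio))
    return spec


@dataclass
class SimConfig:
    """Study-design parameters for the synthetic cohort generator."""

    n_families: int = 40
    children_min: int = 2
    children_max: int = 5
    pool_spec: dict | None = None  # locus -> (alleles, freqs); default study-like
    ceh_block: dict | None = None  # locus -> HLAAllele over the 5 CEH loci
    ceh_fraction: float = 0.0
    missing_parent_rate: float = 0.0
    locus_missing_rate: float = 0.0
    dropout_rate: float = 0.0
    crossover_rate: float = 0.0
    seed: int = 0
    panel: tuple[str, ...] = PANEL

    def __post_init__(self) -> None:
        for name in (
            "ceh_fraction",
            "missing_parent_rate",
            "locus_missing_rate",
            "dropout_rate",
            "crossover_rate",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.pool_spec is None:
            self.pool_spec = default_pool_spec(self.panel)


@dataclass
class GroundTruth:
    """True founder haplotypes and per-child transmission labels."""

    # family -> founder individual id -> (hap1, hap2), each locus->HLAAllele
    founder_haplotypes: dict[str, dict[str, tuple[dict, dict]]] = field(
        default_factory=dict
    )
    # family -> child id -> (paternal label, maternal label), 1-based
    transmissions: dict[str, dict[str, tuple[int, int]]] = field(default_factory=dict)

    def pool_multiset(self, panel: Sequence[str] = PANEL):
        """All founder haplotypes as a multiset of rendered tuples."""
        out = []
        for fam in self.founder_haplotypes.values():
            for h1, h2 in fam.values():
                for h in (h1, h2):
                    out.append(tuple(h[l].render() for l in panel))
        return sorted(out)


def generate_pool(
    pool_spec: dict,
    n: int,
    rng: np.random.Generator,
    ceh_block: dict | None = None,
    ceh_fraction: float = 0.0,
    panel: Sequence[str] = PANEL,
) -> list[dict]:
    """Draw ``n`` founder haplotypes, one allele per locus independently.

    With ``ceh_fraction > 0`` a Bernoulli fraction of draws has the five-locus
    ``ceh_block`` substituted in, emulating a conserved extended haplotype.
    """
    haps = []
    for _ in range(n):
        hap = {}
        for locus in panel:
            alleles, freqs = pool_spec[locus]
            if len(alleles) == 0:
                raise ValueError(f"empty allele list for locus {locus}")
            hap[locus] = alleles[rng.choice(len(alleles), p=np.asarray(freqs))]
        if ceh_block is not None and rng.random() < ceh_fraction:
            for locus, allele in ceh_block.items():
                hap[locus] = allele
        haps.append(hap)
    return haps


def _transmit(h1: dict, h2: dict, label: int, crossover_rate: float, rng, panel):
    """One meiosis: whole-haplotype transmission, optional single crossover."""
    src = (h1, h2)[label - 1]
    if crossover_rate > 0.0 and rng.random() < crossover_rate:
        other = (h2, h1)[label - 1]
        cut = int(rng.integers(1, len(panel)))  # breakpoint between loci
        return {
            l: (src[l] if i < cut else other[l]) for i, l in enumerate(panel)
        }, True
    return dict(src), False


def _apply_noise(ind: Individual, cfg: SimConfig, rng, is_parent: bool) -> None:
    for locus in cfg.panel:
        g = ind.genotypes.get(locus)
        if g is None:
            continue
        if rng.random() < cfg.locus_missing_rate:
            ind.genotypes[locus] = None
            continue
        if is_parent and g[0] != g[1] and rng.random() < cfg.dropout_rate:
            keep = g[int(rng.integers(0, 2))]
            ind.genotypes[locus] = (keep, keep)


def _make_family(
    family_id: str,
    cfg: SimConfig,
    rng: np.random.Generator,
    truth: GroundTruth,
) -> Pedigree:
    panel = cfg.panel
    pool4 = generate_pool(
        cfg.pool_spec, 4, rng, cfg.ceh_block, cfg.ceh_fraction, panel
    )
    f1, f2, m1, m2 = pool4
    father = Individual(family_id, "F", None, None, {l: (f1[l], f2[l]) for l in panel})
    mother = Individual(family_id, "M", None, None, {l: (m1[l], m2[l]) for l in panel})
    n_children = int(rng.integers(cfg.children_min, cfg.children_max + 1))
    members = [father, mother]
    truth.founder_haplotypes[family_id] = {"F": (f1, f2), "M": (m1, m2)}
    truth.transmissions[family_id] = {}
    for i in range(n_children):
        pf, pm = int(rng.integers(1, 3)), int(rng.integers(1, 3))
        pat, _ = _transmit(f1, f2, pf, cfg.crossover_rate, rng, panel)
        mat, _ = _transmit(m1, m2, pm, cfg.crossover_rate, rng, panel)
        cid = f"C{i + 1}"
        members.append(
            Individual(
                family_id, cid, "F", "M", {l: (pat[l], mat[l]) for l in panel}
            )
        )
        truth.transmissions[family_id][cid] = (pf, pm)
    # typing artefacts on observed genotypes only
    if rng.random() < cfg.missing_parent_rate:
        victim = members[int(rng.integers(0, 2))]
        victim.genotypes = {l: None for l in panel}
    for m in members:
        _apply_noise(m, cfg, rng, is_parent=m.is_founder)
    return Pedigree(family_id, members)


def generate_cohort(config: SimConfig) -> tuple[Cohort, GroundTruth]:
    """Generate ``n_families`` two-generation families; seed-deterministic."""
    rng = np.random.default_rng(config.seed)
    truth = GroundTruth()
    peds = [
        _make_family(f"SF{i + 1}", config, rng, truth)
        for i in range(config.n_families)
    ]
    return Cohort(pedigrees=peds, panel=tuple(config.panel)), truth


def generate_three_generation(
    config: SimConfig, n_marryins: int = 3, family_id: str = "TG1"
) -> tuple[Pedigree, GroundTruth]:
    """One three-generation pedigree: grandparent couple, children, of whom
    ``n_marryins`` marry ungenotyped-pool spouses and have two grandchildren
    each.  Founder haplotype count is ``4 + 2 * n_marryins``."""
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 3]))
    panel = config.panel
    truth = GroundTruth()
    gp = generate_pool(config.pool_spec, 4, rng, config.ceh_block, config.ceh_fraction, panel)
    gf1, gf2, gm1, gm2 = gp
    gfather = Individual(family_id, "GF", None, None, {l: (gf1[l], gf2[l]) for l in panel})
    gmother = Individual(family_id, "GM", None, None, {l: (gm1[l], gm2[l]) for l in panel})
    members = [gfather, gmother]
    truth.founder_haplotypes[family_id] = {"GF": (gf1, gf2), "GM": (gm1, gm2)}
    truth.transmissions[family_id] = {}
    n_children = max(2, n_marryins)
    child_haps = []
    for i in range(n_children):
        pf, pm = int(rng.integers(1, 3)), int(rng.integers(1, 3))
        pat, _ = _transmit(gf1, gf2, pf, 0.0, rng, panel)
        mat, _ = _transmit(gm1, gm2, pm, 0.0, rng, panel)
        cid = f"P{i + 1}"
        members.append(
            Individual(family_id, cid, "GF", "GM", {l: (pat[l], mat[l]) for l in panel})
        )
        truth.transmissions[family_id][cid] = (pf, pm)
        child_haps.append((pat, mat))
    for j in range(n_marryins):
        s1, s2 = generate_pool(
            config.pool_spec, 2, rng, config.ceh_block, config.ceh_fraction, panel
        )
        sid = f"S{j + 1}"
        spouse = Individual(family_id, sid, None, None, {l: (s1[l], s2[l]) for l in panel})
        members.append(spouse)
        truth.founder_haplotypes[family_id][sid] = (s1, s2)
        pat_hap, mat_hap = child_haps[j]
        parent_id = f"P{j + 1}"
        for g in range(2):
            # the married-in parent is the mother of the grandchildren when the
            # middle-generation child is male-labelled; orientation is
            # irrelevant to phasing, use child as father
            pf, pm = int(rng.integers(1, 3)), int(rng.integers(1, 3))
            mid_haps = ((pat_hap, mat_hap)[pf - 1]).copy()
            sp_haps = (s1, s2)[pm - 1].copy()
            gid = f"G{j + 1}.{g + 1}"
            members.append(
                Individual(
                    family_id,
                    gid,
                    parent_id,
                    sid,
                    {l: (mid_haps[l], sp_haps[l]) for l in panel},
                )
            )
            truth.transmissions[family_id][gid] = (pf, pm)
    ped = Pedigree(family_id, members)
    return ped, truth


def generate_study_cohort(seed: int = 0, **overrides) -> tuple[Cohort, GroundTruth]:
    """The study design: 40 two-generation families plus one three-generation
    family with 3 marry-in spouses (4 + 6 = 10 founder haplotypes), for a
    founder pool of 40 x 4 + 10 = 170 haplotypes."""
    cfg = SimConfig(seed=seed, **overrides)
    cohort, truth = generate_cohort(cfg)
    ped3, truth3 = generate_three_generation(cfg, n_marryins=3, family_id="HF8")
    cohort.pedigrees.append(ped3)
    truth.founder_haplotypes.update(truth3.founder_haplotypes)
    truth.transmissions.update(truth3.transmissions)
    return cohort, truth
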