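"""Segregation phasing: soundness, recovery, repairs, diagnostics.

Includes an independent brute-force phaser (joint enumeration of transmission
labels and per-locus orientations, no propagation, no repairs) used as an
oracle for noise-free families.
"""

from itertools import product

import pytest

from mhcfam import (
    PANEL,
    SimConfig,
    extract_founder_pool,
    generate_cohort,
    generate_three_generation,
    mendel_report,
    parse_allele,
    phase_cohort,
    phase_family,
    phase_pedigree,
)
from conftest import family, geno, uniform_geno


# ---------------------------------------------------------------------------
# independent oracle


def brute_force_solutions(ped):
    """All (f1, f2, m1, m2) placements per locus consistent with some global
    transmission labelling, for noise-free two-generation families with both
    parents genotyped.  The global within-parent relabelling symmetry is
    removed by fixing the first child's labels to (1, 1), matching the
    solver's own symmetry reduction.  Returns ``({locus: set of placements},
    n_consistent_labelings)``."""
    father = ped.member("F")
    mother = ped.member("M")
    kids = [m for m in ped.members if not m.is_founder and m.is_genotyped]

    def orients(pair):
        if pair is None:
            return [(None, None)]
        a, b = pair
        return [(a, b)] if a == b else [(a, b), (b, a)]

    per_locus = {l: set() for l in PANEL}
    n_ok = 0
    for rest in product([(1, 1), (1, 2), (2, 1), (2, 2)], repeat=len(kids) - 1):
        labels = ((1, 1),) + rest
        ok_all = True
        tentative = {}
        for l in PANEL:
            fg = father.genotype_at(l)
            mg = mother.genotype_at(l)
            good = []
            for fo in orients(fg):
                for mo in orients(mg):
                    consistent = True
                    for kid, (pf, pm) in zip(kids, labels):
                        g = kid.genotype_at(l)
                        if g is None:
                            continue
                        tf, tm = fo[pf - 1], mo[pm - 1]
                        if sorted([tf.key, tm.key]) != sorted(
                            [g[0].key, g[1].key]
                        ):
                            consistent = False
                            break
                    if consistent:
                        good.append((*fo, *mo))
            if not good:
                ok_all = False
                break
            tentative[l] = good
        if ok_all:
            n_ok += 1
            for l, good in tentative.items():
                per_locus[l].update(
                    tuple(x.key if x else None for x in g) for g in good
                )
    return per_locus, n_ok


def _hap_sets(pf):
    return [
        dict(h) for h in (*pf.father_haplotypes, *pf.mother_haplotypes)
    ]


# ---------------------------------------------------------------------------
# hand-built cases


def test_fully_informative_family_unique_solution(informative_trio):
    pf = phase_family(informative_trio)
    assert pf.eligible and pf.consistent
    assert not pf.diagnostics
    rendered = sorted(
        tuple(h[l].render() for l in PANEL)
        for h in (*pf.father_haplotypes, *pf.mother_haplotypes)
    )
    groups = sorted(t[0].split("*")[1] for t in rendered)
    assert groups == ["01:01", "02:01", "03:01", "11:01"]


def test_symmetric_family_flags_ambiguous_phase():
    """Both parents share a heterozygous pair and the only child is
    heterozygous: the child's parental origin is undecidable at that locus."""
    base_f = uniform_geno(("X*01:01", "X*02:01"))
    base_m = uniform_geno(("X*03:01", "X*04:01"))
    kid = uniform_geno(("X*01:01", "X*03:01"))
    # overwrite one locus with the symmetric configuration
    amb = geno({"B": ("B*07:02", "B*08:01")})["B"]
    base_f["B"] = base_m["B"] = kid["B"] = amb
    pf = phase_family(family("S1", base_f, base_m, [kid]))
    kinds = {(d.locus, d.kind) for d in pf.diagnostics}
    assert ("B", "ambiguous_phase") in kinds
    assert pf.father_haplotypes[0]["B"] is None
    assert pf.father_haplotypes[0]["A"] is not None


def test_homozygous_everywhere_family_not_flagged():
    f = uniform_geno(("X*01:01", "X*01:01"))
    m = uniform_geno(("X*01:01", "X*01:01"))
    kid = uniform_geno(("X*01:01", "X*01:01"))
    pf = phase_family(family("H1", f, m, [kid]))
    assert not pf.diagnostics
    assert pf.father_haplotypes[0]["A"].render() == "A*01:01"


def test_missing_parent_identical_children_ineligible():
    m = uniform_geno(("X*03:01", "X*04:01"))
    kid = uniform_geno(("X*01:01", "X*03:01"))
    pf = phase_family(family("MP1", None, m, [dict(kid), dict(kid)]))
    assert not pf.eligible
    assert extract_founder_pool([pf]).total_count == 0


def test_missing_parent_reconstruction():
    m = uniform_geno(("X*03:01", "X*04:01"))
    kid1 = uniform_geno(("X*01:01", "X*03:01"))
    kid2 = uniform_geno(("X*02:01", "X*04:01"))
    pf = phase_family(family("MP2", None, m, [kid1, kid2]))
    assert pf.eligible
    recon = sorted(h["A"].render() for h in pf.father_haplotypes)
    assert recon == ["A*01:01", "A*02:01"]
    assert extract_founder_pool([pf]).total_count == 4


def test_both_parents_missing_ineligible():
    kid = uniform_geno(("X*01:01", "X*03:01"))
    pf = phase_family(family("MP3", None, None, [kid, kid]))
    assert not pf.eligible


def test_no_genotyped_children_raises():
    from mhcfam import PhasingError

    f = uniform_geno(("X*01:01", "X*02:01"))
    m = uniform_geno(("X*03:01", "X*04:01"))
    empty = {l: None for l in PANEL}
    with pytest.raises(PhasingError):
        phase_family(family("E1", f, m, [empty]))


def test_dropout_repair_infers_hidden_allele():
    """Father truly A*01:01/A*02:01 recorded homozygous; three children reveal
    the hidden allele, which is repaired and flagged."""
    f = uniform_geno(("X*01:01", "X*01:01"))  # recorded hom at every locus
    m = uniform_geno(("X*03:01", "X*04:01"))
    kids = [
        uniform_geno(("X*02:01", "X*03:01")),  # carries hidden X*02:01
        uniform_geno(("X*01:01", "X*04:01")),
        uniform_geno(("X*01:01", "X*03:01")),
    ]
    pf = phase_family(family("D1", f, m, kids))
    assert pf.consistent
    resolved = [d for d in pf.diagnostics if d.kind == "dropout_resolved"]
    assert {d.locus for d in resolved} == set(PANEL)
    assert all("02:01" in d.detail for d in resolved)
    haps = sorted(h["A"].render() for h in pf.father_haplotypes)
    assert haps == ["A*01:01", "A*02:01"]


def test_corrupted_child_allele_flags_exactly_one_family():
    cohort, _ = generate_cohort(SimConfig(n_families=6, seed=21, children_min=3))
    victim = cohort.pedigrees[2]
    child = [m for m in victim.members if not m.is_founder][0]
    g = child.genotypes["B"]
    child.genotypes["B"] = (g[0], parse_allele("B*99:99"))
    phased = phase_cohort(cohort)
    rep = mendel_report(phased)
    bad = rep[rep["kind"].isin(["mendel_error", "recombination_candidate"])]
    assert set(bad["family_id"]) == {victim.family_id}


def test_crossover_produces_recombination_candidates():
    cohort, _ = generate_cohort(
        SimConfig(n_families=12, seed=3, children_min=3, crossover_rate=0.5)
    )
    rep = mendel_report(phase_cohort(cohort))
    assert (rep["kind"] == "recombination_candidate").sum() >= 1


def test_recombinant_family_excluded_from_pool_by_default():
    cohort, _ = generate_cohort(
        SimConfig(n_families=8, seed=13, children_min=3, crossover_rate=0.9)
    )
    phased = phase_cohort(cohort)
    flagged = {p.family_id for p in phased if not p.consistent}
    assert flagged
    pool = extract_founder_pool(phased)
    assert flagged.isdisjoint({h.origin[0] for h in pool})
    kept = extract_founder_pool(phased, keep_recombinants=True)
    assert kept.total_count > pool.total_count


# ---------------------------------------------------------------------------
# pool arithmetic


def test_trio_pool_size_four(informative_trio):
    pool = extract_founder_pool([phase_family(informative_trio)])
    assert pool.total_count == 4
    assert [h.origin[2] for h in pool] == ["a", "b", "c", "d"]


def test_three_generation_pool_decomposition():
    """Grandparents plus marry-ins are founders (4 + 2 x 3 = 10 haplotypes);
    the middle generation contributes nothing."""
    ped, truth = generate_three_generation(SimConfig(seed=8), n_marryins=3)
    phased = phase_pedigree(ped)
    pool = extract_founder_pool(phased)
    assert pool.total_count == 10
    founder_ids = {h.origin[1] for h in pool}
    assert founder_ids == {"GF", "GM", "S1", "S2", "S3"}


# ---------------------------------------------------------------------------
# properties against simulation and the brute-force oracle


def test_soundness_and_oracle_equivalence():
    """For noise-free families the solver's per-locus placements equal the
    brute-force enumeration's, and every unambiguous locus is uniquely
    determined."""
    cohort, _ = generate_cohort(SimConfig(n_families=15, seed=31, children_min=1,
                                          children_max=4))
    for ped in cohort.pedigrees:
        pf = phase_family(ped)
        per_locus, n_ok = brute_force_solutions(ped)
        assert n_ok >= 1
        ambiguous = {d.locus for d in pf.diagnostics if d.kind == "ambiguous_phase"}
        unique_loci = []
        for l in PANEL:
            if len(per_locus[l]) > 1:
                assert l in ambiguous
            else:
                assert l not in ambiguous
                unique_loci.append(l)
        # on unambiguous loci the solver's haplotypes equal the oracle's
        # single placement under one global within-parent flip combination
        impl = {
            l: tuple(
                h[l].key if h[l] else None
                for h in (*pf.father_haplotypes, *pf.mother_haplotypes)
            )
            for l in unique_loci
        }
        flips = [
            lambda p: p,
            lambda p: (p[1], p[0], p[2], p[3]),
            lambda p: (p[0], p[1], p[3], p[2]),
            lambda p: (p[1], p[0], p[3], p[2]),
        ]
        assert any(
            all(flip(impl[l]) in per_locus[l] for l in unique_loci)
            for flip in flips
        )


def test_child_genotypes_reproduced_by_solution():
    """Soundness: transmitted labelled haplotypes reproduce every child
    genotype at every unflagged locus."""
    cohort, _ = generate_cohort(SimConfig(n_families=10, seed=17, children_min=2))
    for ped in cohort.pedigrees:
        pf = phase_family(ped)
        flagged = {d.locus for d in pf.diagnostics}
        for m in ped.members:
            if m.is_founder:
                continue
            labels = pf.transmissions[m.individual_id]
            pat = pf.father_haplotypes[labels[0] - 1]
            mat = pf.mother_haplotypes[labels[1] - 1]
            for l in PANEL:
                if l in flagged:
                    continue
                g = m.genotype_at(l)
                assert sorted([pat[l].key, mat[l].key]) == sorted(
                    [g[0].key, g[1].key]
                )
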