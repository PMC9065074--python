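"""Locus-level population-genetic statistics on the founder haplotype pool.

All statistics operate at two-field allele resolution.  Frequencies are
estimated over founder gene copies; by default the denominator is the number
of copies with a *known* allele at the locus (``denominator="known"``), with
``"total"`` available to divide by the full pool size as printed tables
sometimes do.

Implemented measures:

* allele frequencies and observed/expected heterozygosity,
* PIC, Botstein's polymorphism information content
  ``1 - sum p_i^2 - sum_{i<j} 2 p_i^2 p_j^2``,
* PD, the forensic power of discrimination ``1 - sum G_j^2`` over observed
  genotype frequencies,
* the Guo-Thompson Markov-chain exact test of Hardy-Weinberg equilibrium for
  multi-allelic loci (with a full-enumeration oracle for small tables),
* the Ewens-Watterson homozygosity test of neutrality with Slatkin-style
  conditional sampling (null configurations drawn under the Ewens sampling
  formula conditional on the sample size n and allele count k), reporting the
  normalized deviation of homozygosity Fnd = (F_obs - E[F]) / sqrt(Var[F]);
  negative Fnd suggests balancing and positive directional selection.

Genotype-based statistics (PD, HWE) use founder genotypes only: children are
copies of parental gene copies and would bias the counts.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy.optimize import brentq
from sympy.utilities.iterables import partitions as _int_partitions

from .nomenclature import HLAAllele, PANEL, truncate
from .phasing import HaplotypePool

#: loci excluded from HWE/PIC/PD/EW by default (tight DPA1-DPB1 linkage and
#: incomplete typing make the genotype-level tests uninformative there)
EXCLUDED_LOCI: tuple[str, ...] = ("DPA1", "DPB1")


@dataclass
class FrequencyTable:
    locus: str
    counts: dict[HLAAllele, int]
    n: int  # gene copies in the denominator

    @property
    def freqs(self) -> dict[HLAAllele, float]:
        return {a: c / self.n for a, c in self.counts.items()}

    @property
    def k(self) -> int:
        return len(self.counts)

    def p_vector(self) -> np.ndarray:
        return np.array([c / self.n for c in self.counts.values()], dtype=float)


@dataclass
class EWResult:
    f_obs: float
    e_f: float
    var_f: float
    fnd: float | None
    p_lower: float  # P(F_null <= F_obs): small under balancing selection
    p_upper: float  # P(F_null >= F_obs): small under directional selection
    n: int
    k: int


@dataclass
class LocusStats:
    locus: str
    table: FrequencyTable
    h_obs: float | None
    h_exp: float
    f_obs: float
    pic: float
    pd: float | None
    hwe_p: float | None
    ew: EWResult | None

    @property
    def k(self) -> int:
        return self.table.k


def allele_frequencies(
    pool: HaplotypePool,
    locus: str,
    resolution: int = 2,
    denominator: str = "known",
) -> FrequencyTable:
    """Allele counts/frequencies at a locus over the founder pool.

    Unknown alleles are excluded from the numerator; with
    ``denominator="known"`` (default) also from the denominator.
    """
    if locus not in pool.panel:
        raise KeyError(f"locus {locus!r} not in panel {pool.panel}")
    if denominator not in ("known", "total"):
        raise ValueError("denominator must be 'known' or 'total'")
    counts: Counter = Counter()
    for hap in pool:
        a = hap.alleles.get(locus)
        if a is not None:
            counts[truncate(a, resolution)] += 1
    if not counts:
        raise ValueError(f"no known alleles at locus {locus}")
    n = sum(counts.values()) if denominator == "known" else pool.total_count
    ordered = dict(sorted(counts.items(), key=lambda kv: (-kv[1], kv[0].key)))
    return FrequencyTable(locus=locus, counts=ordered, n=n)


def pic(freqs) -> float:
    """Botstein's polymorphism information content from allele frequencies.

    Accepts a :class:`FrequencyTable`, a mapping allele->frequency, or a
    sequence of frequencies.
    """
    p = _as_p(freqs)
    s2 = float(np.sum(p**2))
    s4 = float(np.sum(p**4))
    # sum_{i<j} 2 p_i^2 p_j^2 == (sum p^2)^2 - sum p^4
    return 1.0 - s2 - (s2 * s2 - s4)


def expected_heterozygosity(freqs, small_sample_n: int | None = None) -> float:
    """``1 - sum p_i^2``, with optional 2N/(2N-1) small-sample factor."""
    p = _as_p(freqs)
    h = 1.0 - float(np.sum(p**2))
    if small_sample_n:
        h *= 2 * small_sample_n / (2 * small_sample_n - 1)
    return h


def _as_p(freqs) -> np.ndarray:
    if isinstance(freqs, FrequencyTable):
        return freqs.p_vector()
    if isinstance(freqs, Mapping):
        return np.array(list(freqs.values()), dtype=float)
    return np.asarray(list(freqs), dtype=float)


# ---------------------------------------------------------------------------
# genotype-level statistics


def founder_genotype_counts(
    cohort, locus: str, resolution: int = 2
) -> dict[tuple, int]:
    """Unordered genotype counts at a locus over genotyped founders."""
    counts: Counter = Counter()
    for ped in cohort.pedigrees:
        for ind in ped.founders():
            g = ind.genotype_at(locus, resolution)
            if g is not None:
                counts[g] += 1
    return dict(counts)


def power_of_discrimination(genotype_counts: Mapping[tuple, int]) -> float:
    """``1 - sum G_j^2`` over observed genotype frequencies."""
    total = sum(genotype_counts.values())
    if total == 0:
        raise ValueError("empty genotype table")
    return 1.0 - sum((c / total) ** 2 for c in genotype_counts.values())


def observed_heterozygosity(genotype_counts: Mapping[tuple, int]) -> float:
    total = sum(genotype_counts.values())
    if total == 0:
        raise ValueError("empty genotype table")
    het = sum(c for (a, b), c in genotype_counts.items() if a != b)
    return het / total


# ---------------------------------------------------------------------------
# Guo-Thompson exact HWE test


def _table_from_counts(genotype_counts: Mapping[tuple, int]):
    alleles = sorted({a for pair in genotype_counts for a in pair})
    index = {a: i for i, a in enumerate(alleles)}
    k = len(alleles)
    mat = np.zeros((k, k), dtype=int)  # lower triangle i >= j
    for (a, b), c in genotype_counts.items():
        i, j = sorted((index[a], index[b]), reverse=True)
        mat[i, j] += c
    return mat, alleles


def _log_table_stat(mat: np.ndarray) -> float:
    """Log of the HWE conditional probability of a genotype table, up to the
    constant shared by all tables with the same allele counts:
    ``h * log 2 - sum log f_ij!`` with h the number of heterozygotes."""
    k = mat.shape[0]
    h = int(mat.sum() - np.trace(mat))
    s = h * math.log(2.0)
    for i in range(k):
        for j in range(i + 1):
            s -= math.lgamma(mat[i, j] + 1.0)
    return s


def hwe_guo_thompson(
    genotype_counts: Mapping[tuple, int],
    n_steps: int = 20000,
    burn_in: int = 0,
    seed: int = 0,
) -> float:
    """Guo-Thompson exact test of Hardy-Weinberg equilibrium, Monte Carlo.

    Conditional on the allele counts, HWE makes the genotype table distributed
    exactly as a uniformly random pairing of the ``2n`` gene copies, so null
    tables are drawn i.i.d. by shuffling the gene copies and pairing them
    (no Markov-chain burn-in is needed; ``burn_in`` is accepted for interface
    compatibility and ignored).  The p-value is the fraction of sampled
    tables, the observed one included, whose conditional probability is at
    most that of the observed table.  NaN for a monomorphic locus.
    """
    mat, alleles = _table_from_counts(genotype_counts)
    k = len(alleles)
    if k < 2:
        return float("nan")
    n = int(mat.sum())
    if n < 2:
        return float("nan")
    margins = np.zeros(k, dtype=int)
    for i in range(k):
        for j in range(i + 1):
            margins[i] += mat[i, j] * (2 if i == j else 1)
            if i != j:
                margins[j] += mat[i, j]
    log_obs = _log_table_stat(mat)
    rng = np.random.default_rng(seed)
    copies = np.repeat(np.arange(k), margins)
    lg = np.array([math.lgamma(c + 1.0) for c in range(n + 1)])
    log2 = math.log(2.0)
    hits = 0
    for _ in range(n_steps):
        rng.shuffle(copies)
        a = copies[0::2]
        b = copies[1::2]
        hi = np.maximum(a, b)
        lo = np.minimum(a, b)
        codes = hi * k + lo
        _, f = np.unique(codes, return_counts=True)
        h = int((hi != lo).sum())
        stat = h * log2 - float(lg[f].sum())
        if stat <= log_obs + 1e-12:
            hits += 1
    return (hits + 1) / (n_steps + 1)


def _enumerate_tables(margins: np.ndarray):
    """All symmetric genotype tables with the given allele-count margins."""
    k = len(margins)
    cells = [(i, j) for i in range(k) for j in range(i + 1)]

    def rec(idx: int, remaining: np.ndarray, mat: np.ndarray):
        if idx == len(cells):
            if not remaining.any():
                yield mat.copy()
            return
        i, j = cells[idx]
        if i == j:
            # homozygote cell consumes two copies of allele i
            max_c = int(remaining[i] // 2)
        else:
            max_c = int(min(remaining[i], remaining[j]))
        for c in range(max_c + 1):
            mat[i, j] = c
            rem = remaining.copy()
            rem[i] -= c * (2 if i == j else 1)
            if i != j:
                rem[j] -= c
            if (rem >= 0).all():
                yield from rec(idx + 1, rem, mat)
        mat[i, j] = 0

    yield from rec(0, margins.copy(), np.zeros((k, k), dtype=int))


def hwe_exact_enumeration(genotype_counts: Mapping[tuple, int]) -> float:
    """Exact HWE p-value by full enumeration of genotype tables.

    Only feasible for small tables (<= 4 alleles and a few tens of
    individuals); used as the independence oracle for the Markov-chain test.
    """
    mat, alleles = _table_from_counts(genotype_counts)
    if len(alleles) < 2:
        return float("nan")
    k = len(alleles)
    margins = np.zeros(k, dtype=int)
    for i in range(k):
        for j in range(i + 1):
            margins[i] += mat[i, j] * (2 if i == j else 1)
            if i != j:
                margins[j] += mat[i, j]
    log_obs = _log_table_stat(mat)
    logs = np.array([_log_table_stat(t) for t in _enumerate_tables(margins)])
    w = np.exp(logs - logs.max())
    w /= w.sum()
    return float(w[logs <= log_obs + 1e-12].sum())


# ---------------------------------------------------------------------------
# Ewens-Watterson homozygosity test of neutrality


def _ewens_theta_hat(n: int, k: int) -> float:
    """theta with E[number of alleles] = k for sample size n."""
    if k <= 1:
        return 1e-9
    if k >= n:
        return 1e9

    def mean_k(theta: float) -> float:
        i = np.arange(n, dtype=float)
        return float(np.sum(theta / (theta + i)))

    return float(brentq(lambda t: mean_k(t) - k, 1e-9, 1e6))


def sample_ewens_configs(
    n: int, k: int, reps: int, rng: np.random.Generator, max_batches: int = 400
) -> list[np.ndarray]:
    """Allele-count configurations under the Ewens sampling formula
    conditional on (n, k), by rejection from the Chinese restaurant process.

    Conditional on the number of alleles k the configuration law is free of
    theta, so any theta gives exact conditional draws; theta is tuned so
    E[k] = k for acceptance efficiency.
    """
    if not 1 <= k <= n:
        raise ValueError(f"need 1 <= k <= n, got n={n}, k={k}")
    theta = _ewens_theta_hat(n, k)
    out: list[np.ndarray] = []
    batch = max(64, reps)
    for _ in range(max_batches):
        if len(out) >= reps:
            break
        # vectorized CRP over `batch` parallel runs
        assign = np.zeros((batch, n), dtype=np.int32)
        n_tables = np.ones(batch, dtype=np.int32)
        for i in range(1, n):
            new = rng.random(batch) < theta / (theta + i)
            join_src = rng.integers(0, i, size=batch)
            assign[:, i] = np.where(new, n_tables, assign[np.arange(batch), join_src])
            n_tables += new.astype(np.int32)
        for r in np.nonzero(n_tables == k)[0]:
            counts = np.bincount(assign[r], minlength=k)
            out.append(np.sort(counts)[::-1])
            if len(out) >= reps:
                break
    if len(out) < reps:
        raise RuntimeError(
            f"conditional sampler accepted only {len(out)}/{reps} draws for "
            f"(n={n}, k={k})"
        )
    return out[:reps]


def ewens_watterson(
    n: int,
    k: int,
    f_obs: float,
    reps: int = 5000,
    seed: int = 0,
) -> EWResult:
    """Ewens-Watterson homozygosity test of neutrality.

    ``f_obs`` is the observed homozygosity statistic ``sum p_i^2``.  The null
    distribution of F is sampled conditional on (n, k); Fnd is the deviation
    of F_obs from its null mean in null standard-deviation units.
    """
    if k > n:
        raise ValueError(f"k={k} exceeds n={n}")
    if k == 1:
        return EWResult(1.0, 1.0, 0.0, None, 1.0, 1.0, n, k)
    if k == n:
        # single configuration (all singletons): the test is degenerate
        f = 1.0 / n
        return EWResult(f_obs, f, 0.0, None, 1.0, 1.0, n, k)
    rng = np.random.default_rng(seed)
    configs = sample_ewens_configs(n, k, reps, rng)
    f_null = np.array([float(np.sum((c / n) ** 2)) for c in configs])
    e_f = float(f_null.mean())
    var_f = float(f_null.var(ddof=1))
    fnd = (f_obs - e_f) / math.sqrt(var_f) if var_f > 0 else None
    p_lower = float(np.mean(f_null <= f_obs + 1e-12))
    p_upper = float(np.mean(f_null >= f_obs - 1e-12))
    return EWResult(f_obs, e_f, var_f, fnd, p_lower, p_upper, n, k)


def ewens_watterson_exact(n: int, k: int):
    """Exact null distribution of the allele configuration given (n, k).

    Enumerates integer partitions of n into k parts; each configuration has
    probability proportional to ``n! / prod_j (j^{a_j} a_j!)`` with ``a_j``
    the number of alleles carried by exactly j copies.  Returns
    ``(configs, probs, E_F, Var_F)``.  Feasible for small n only; serves as
    the oracle for the conditional sampler.
    """
    if not 1 <= k <= n:
        raise ValueError(f"need 1 <= k <= n, got n={n}, k={k}")
    configs = []
    weights = []
    for part in _int_partitions(n):
        if sum(part.values()) != k:
            continue
        logw = math.lgamma(n + 1)
        for j, a_j in part.items():
            logw -= a_j * math.log(j) + math.lgamma(a_j + 1)
        counts = np.array(
            sorted(
                [j for j, a_j in part.items() for _ in range(a_j)], reverse=True
            )
        )
        configs.append(counts)
        weights.append(logw)
    w = np.exp(np.array(weights) - max(weights))
    probs = w / w.sum()
    f_vals = np.array([float(np.sum((c / n) ** 2)) for c in configs])
    e_f = float(np.sum(probs * f_vals))
    var_f = float(np.sum(probs * (f_vals - e_f) ** 2))
    return configs, probs, e_f, var_f


# ---------------------------------------------------------------------------
# assembled per-locus report


def locus_stats(
    pool: HaplotypePool,
    cohort,
    locus: str,
    resolution: int = 2,
    denominator: str = "known",
    hwe_steps: int = 20000,
    ew_reps: int = 5000,
    seed: int = 0,
) -> LocusStats:
    """All locus-level statistics for one locus; DPA1/DPB1 get frequency and
    diversity numbers but no HWE/PD/EW (excluded by convention)."""
    table = allele_frequencies(pool, locus, resolution, denominator)
    f_obs = float(np.sum(table.p_vector() ** 2))
    excluded = locus in EXCLUDED_LOCI
    h_obs = pd_val = hwe_p = None
    ew = None
    if cohort is not None and not excluded:
        gcounts = founder_genotype_counts(cohort, locus, resolution)
        if gcounts:
            h_obs = observed_heterozygosity(gcounts)
            pd_val = power_of_discrimination(gcounts)
            hwe_p = hwe_guo_thompson(gcounts, n_steps=hwe_steps, seed=seed)
    if not excluded and table.k >= 2:
        ew = ewens_watterson(
            n=sum(table.counts.values()), k=table.k, f_obs=f_obs,
            reps=ew_reps, seed=seed,
        )
    return LocusStats(
        locus=locus,
        table=table,
        h_obs=h_obs,
        h_exp=expected_heterozygosity(table),
        f_obs=f_obs,
        pic=pic(table),
        pd=pd_val,
        hwe_p=hwe_p,
        ew=ew,
    )
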