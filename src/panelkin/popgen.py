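"""Per-locus and per-population statistics.

Covers the population-genetic characterization used both for marker
selection and for describing genotyped collections: allele frequencies and
heterozygosities, Weir & Cockerham (1984) F_ST (per locus and multilocus
with a bootstrap CI), an exact Hardy–Weinberg proportions test, private
alleles, the Ritland (1996) moment estimator of pairwise relatedness with
first-degree purging, and a PCA on genotype dosages.

All estimators assume biallelic SNPs coded as alternate-allele dosage.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.special import gammaln

from .exceptions import UsageError
from .genotype_io import GenotypeMatrix, HET, HOMALT, HOMREF, MISSING


@dataclass
class LocusStats:
    """Summary statistics for one biallelic locus."""

    locus_id: str
    n_typed: int
    p_alt: float  # alternate-allele frequency
    maf: float  # min(p_alt, 1 - p_alt)
    h_obs: float  # observed heterozygote proportion
    h_exp: float  # 2 p (1 - p), no small-sample correction
    fst: float = float("nan")  # multi-population Weir-Cockerham theta
    hwp_pvalue: dict[str, float] = field(default_factory=dict)  # per population

    @property
    def defined(self) -> bool:
        return self.n_typed > 0


@dataclass
class RelatednessPair:
    """Pairwise Ritland relatedness estimate (symmetric in the two samples;
    negative values are a normal property of the moment estimator)."""

    sample_a: str
    sample_b: str
    r: float
    n_loci_used: int


# ---------------------------------------------------------------------------
# Allele frequencies & heterozygosity
# ---------------------------------------------------------------------------

def _locus_stats_from_calls(locus_id: str, col: np.ndarray) -> LocusStats:
    typed = col != MISSING
    n = int(typed.sum())
    if n == 0:
        nan = float("nan")
        return LocusStats(locus_id, 0, nan, nan, nan, nan)
    n_het = int((col == HET).sum())
    n_alt_hom = int((col == HOMALT).sum())
    p = (2 * n_alt_hom + n_het) / (2 * n)
    return LocusStats(
        locus_id,
        n,
        p,
        min(p, 1 - p),
        n_het / n,
        2 * p * (1 - p),
    )


def allele_freq_stats(
    matrix: GenotypeMatrix, by_population: bool = False
) -> list[LocusStats] | dict[str, list[LocusStats]]:
    """Per-locus allele frequency, MAF and heterozygosity.

    ``p_alt = (2 n_HOMALT + n_HET) / (2 n_typed)``; ``h_obs = n_HET /
    n_typed``; ``h_exp = 2 p (1 - p)``.  Loci with zero typed calls carry
    NaN statistics and ``defined == False``.  With ``by_population`` the
    same statistics are computed within each collection.
    """
    if not by_population:
        return [
            _locus_stats_from_calls(l, matrix.calls[:, j])
            for j, l in enumerate(matrix.locus_ids)
        ]
    out: dict[str, list[LocusStats]] = {}
    for pop, members in matrix.populations().items():
        sub = matrix.subset(samples=members)
        out[pop] = [
            _locus_stats_from_calls(l, sub.calls[:, j])
            for j, l in enumerate(sub.locus_ids)
        ]
    return out


def allele_frequencies(matrix: GenotypeMatrix) -> dict[str, float]:
    """Locus id -> alternate-allele frequency (NaN when untyped)."""
    return {s.locus_id: s.p_alt for s in allele_freq_stats(matrix)}


def filter_maf(stats: list[LocusStats], min_maf: float = 0.01) -> set[str]:
    """Loci passing the minor-allele-frequency floor (keep ``maf >= min_maf``)."""
    return {s.locus_id for s in stats if s.defined and s.maf >= min_maf}


# ---------------------------------------------------------------------------
# Weir & Cockerham (1984) F_ST
# ---------------------------------------------------------------------------

def _wc84_components(
    n: np.ndarray, p: np.ndarray, h: np.ndarray
) -> tuple[float, float, float]:
    """Variance components (a, b, c) for one biallelic locus.

    ``n``: diploid sample sizes per population; ``p``: alternate-allele
    frequencies; ``h``: observed heterozygote proportions.  theta = a /
    (a + b + c).  Requires >= 2 populations with n >= 2.
    """
    r = len(n)
    nbar = n.mean()
    nc = (r * nbar - (n**2).sum() / (r * nbar)) / (r - 1)
    pbar = (n * p).sum() / (r * nbar)
    s2 = (n * (p - pbar) ** 2).sum() / ((r - 1) * nbar)
    hbar = (n * h).sum() / (r * nbar)
    a = (nbar / nc) * (
        s2 - (pbar * (1 - pbar) - (r - 1) / r * s2 - hbar / 4) / (nbar - 1)
    )
    b = (nbar / (nbar - 1)) * (
        pbar * (1 - pbar) - (r - 1) / r * s2 - (2 * nbar - 1) / (4 * nbar) * hbar
    )
    c = hbar / 2
    return float(a), float(b), float(c)


def _pop_counts(matrix: GenotypeMatrix, pops: dict[str, list[str]]):
    """Per-population (n_typed, p_alt, h_obs) arrays, shape (n_pops, n_loci)."""
    ns, ps, hs = [], [], []
    for members in pops.values():
        sub = matrix.subset(samples=members).calls
        typed = sub != MISSING
        n = typed.sum(axis=0)
        with np.errstate(divide="ignore", invalid="ignore"):
            p = (2 * (sub == HOMALT).sum(axis=0) + (sub == HET).sum(axis=0)) / (2 * n)
            h = (sub == HET).sum(axis=0) / n
        ns.append(n)
        ps.append(p)
        hs.append(h)
    return np.array(ns, dtype=float), np.array(ps), np.array(hs)


def _locus_components(
    n: np.ndarray, p: np.ndarray, h: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Per-locus (a, a+b+c); NaN where fewer than two populations have
    two or more typed individuals."""
    n_loci = n.shape[1]
    a_arr = np.full(n_loci, np.nan)
    abc_arr = np.full(n_loci, np.nan)
    for j in range(n_loci):
        ok = n[:, j] >= 2
        if ok.sum() < 2:
            continue
        a, b, c = _wc84_components(n[ok, j], p[ok, j], h[ok, j])
        a_arr[j] = a
        abc_arr[j] = a + b + c
    return a_arr, abc_arr


def per_locus_fst(
    matrix: GenotypeMatrix, populations: dict[str, list[str]] | None = None
) -> dict[str, float]:
    """Weir–Cockerham theta per locus over the given populations.

    Loci where fewer than two populations have >= 2 typed individuals, or
    where the total variance (a+b+c) is zero (no variation), are NaN.
    """
    pops = populations if populations is not None else matrix.populations()
    if len(pops) < 2:
        raise UsageError("per-locus F_ST requires at least two populations")
    n, p, h = _pop_counts(matrix, pops)
    a_arr, abc_arr = _locus_components(n, p, h)
    out: dict[str, float] = {}
    for j, locus in enumerate(matrix.locus_ids):
        if np.isnan(abc_arr[j]) or abc_arr[j] == 0:
            out[locus] = float("nan")
        else:
            out[locus] = float(a_arr[j] / abc_arr[j])
    return out


def pairwise_pop_fst_ci(
    matrix: GenotypeMatrix,
    populations: dict[str, list[str]] | None = None,
    min_n: int = 15,
    n_boot: int = 1000,
    seed: int | None = None,
) -> list[dict]:
    """Multilocus pairwise F_ST with a 95% bootstrap CI.

    Populations with ``min_n`` or fewer individuals are excluded.  The
    multilocus estimate is the ratio of averages: sum of the ``a``
    component over loci divided by the sum of ``a + b + c``.  The CI is a
    percentile bootstrap over loci (``n_boot`` resamples, seeded).
    """
    pops = populations if populations is not None else matrix.populations()
    qualifying = {k: v for k, v in pops.items() if len(v) > min_n}
    if len(qualifying) < 2:
        raise UsageError(
            f"need >= 2 populations with more than {min_n} individuals; "
            f"have {len(qualifying)}"
        )
    rng = np.random.default_rng(seed)
    results = []
    for pa, pb in itertools.combinations(sorted(qualifying), 2):
        n, p, h = _pop_counts(matrix, {pa: qualifying[pa], pb: qualifying[pb]})
        a_arr, abc_arr = _locus_components(n, p, h)
        ok = ~np.isnan(abc_arr)
        a_ok, abc_ok = a_arr[ok], abc_arr[ok]
        if abc_ok.sum() == 0:
            results.append(
                {"pop_a": pa, "pop_b": pb, "fst": float("nan"),
                 "ci_low": float("nan"), "ci_high": float("nan"),
                 "n_loci": int(ok.sum())}
            )
            continue
        fst = float(a_ok.sum() / abc_ok.sum())
        L = len(a_ok)
        idx = rng.integers(0, L, size=(n_boot, L))
        num = a_ok[idx].sum(axis=1)
        den = abc_ok[idx].sum(axis=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            boot = num / den
        boot = boot[np.isfinite(boot)]
        lo, hi = np.percentile(boot, [2.5, 97.5])
        results.append(
            {"pop_a": pa, "pop_b": pb, "fst": fst,
             "ci_low": float(lo), "ci_high": float(hi), "n_loci": L}
        )
    return results


# ---------------------------------------------------------------------------
# Hardy-Weinberg proportions (exact test)
# ---------------------------------------------------------------------------

def hwe_exact_pvalue(n_homref: int, n_het: int, n_homalt: int) -> float:
    """Exact two-sided HWP test for a biallelic locus.

    Full enumeration over all heterozygote counts compatible with the
    observed allele counts; the p-value is the total probability of
    configurations no more likely than the observed one.  Monomorphic
    samples return 1 by convention.
    """
    n = n_homref + n_het + n_homalt
    n_a = 2 * n_homalt + n_het  # alt allele copies
    n_b = 2 * n - n_a
    if n == 0 or n_a == 0 or n_b == 0:
        return 1.0
    rare = min(n_a, n_b)

    def logprob(h: int) -> float:
        hom_rare = (rare - h) // 2
        hom_common = n - h - hom_rare
        return (
            gammaln(n + 1)
            - gammaln(hom_rare + 1)
            - gammaln(h + 1)
            - gammaln(hom_common + 1)
            + h * np.log(2)
            + gammaln(n_a + 1)
            + gammaln(n_b + 1)
            - gammaln(2 * n + 1)
        )

    h_obs = n_het
    hs = np.arange(rare % 2, rare + 1, 2)
    logps = np.array([logprob(int(h)) for h in hs])
    probs = np.exp(logps - logps.max())
    probs /= probs.sum()
    p_obs = probs[np.where(hs == h_obs)[0][0]]
    return float(min(1.0, probs[probs <= p_obs * (1 + 1e-12)].sum()))


def hwp_test(
    matrix: GenotypeMatrix,
    populations: dict[str, list[str]] | None = None,
    alpha: float = 0.05,
) -> tuple[dict[tuple[str, str], float], set[tuple[str, str]]]:
    """Exact HWP p-value per (locus, population), plus flagged deviations.

    Flagged (p < ``alpha``) loci are reported, never removed — deviation
    from HWP in these panels often reflects null alleles or family
    structure worth inspecting rather than discarding outright.
    """
    pops = populations if populations is not None else matrix.populations()
    pvalues: dict[tuple[str, str], float] = {}
    flags: set[tuple[str, str]] = set()
    for pop, members in pops.items():
        sub = matrix.subset(samples=members).calls
        for j, locus in enumerate(matrix.locus_ids):
            col = sub[:, j]
            p = hwe_exact_pvalue(
                int((col == HOMREF).sum()),
                int((col == HET).sum()),
                int((col == HOMALT).sum()),
            )
            pvalues[(locus, pop)] = p
            if p < alpha:
                flags.add((locus, pop))
    return pvalues, flags


# ---------------------------------------------------------------------------
# Private alleles
# ---------------------------------------------------------------------------

def private_alleles(
    matrix: GenotypeMatrix, groupings: dict[str, str]
) -> list[tuple[str, str, str, int]]:
    """Alleles observed in exactly one genetic grouping.

    ``groupings`` maps sample id -> group label (a partition of the
    samples, possibly pooling collections).  Returns
    ``(locus_id, allele, group, n_copies)`` tuples where ``allele`` is
    ``"ref"`` or ``"alt"`` and ``n_copies`` counts allele copies within
    the private group.
    """
    groups = sorted(set(groupings.values()))
    out: list[tuple[str, str, str, int]] = []
    counts = {}  # group -> (ref_copies, alt_copies) arrays
    for g in groups:
        members = [s for s in matrix.sample_ids if groupings.get(s) == g]
        sub = matrix.subset(samples=members).calls
        alt = 2 * (sub == HOMALT).sum(axis=0) + (sub == HET).sum(axis=0)
        ref = 2 * (sub == HOMREF).sum(axis=0) + (sub == HET).sum(axis=0)
        counts[g] = (ref, alt)
    for j, locus in enumerate(matrix.locus_ids):
        for allele, k in (("ref", 0), ("alt", 1)):
            present = [g for g in groups if counts[g][k][j] >= 1]
            if len(present) == 1:
                g = present[0]
                out.append((locus, allele, g, int(counts[g][k][j])))
    return out


# ---------------------------------------------------------------------------
# Ritland relatedness
# ---------------------------------------------------------------------------

def ritland_relatedness(
    matrix: GenotypeMatrix, freqs: dict[str, float] | None = None
) -> list[RelatednessPair]:
    """Pairwise relatedness via the Ritland (1996) moment estimator.

    Per locus l with alleles a at reference frequencies ``p_a``:

        r_l = 2 [ sum_a (S_xa S_ya / p_a) - 1 ] / (A_l - 1)

    where ``S_xa`` is half the count of allele a in individual x's genotype
    and ``A_l`` the number of alleles (2 here).  The multilocus estimate
    averages r_l with weights ``A_l - 1`` (uniform for SNPs) over loci
    typed in both individuals.  Loci monomorphic in the frequency table
    are skipped.  Pairs sharing zero usable loci get ``r = NaN``.
    """
    if freqs is None:
        freqs = allele_frequencies(matrix)
    p = np.array([freqs.get(l, np.nan) for l in matrix.locus_ids])
    usable = np.isfinite(p) & (p > 0) & (p < 1)

    calls = matrix.calls[:, usable].astype(float)
    p = p[usable]
    q = 1 - p
    typed = calls != MISSING
    s_alt = np.where(typed, calls / 2.0, 0.0)  # S for the alt allele
    s_ref = np.where(typed, 1 - calls / 2.0, 0.0)
    mask = typed.astype(float)

    # sum over loci of S_x S_y / p decomposes into matrix products
    term = (s_ref / np.sqrt(q)) @ (s_ref / np.sqrt(q)).T
    term += (s_alt / np.sqrt(p)) @ (s_alt / np.sqrt(p)).T
    shared = mask @ mask.T

    out: list[RelatednessPair] = []
    ids = matrix.sample_ids
    for i in range(len(ids)):
        for j in range(i + 1, len(ids)):
            n_sh = int(round(shared[i, j]))
            if n_sh == 0:
                out.append(RelatednessPair(ids[i], ids[j], float("nan"), 0))
                continue
            r = 2.0 * (term[i, j] - n_sh) / n_sh
            out.append(RelatednessPair(ids[i], ids[j], float(r), n_sh))
    return out


def purge_first_degree(
    pairs: list[RelatednessPair],
    threshold: float = 0.26,
    population_of: dict[str, str] | None = None,
    genotyping_rate: dict[str, float] | None = None,
    samples: list[str] | None = None,
) -> set[str]:
    """Iteratively remove individuals until no within-population pair
    exceeds the relatedness threshold.

    At each step the individual participating in the most above-threshold
    pairs is removed (ties: lower genotyping rate, then lexicographically
    first id).  When ``population_of`` is given, only same-population
    pairs count.  Returns the retained sample set.
    """
    if samples is None:
        samples = sorted({s for pr in pairs for s in (pr.sample_a, pr.sample_b)})
    retained = set(samples)

    def same_pop(pr: RelatednessPair) -> bool:
        if population_of is None:
            return True
        return population_of.get(pr.sample_a) == population_of.get(pr.sample_b)

    active = [
        pr for pr in pairs
        if np.isfinite(pr.r) and pr.r > threshold and same_pop(pr)
    ]
    while True:
        live = [
            pr for pr in active if pr.sample_a in retained and pr.sample_b in retained
        ]
        if not live:
            break
        degree: dict[str, int] = {}
        for pr in live:
            degree[pr.sample_a] = degree.get(pr.sample_a, 0) + 1
            degree[pr.sample_b] = degree.get(pr.sample_b, 0) + 1
        gr = genotyping_rate or {}
        victim = sorted(
            degree, key=lambda s: (-degree[s], gr.get(s, 0.0), s)
        )[0]
        retained.discard(victim)
    return retained


# ---------------------------------------------------------------------------
# PCA on dosages
# ---------------------------------------------------------------------------

@dataclass
class PCAResult:
    sample_ids: list[str]
    scores: np.ndarray  # (n_samples, k)
    explained_var_frac: np.ndarray  # (k,)
    loadings: np.ndarray  # (n_loci, k)


def pca_dosage(matrix: GenotypeMatrix, n_components: int = 4) -> PCAResult:
    """PCA on the alternate-allele dosage matrix.

    Missing calls are imputed to the locus mean dosage, columns centred,
    and the decomposition done by SVD.  Each component is oriented so its
    largest-magnitude loading is positive, making score signs reproducible.
    """
    if matrix.n_samples < 5 or matrix.n_loci < 2:
        raise UsageError("PCA requires >= 5 samples and >= 2 loci")
    X = matrix.calls.astype(float)
    X[X == MISSING] = np.nan
    col_mean = np.nanmean(X, axis=0)
    col_mean = np.where(np.isnan(col_mean), 0.0, col_mean)
    inds = np.where(np.isnan(X))
    X[inds] = col_mean[inds[1]]
    X -= X.mean(axis=0)

    U, S, Vt = np.linalg.svd(X, full_matrices=False)
    k_avail = int((S > 1e-12).sum())
    k = min(n_components, k_avail)
    if k < n_components:
        warnings.warn(
            f"only {k} non-degenerate components available "
            f"(requested {n_components})",
            stacklevel=2,
        )
    # orient: largest-|loading| positive
    for c in range(k):
        piv = np.argmax(np.abs(Vt[c]))
        if Vt[c, piv] < 0:
            Vt[c] *= -1
            U[:, c] *= -1
    scores = U[:, :k] * S[:k]
    total_var = (S**2).sum()
    return PCAResult(
        sample_ids=list(matrix.sample_ids),
        scores=scores,
        explained_var_frac=(S[:k] ** 2) / total_var,
        loadings=Vt[:k].T,
    )
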