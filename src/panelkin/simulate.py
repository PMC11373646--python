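"""Synthetic multi-population SNP data and pedigrees with known truth.

The generator emulates the data an amplicon panel produces when applied
to structured populations and breeding-program crosses, so every
downstream module can be tested end to end without external downloads:

* ancestral allele frequencies from a stated distribution, with
  per-population frequencies drawn under the Balding–Nichols model
  (Beta(p(1-F)/F, (1-p)(1-F)/F) around ancestral p with drift F);
* founders drawn in Hardy–Weinberg proportions from their population's
  frequencies, tracked as haplotypes (allele pairs) so inheritance is
  exact;
* full-sib families: each offspring receives one uniformly chosen allele
  per parent per locus, independently across loci (no linkage);
* hidden null alleles at a chosen fraction of loci: a non-amplifying
  allele at frequency ``null_allele_freq`` is planted on founder
  haplotypes and inherited; a heterozygous carrier is observed as a
  spurious homozygote of its visible allele, and a null homozygote fails
  entirely (MISSING) — the standard null-allele phenomenology, and the
  mechanism that produces Mendelian incompatibilities in trios;
* per-genotype miscalls (symmetric, rate epsilon), random missingness,
  and technical replicates re-observed independently from the same true
  genotypes.

All randomness flows from the single spec seed through named substreams,
so an identical spec yields an identical bundle.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .exceptions import UsageError
from .genotype_io import GenotypeMatrix, MISSING

# haplotype allele codes
_REF, _ALT, _NULL = 0, 1, 2


@dataclass
class SimulationSpec:
    """Parameters of one synthetic dataset.

    ``freq_dist`` is ``("uniform", lo, hi)`` or ``("beta", a, b)`` for the
    ancestral alternate-allele frequency.  ``populations`` lists
    ``(name, n_founders, drift_F)``; ``families`` lists
    ``(dam_id, sire_id, n_offspring)`` where parents are founder ids.
    """

    n_loci: int
    populations: list[tuple[str, int, float]]
    seed: int
    freq_dist: tuple = ("uniform", 0.1, 0.5)
    families: list[tuple[str, str, int]] = field(default_factory=list)
    null_loci_fraction: float = 0.0
    null_allele_freq: float = 0.25
    epsilon: float = 0.0
    missing_rate: float = 0.0
    replicate_fraction: float = 0.0

    def __post_init__(self) -> None:
        for name, value in (
            ("null_loci_fraction", self.null_loci_fraction),
            ("null_allele_freq", self.null_allele_freq),
            ("epsilon", self.epsilon),
            ("missing_rate", self.missing_rate),
            ("replicate_fraction", self.replicate_fraction),
        ):
            if not 0.0 <= value <= 1.0:
                raise UsageError(f"{name} must be in [0, 1], got {value}")
        if self.seed is None:
            raise UsageError("a seed is mandatory")
        if self.n_loci < 1:
            raise UsageError("n_loci must be >= 1")
        for _, _, F in self.populations:
            if not 0.0 <= F < 1.0:
                raise UsageError(f"drift F must be in [0, 1), got {F}")


@dataclass
class TruthBundle:
    """A simulated dataset plus everything needed to score results.

    ``matrix`` holds the observed calls (after null masking, error and
    missingness); ``true_calls`` the pre-error, pre-null genotype codes
    (alternate-allele dosage of the underlying alleles, nulls excluded
    from the count may leave a one-allele genotype — coded by the visible
    allele); ``visible_truth`` the codes after null masking but before
    error/missingness (what a perfect assay of amplifiable alleles gives).
    """

    spec: SimulationSpec
    matrix: GenotypeMatrix
    true_calls: np.ndarray
    visible_truth: np.ndarray
    pedigree: dict[str, tuple[str, str]]
    null_loci: set[str]
    replicate_groups: dict[str, list[str]]
    population_of: dict[str, str]
    ancestral_freqs: np.ndarray
    population_freqs: dict[str, np.ndarray]


# ---------------------------------------------------------------------------
# Component operations
# ---------------------------------------------------------------------------

def simulate_base_frequencies(
    spec: SimulationSpec, rng: np.random.Generator | None = None
) -> tuple[np.ndarray, dict[str, np.ndarray]]:
    """Ancestral frequencies plus per-population Balding–Nichols draws.

    With drift ``F = 0`` the population frequencies equal the ancestral
    ones exactly (the Beta degenerates to a point mass).
    """
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    kind, *params = spec.freq_dist
    if kind == "uniform":
        lo, hi = params
        anc = rng.uniform(lo, hi, size=spec.n_loci)
    elif kind == "beta":
        a, b = params
        anc = rng.beta(a, b, size=spec.n_loci)
    else:
        raise UsageError(f"unknown frequency distribution {kind!r}")
    pop_freqs: dict[str, np.ndarray] = {}
    for name, _, F in spec.populations:
        if F == 0.0:
            pop_freqs[name] = anc.copy()
        else:
            scale = (1.0 - F) / F
            pop_freqs[name] = rng.beta(anc * scale, (1.0 - anc) * scale)
    return anc, pop_freqs


def draw_founder_haplotypes(
    pop_freqs: np.ndarray, n: int, rng: np.random.Generator
) -> np.ndarray:
    """HWE founders: allele pairs drawn independently, shape (n, L, 2)."""
    return (
        rng.random((n, len(pop_freqs), 2)) < pop_freqs[None, :, None]
    ).astype(np.int8)


def apply_null_alleles(
    haplotypes: np.ndarray,
    null_locus_idx: np.ndarray,
    null_freq: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Overwrite founder haplotype alleles with the null allele.

    At each null locus every founder haplotype independently becomes null
    with probability ``null_freq``, regardless of its visible allele; the
    null is then inherited like any other allele.
    """
    out = haplotypes.copy()
    if len(null_locus_idx) == 0 or null_freq == 0.0:
        return out
    sub = out[:, null_locus_idx, :]
    mask = rng.random(sub.shape) < null_freq
    sub[mask] = _NULL
    out[:, null_locus_idx, :] = sub
    return out


def simulate_families(
    founder_haplotypes: dict[str, np.ndarray],
    families: list[tuple[str, str, int]],
    rng: np.random.Generator,
) -> tuple[dict[str, np.ndarray], dict[str, tuple[str, str]]]:
    """Mendelian inheritance: one uniformly chosen allele per parent per
    locus, independent across loci.  Offspring are named
    ``F<k>_<i>`` after their family index.  Returns (offspring
    haplotypes, pedigree)."""
    offspring: dict[str, np.ndarray] = {}
    pedigree: dict[str, tuple[str, str]] = {}
    for k, (dam, sire, n_off) in enumerate(families, start=1):
        for parent in (dam, sire):
            if parent not in founder_haplotypes:
                raise UsageError(f"family parent {parent!r} is not a founder")
        dam_h = founder_haplotypes[dam]
        sire_h = founder_haplotypes[sire]
        n_loci = dam_h.shape[0]
        for i in range(1, n_off + 1):
            pick_d = rng.integers(0, 2, size=n_loci)
            pick_s = rng.integers(0, 2, size=n_loci)
            child = np.stack(
                [dam_h[np.arange(n_loci), pick_d], sire_h[np.arange(n_loci), pick_s]],
                axis=1,
            )
            name = f"F{k}_{i}"
            offspring[name] = child
            pedigree[name] = (dam, sire)
    return offspring, pedigree


def haplotypes_to_codes(haps: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Collapse allele pairs to genotype codes.

    Returns ``(true, visible)``: ``true`` counts alternate alleles among
    non-null alleles (a single-null genotype is coded by its visible
    allele); ``visible`` applies null masking — one null looks like a
    homozygote of the visible allele (identical to ``true`` here), two
    nulls are MISSING.
    """
    n_null = (haps == _NULL).sum(axis=-1)
    n_alt = (haps == _ALT).sum(axis=-1)
    visible = np.where(n_null == 2, MISSING, np.where(n_null == 1, 2 * n_alt, n_alt))
    true = np.where(n_null == 2, MISSING, visible)
    return true.astype(np.int8), visible.astype(np.int8)


def apply_error_and_missingness(
    calls: np.ndarray,
    epsilon: float,
    missing_rate: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Observe true codes through the assay: each non-missing call is
    miscalled to each of the two other genotypes with probability
    epsilon/2, then dropped to MISSING with ``missing_rate``."""
    out = calls.copy()
    typed = out != MISSING
    if epsilon > 0:
        u = rng.random(out.shape)
        # shift by +1 or +2 (mod 3) with eps/2 each
        shift = np.zeros(out.shape, dtype=np.int8)
        shift[u < epsilon / 2] = 1
        shift[(u >= epsilon / 2) & (u < epsilon)] = 2
        out[typed] = (out[typed] + shift[typed]) % 3
    if missing_rate > 0:
        drop = rng.random(out.shape) < missing_rate
        out[typed & drop] = MISSING
    return out


# ---------------------------------------------------------------------------
# Orchestration
# ---------------------------------------------------------------------------

def simulate(spec: SimulationSpec) -> TruthBundle:
    """Run the full generator for a spec and return the truth bundle."""
    streams = np.random.SeedSequence(spec.seed).spawn(6)
    rng_freq, rng_founder, rng_null, rng_meiosis, rng_obs, rng_rep = (
        np.random.default_rng(s) for s in streams
    )

    anc, pop_freqs = simulate_base_frequencies(spec, rng_freq)

    founder_haps: dict[str, np.ndarray] = {}
    population_of: dict[str, str] = {}
    for name, n, _ in spec.populations:
        haps = draw_founder_haplotypes(pop_freqs[name], n, rng_founder)
        for i in range(n):
            sid = f"{name}_{i + 1}"
            founder_haps[sid] = haps[i]
            population_of[sid] = name

    n_null = int(round(spec.null_loci_fraction * spec.n_loci))
    null_idx = np.sort(
        rng_null.choice(spec.n_loci, size=n_null, replace=False)
    ) if n_null else np.array([], dtype=int)
    if n_null:
        all_ids = list(founder_haps)
        stacked = np.stack([founder_haps[s] for s in all_ids])
        stacked = apply_null_alleles(stacked, null_idx, spec.null_allele_freq, rng_null)
        founder_haps = {s: stacked[i] for i, s in enumerate(all_ids)}

    offspring_haps, pedigree = simulate_families(
        founder_haps, spec.families, rng_meiosis
    )
    for name in offspring_haps:
        population_of[name] = "offspring"

    sample_ids = list(founder_haps) + list(offspring_haps)
    haps = np.stack([{**founder_haps, **offspring_haps}[s] for s in sample_ids])
    true_calls, visible = haplotypes_to_codes(haps)

    observed = apply_error_and_missingness(
        visible, spec.epsilon, spec.missing_rate, rng_obs
    )

    replicate_groups: dict[str, list[str]] = {}
    if spec.replicate_fraction > 0:
        n_rep = int(round(spec.replicate_fraction * len(sample_ids)))
        rep_of = rng_rep.choice(len(sample_ids), size=n_rep, replace=False)
        extra_rows = []
        for i in sorted(rep_of):
            base = sample_ids[i]
            rep_id = f"{base}_rep"
            rep_obs = apply_error_and_missingness(
                visible[i : i + 1], spec.epsilon, spec.missing_rate, rng_rep
            )
            extra_rows.append((rep_id, rep_obs[0], population_of[base]))
            replicate_groups[base] = [base, rep_id]
        if extra_rows:
            observed = np.vstack([observed] + [r[1][None, :] for r in extra_rows])
            for rep_id, _, pop in extra_rows:
                sample_ids.append(rep_id)
                population_of[rep_id] = pop

    locus_ids = [f"L{j + 1}" for j in range(spec.n_loci)]
    generation_of = {
        s: ("offspring" if s in pedigree else "parent") for s in sample_ids
    }
    matrix = GenotypeMatrix(
        sample_ids, locus_ids, observed, dict(population_of), generation_of
    )
    return TruthBundle(
        spec=spec,
        matrix=matrix,
        true_calls=true_calls,
        visible_truth=visible,
        pedigree=pedigree,
        null_loci={locus_ids[j] for j in null_idx},
        replicate_groups=replicate_groups,
        population_of=population_of,
        ancestral_freqs=anc,
        population_freqs=pop_freqs,
    )


def breeding_program_spec(
    seed: int,
    n_loci: int = 300,
    n_families: int = 15,
    n_offspring: int = 7,
    epsilon: float = 0.005,
    null_loci_fraction: float = 0.10,
    null_allele_freq: float = 0.25,
    missing_rate: float = 0.0,
) -> SimulationSpec:
    """A breeding-program scenario: 18 broodstock (9 dams, 9 sires) in 15
    partial-factorial crosses of 7 offspring each, 300 loci with MAF ~
    U(0.1, 0.5) — the family structure and panel size typical of a
    shellfish parentage run."""
    dams = [f"BS_{i}" for i in range(1, 10)]
    sires = [f"BS_{i}" for i in range(10, 19)]
    families: list[tuple[str, str, int]] = []
    for i in range(9):  # diagonal crosses
        families.append((dams[i], sires[i], n_offspring))
    for i in range(n_families - 9):  # off-diagonal re-uses
        families.append((dams[i % 9], sires[(i + 1) % 9], n_offspring))
    return SimulationSpec(
        n_loci=n_loci,
        populations=[("BS", 18, 0.0)],
        families=families[:n_families],
        seed=seed,
        freq_dist=("uniform", 0.1, 0.5),
        null_loci_fraction=null_loci_fraction,
        null_allele_freq=null_allele_freq,
        epsilon=epsilon,
        missing_rate=missing_rate,
    )


def split_generations(bundle: TruthBundle) -> tuple[GenotypeMatrix, GenotypeMatrix]:
    """(offspring matrix, candidate-parent matrix) from a bundle, using
    the recorded generation labels; replicates are excluded."""
    m = bundle.matrix
    off = [s for s in m.sample_ids if m.generation_of[s] == "offspring"]
    parents = [
        s for s in m.sample_ids
        if m.generation_of[s] == "parent" and not s.endswith("_rep")
    ]
    return m.subset(samples=off), m.subset(samples=parents)
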