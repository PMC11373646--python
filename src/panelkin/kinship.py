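"""Pairwise relationship likelihoods with a genotyping-error model.

The joint probability of a genotype pair at a biallelic locus under a
relationship R is decomposed through the IBD coefficients
kappa = (k0, k1, k2) — the probabilities that the pair shares 0, 1 or 2
alleles identical by descent:

    P(g1, g2 | R) = k0 P(g1) P(g2) + k1 P(g1) T(g2 | g1) + k2 P(g1) 1[g2 = g1]

where P(.) are Hardy–Weinberg genotype probabilities and T is the
one-shared-allele transition: the shared allele is drawn uniformly from
g1's two alleles and the other allele from the population.  The standard
relationship models are parent–offspring PO (0,1,0), full-sib FS
(0.25,0.5,0.25), half-sib HS (0.5,0.5,0) and unrelated U (1,0,0).

Genotyping error is a symmetric per-genotype miscall: each true genotype
is observed correctly with probability 1 - eps and as each of the two
other genotypes with eps/2, independently for the two individuals.  A
non-zero eps keeps single Mendelian exclusions from driving a true
parent–offspring log-likelihood to -inf.

Evidence for parentage is summarised as logl — the natural-log likelihood
ratio of PO versus U summed over loci typed in both individuals.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np

from .exceptions import UsageError
from .genotype_io import GenotypeMatrix, MISSING

KAPPA = {
    "PO": (0.0, 1.0, 0.0),
    "FS": (0.25, 0.5, 0.25),
    "HS": (0.5, 0.5, 0.0),
    "U": (1.0, 0.0, 0.0),
}


@dataclass(frozen=True)
class RelationshipModel:
    """A relationship hypothesis: IBD-sharing coefficients plus the
    per-genotype miscall rate used when evaluating likelihoods."""

    name: str
    kappa: tuple[float, float, float]
    epsilon: float = 0.0

    def __post_init__(self) -> None:
        k = self.kappa
        if any(x < 0 for x in k) or abs(sum(k) - 1.0) > 1e-9:
            raise UsageError(f"kappa must be a probability vector, got {k}")
        if self.epsilon < 0:
            raise UsageError("epsilon must be >= 0")


def relationship_model(name: str, epsilon: float = 0.0) -> RelationshipModel:
    """Standard model by name: PO, FS, HS or U."""
    if name not in KAPPA:
        raise UsageError(f"unknown relationship {name!r}; choose from {sorted(KAPPA)}")
    return RelationshipModel(name, KAPPA[name], epsilon)


# ---------------------------------------------------------------------------
# Single-locus machinery
# ---------------------------------------------------------------------------

def genotype_probs(p_alt: float) -> np.ndarray:
    """HWE genotype probabilities (homref, het, homalt) at alt freq p."""
    q = 1.0 - p_alt
    return np.array([q * q, 2 * p_alt * q, p_alt * p_alt])


def transition_matrix(p_alt: float) -> np.ndarray:
    """T[g1, g2]: genotype distribution of a relative sharing exactly one
    allele IBD with g1 (shared allele uniform over g1's two alleles, the
    other allele drawn from the population)."""
    p, q = p_alt, 1.0 - p_alt
    return np.array(
        [
            [q, p, 0.0],
            [q / 2, 0.5, p / 2],
            [0.0, q, p],
        ]
    )


def error_kernel(epsilon: float) -> np.ndarray:
    """Observation kernel E[observed, true]: correct with 1 - eps, each
    wrong genotype with eps/2."""
    e = epsilon
    return np.full((3, 3), e / 2) + np.eye(3) * (1 - 1.5 * e)


def pair_joint(p_alt: float, model: RelationshipModel) -> np.ndarray:
    """3x3 joint probability of an *observed* genotype pair under a model."""
    if not 0.0 < p_alt < 1.0:
        raise UsageError(f"allele frequency must be in (0, 1), got {p_alt}")
    P = genotype_probs(p_alt)
    k0, k1, k2 = model.kappa
    J = (
        k0 * np.outer(P, P)
        + k1 * P[:, None] * transition_matrix(p_alt)
        + k2 * np.diag(P)
    )
    if model.epsilon > 0:
        E = error_kernel(model.epsilon)
        J = E @ J @ E.T
    return J


def pair_likelihood(g1: int, g2: int, p_alt: float, model: RelationshipModel) -> float:
    """P(observed pair (g1, g2) | relationship) at one locus."""
    if g1 == MISSING or g2 == MISSING:
        raise UsageError("pair_likelihood requires non-missing genotypes")
    return float(pair_joint(p_alt, model)[g1, g2])


def logl_tables(
    freqs: np.ndarray,
    epsilon: float = 0.0,
    numerator: str = "PO",
    denominator: str = "U",
) -> np.ndarray:
    """Per-locus 4x4 log-likelihood-ratio lookup tables.

    ``tables[l, g1, g2]`` is ln P(g1,g2|num) - ln P(g1,g2|den) for
    observable codes 0..2; index 3 (reachable as code -1 = MISSING)
    contributes 0, as do loci with undefined or fixed frequencies.
    With ``epsilon == 0`` Mendelian exclusions are -inf.
    """
    freqs = np.asarray(freqs, dtype=float)
    num = relationship_model(numerator, epsilon)
    den = relationship_model(denominator, epsilon)
    tables = np.zeros((len(freqs), 4, 4))
    with np.errstate(divide="ignore"):
        for l, p in enumerate(freqs):
            if not (np.isfinite(p) and 0.0 < p < 1.0):
                continue
            tables[l, :3, :3] = np.log(pair_joint(p, num)) - np.log(
                pair_joint(p, den)
            )
    return tables


def pair_logl(
    genotypes1: np.ndarray,
    genotypes2: np.ndarray,
    freqs: np.ndarray,
    numerator: str = "PO",
    denominator: str = "U",
    epsilon: float = 0.005,
) -> tuple[float, int]:
    """Summed log-likelihood ratio over loci typed in both individuals.

    Returns ``(logl, n_shared_loci)``; ``logl`` is NaN when no usable
    locus is shared and -inf when an exclusion occurs at ``epsilon = 0``.
    """
    g1 = np.asarray(genotypes1)
    g2 = np.asarray(genotypes2)
    freqs = np.asarray(freqs, dtype=float)
    tables = logl_tables(freqs, epsilon, numerator, denominator)
    usable = (
        (g1 != MISSING)
        & (g2 != MISSING)
        & np.isfinite(freqs)
        & (freqs > 0)
        & (freqs < 1)
    )
    n_shared = int(usable.sum())
    if n_shared == 0:
        return float("nan"), 0
    idx = np.arange(len(freqs))
    contrib = tables[idx, g1, g2]
    return float(contrib[usable].sum()), n_shared


# ---------------------------------------------------------------------------
# Monte-Carlo logl distributions & cutoff calibration
# ---------------------------------------------------------------------------

@dataclass
class LoglDistribution:
    """Sorted PO-vs-U logl values for pairs simulated under one
    relationship model."""

    name: str
    values: np.ndarray
    n_sim: int
    seed: int | None


def simulate_logl_distributions(
    freqs: np.ndarray,
    models: tuple[str, ...] = ("PO", "FS", "HS", "U"),
    n_sim: int = 10000,
    epsilon: float = 0.005,
    missing_rate: float = 0.0,
    seed: int | None = None,
) -> dict[str, LoglDistribution]:
    """Simulate genotype pairs under each relationship and score PO vs U.

    Pairs are drawn locus-by-locus from the observed-genotype joint
    (including the error kernel), missing calls are masked independently
    per individual, and each pair is scored with the same PO-vs-U tables
    used for real assignments.  Plain Monte-Carlo: tail rates below
    ~1/n_sim are only bounded, not resolved.
    """
    rng = np.random.default_rng(seed)
    freqs = np.asarray(freqs, dtype=float)
    usable = np.isfinite(freqs) & (freqs > 0) & (freqs < 1)
    tables = logl_tables(freqs, epsilon)
    out: dict[str, LoglDistribution] = {}
    for name in models:
        model = relationship_model(name, epsilon)
        totals = np.zeros(n_sim)
        for l in np.flatnonzero(usable):
            probs = pair_joint(freqs[l], model).ravel()
            cats = np.searchsorted(np.cumsum(probs), rng.random(n_sim))
            cats = np.minimum(cats, 8)
            contrib = tables[l, :3, :3].ravel()[cats]
            if missing_rate > 0:
                observed = rng.random((n_sim, 2)) >= missing_rate
                contrib = np.where(observed.all(axis=1), contrib, 0.0)
            totals += contrib
        out[name] = LoglDistribution(name, np.sort(totals), n_sim, seed)
    return out


def false_positive_rate(
    dists: dict[str, LoglDistribution],
    cutoff: float,
    n_comparisons: int | None = None,
) -> dict[str, dict[str, float]]:
    """Per-relationship error rates at a logl cutoff.

    For non-PO relationships the FPR is the fraction of simulated pairs
    exceeding the cutoff (they would be wrongly accepted as PO); for PO
    the FNR is the fraction at or below it.  With ``n_comparisons`` the
    expected number of false positives is also reported.
    """
    out: dict[str, dict[str, float]] = {}
    for name, dist in dists.items():
        row: dict[str, float] = {}
        if name == "PO":
            row["fnr"] = float((dist.values <= cutoff).mean())
        else:
            fpr = float((dist.values > cutoff).mean())
            row["fpr"] = fpr
            if n_comparisons is not None:
                row["expected_false_positives"] = fpr * n_comparisons
        out[name] = row
    return out


# ---------------------------------------------------------------------------
# Duplicate detection
# ---------------------------------------------------------------------------

def find_duplicates(
    matrix: GenotypeMatrix,
    min_concordance: float = 0.95,
    min_shared: int = 100,
) -> list[tuple[str, str, float, int]]:
    """Sample pairs so concordant they are likely the same individual.

    Reports all pairs sharing at least ``min_shared`` typed loci with
    genotype concordance at or above ``min_concordance``.
    """
    typed = (matrix.calls != MISSING).astype(float)
    shared = typed @ typed.T
    concordant = np.zeros_like(shared)
    for code in (0, 1, 2):
        ind = ((matrix.calls == code) & (matrix.calls != MISSING)).astype(float)
        concordant += ind @ ind.T
    out = []
    ids = matrix.sample_ids
    for i, j in itertools.combinations(range(len(ids)), 2):
        n_sh = int(shared[i, j])
        if n_sh < min_shared:
            continue
        conc = concordant[i, j] / n_sh
        if conc >= min_concordance:
            out.append((ids[i], ids[j], float(conc), n_sh))
    return out
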