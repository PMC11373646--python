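"""Technical-replicate concordance, negative-control checks, and the
sample -> locus filtering cascade.

The filtering order follows common amplicon-panel practice: samples are
filtered for genotyping rate first, then loci are filtered over the
retained samples.  The order matters — a loci-first pass can remove loci
that would have been rescued by dropping poor samples — so it is an
explicit, logged parameter.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .exceptions import EmptyResultError, UsageError
from .genotype_io import GenotypeMatrix, HET, HOMALT, HOMREF, MISSING


@dataclass
class ReplicatePairReport:
    """Genotype concordance between one pair of technical replicates.

    Discordant calls are classified into the three unordered genotype-pair
    categories; the counts partition ``n_both_typed``:
    ``n_concordant + n_homalt_het + n_homref_het + n_homref_homalt``.
    """

    sample_a: str
    sample_b: str
    n_both_typed: int
    n_concordant: int
    n_homalt_het: int
    n_homref_het: int
    n_homref_homalt: int

    @property
    def concordance(self) -> float:
        if self.n_both_typed == 0:
            return float("nan")
        return self.n_concordant / self.n_both_typed


@dataclass
class FilterLog:
    """Ordered record of filtering steps: (step, dimension, removed, remaining)."""

    steps: list[tuple[str, str, int, int]] = field(default_factory=list)

    def add(self, step: str, dimension: str, removed: int, remaining: int) -> None:
        self.steps.append((step, dimension, removed, remaining))

    def extend(self, other: "FilterLog") -> None:
        self.steps.extend(other.steps)

    def to_rows(self) -> list[dict]:
        return [
            {"step": s, "dimension": d, "removed": rm, "remaining": re}
            for s, d, rm, re in self.steps
        ]


def _classify_pair(a: int, b: int) -> str:
    pair = frozenset((a, b))
    if pair == {HOMALT, HET}:
        return "homalt_het"
    if pair == {HOMREF, HET}:
        return "homref_het"
    if pair == {HOMREF, HOMALT}:
        return "homref_homalt"
    raise AssertionError(f"unexpected discordant pair {a},{b}")  # pragma: no cover


def replicate_concordance(
    matrix: GenotypeMatrix,
    replicate_groups: Mapping[str, Sequence[str]],
    min_gr: float = 0.5,
) -> tuple[list[ReplicatePairReport], dict]:
    """Per-pair genotype concordance between technical replicates.

    Pairs in which either member has a genotyping rate below ``min_gr``
    are excluded.  The summary is the unweighted mean +/- sample s.d. of
    per-pair concordance values (each pair contributes equally regardless
    of how many loci it shares), plus pooled discordance-category counts.
    """
    gr = dict(zip(matrix.sample_ids, matrix.genotyping_rate()))
    reports: list[ReplicatePairReport] = []
    for group, members in replicate_groups.items():
        usable = [s for s in members if s in gr and gr[s] >= min_gr]
        if len(usable) < 2:
            warnings.warn(
                f"replicate group {group!r} has fewer than 2 qualifying members; skipped",
                stacklevel=2,
            )
            continue
        for a, b in itertools.combinations(usable, 2):
            ra = matrix.calls[matrix.sample_index(a)]
            rb = matrix.calls[matrix.sample_index(b)]
            both = (ra != MISSING) & (rb != MISSING)
            n_both = int(both.sum())
            conc = int(((ra == rb) & both).sum())
            counts = {"homalt_het": 0, "homref_het": 0, "homref_homalt": 0}
            for x, y in zip(ra[both & (ra != rb)], rb[both & (ra != rb)]):
                counts[_classify_pair(int(x), int(y))] += 1
            reports.append(
                ReplicatePairReport(
                    a, b, n_both, conc,
                    counts["homalt_het"], counts["homref_het"], counts["homref_homalt"],
                )
            )
    values = [r.concordance for r in reports if r.n_both_typed > 0]
    summary = {
        "n_pairs": len(reports),
        "mean_concordance": float(np.mean(values)) if values else float("nan"),
        "sd_concordance": float(np.std(values, ddof=1)) if len(values) > 1 else float("nan"),
        "total_genotypes": sum(r.n_both_typed for r in reports),
        "n_homalt_het": sum(r.n_homalt_het for r in reports),
        "n_homref_het": sum(r.n_homref_het for r in reports),
        "n_homref_homalt": sum(r.n_homref_homalt for r in reports),
    }
    return reports, summary


def discordance_percentages(
    n_homalt_het: int, n_homref_het: int, n_homref_homalt: int, n_genotypes: int
) -> dict[str, float]:
    """Discordance-class percentages of all shared genotypes (0-100 scale)."""
    if n_genotypes <= 0:
        raise UsageError("n_genotypes must be positive")
    return {
        "homalt_het": 100.0 * n_homalt_het / n_genotypes,
        "homref_het": 100.0 * n_homref_het / n_genotypes,
        "homref_homalt": 100.0 * n_homref_homalt / n_genotypes,
    }


def select_best_replicate(
    matrix: GenotypeMatrix, replicate_groups: Mapping[str, Sequence[str]]
) -> GenotypeMatrix:
    """Keep one member per replicate group: the sample with the most
    non-missing calls (ties go to the lexicographically first id).
    Non-replicated samples pass through unchanged."""
    n_typed = dict(zip(matrix.sample_ids, (matrix.calls != MISSING).sum(axis=1)))
    drop: set[str] = set()
    for members in replicate_groups.values():
        present = [s for s in members if s in n_typed]
        if len(present) < 2:
            continue
        best = sorted(present, key=lambda s: (-n_typed[s], s))[0]
        drop.update(s for s in present if s != best)
    return matrix.subset(samples=[s for s in matrix.sample_ids if s not in drop])


def filter_missingness(
    matrix: GenotypeMatrix,
    max_missing: float = 0.30,
    order: str = "samples_then_loci",
) -> tuple[GenotypeMatrix, FilterLog]:
    """Drop samples, then loci (or the reverse), with a missing-call
    fraction at or above ``max_missing`` — i.e. keep strictly below.

    Sample missingness is computed over all loci present at that step, and
    locus missingness over the samples retained by the preceding step.
    """
    if not 0 < max_missing < 1:
        raise UsageError("max_missing must be in (0, 1)")
    if order not in ("samples_then_loci", "loci_then_samples"):
        raise UsageError(f"unknown order {order!r}")
    log = FilterLog()

    def pass_samples(m: GenotypeMatrix) -> GenotypeMatrix:
        miss = (m.calls == MISSING).mean(axis=1) if m.n_loci else np.ones(m.n_samples)
        keep = [s for s, f in zip(m.sample_ids, miss) if f < max_missing]
        if not keep:
            raise EmptyResultError("missingness filter removed every sample")
        log.add("missingness", "samples", m.n_samples - len(keep), len(keep))
        return m.subset(samples=keep)

    def pass_loci(m: GenotypeMatrix) -> GenotypeMatrix:
        miss = (m.calls == MISSING).mean(axis=0) if m.n_samples else np.ones(m.n_loci)
        keep = [l for l, f in zip(m.locus_ids, miss) if f < max_missing]
        log.add("missingness", "loci", m.n_loci - len(keep), len(keep))
        return m.subset(loci=keep)

    if order == "samples_then_loci":
        out = pass_loci(pass_samples(matrix))
    else:
        out = pass_samples(pass_loci(matrix))
    return out, log


def drop_monomorphic(matrix: GenotypeMatrix) -> tuple[GenotypeMatrix, FilterLog]:
    """Remove loci at which all observed calls imply a single allele.

    A locus with any heterozygote is polymorphic; a locus with only HOMREF
    (or only HOMALT) calls, or with no observed calls at all, is removed.
    """
    calls = matrix.calls
    has_het = (calls == HET).any(axis=0)
    has_ref = ((calls == HOMREF) | (calls == HET)).any(axis=0)
    has_alt = ((calls == HOMALT) | (calls == HET)).any(axis=0)
    poly = has_het | (has_ref & has_alt)
    keep = [l for l, p in zip(matrix.locus_ids, poly) if p]
    log = FilterLog()
    log.add("monomorphic", "loci", matrix.n_loci - len(keep), len(keep))
    return matrix.subset(loci=keep), log


def negative_control_check(
    depth_table: Mapping[str, float], max_mean_depth: float = 40.0
) -> list[str]:
    """Flag negative-control wells whose mean amplicon depth exceeds the
    threshold (strictly greater), suggesting contamination."""
    if not depth_table:
        warnings.warn("no negative controls provided", stacklevel=2)
        return []
    return [c for c, depth in depth_table.items() if depth > max_mean_depth]
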