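"""Parentage assignment, strong-trio discovery, Mendelian-incompatibility
tallying, null-allele flagging, and evaluation against a known pedigree.

The workflow mirrors how an amplicon panel is used for pedigree quality
control in a breeding program:

1. every (offspring, candidate parent) pair is scored with the PO-vs-U
   log-likelihood ratio and all assignments above a cutoff are retained
   (deliberately not limited to two per offspring, so contamination and
   pedigree errors stay visible);
2. offspring with exactly two retained candidates, both strongly
   supported, define trios; parent pairs seen in more than one trio are
   confirmed families;
3. within confirmed trios, offspring genotypes impossible under Mendelian
   transmission from the two parents are tallied per locus — loci with
   recurrent incompatibilities are the signature of null alleles
   (non-amplifying alleles that make heterozygotes look homozygous);
4. flagged loci are removed and assignment is re-run; completeness and
   false-positive rates are computed against the pedigree truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .exceptions import IntegrityError, UsageError
from .genotype_io import GenotypeMatrix, MISSING
from .kinship import logl_tables
from .popgen import allele_frequencies


@dataclass
class AssignmentRecord:
    """One retained offspring -> candidate-parent link."""

    offspring_id: str
    candidate_parent_id: str
    logl: float
    n_shared_loci: int


@dataclass
class Trio:
    """An offspring with exactly two strongly supported parents."""

    offspring_id: str
    parent_a: str
    parent_b: str
    logl_a: float
    logl_b: float
    confirmed: bool = False

    @property
    def parent_pair(self) -> tuple[str, str]:
        return tuple(sorted((self.parent_a, self.parent_b)))


@dataclass
class IncompatibilityTally:
    """Per-locus counts of trio offspring with impossible genotypes."""

    counts: dict[str, int] = field(default_factory=dict)
    n_typed: dict[str, int] = field(default_factory=dict)  # typed trio offspring


@dataclass
class PedigreeTable:
    """Truth pedigree: offspring id -> (dam id, sire id)."""

    parents_of: dict[str, tuple[str, str]]

    def all_parents(self) -> set[str]:
        return {p for pair in self.parents_of.values() for p in pair}


def read_pedigree(path) -> PedigreeTable:
    """Read a TSV with columns offspring, dam, sire (header optional)."""
    parents: dict[str, tuple[str, str]] = {}
    with open(path) as fh:
        for ln in fh:
            parts = ln.strip().split("\t")
            if not parts or parts == [""]:
                continue
            if parts[0].lower() in {"offspring", "offspring_id"}:
                continue
            if len(parts) < 3:
                raise IntegrityError(f"pedigree line with <3 fields: {ln!r}")
            parents[parts[0]] = (parts[1], parts[2])
    return PedigreeTable(parents)


# ---------------------------------------------------------------------------
# Assignment
# ---------------------------------------------------------------------------

def assign_parents(
    offspring: GenotypeMatrix,
    candidates: GenotypeMatrix,
    freqs: dict[str, float] | None = None,
    cutoff: float = 5.0,
    epsilon: float = 0.005,
) -> list[AssignmentRecord]:
    """Score all offspring x candidate pairs; keep those with
    ``logl > cutoff``.

    The candidate set should be the genotyped parent generation (sex is
    not used).  Allele frequencies default to estimates pooled over both
    matrices; for breeding-program data that matches estimating them from
    the analysed dataset itself.
    """
    if candidates.n_samples == 0:
        raise UsageError("empty candidate parent set")
    if offspring.locus_ids != candidates.locus_ids:
        common = [l for l in offspring.locus_ids if l in set(candidates.locus_ids)]
        if not common:
            raise UsageError("offspring and candidate matrices share no loci")
        offspring = offspring.subset(loci=common)
        candidates = candidates.subset(loci=common)
    if freqs is None:
        pooled = GenotypeMatrix(
            offspring.sample_ids + candidates.sample_ids,
            offspring.locus_ids,
            np.vstack([offspring.calls, candidates.calls]),
        )
        freqs = allele_frequencies(pooled)
    p = np.array([freqs.get(l, np.nan) for l in offspring.locus_ids])
    tables = logl_tables(p, epsilon)
    usable = np.isfinite(p) & (p > 0) & (p < 1)
    idx = np.arange(len(p))

    records: list[AssignmentRecord] = []
    for i, off in enumerate(offspring.sample_ids):
        g_off = offspring.calls[i]
        for j, cand in enumerate(candidates.sample_ids):
            g_cand = candidates.calls[j]
            ok = usable & (g_off != MISSING) & (g_cand != MISSING)
            n_shared = int(ok.sum())
            if n_shared == 0:
                continue
            logl = float(tables[idx[ok], g_off[ok], g_cand[ok]].sum())
            if logl > cutoff:
                records.append(AssignmentRecord(off, cand, logl, n_shared))
    return records


def identify_trios(
    assignments: list[AssignmentRecord],
    strong_cutoff: float = 10.0,
    min_obs: int = 2,
) -> list[Trio]:
    """Offspring with exactly two retained candidates, both with
    ``logl >= strong_cutoff``, form trios; parent pairs supported by at
    least ``min_obs`` trios are marked confirmed.  Only confirmed trios
    should feed incompatibility tallying."""
    by_off: dict[str, list[AssignmentRecord]] = {}
    for rec in assignments:
        by_off.setdefault(rec.offspring_id, []).append(rec)
    trios: list[Trio] = []
    for off, recs in by_off.items():
        if len(recs) != 2:
            continue
        a, b = sorted(recs, key=lambda r: r.candidate_parent_id)
        if a.logl >= strong_cutoff and b.logl >= strong_cutoff:
            trios.append(Trio(off, a.candidate_parent_id, b.candidate_parent_id,
                              a.logl, b.logl))
    pair_counts: dict[tuple[str, str], int] = {}
    for t in trios:
        pair_counts[t.parent_pair] = pair_counts.get(t.parent_pair, 0) + 1
    for t in trios:
        t.confirmed = pair_counts[t.parent_pair] >= min_obs
    return trios


# ---------------------------------------------------------------------------
# Mendelian incompatibilities & null-allele flagging
# ---------------------------------------------------------------------------

def _gametes(code: int) -> tuple[int, int]:
    return {0: (0, 0), 1: (0, 1), 2: (1, 1)}[code]


def _build_compat_table() -> np.ndarray:
    table = np.zeros((3, 3, 3), dtype=bool)
    for dam in range(3):
        for sire in range(3):
            possible = {
                a + b for a in _gametes(dam) for b in _gametes(sire)
            }
            for off in possible:
                table[dam, sire, off] = True
    return table


_COMPAT = _build_compat_table()


def mendelian_compatible(dam_g: int, sire_g: int, off_g: int) -> bool:
    """True iff the offspring genotype can arise from one allele of each
    parent (e.g. HOMREF x HOMREF -> {HOMREF}; HET x HET -> any)."""
    if MISSING in (dam_g, sire_g, off_g):
        raise UsageError("mendelian_compatible requires non-missing genotypes")
    return bool(_COMPAT[dam_g, sire_g, off_g])


def tally_incompatibilities(
    trios: list[Trio], matrix: GenotypeMatrix
) -> IncompatibilityTally:
    """Count, per locus, confirmed-trio offspring whose genotype is
    impossible given both assigned parents.  Loci with any member of the
    trio untyped are skipped for that offspring."""
    tally = IncompatibilityTally(
        counts={l: 0 for l in matrix.locus_ids},
        n_typed={l: 0 for l in matrix.locus_ids},
    )
    row = {s: i for i, s in enumerate(matrix.sample_ids)}
    for t in trios:
        if not t.confirmed:
            continue
        g_off = matrix.calls[row[t.offspring_id]]
        g_dam = matrix.calls[row[t.parent_a]]
        g_sire = matrix.calls[row[t.parent_b]]
        typed = (g_off != MISSING) & (g_dam != MISSING) & (g_sire != MISSING)
        compat = np.ones(matrix.n_loci, dtype=bool)
        compat[typed] = _COMPAT[g_dam[typed], g_sire[typed], g_off[typed]]
        for j in np.flatnonzero(typed):
            locus = matrix.locus_ids[j]
            tally.n_typed[locus] += 1
            if not compat[j]:
                tally.counts[locus] += 1
    return tally


def flag_null_loci(tally: IncompatibilityTally, min_count: int = 4) -> set[str]:
    """Loci with at least ``min_count`` incompatible trio offspring —
    candidates for null alleles; call again with ``min_count=2`` for the
    broader watch list."""
    return {l for l, c in tally.counts.items() if c >= min_count}


# ---------------------------------------------------------------------------
# Re-run and evaluation against the pedigree
# ---------------------------------------------------------------------------

def assignment_metrics(n_correct: int, n_possible: int, n_fp: int) -> dict[str, float]:
    """Completeness and false-positive percentages.

    ``pct_complete = 100 * n_correct / n_possible`` (correct assignments
    over possible parent slots); ``pct_fp = 100 * n_fp / (n_correct +
    n_fp)`` (false positives over all assignments made).
    """
    made = n_correct + n_fp
    return {
        "n_assigned_correct": n_correct,
        "n_possible": n_possible,
        "n_fp": n_fp,
        "n_assigned_total": made,
        "pct_complete": 100.0 * n_correct / n_possible if n_possible else float("nan"),
        "pct_fp": 100.0 * n_fp / made if made else 0.0,
    }


def rerun_and_evaluate(
    offspring: GenotypeMatrix,
    candidates: GenotypeMatrix,
    pedigree: PedigreeTable,
    flagged_loci: set[str] | None = None,
    cutoff: float = 5.0,
    epsilon: float = 0.005,
) -> tuple[dict, list[dict]]:
    """Remove flagged loci, re-assign, and score against the pedigree.

    A possible assignment is one (offspring, true parent) slot where the
    parent is genotyped in the candidate set; an assignment is correct
    when the retained candidate is a true parent, otherwise a false
    positive.  Returns the overall metrics plus a per-family table
    (two-parent assignments, one-parent assignments, % ID, incorrect
    assignments).
    """
    missing_ped = [s for s in offspring.sample_ids if s not in pedigree.parents_of]
    if missing_ped:
        raise IntegrityError(
            f"{len(missing_ped)} offspring missing from the pedigree, "
            f"e.g. {missing_ped[:3]}"
        )
    if flagged_loci:
        offspring = offspring.drop_loci(flagged_loci)
        candidates = candidates.drop_loci(flagged_loci)
    records = assign_parents(offspring, candidates, cutoff=cutoff, epsilon=epsilon)

    genotyped = set(candidates.sample_ids)
    n_possible = 0
    correct_by_off: dict[str, set[str]] = {s: set() for s in offspring.sample_ids}
    fp_by_off: dict[str, set[str]] = {s: set() for s in offspring.sample_ids}
    for s in offspring.sample_ids:
        n_possible += sum(1 for p in pedigree.parents_of[s] if p in genotyped)
    for rec in records:
        truth = pedigree.parents_of[rec.offspring_id]
        if rec.candidate_parent_id in truth:
            correct_by_off[rec.offspring_id].add(rec.candidate_parent_id)
        else:
            fp_by_off[rec.offspring_id].add(rec.candidate_parent_id)

    n_correct = sum(len(v) for v in correct_by_off.values())
    n_fp = sum(len(v) for v in fp_by_off.values())
    metrics = assignment_metrics(n_correct, n_possible, n_fp)
    metrics["n_offspring"] = offspring.n_samples
    metrics["n_loci"] = offspring.n_loci

    families: dict[tuple[str, str], dict] = {}
    for s in offspring.sample_ids:
        fam = pedigree.parents_of[s]
        row = families.setdefault(
            fam,
            {"dam": fam[0], "sire": fam[1], "n_offspring": 0,
             "two_parent_assign": 0, "one_parent_assign": 0,
             "n_possible": 0, "n_correct": 0, "incorrect_assign": 0},
        )
        row["n_offspring"] += 1
        n_slots = sum(1 for p in fam if p in genotyped)
        row["n_possible"] += n_slots
        got = len(correct_by_off[s])
        row["n_correct"] += got
        if got == 2:
            row["two_parent_assign"] += 1
        elif got == 1:
            row["one_parent_assign"] += 1
        row["incorrect_assign"] += len(fp_by_off[s])
    table = []
    for fam in sorted(families):
        row = families[fam]
        row["pct_id"] = (
            100.0 * row["n_correct"] / row["n_possible"]
            if row["n_possible"] else float("nan")
        )
        table.append(row)
    return metrics, table


def export_assignment_network(assignments: list[AssignmentRecord], path) -> None:
    """TSV edge list (offspring, parent, logl weight) for graph tools;
    all retained linkages are exported, including >2 per offspring."""
    with open(path, "w") as fh:
        fh.write("offspring_id\tcandidate_parent_id\tlogl\tn_shared_loci\n")
        for rec in assignments:
            fh.write(
                f"{rec.offspring_id}\t{rec.candidate_parent_id}\t"
                f"{rec.logl:.4f}\t{rec.n_shared_loci}\n"
            )
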