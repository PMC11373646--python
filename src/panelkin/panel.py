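"""Marker selection for panel design, flank-window extraction, and
mapping-category bookkeeping.

Selection takes the per-locus statistics of a discovery dataset and picks
targets by elevated observed heterozygosity (informative everywhere) and
by elevated F_ST (discriminates source populations), after capping H_OBS
to avoid collapsed duplicated genomic regions.  For each selected SNP a
symmetric flank window is cut from the reference so a primer-design
pipeline can take over.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from pyfaidx import Fasta

from .exceptions import IntegrityError
from .genotype_io import LocusRecord
from .popgen import LocusStats

_KNOWN_CATEGORIES = {"single", "multi", "non_chromosome", "unmapped", "unknown"}


@dataclass
class TargetWindow:
    """A variant with its symmetric reference flank window.

    ``window_sequence[variant_offset]`` is the reference allele;
    for non-edge targets with the default flank the window is 401 bp and
    the offset 200.
    """

    locus_id: str
    contig: str
    variant_position: int  # 1-based
    window_sequence: str
    variant_offset: int
    ref_allele: str
    alt_allele: str


def select_markers(
    stats: list[LocusStats],
    n_hobs: int = 300,
    n_fst: int = 300,
    hobs_cap: float = 0.5,
    extra_loci: list[str] | None = None,
) -> tuple[dict[str, set[str]], int]:
    """Select panel targets by top heterozygosity and top differentiation.

    Loci with ``h_obs > hobs_cap`` are excluded entirely (putative
    duplicated regions).  The top ``n_hobs`` remaining loci by ``h_obs``
    and the top ``n_fst`` by ``fst`` are taken (ties broken by locus id),
    then unioned with ``extra_loci`` (e.g. known private-allele markers).

    Returns ``(selected, overlap)`` where ``selected`` maps locus id to
    its set of applicable reason labels (``high_hobs``, ``high_fst``,
    ``private_allele``) and ``overlap`` counts loci on both ranked lists.
    """
    candidates = [s for s in stats if s.defined and s.h_obs <= hobs_cap]

    def top(by_attr: str, n: int) -> list[str]:
        ranked = [s for s in candidates if np.isfinite(getattr(s, by_attr))]
        if len(ranked) < n:
            warnings.warn(
                f"only {len(ranked)} candidates for top-{n} {by_attr} ranking",
                stacklevel=2,
            )
        ranked.sort(key=lambda s: (-getattr(s, by_attr), s.locus_id))
        return [s.locus_id for s in ranked[:n]]

    hobs_list = top("h_obs", n_hobs)
    fst_list = top("fst", n_fst)
    overlap = len(set(hobs_list) & set(fst_list))

    selected: dict[str, set[str]] = {}
    for l in hobs_list:
        selected.setdefault(l, set()).add("high_hobs")
    for l in fst_list:
        selected.setdefault(l, set()).add("high_fst")
    for l in extra_loci or []:
        selected.setdefault(l, set()).add("private_allele")
    return selected, overlap


def extract_flanks(
    fasta_path,
    targets: list[LocusRecord],
    flank: int = 200,
) -> tuple[list[TargetWindow], list[tuple[str, str]]]:
    """Cut ``2*flank + 1`` bp windows centred on each target variant.

    Coordinates are 1-based inclusive internally; the window spans
    ``[pos - flank, pos + flank]``.  Targets too close to a contig edge
    for a full window, on absent contigs, or whose reference base does not
    match the stated ref allele, are skipped and reported as
    ``(locus_id, reason)``.
    """
    fasta = Fasta(str(fasta_path), as_raw=True, sequence_always_upper=True)
    windows: list[TargetWindow] = []
    skipped: list[tuple[str, str]] = []
    for t in targets:
        if t.contig not in fasta:
            skipped.append((t.locus_id, "contig_absent"))
            continue
        contig_len = len(fasta[t.contig])
        if t.position > contig_len:
            skipped.append((t.locus_id, "position_beyond_contig"))
            continue
        if t.position - flank < 1:
            skipped.append((t.locus_id, "insufficient_left_flank"))
            continue
        if t.position + flank > contig_len:
            skipped.append((t.locus_id, "insufficient_right_flank"))
            continue
        seq = str(fasta[t.contig][t.position - flank - 1 : t.position + flank])
        if seq[flank] != t.ref_allele.upper():
            skipped.append((t.locus_id, "ref_allele_mismatch"))
            continue
        windows.append(
            TargetWindow(
                locus_id=t.locus_id,
                contig=t.contig,
                variant_position=t.position,
                window_sequence=seq,
                variant_offset=flank,
                ref_allele=t.ref_allele,
                alt_allele=t.alt_allele,
            )
        )
    return windows, skipped


def write_windows_fasta(windows: list[TargetWindow], path) -> None:
    with open(path, "w") as fh:
        for w in windows:
            fh.write(f">{w.locus_id} {w.contig}:{w.variant_position} "
                     f"{w.ref_allele}/{w.alt_allele}\n{w.window_sequence}\n")


def write_targets_bed(targets: list[LocusRecord], path, flank: int = 0) -> None:
    """BED export (0-based half-open); with ``flank`` the interval covers
    the window, otherwise the single variant base."""
    with open(path, "w") as fh:
        for t in targets:
            start = max(t.position - 1 - flank, 0)
            end = t.position + flank
            fh.write(f"{t.contig}\t{start}\t{end}\t{t.locus_id}\n")


def mapping_summary(
    targets: list[LocusRecord],
    chromosome_of: dict[str, str] | None = None,
) -> dict:
    """Tally externally assigned mapping categories and summarise
    single-mapper counts per chromosome (mean, sample s.d., range).

    ``chromosome_of`` maps contig -> chromosome label; by default the
    contig itself is used.
    """
    category_counts: dict[str, int] = {}
    per_chrom: dict[str, int] = {}
    for t in targets:
        if t.mapping_category not in _KNOWN_CATEGORIES:
            raise IntegrityError(f"unknown mapping category {t.mapping_category!r}")
        category_counts[t.mapping_category] = (
            category_counts.get(t.mapping_category, 0) + 1
        )
        if t.mapping_category == "single":
            chrom = (chromosome_of or {}).get(t.contig, t.contig)
            per_chrom[chrom] = per_chrom.get(chrom, 0) + 1
    counts = np.array(list(per_chrom.values()), dtype=float)
    return {
        "category_counts": category_counts,
        "per_chromosome": dict(sorted(per_chrom.items())),
        "mean_per_chromosome": float(counts.mean()) if counts.size else float("nan"),
        "sd_per_chromosome": float(counts.std(ddof=1)) if counts.size > 1 else float("nan"),
        "range_per_chromosome": (
            (int(counts.min()), int(counts.max())) if counts.size else (0, 0)
        ),
    }
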