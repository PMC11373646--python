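"""Genotype containers and on-disk formats.

Genotypes at biallelic SNP loci are stored as a dense integer code matrix
(individuals x loci) with the four-symbol alphabet

    HOMREF = 0   homozygous reference
    HET    = 1   heterozygous
    HOMALT = 2   homozygous alternate
    MISSING = -1 no call

Supported formats: long-format "hotspot" genotype tables as exported by
amplicon variant-calling software (one row per sample x target), the
two-digit genepop dialect, plain-text locus exclusion lists, and TSV sample
annotation tables.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .exceptions import FormatError, IntegrityError, UnsupportedDialectError, UsageError

HOMREF = 0
HET = 1
HOMALT = 2
MISSING = -1

#: valid genotype codes
CODES = (HOMREF, HET, HOMALT, MISSING)

# hotspot allele-call category -> code.  "Absent" means the variant allele is
# absent, i.e. the sample is homozygous for the reference allele.
_ALLELE_CALL_MAP = {
    "absent": HOMREF,
    "heterozygous": HET,
    "homozygous": HOMALT,
    "no call": MISSING,
}

_GENEPOP_CODE = {HOMREF: "0101", HET: "0102", HOMALT: "0202", MISSING: "0000"}

_SELECTION_REASONS = frozenset({"high_hobs", "high_fst", "private_allele", "none"})
_MAPPING_CATEGORIES = frozenset({"single", "multi", "non_chromosome", "unmapped", "unknown"})


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass
class GenotypeMatrix:
    """Individuals x loci genotype code matrix with sample/locus metadata.

    Parameters
    ----------
    sample_ids, locus_ids
        Ordered unique identifiers for the rows / columns of ``calls``.
    calls
        Integer array of shape ``(len(sample_ids), len(locus_ids))`` over
        the code alphabet {HOMREF, HET, HOMALT, MISSING}.
    population_of
        Mapping sample id -> collection label.  Samples absent from the
        mapping belong to an implicit single population.
    generation_of
        Optional mapping sample id -> generation label (e.g. parent /
        offspring), used by the parentage pipeline's two-generation guard.
    """

    sample_ids: list[str]
    locus_ids: list[str]
    calls: np.ndarray
    population_of: dict[str, str] = field(default_factory=dict)
    generation_of: dict[str, str] | None = None

    def __post_init__(self) -> None:
        self.sample_ids = list(self.sample_ids)
        self.locus_ids = list(self.locus_ids)
        self.calls = np.asarray(self.calls, dtype=np.int8)
        if self.calls.shape != (len(self.sample_ids), len(self.locus_ids)):
            raise IntegrityError(
                f"calls shape {self.calls.shape} does not match "
                f"{len(self.sample_ids)} samples x {len(self.locus_ids)} loci"
            )
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise IntegrityError("duplicate sample ids")
        if len(set(self.locus_ids)) != len(self.locus_ids):
            raise IntegrityError("duplicate locus ids")
        bad = ~np.isin(self.calls, CODES)
        if bad.any():
            raise IntegrityError(f"{bad.sum()} calls outside the code alphabet")

    # -- basic accessors ----------------------------------------------------

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_loci(self) -> int:
        return len(self.locus_ids)

    def sample_index(self, sample_id: str) -> int:
        return self.sample_ids.index(sample_id)

    def genotyping_rate(self) -> np.ndarray:
        """Per-sample fraction of non-missing calls."""
        if self.n_loci == 0:
            return np.zeros(self.n_samples)
        return (self.calls != MISSING).mean(axis=1)

    def locus_missingness(self) -> np.ndarray:
        """Per-locus fraction of missing calls."""
        if self.n_samples == 0:
            return np.zeros(self.n_loci)
        return (self.calls == MISSING).mean(axis=0)

    def populations(self) -> dict[str, list[str]]:
        """Collection label -> sample ids, in sample order; unlabelled
        samples fall into ``"pop1"``."""
        out: dict[str, list[str]] = {}
        for s in self.sample_ids:
            out.setdefault(self.population_of.get(s, "pop1"), []).append(s)
        return out

    def subset(
        self,
        samples: Sequence[str] | None = None,
        loci: Sequence[str] | None = None,
    ) -> "GenotypeMatrix":
        """Return a new matrix restricted to the given samples and/or loci
        (order follows the argument order)."""
        samples = list(samples) if samples is not None else self.sample_ids
        loci = list(loci) if loci is not None else self.locus_ids
        srow = {s: i for i, s in enumerate(self.sample_ids)}
        lcol = {l: j for j, l in enumerate(self.locus_ids)}
        try:
            ridx = [srow[s] for s in samples]
            cidx = [lcol[l] for l in loci]
        except KeyError as exc:  # pragma: no cover - defensive
            raise IntegrityError(f"unknown identifier {exc.args[0]!r}") from exc
        return GenotypeMatrix(
            sample_ids=samples,
            locus_ids=loci,
            calls=self.calls[np.ix_(ridx, cidx)] if samples and loci
            else np.zeros((len(samples), len(loci)), dtype=np.int8),
            population_of={s: self.population_of[s] for s in samples if s in self.population_of},
            generation_of=None
            if self.generation_of is None
            else {s: self.generation_of[s] for s in samples if s in self.generation_of},
        )

    def drop_loci(self, loci: Iterable[str]) -> "GenotypeMatrix":
        drop = set(loci)
        return self.subset(loci=[l for l in self.locus_ids if l not in drop])


@dataclass
class LocusRecord:
    """A targeted SNP: position, alleles, and panel-design bookkeeping."""

    locus_id: str
    contig: str
    position: int  # 1-based
    ref_allele: str
    alt_allele: str
    selection_reason: str = "none"
    mapping_category: str = "unknown"

    def __post_init__(self) -> None:
        if self.position < 1:
            raise IntegrityError(f"{self.locus_id}: position must be >= 1")
        if self.ref_allele == self.alt_allele:
            raise IntegrityError(f"{self.locus_id}: ref and alt alleles identical")
        if self.selection_reason not in _SELECTION_REASONS:
            raise IntegrityError(f"unknown selection reason {self.selection_reason!r}")
        if self.mapping_category not in _MAPPING_CATEGORIES:
            raise IntegrityError(f"unknown mapping category {self.mapping_category!r}")


@dataclass
class SampleAnnotation:
    """Per-sample metadata: collection, source type, generation, replicate
    grouping and negative-control status."""

    sample_id: str
    collection: str
    type: str = "wild"
    generation: str | None = None
    replicate_group: str | None = None
    is_negative_control: bool = False


# ---------------------------------------------------------------------------
# Hotspot tables
# ---------------------------------------------------------------------------

_HOTSPOT_COLUMNS = {
    "sample name": "sample",
    "allele call": "call",
    "allele source": "source",
    "chrom": "chrom",
    "position": "position",
    "ref": "ref",
    "variant": "variant",
}


def parse_hotspot_table(
    path,
    target_loci: Iterable[LocusRecord] | None = None,
    hotspot_label: str = "Hotspot",
) -> GenotypeMatrix:
    """Read a long-format variant-caller hotspot genotype table.

    One row per (sample, target).  Columns are matched case-insensitively
    against the canonical names "Sample Name", "Allele Call", "Allele
    Source", "Chrom", "Position", "Ref", "Variant"; extra columns are
    ignored.  Rows whose allele source differs from ``hotspot_label`` are
    skipped (de-novo calls within the amplicon).  Allele-call categories map
    to codes: Absent -> HOMREF, Heterozygous -> HET, Homozygous -> HOMALT,
    No Call -> MISSING.

    When ``target_loci`` is given, only rows matching a target's
    (contig, position) are kept and the target's ``locus_id`` is used;
    otherwise loci are named ``<contig>_<position>``.

    (Sample, locus) combinations absent from the table are MISSING.
    Duplicate rows with conflicting calls raise :class:`IntegrityError`.
    """
    df = pd.read_csv(path, sep=None, engine="python", dtype=str)
    colmap: dict[str, str] = {}
    lowered = {str(c).strip().lower(): c for c in df.columns}
    for canon, short in _HOTSPOT_COLUMNS.items():
        if canon not in lowered:
            raise FormatError(f"hotspot table is missing required column {canon!r}")
        colmap[short] = lowered[canon]

    df = df[[colmap[s] for s in _HOTSPOT_COLUMNS.values()]]
    df.columns = list(_HOTSPOT_COLUMNS.values())
    df = df[df["source"].str.strip().str.lower() == hotspot_label.lower()]

    target_by_pos: dict[tuple[str, int], str] | None = None
    if target_loci is not None:
        target_by_pos = {(t.contig, t.position): t.locus_id for t in target_loci}

    records: dict[tuple[str, str], int] = {}
    conflicts: list[str] = []
    for row in df.itertuples(index=False):
        key = (str(row.chrom), int(row.position))
        if target_by_pos is not None:
            locus = target_by_pos.get(key)
            if locus is None:
                continue
        else:
            locus = f"{key[0]}_{key[1]}"
        call = _ALLELE_CALL_MAP.get(str(row.call).strip().lower())
        if call is None:
            raise FormatError(f"unrecognised allele call {row.call!r}")
        rkey = (str(row.sample), locus)
        if rkey in records and records[rkey] != call:
            conflicts.append(f"{rkey[0]}/{rkey[1]}")
        records[rkey] = call
    if conflicts:
        raise IntegrityError(
            "conflicting duplicate rows for: " + ", ".join(sorted(set(conflicts)))
        )

    samples = list(dict.fromkeys(s for s, _ in records))
    loci = list(dict.fromkeys(l for _, l in records))
    if target_by_pos is not None:
        # preserve target order for loci that were observed
        order = [t.locus_id for t in target_loci]
        seen = set(loci)
        loci = [l for l in order if l in seen]
    calls = np.full((len(samples), len(loci)), MISSING, dtype=np.int8)
    srow = {s: i for i, s in enumerate(samples)}
    lcol = {l: j for j, l in enumerate(loci)}
    for (s, l), c in records.items():
        calls[srow[s], lcol[l]] = c
    return GenotypeMatrix(samples, loci, calls)


# ---------------------------------------------------------------------------
# Genepop
# ---------------------------------------------------------------------------

def write_genepop(matrix: GenotypeMatrix, path, title: str = "panelkin export") -> None:
    """Write the two-digit genepop dialect (01=ref allele, 02=alt allele).

    Samples are grouped into "Pop" blocks by their collection label, in
    order of first appearance; codes: HOMREF -> 0101, HET -> 0102,
    HOMALT -> 0202, MISSING -> 0000.
    """
    if matrix.n_samples == 0 or matrix.n_loci == 0:
        raise UsageError("cannot write an empty genotype matrix")
    with open(path, "w") as fh:
        fh.write(title + "\n")
        for locus in matrix.locus_ids:
            fh.write(locus + "\n")
        for _, members in matrix.populations().items():
            fh.write("Pop\n")
            for s in members:
                row = matrix.calls[matrix.sample_index(s)]
                codes = " ".join(_GENEPOP_CODE[int(c)] for c in row)
                fh.write(f"{s} ,  {codes}\n")


def read_genepop(path) -> GenotypeMatrix:
    """Read the two-digit genepop dialect written by :func:`write_genepop`.

    Locus names may be one per line or comma-separated on a single line.
    Allele order within a genotype is not meaningful ("0201" == "0102").
    Populations are labelled ``pop1``, ``pop2``, ... in file order.
    Three-digit codes or alleles other than 01/02 raise
    :class:`UnsupportedDialectError`.
    """
    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh]
    if not lines:
        raise FormatError("empty genepop file")
    body = lines[1:]
    loci: list[str] = []
    i = 0
    while i < len(body) and body[i].strip().lower() != "pop":
        chunk = body[i].strip()
        if chunk:
            loci.extend(x.strip() for x in chunk.split(",") if x.strip())
        i += 1
    if i == len(body):
        raise FormatError("no 'Pop' separator found")

    samples: list[str] = []
    rows: list[list[int]] = []
    population_of: dict[str, str] = {}
    pop = 0
    for ln in body[i:]:
        if not ln.strip():
            continue
        if ln.strip().lower() == "pop":
            pop += 1
            continue
        if "," not in ln:
            raise FormatError(f"sample line without comma separator: {ln!r}")
        name, geno = ln.split(",", 1)
        name = name.strip()
        codes = geno.split()
        if len(codes) != len(loci):
            raise FormatError(
                f"sample {name!r} has {len(codes)} genotypes for {len(loci)} loci"
            )
        row = [_decode_genepop(c, name) for c in codes]
        samples.append(name)
        rows.append(row)
        population_of[name] = f"pop{pop}"
    return GenotypeMatrix(samples, loci, np.array(rows, dtype=np.int8), population_of)


def _decode_genepop(code: str, sample: str) -> int:
    if len(code) != 4 or not code.isdigit():
        raise UnsupportedDialectError(
            f"sample {sample!r}: genotype {code!r} is not a two-digit diploid code"
        )
    a, b = code[:2], code[2:]
    alleles = frozenset({a, b})
    if alleles == {"00"}:
        return MISSING
    if alleles == {"01"}:
        return HOMREF
    if alleles == {"02"}:
        return HOMALT
    if alleles == {"01", "02"}:
        return HET
    raise UnsupportedDialectError(
        f"sample {sample!r}: genotype {code!r} uses alleles outside 01/02"
    )


# ---------------------------------------------------------------------------
# Exclusion lists & annotations
# ---------------------------------------------------------------------------

def load_exclusion_list(path, known_loci: Iterable[str] | None = None) -> set[str]:
    """Load loci to drop (e.g. multi-mapping amplicons flagged by an
    external alignment step).

    Accepts either one locus id per line, or a TSV with a
    ``mapping_category`` column in which case loci with category ``multi``
    are returned.  Ids absent from ``known_loci`` (when given) are tolerated
    with a warning reporting their count.
    """
    with open(path) as fh:
        first = fh.readline()
        rest = fh.read()
    text = first + rest
    if "\t" in first and "mapping_category" in first.lower():
        df = pd.read_csv(path, sep="\t", dtype=str)
        df.columns = [c.strip().lower() for c in df.columns]
        idcol = next(
            (c for c in ("locus_id", "locus", "id") if c in df.columns), df.columns[0]
        )
        excl = set(df.loc[df["mapping_category"].str.strip() == "multi", idcol])
    else:
        excl = {ln.strip() for ln in text.splitlines() if ln.strip()}
    if known_loci is not None:
        unknown = excl - set(known_loci)
        if unknown:
            warnings.warn(
                f"{len(unknown)} excluded locus ids not present in the dataset",
                stacklevel=2,
            )
    return excl


def read_annotations(path) -> dict[str, SampleAnnotation]:
    """Read a TSV sample annotation table.

    Required columns: ``sample_id``, ``collection``; optional: ``type``,
    ``generation``, ``replicate_group``, ``is_negative_control``.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    df.columns = [c.strip().lower() for c in df.columns]
    for col in ("sample_id", "collection"):
        if col not in df.columns:
            raise FormatError(f"annotation table is missing required column {col!r}")
    if df["sample_id"].duplicated().any():
        dups = df.loc[df["sample_id"].duplicated(), "sample_id"].tolist()
        raise IntegrityError(f"duplicate sample ids in annotations: {dups}")
    out: dict[str, SampleAnnotation] = {}
    for row in df.itertuples(index=False):
        d = row._asdict()
        neg = str(d.get("is_negative_control", "")).strip().lower() in {"1", "true", "yes"}
        out[d["sample_id"]] = SampleAnnotation(
            sample_id=d["sample_id"],
            collection=d["collection"],
            type=d.get("type") or "wild",
            generation=_opt(d.get("generation")),
            replicate_group=_opt(d.get("replicate_group")),
            is_negative_control=neg,
        )
    return out


def _opt(value) -> str | None:
    if value is None or (isinstance(value, float) and np.isnan(value)):
        return None
    value = str(value).strip()
    return value or None


def apply_annotations(
    matrix: GenotypeMatrix, annotations: Mapping[str, SampleAnnotation]
) -> GenotypeMatrix:
    """Attach collection/generation labels from annotations to a matrix."""
    pop = dict(matrix.population_of)
    gen = dict(matrix.generation_of or {})
    for s in matrix.sample_ids:
        ann = annotations.get(s)
        if ann is None:
            continue
        pop[s] = ann.collection
        if ann.generation is not None:
            gen[s] = ann.generation
    return GenotypeMatrix(
        matrix.sample_ids, matrix.locus_ids, matrix.calls.copy(), pop, gen or None
    )


def write_matrix_tsv(matrix: GenotypeMatrix, path) -> None:
    """Write the code matrix as TSV (samples x loci; -1 = missing)."""
    pd.DataFrame(
        matrix.calls, index=matrix.sample_ids, columns=matrix.locus_ids
    ).to_csv(path, sep="\t", index_label="sample_id")
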