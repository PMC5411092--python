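"""Readers and validators for the pipeline's external inputs.

Covers single-sample VCF v4.x (via pysam), per-variant pathogenicity score
tables keyed by ``chrom:pos:ref:alt`` (three sources, as produced by
genome-wide pathogenicity predictors), minor-allele-frequency tables, gene
interval annotations (BED-like TSV), disease–phenotype/mode-of-inheritance
tables, and ClinVar-style labeled variant tables.  All tabular readers
validate their header and reject unknown columns loudly.
"""

from __future__ import annotations

import csv
import warnings
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

HET = "het"
HOM = "hom"
UNCALLED = "uncalled"

MOI_VALUES = ("Dominant", "Recessive", "X-linked", "Other")

#: Collapse of the source table's seven inheritance categories onto the
#: four feature values.
MOI_COLLAPSE = {
    "Dominant": "Dominant",
    "Recessive": "Recessive",
    "X-linked": "X-linked",
    "Multifactorial": "Other",
    "Others": "Other",
    "Other": "Other",
    "Sporadic": "Other",
    "Y-linked": "Other",
}

SCORE_SOURCES = ("score_1", "score_2", "score_3")


class ResourceError(ValueError):
    pass


@dataclass(frozen=True)
class VariantRecord:
    """One bi-allelic variant with genotype call and annotations.

    Multi-allelic VCF rows are split into one record per alternate allele;
    positions stay 1-based (VCF convention).
    """

    chrom: str
    pos: int
    ref: str
    alt: str
    genotype: str = UNCALLED
    maf: float | None = None
    scores: tuple[float | None, float | None, float | None] = (None, None, None)
    gene: str | None = None
    exonic: bool = False

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ResourceError(f"position must be >= 1, got {self.pos}")
        if not self.ref or not self.alt or self.ref == self.alt:
            raise ResourceError(f"bad alleles {self.ref!r}>{self.alt!r}")
        if self.genotype not in (HET, HOM, UNCALLED):
            raise ResourceError(f"bad genotype {self.genotype!r}")

    @property
    def key(self) -> str:
        return f"{self.chrom}:{self.pos}:{self.ref}:{self.alt}"


@dataclass(frozen=True)
class Disease:
    disease_id: str
    phenotypes: frozenset[str]
    moi: str

    def __post_init__(self) -> None:
        if self.moi not in MOI_VALUES:
            raise ResourceError(f"bad mode of inheritance {self.moi!r}")


DiseaseTable = dict[str, Disease]


@dataclass(frozen=True)
class LabeledVariant:
    """A ClinVar-style row: a variant, a pathogenic/benign label, and (for
    pathogenic rows) the disease it causes.  A variant causal for several
    diseases appears as several rows."""

    variant: VariantRecord
    label: str  # "pathogenic" | "benign"
    disease_id: str | None = None

    def __post_init__(self) -> None:
        if self.label not in ("pathogenic", "benign"):
            raise ResourceError(f"bad label {self.label!r}")
        if self.label == "pathogenic" and not self.disease_id:
            raise ResourceError("pathogenic rows need a disease_id")


@dataclass
class GeneAnnotation:
    """Gene intervals, 0-based half-open, possibly overlapping."""

    intervals: dict[str, tuple[str, int, int]]  # gene -> (chrom, start, end)

    def __post_init__(self) -> None:
        self._by_chrom: dict[str, list[tuple[int, int, str]]] = {}
        for gene, (chrom, start, end) in self.intervals.items():
            if start >= end:
                raise ResourceError(f"empty interval for {gene}: [{start},{end})")
            self._by_chrom.setdefault(chrom, []).append((start, end, gene))
        for lst in self._by_chrom.values():
            lst.sort()

    def on_chrom(self, chrom: str) -> list[tuple[int, int, str]]:
        return self._by_chrom.get(chrom, [])


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------


def _genotype_for_alt(gt: tuple, phased_ignored: bool, alt_index: int) -> str:
    """Map a GT tuple to het/hom/uncalled with respect to one alt allele.

    ``0/i`` (either order) is het, ``i/i`` hom; anything else — missing
    calls, half-calls, or genotypes mixing other alternate alleles — is
    uncalled for this split record.
    """
    if gt is None or any(a is None for a in gt) or len(gt) != 2:
        return UNCALLED
    pair = tuple(sorted(gt))
    if pair == (0, alt_index):
        return HET
    if pair == (alt_index, alt_index):
        return HOM
    return UNCALLED


def read_vcf(path) -> list[VariantRecord]:
    """Read a single-sample VCF v4.x into split variant records.

    One record per (row, alt allele); genotypes 0/1 and 0|1 map to het,
    1/1 and 1|1 to hom, and missing/half/multi-alt calls to uncalled.
    """
    import pysam

    try:
        vf = pysam.VariantFile(str(path))
    except Exception as exc:
        raise ResourceError(f"cannot parse VCF {path}: {exc}") from exc
    samples = list(vf.header.samples)
    if len(samples) != 1:
        raise ResourceError(
            f"expected a single-sample VCF, found {len(samples)} samples in {path}"
        )
    records: list[VariantRecord] = []
    for i, rec in enumerate(vf, start=1):
        try:
            gt = rec.samples[0].get("GT")
            alts = rec.alts or ()
            for alt_index, alt in enumerate(alts, start=1):
                records.append(
                    VariantRecord(
                        chrom=rec.chrom,
                        pos=rec.pos,
                        ref=rec.ref,
                        alt=alt,
                        genotype=_genotype_for_alt(gt, False, alt_index),
                    )
                )
        except ResourceError:
            raise
        except Exception as exc:
            raise ResourceError(f"malformed VCF row {i} in {path}: {exc}") from exc
    return records


VCF_HEADER = (
    "##fileformat=VCFv4.2\n"
    '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n'
)


def write_vcf(records: Sequence[VariantRecord], path, sample: str = "SAMPLE") -> None:
    """Write records as a minimal single-sample VCF (one row per record)."""
    gt_map = {HET: "0/1", HOM: "1/1", UNCALLED: "./."}
    chroms: list[str] = []
    for r in records:
        if r.chrom not in chroms:
            chroms.append(r.chrom)
    with open(path, "w") as fh:
        fh.write(VCF_HEADER)
        for c in chroms:
            fh.write(f"##contig=<ID={c}>\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + sample + "\n"
        )
        for r in records:
            fh.write(
                f"{r.chrom}\t{r.pos}\t.\t{r.ref}\t{r.alt}\t.\t.\t.\tGT\t"
                f"{gt_map[r.genotype]}\n"
            )


# ---------------------------------------------------------------------------
# gene assignment and score attachment
# ---------------------------------------------------------------------------


def assign_gene(v: VariantRecord, genes: GeneAnnotation) -> VariantRecord:
    """Assign the containing gene (exonic) or, failing that, the closest
    gene in genomic coordinates.

    A 1-based position ``pos`` is contained in the 0-based half-open
    interval [start, end) iff start < pos <= end.  Distance to a gene
    downstream of the variant is ``start − pos``; to a gene upstream it is
    ``pos − end + 1``.  Ties break by smaller start coordinate.
    """
    candidates = genes.on_chrom(v.chrom)
    if not candidates:
        warnings.warn(f"no gene on chromosome {v.chrom!r}; variant left unassigned",
                      stacklevel=2)
        return replace(v, gene=None, exonic=False)
    containing = [(start, gene) for start, end, gene in candidates
                  if start < v.pos <= end]
    if containing:
        _, gene = min(containing)
        return replace(v, gene=gene, exonic=True)
    best: tuple[int, int, str] | None = None
    for start, end, gene in candidates:
        if v.pos <= start:
            dist = start - v.pos
        else:
            dist = v.pos - end + 1
        cand = (dist, start, gene)
        if best is None or cand < best:
            best = cand
    return replace(v, gene=best[2], exonic=False)


ScoreTable = Mapping[str, float]


def attach_scores(
    v: VariantRecord, score_tables: Sequence[ScoreTable], maf_table: ScoreTable | None = None
) -> VariantRecord:
    """Attach the three pathogenicity scores (and MAF, if a table is given)
    where present; absent entries stay missing and records are never
    dropped for missing scores."""
    if len(score_tables) != 3:
        raise ResourceError(f"expected 3 score tables, got {len(score_tables)}")
    scores = tuple(t.get(v.key) for t in score_tables)
    maf = v.maf if maf_table is None else maf_table.get(v.key, v.maf)
    return replace(v, scores=scores, maf=maf)


# ---------------------------------------------------------------------------
# tabular readers
# ---------------------------------------------------------------------------


def _read_tsv(path, columns: list[str]) -> list[dict[str, str]]:
    with open(path) as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        if reader.fieldnames != columns:
            raise ResourceError(
                f"{path}: expected columns {columns}, found {reader.fieldnames}"
            )
        return [row for row in reader]


SCORE_COLUMNS = ["variant_key", "score"]


def read_score_table(path) -> dict[str, float]:
    """Score or MAF table: ``variant_key`` (chrom:pos:ref:alt) and value."""
    out: dict[str, float] = {}
    for row in _read_tsv(path, SCORE_COLUMNS):
        out[row["variant_key"]] = float(row["score"])
    return out


def write_score_table(table: Mapping[str, float], path) -> None:
    with open(path, "w") as fh:
        fh.write("variant_key\tscore\n")
        for k in sorted(table):
            fh.write(f"{k}\t{table[k]:.10g}\n")


GENE_COLUMNS = ["chrom", "start", "end", "gene_id"]


def read_gene_annotation(path) -> GeneAnnotation:
    """BED-like gene intervals: chrom, start, end (0-based half-open),
    gene_id."""
    intervals: dict[str, tuple[str, int, int]] = {}
    for row in _read_tsv(path, GENE_COLUMNS):
        intervals[row["gene_id"]] = (row["chrom"], int(row["start"]), int(row["end"]))
    return GeneAnnotation(intervals)


def write_gene_annotation(genes: GeneAnnotation, path) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(GENE_COLUMNS) + "\n")
        for gene, (chrom, start, end) in sorted(genes.intervals.items()):
            fh.write(f"{chrom}\t{start}\t{end}\t{gene}\n")


DISEASE_COLUMNS = ["disease_id", "moi", "phenotypes"]


def read_disease_table(path) -> DiseaseTable:
    """Disease table: disease_id, mode of inheritance (seven source
    categories accepted, collapsed to four), comma-separated phenotypes."""
    out: DiseaseTable = {}
    for row in _read_tsv(path, DISEASE_COLUMNS):
        moi = MOI_COLLAPSE.get(row["moi"])
        if moi is None:
            raise ResourceError(f"unknown mode of inheritance {row['moi']!r}")
        phen = frozenset(p for p in row["phenotypes"].split(",") if p)
        out[row["disease_id"]] = Disease(row["disease_id"], phen, moi)
    return out


def write_disease_table(diseases: DiseaseTable, path) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(DISEASE_COLUMNS) + "\n")
        for did in sorted(diseases):
            d = diseases[did]
            fh.write(f"{did}\t{d.moi}\t{','.join(sorted(d.phenotypes))}\n")


LABELED_COLUMNS = ["chrom", "pos", "ref", "alt", "label", "disease_id"]


def read_labeled_variants(path) -> list[LabeledVariant]:
    """ClinVar-style labeled variant table (pathogenic/benign)."""
    out: list[LabeledVariant] = []
    for row in _read_tsv(path, LABELED_COLUMNS):
        v = VariantRecord(row["chrom"], int(row["pos"]), row["ref"], row["alt"])
        out.append(LabeledVariant(v, row["label"], row["disease_id"] or None))
    return out


def write_labeled_variants(rows: Iterable[LabeledVariant], path) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(LABELED_COLUMNS) + "\n")
        for lv in rows:
            v = lv.variant
            fh.write(
                f"{v.chrom}\t{v.pos}\t{v.ref}\t{v.alt}\t{lv.label}\t"
                f"{lv.disease_id or ''}\n"
            )
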