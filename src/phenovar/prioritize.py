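"""End-to-end variant prioritization.

Reads a patient VCF and phenotype profile, filters variants (uncalled
genotypes; heterozygotes under a recessive mode of inheritance; common
variants above the minor-allele-frequency cutoff, default 1%, with missing
MAF treated as rare and retained), builds the 60-feature representation of
every surviving variant against the profile, scores with a trained
causative classifier, and emits a deterministically ranked list.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .features import build_features, derive_panel
from .ontology import PhenotypeHierarchy
from .resources import (
    HET,
    UNCALLED,
    GeneAnnotation,
    VariantRecord,
    assign_gene,
    attach_scores,
    read_gene_annotation,
    read_score_table,
    read_vcf,
)
from .similarity import PhenotypeProfile, SimilarityEngine, SOURCES
from .training import CausativeVariantClassifier

DEFAULT_MAF_CUTOFF = 0.01


class PipelineError(ValueError):
    pass


@dataclass
class FilterLog:
    """Counts of variants removed per filter rule."""

    n_input: int = 0
    removed_uncalled: int = 0
    removed_recessive_het: int = 0
    removed_common: int = 0

    @property
    def n_kept(self) -> int:
        return (
            self.n_input
            - self.removed_uncalled
            - self.removed_recessive_het
            - self.removed_common
        )

    def as_dict(self) -> dict:
        return {
            "n_input": self.n_input,
            "removed_uncalled": self.removed_uncalled,
            "removed_recessive_het": self.removed_recessive_het,
            "removed_common": self.removed_common,
            "n_kept": self.n_kept,
        }


def filter_variants(
    records: Sequence[VariantRecord],
    moi: str | None,
    maf_cutoff: float = DEFAULT_MAF_CUTOFF,
) -> tuple[list[VariantRecord], FilterLog]:
    """Apply the genotype-call, recessive-zygosity and MAF filters.

    Rules apply in order per variant: uncalled genotypes go first; under a
    recessive mode of inheritance heterozygotes go next (the disease needs
    a homozygous genotype); finally variants whose *known* MAF exceeds the
    cutoff are removed — missing MAF is treated as rare and retained.
    """
    if not (0 < maf_cutoff <= 1):
        raise PipelineError(f"maf_cutoff must be in (0, 1], got {maf_cutoff}")
    log = FilterLog(n_input=len(records))
    kept: list[VariantRecord] = []
    for r in records:
        if r.genotype == UNCALLED:
            log.removed_uncalled += 1
        elif moi == "Recessive" and r.genotype == HET:
            log.removed_recessive_het += 1
        elif r.maf is not None and r.maf > maf_cutoff:
            log.removed_common += 1
        else:
            kept.append(r)
    return kept, log


@dataclass
class RankedResult:
    """A ranked variant list with provenance.

    Entries are ``(rank, record, probability)`` with consecutive 1-based
    ranks and non-increasing probabilities.
    """

    entries: list[tuple[int, VariantRecord, float]]
    provenance: dict = field(default_factory=dict)

    def rank_of(self, variant_key: str) -> int | None:
        for rank, rec, _ in self.entries:
            if rec.key == variant_key:
                return rank
        return None

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(
                "rank\tchrom\tpos\tref\talt\tgene\tgenotype\tprobability\t"
                "similarity\tscore_1\tscore_2\tscore_3\tmaf\n"
            )
            sim = self.provenance.get("similarity", {})
            for rank, r, p in self.entries:
                sc = ["" if s is None else f"{s:.6g}" for s in r.scores]
                fh.write(
                    f"{rank}\t{r.chrom}\t{r.pos}\t{r.ref}\t{r.alt}\t"
                    f"{r.gene or ''}\t{r.genotype}\t{p:.6f}\t"
                    f"{sim.get(r.gene, 0.0):.6f}\t{sc[0]}\t{sc[1]}\t{sc[2]}\t"
                    f"{'' if r.maf is None else f'{r.maf:.6g}'}\n"
                )


def _tie_key(record: VariantRecord) -> tuple:
    available = [s for s in record.scores if s is not None]
    mean_score = float(np.mean(available)) if available else float("-inf")
    return (-mean_score, record.chrom, record.pos, record.ref, record.alt)


def rank_variants(
    kept: Sequence[VariantRecord],
    profile: PhenotypeProfile,
    model: CausativeVariantClassifier,
    sim_table: Mapping[str, float],
    hierarchy: PhenotypeHierarchy,
    panel: Sequence[str],
) -> RankedResult:
    """Score every kept variant with the model and sort descending.

    Ties break by higher mean of available pathogenicity scores, then by
    chromosome, position, and alleles — the order is fully deterministic.
    """
    if not kept:
        warnings.warn("no variants left to rank", stacklevel=2)
        return RankedResult(entries=[], provenance={"similarity": dict(sim_table)})
    X = np.vstack(
        [build_features(v, profile, sim_table, hierarchy, panel) for v in kept]
    )
    probs = model.causative_probability(X)
    order = sorted(
        range(len(kept)), key=lambda i: (-probs[i],) + _tie_key(kept[i])
    )
    entries = [
        (rank, kept[i], float(probs[i])) for rank, i in enumerate(order, start=1)
    ]
    return RankedResult(entries=entries, provenance={"similarity": dict(sim_table)})


def prioritize_records(
    records: Sequence[VariantRecord],
    profile: PhenotypeProfile,
    model: CausativeVariantClassifier,
    engine: SimilarityEngine,
    genes: GeneAnnotation,
    panel: Sequence[str],
    score_tables: Sequence[Mapping[str, float]] | None = None,
    maf_table: Mapping[str, float] | None = None,
    maf_cutoff: float = DEFAULT_MAF_CUTOFF,
) -> RankedResult:
    """Core in-memory pipeline: annotate, filter, score, rank."""
    missing = [p for p in profile.phenotypes if not engine.hierarchy.has_class(p)]
    if missing:
        raise PipelineError(
            f"profile classes absent from the hierarchy: {sorted(missing)}"
        )
    annotated = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # unassigned-gene warnings logged in counts
        for v in records:
            if score_tables is not None:
                v = attach_scores(v, score_tables, maf_table)
            annotated.append(assign_gene(v, genes))
    kept, log = filter_variants(annotated, profile.moi, maf_cutoff)
    sim_table = engine.normalized_gene_scores(profile)
    result = rank_variants(kept, profile, model, sim_table, engine.hierarchy, panel)
    result.provenance.update(
        {
            "filter_log": log.as_dict(),
            "moi": profile.moi,
            "maf_cutoff": maf_cutoff,
            "sources": list(engine.sources),
            "n_profile_phenotypes": len(profile.phenotypes),
        }
    )
    return result


@dataclass
class PipelineConfig:
    """Resource locations and knobs for a file-based pipeline run."""

    hierarchy_dir: str
    corpus: str
    genes: str
    score_tables: tuple[str, str, str]
    maf_table: str | None = None
    panel: str | None = None  # newline-delimited class IDs; derived if absent
    sources: tuple[str, ...] = SOURCES
    maf_cutoff: float = DEFAULT_MAF_CUTOFF

    @staticmethod
    def from_yaml(path) -> "PipelineConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh)
        known = {
            "hierarchy_dir", "corpus", "genes", "score_tables", "maf_table",
            "panel", "sources", "maf_cutoff",
        }
        unknown = set(raw) - known
        if unknown:
            raise PipelineError(f"unknown config keys: {sorted(unknown)}")
        raw["score_tables"] = tuple(raw["score_tables"])
        if "sources" in raw:
            raw["sources"] = tuple(raw["sources"])
        return PipelineConfig(**raw)


def read_panel(path) -> list[str]:
    with open(path) as fh:
        return [line.strip() for line in fh if line.strip()]


def run_pipeline(
    vcf_path,
    profile: PhenotypeProfile,
    model: CausativeVariantClassifier,
    config: PipelineConfig,
    out_dir=None,
) -> RankedResult:
    """File-based pipeline: read → split → annotate → filter → similarity →
    features → impute → predict → rank; optionally writes the ranked TSV
    and a JSON provenance file."""
    from .ontology import read_hierarchy

    hierarchy = read_hierarchy(config.hierarchy_dir)
    from .similarity import read_corpus

    corpus = read_corpus(config.corpus)
    engine = SimilarityEngine(hierarchy, corpus, sources=config.sources)
    genes = read_gene_annotation(config.genes)
    score_tables = [read_score_table(p) for p in config.score_tables]
    maf_table = read_score_table(config.maf_table) if config.maf_table else {}
    panel = read_panel(config.panel) if config.panel else derive_panel(hierarchy)
    records = read_vcf(vcf_path)
    result = prioritize_records(
        records,
        profile,
        model,
        engine,
        genes,
        panel,
        score_tables=score_tables,
        maf_table=maf_table,
        maf_cutoff=config.maf_cutoff,
    )
    result.provenance["vcf"] = str(vcf_path)
    result.provenance["n_vcf_records"] = len(records)
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        result.to_tsv(out / "ranked_variants.tsv")
        prov = {k: v for k, v in result.provenance.items() if k != "similarity"}
        with open(out / "provenance.json", "w") as fh:
            json.dump(prov, fh, indent=2, sort_keys=True)
            fh.write("\n")
    return result
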