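"""Synthetic worlds and spike-in cohorts.

Generates every input the pipeline consumes: a toy entity/quality ontology
with is-a and part-of structure, phene-pattern phenotype classes, a
gene–phenotype annotation corpus (human/mouse/zebrafish source tags), a
disease table with modes of inheritance, gene intervals, ClinVar-style
labeled variant tables for training, and spike-in patient cases — a
background of benign variants plus exactly one causative variant inserted
into the disease's causal gene, with the disease's phenotype profile as
the patient profile.

The signal model is parametric: benign pathogenicity scores are drawn from
a truncated Normal centred at 0.3 and pathogenic scores from one centred
at 0.8; ``separable`` clips the two into disjoint ranges, ``noisy``
overlaps them with a configurable σ.  A similarity-decay parameter removes
a fraction of each causal gene's annotations before corpus construction,
weakening the phenotype-match signal.  Everything is deterministic per
seed.
"""

from __future__ import annotations

import shutil
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .features import derive_panel
from .ontology import (
    EntityOntology,
    PhenotypeHierarchy,
    RawEQAxiom,
    build_ontology,
    read_hierarchy,
    write_hierarchy,
)
from .resources import (
    HET,
    HOM,
    UNCALLED,
    Disease,
    DiseaseTable,
    GeneAnnotation,
    LabeledVariant,
    VariantRecord,
    read_disease_table,
    read_gene_annotation,
    write_disease_table,
    write_gene_annotation,
    write_score_table,
    write_vcf,
)
from .similarity import (
    AnnotationCorpus,
    PhenotypeProfile,
    SimilarityEngine,
    SOURCES,
    read_corpus,
    write_corpus,
)


class SimulationError(ValueError):
    pass


# ---------------------------------------------------------------------------
# parameters
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class WorldParams:
    """Shape of a synthetic world.

    Defaults give ~50 concrete phenotype classes over a 4-level anatomy
    with part-of structure, 30 genes with disjoint annotation themes, and
    20 phenotype-annotated diseases, one designated causal gene each.
    """

    n_entities: int = 24
    depth: int = 4
    n_qualities: int = 8
    n_genes: int = 30
    n_diseases: int = 20
    phenotypes_per_disease: int = 4
    qualities_per_entity: int = 2
    partof_prob: float = 0.35
    similarity_decay: float = 0.0  # fraction of causal-gene annotations removed

    def validate(self) -> None:
        if self.n_entities > 1 and self.depth < 1:
            raise SimulationError("depth 0 is inconsistent with n_entities > 1")
        if self.phenotypes_per_disease < 1:
            raise SimulationError("phenotypes_per_disease must be >= 1")
        if self.n_diseases < 2:
            raise SimulationError("need >= 2 diseases (profile mismatching)")
        if not (0 <= self.similarity_decay < 1):
            raise SimulationError("similarity_decay must be in [0, 1)")
        n_phen = self.n_entities * self.qualities_per_entity
        if n_phen < self.n_genes:
            raise SimulationError("fewer phenotype classes than genes")


@dataclass(frozen=True)
class SignalModel:
    """Score-generating model for benign vs pathogenic variants."""

    kind: str = "separable"  # "separable" | "noisy"
    sigma: float = 0.1
    benign_mean: float = 0.3
    pathogenic_mean: float = 0.8
    missing_rate: float = 0.0  # per-table probability a score is absent

    def __post_init__(self) -> None:
        if self.kind not in ("separable", "noisy"):
            raise SimulationError(f"unknown signal kind {self.kind!r}")
        if self.sigma < 0:
            raise SimulationError("sigma must be >= 0")

    def benign_scores(self, rng: np.random.Generator) -> tuple[float, ...]:
        if self.kind == "separable":
            draws = rng.normal(self.benign_mean, 0.05, size=3).clip(0.0, 0.55)
        else:
            draws = rng.normal(self.benign_mean, self.sigma, size=3).clip(0.0, 1.0)
        return tuple(round(float(x), 6) for x in draws)

    def pathogenic_scores(self, rng: np.random.Generator) -> tuple[float, ...]:
        if self.kind == "separable":
            draws = rng.normal(self.pathogenic_mean, 0.05, size=3).clip(0.6, 1.0)
        else:
            draws = rng.normal(self.pathogenic_mean, self.sigma, size=3).clip(0.0, 1.0)
        return tuple(round(float(x), 6) for x in draws)


GENE_LENGTH = 10_000
GENE_SPACING = 20_000


# ---------------------------------------------------------------------------
# world
# ---------------------------------------------------------------------------


@dataclass
class World:
    """A self-contained synthetic study world plus its truth metadata.

    ``causal_gene`` (disease → gene) is truth: it is never written into
    any pipeline-visible file.
    """

    params: WorldParams
    seed: int
    entities: EntityOntology | None
    hierarchy: PhenotypeHierarchy
    corpus: AnnotationCorpus
    diseases: DiseaseTable
    genes: GeneAnnotation
    causal_gene: dict[str, str]
    panel: list[str]
    _engines: dict = field(default_factory=dict, repr=False)

    def engine(self, sources: Iterable[str] = SOURCES) -> SimilarityEngine:
        key = tuple(sources)
        if key not in self._engines:
            self._engines[key] = SimilarityEngine(self.hierarchy, self.corpus, key)
        return self._engines[key]

    def profile_of(self, disease_id: str) -> PhenotypeProfile:
        d = self.diseases[disease_id]
        return PhenotypeProfile(d.phenotypes, moi=d.moi)


def generate_toy_world(params: WorldParams, seed: int) -> World:
    """Build a random world: entity DAG → phene-pattern phenotype classes →
    inferred hierarchy → genes with disjoint annotation themes → diseases
    whose phenotypes come from exactly one causal gene's annotations."""
    params.validate()
    rng = np.random.default_rng(seed)

    # --- entity ontology (anatomy-like DAG with is-a and part-of) ---------
    ent_root = "ENT:ROOT"
    entity_ids = [ent_root] + [f"ENT:{i:04d}" for i in range(1, params.n_entities)]
    levels: dict[str, int] = {ent_root: 0}
    isa: set[tuple[str, str]] = set()
    partof: set[tuple[str, str]] = set()
    for i, e in enumerate(entity_ids[1:], start=1):
        level = 1 + (i - 1) * params.depth // max(1, len(entity_ids) - 1)
        pool = [x for x in entity_ids[:i] if levels[x] == level - 1] or [ent_root]
        parent = pool[rng.integers(len(pool))]
        levels[e] = level
        isa.add((e, parent))
        if level >= 2 and rng.random() < params.partof_prob:
            whole_pool = [x for x in entity_ids[:i] if levels[x] < level]
            whole = whole_pool[rng.integers(len(whole_pool))]
            if whole != parent:
                partof.add((e, whole))

    # --- qualities (two-level is-a tree) ----------------------------------
    qual_root = "QUAL:ROOT"
    quality_ids = [f"QUAL:{i:02d}" for i in range(params.n_qualities)]
    severe_ids = []
    for q in quality_ids:
        isa.add((q, qual_root))
    for q in quality_ids[:: 2]:
        sq = q + ":severe"
        severe_ids.append(sq)
        isa.add((sq, q))
    classes = set(entity_ids) | {qual_root} | set(quality_ids) | set(severe_ids)
    entities = EntityOntology(classes=classes, isa_edges=isa, partof_edges=partof)

    # --- phenotype classes via the rewrite rules --------------------------
    all_qualities = quality_ids + severe_ids
    axioms: list[RawEQAxiom] = []
    n = 0
    for e in entity_ids:
        picks = rng.choice(len(all_qualities),
                           size=min(params.qualities_per_entity, len(all_qualities)),
                           replace=False)
        for qi in sorted(picks):
            axioms.append(
                RawEQAxiom(
                    f"P:{n:04d}",
                    (("inheres-in", e), ("has-quality", all_qualities[qi])),
                )
            )
            n += 1
    hierarchy, _ = build_ontology(entities, axioms)
    concrete = [a.phenotype_id for a in axioms]

    # --- genes: disjoint annotation themes --------------------------------
    gene_ids = [f"G:{i:04d}" for i in range(params.n_genes)]
    shuffled = list(concrete)
    rng.shuffle(shuffled)
    gene_annotations: dict[str, list[str]] = {g: [] for g in gene_ids}
    for i, p in enumerate(shuffled):
        gene_annotations[gene_ids[i % params.n_genes]].append(p)

    # --- diseases: phenotypes drawn from one causal gene ------------------
    moi_pool = ("Dominant", "Recessive", "X-linked", "Other")
    moi_probs = (0.40, 0.35, 0.10, 0.15)
    diseases: DiseaseTable = {}
    causal: dict[str, str] = {}
    for i in range(params.n_diseases):
        did = f"D:{i:04d}"
        gene = gene_ids[i % params.n_genes]
        pool = gene_annotations[gene]
        k = min(params.phenotypes_per_disease, len(pool))
        picks = rng.choice(len(pool), size=k, replace=False)
        moi = moi_pool[rng.choice(4, p=moi_probs)]
        diseases[did] = Disease(did, frozenset(pool[j] for j in picks), moi)
        causal[did] = gene

    # --- corpus with source tags and optional similarity decay ------------
    associations: set[tuple[str, str, str]] = set()
    causal_genes = set(causal.values())
    for g in gene_ids:
        annots = list(gene_annotations[g])
        if params.similarity_decay > 0 and g in causal_genes and len(annots) > 1:
            keep = max(1, int(round(len(annots) * (1 - params.similarity_decay))))
            idx = rng.choice(len(annots), size=keep, replace=False)
            annots = [annots[j] for j in sorted(idx)]
        for p in annots:
            primary = SOURCES[rng.choice(3, p=(0.5, 0.3, 0.2))]
            associations.add((g, p, primary))
            if rng.random() < 0.3:  # some genes annotated in a second species
                other = SOURCES[rng.integers(3)]
                associations.add((g, p, other))

    # --- gene intervals ----------------------------------------------------
    intervals = {
        g: ("1", GENE_SPACING * i + 5_000, GENE_SPACING * i + 5_000 + GENE_LENGTH)
        for i, g in enumerate(gene_ids)
    }
    genes = GeneAnnotation(intervals)

    return World(
        params=params,
        seed=seed,
        entities=entities,
        hierarchy=hierarchy,
        corpus=AnnotationCorpus(associations),
        diseases=diseases,
        genes=genes,
        causal_gene=causal,
        panel=derive_panel(hierarchy),
    )


# ---------------------------------------------------------------------------
# labeled training variants
# ---------------------------------------------------------------------------

_BASES = ("A", "C", "G", "T")


def _random_snv(rng: np.random.Generator, pos: int) -> tuple[str, str]:
    ref = _BASES[rng.integers(4)]
    alt = _BASES[(int(_BASES.index(ref)) + 1 + rng.integers(3)) % 4]
    return ref, alt


def make_labeled_variants(
    world: World,
    signal: SignalModel,
    seed: int,
    pathogenic_per_disease: int = 3,
    n_benign: int = 80,
) -> tuple[list[LabeledVariant], list[dict[str, float]], dict[str, float]]:
    """A ClinVar-style labeled table for ``world`` plus matching score and
    MAF tables: pathogenic variants sit in each disease's causal gene with
    pathogenic-model scores, benign variants anywhere with benign-model
    scores."""
    rng = np.random.default_rng(seed)
    rows: list[LabeledVariant] = []
    score_tables: list[dict[str, float]] = [{}, {}, {}]
    maf_table: dict[str, float] = {}
    used: set[int] = set()

    def fresh_pos(start: int, end: int) -> int:
        while True:
            p = int(rng.integers(start + 1, end + 1))  # 1-based inside [start,end)
            if p not in used:
                used.add(p)
                return p

    def register(v: VariantRecord, pathogenic: bool) -> None:
        scores = (
            signal.pathogenic_scores(rng) if pathogenic else signal.benign_scores(rng)
        )
        for t, s in zip(score_tables, scores):
            if rng.random() >= signal.missing_rate:
                t[v.key] = s
        maf_table[v.key] = round(float(rng.uniform(0.0, 0.009)), 6)

    for did in sorted(world.diseases):
        chrom, start, end = world.genes.intervals[world.causal_gene[did]]
        for _ in range(pathogenic_per_disease):
            pos = fresh_pos(start, end)
            ref, alt = _random_snv(rng, pos)
            v = VariantRecord(chrom, pos, ref, alt)
            rows.append(LabeledVariant(v, "pathogenic", did))
            register(v, pathogenic=True)
    gene_list = sorted(world.genes.intervals)
    for _ in range(n_benign):
        chrom, start, end = world.genes.intervals[gene_list[rng.integers(len(gene_list))]]
        pos = fresh_pos(start, end)
        ref, alt = _random_snv(rng, pos)
        v = VariantRecord(chrom, pos, ref, alt)
        rows.append(LabeledVariant(v, "benign", None))
        register(v, pathogenic=False)
    return rows, score_tables, maf_table


# ---------------------------------------------------------------------------
# spike-in cases
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CaseTruth:
    disease_id: str
    variant_key: str
    causal_gene: str


@dataclass
class Case:
    """One synthetic patient: background + spiked causative variant."""

    case_id: str
    records: list[VariantRecord]
    score_tables: list[dict[str, float]]
    maf_table: dict[str, float]
    profile: PhenotypeProfile
    truth: CaseTruth


def spike_in_case(
    world: World,
    disease_id: str,
    background_n: int,
    signal: SignalModel,
    seed: int,
    fraction_exonic: float = 0.9,
    case_id: str | None = None,
) -> Case:
    """Insert one causative variant for ``disease_id`` into a background of
    benign variants.

    Background variants are placed uniformly over genes (with probability
    ``fraction_exonic``) or intergenic space, with het/hom genotypes, a
    small fraction of uncalled calls, and a MAF mix of common (filtered
    later), rare, and missing.  The causative variant lands in the
    disease's causal gene, homozygous if the disease is recessive, with
    pathogenic-model scores and missing MAF.
    """
    if disease_id not in world.diseases:
        raise SimulationError(f"unknown disease {disease_id!r}")
    gene = world.causal_gene.get(disease_id)
    if gene is None or gene not in world.genes.intervals:
        raise SimulationError(f"causal gene for {disease_id!r} absent from world")
    rng = np.random.default_rng(seed)
    disease = world.diseases[disease_id]
    gene_list = sorted(world.genes.intervals)
    chrom_span = GENE_SPACING * len(gene_list) + 5_000

    records: list[VariantRecord] = []
    score_tables: list[dict[str, float]] = [{}, {}, {}]
    maf_table: dict[str, float] = {}
    used: set[int] = set()

    def fresh(start: int, end: int) -> int:
        while True:
            p = int(rng.integers(start + 1, end + 1))
            if p not in used:
                used.add(p)
                return p

    for _ in range(background_n):
        if rng.random() < fraction_exonic:
            _, start, end = world.genes.intervals[gene_list[rng.integers(len(gene_list))]]
            pos = fresh(start, end)
        else:
            pos = fresh(0, chrom_span)
        ref, alt = _random_snv(rng, pos)
        u = rng.random()
        genotype = UNCALLED if u < 0.02 else (HET if u < 0.51 else HOM)
        v = VariantRecord("1", pos, ref, alt, genotype=genotype)
        records.append(v)
        for t, s in zip(score_tables, signal.benign_scores(rng)):
            if rng.random() >= signal.missing_rate:
                t[v.key] = s
        m = rng.random()
        if m < 0.25:
            maf_table[v.key] = round(float(rng.uniform(0.02, 0.5)), 6)
        elif m < 0.85:
            maf_table[v.key] = round(float(rng.uniform(0.0, 0.009)), 6)
        # else: MAF unknown (novel variant)

    _, start, end = world.genes.intervals[gene]
    pos = fresh(start, end)
    ref, alt = _random_snv(rng, pos)
    genotype = HOM if disease.moi == "Recessive" else (HET, HOM)[rng.integers(2)]
    causative = VariantRecord("1", pos, ref, alt, genotype=genotype)
    records.append(causative)
    for t, s in zip(score_tables, signal.pathogenic_scores(rng)):
        t[causative.key] = s

    records.sort(key=lambda r: (r.chrom, r.pos, r.ref, r.alt))
    return Case(
        case_id=case_id or f"{disease_id}:case",
        records=records,
        score_tables=score_tables,
        maf_table=maf_table,
        profile=world.profile_of(disease_id),
        truth=CaseTruth(disease_id, causative.key, gene),
    )


# ---------------------------------------------------------------------------
# profile perturbation
# ---------------------------------------------------------------------------


def most_similar_disease(world: World, disease_id: str) -> str:
    """The other disease most phenotypically similar by BMA (full corpus)."""
    engine = world.engine()
    base = world.diseases[disease_id].phenotypes
    best = None
    for did in sorted(world.diseases):
        if did == disease_id or not world.diseases[did].phenotypes:
            continue
        s = engine.bma(base, world.diseases[did].phenotypes)
        if best is None or s > best[0]:
            best = (s, did)
    if best is None:
        raise SimulationError("no second disease available")
    return best[1]


def perturb_profile(
    profile: PhenotypeProfile,
    mode: str,
    world: World,
    seed: int,
    dropout_p: float = 1 / 3,
    disease_id: str | None = None,
) -> PhenotypeProfile:
    """Perturb a patient profile to emulate noisy phenotyping.

    ``comorbid`` unions in a uniformly sampled different disease's
    phenotypes; ``dropout`` removes each class independently with
    probability ``dropout_p``, resampling until at least one class
    survives; ``two-variant`` returns the profile of the most similar
    other disease (for a second spike-in).
    """
    rng = np.random.default_rng(seed)
    if mode == "comorbid":
        others = [
            d
            for d in sorted(world.diseases)
            if d != disease_id
            and world.diseases[d].phenotypes
            and world.diseases[d].phenotypes != profile.phenotypes
        ]
        if not others:
            raise SimulationError("no second disease for co-morbidity")
        second = others[rng.integers(len(others))]
        return PhenotypeProfile(
            profile.phenotypes | world.diseases[second].phenotypes, moi=profile.moi
        )
    if mode == "dropout":
        classes = sorted(profile.phenotypes)
        for _ in range(1000):
            keep = [c for c in classes if rng.random() >= dropout_p]
            if keep:
                return PhenotypeProfile(frozenset(keep), moi=profile.moi)
        # dropout_p ~ 1: guarantee one surviving class
        return PhenotypeProfile(
            frozenset([classes[rng.integers(len(classes))]]), moi=profile.moi
        )
    if mode == "two-variant":
        if disease_id is None:
            raise SimulationError("two-variant mode needs the base disease_id")
        other = most_similar_disease(world, disease_id)
        return world.profile_of(other)
    raise SimulationError(f"unknown perturbation mode {mode!r}")


# ---------------------------------------------------------------------------
# cohort I/O
# ---------------------------------------------------------------------------


def save_world(world: World, out_dir) -> None:
    """Write the pipeline-visible world files (no truth metadata)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_hierarchy(world.hierarchy, out / "ontology")
    write_corpus(world.corpus, out / "corpus.tsv")
    write_disease_table(world.diseases, out / "diseases.tsv")
    write_gene_annotation(world.genes, out / "genes.tsv")
    with open(out / "panel.txt", "w") as fh:
        fh.write("\n".join(world.panel) + "\n")


def load_world_resources(out_dir):
    """Load the pipeline-visible pieces written by :func:`save_world`."""
    out = Path(out_dir)
    hierarchy = read_hierarchy(out / "ontology")
    corpus = read_corpus(out / "corpus.tsv")
    diseases = read_disease_table(out / "diseases.tsv")
    genes = read_gene_annotation(out / "genes.tsv")
    with open(out / "panel.txt") as fh:
        panel = [line.strip() for line in fh if line.strip()]
    return hierarchy, corpus, diseases, genes, panel


def write_case(case: Case, out_dir) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_vcf(case.records, out / "patient.vcf", sample=case.case_id.replace(":", "_"))
    for i, table in enumerate(case.score_tables, start=1):
        write_score_table(table, out / f"scores_{i}.tsv")
    write_score_table(case.maf_table, out / "maf.tsv")
    with open(out / "profile.txt", "w") as fh:
        fh.write("\n".join(sorted(case.profile.phenotypes)) + "\n")
    with open(out / "moi.txt", "w") as fh:
        fh.write((case.profile.moi or "Other") + "\n")


def write_cohort(world: World, cases: Sequence[Case], out_dir) -> None:
    """Write a self-contained cohort directory: world files, one directory
    per case, and the truth table under ``truth/`` (kept separate from
    everything the pipeline reads)."""
    out = Path(out_dir)
    if out.exists():
        shutil.rmtree(out)
    save_world(world, out / "world")
    for case in cases:
        write_case(case, out / "cases" / case.case_id.replace(":", "_"))
    truth_dir = out / "truth"
    truth_dir.mkdir(parents=True, exist_ok=True)
    with open(truth_dir / "truth.tsv", "w") as fh:
        fh.write("case_id\tdisease_id\tvariant_key\tcausal_gene\n")
        for case in cases:
            t = case.truth
            fh.write(
                f"{case.case_id}\t{t.disease_id}\t{t.variant_key}\t{t.causal_gene}\n"
            )


def generate_cohort(
    world: World,
    n_cases: int,
    background_n: int,
    signal: SignalModel,
    seed: int,
    fraction_exonic: float = 0.9,
) -> list[Case]:
    """Spike-in cases cycling through the world's diseases, with per-case
    seeds derived from ``seed``."""
    if n_cases < 1:
        raise SimulationError("n_cases must be >= 1")
    ids = sorted(world.diseases)
    rng = np.random.default_rng(seed)
    case_seeds = rng.integers(0, 2**31 - 1, size=n_cases)
    return [
        spike_in_case(
            world,
            ids[i % len(ids)],
            background_n,
            signal,
            seed=int(case_seeds[i]),
            fraction_exonic=fraction_exonic,
            case_id=f"case_{i:04d}",
        )
        for i in range(n_cases)
    ]
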