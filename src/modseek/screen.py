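"""Subtractive comparative-genomics screen (phylogenetic profiling).

Candidate genes for a trait (here: presence of a tRNA ribose methylation)
are those whose homologs are present in every trait-positive genome and
absent from every trait-negative genome, under a fixed E-value inclusion
criterion, followed by an annotation keyword filter.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence, TextIO, Union

import numpy as np

from .alignment import (
    Proteome,
    ProteinRecord,
    SearchParams,
    SimilarityHit,
    ValidationError,
    search,
)

__all__ = [
    "GenomeLabel",
    "PresenceMatrix",
    "CandidateGene",
    "DEFAULT_KEYWORD_RULES",
    "build_presence_matrix",
    "presence_matrix_from_hits",
    "subtractive_screen",
    "annotation_filter",
    "screen_report",
]

POSITIVE = "positive"
NEGATIVE = "negative"


@dataclass(frozen=True)
class GenomeLabel:
    """A genome and its explicitly assigned trait phenotype."""

    genome_id: str
    phenotype: str

    def __post_init__(self) -> None:
        if self.phenotype not in (POSITIVE, NEGATIVE):
            raise ValidationError(
                f"phenotype must be {POSITIVE!r} or {NEGATIVE!r}, got {self.phenotype!r}"
            )


@dataclass(frozen=True)
class PresenceMatrix:
    """Boolean homolog-presence table: reference genes x labeled genomes.

    The first column is the reference genome itself (all true by
    construction).  ``criterion`` records the E-value threshold used.
    """

    reference_gene_ids: tuple[str, ...]
    genome_labels: tuple[GenomeLabel, ...]
    presence: np.ndarray
    criterion: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "reference_gene_ids", tuple(self.reference_gene_ids))
        object.__setattr__(self, "genome_labels", tuple(self.genome_labels))
        pres = np.asarray(self.presence, dtype=bool)
        if pres.shape != (len(self.reference_gene_ids), len(self.genome_labels)):
            raise ValidationError(
                f"presence table shape {pres.shape} inconsistent with "
                f"{len(self.reference_gene_ids)} genes x {len(self.genome_labels)} genomes"
            )
        object.__setattr__(self, "presence", pres)
        ids = [g.genome_id for g in self.genome_labels]
        if len(set(ids)) != len(ids):
            raise ValidationError("duplicate genome_id in presence matrix")
        if len(self.genome_labels) and not pres[:, 0].all():
            raise ValidationError("reference genome column must be all true")

    def column(self, genome_id: str) -> np.ndarray:
        idx = [g.genome_id for g in self.genome_labels].index(genome_id)
        return self.presence[:, idx]


@dataclass(frozen=True)
class CandidateGene:
    gene_id: str
    annotation: str
    category: str  # rna_methyltransferase | trna_binding | unknown_function | other


# Ordered keyword rules; first matching category wins.  Matching is
# case-insensitive substring search over the annotation text.
DEFAULT_KEYWORD_RULES: tuple[tuple[str, tuple[str, ...]], ...] = (
    ("rna_methyltransferase", ("methyltransferase", "sam", "spou", "trmh")),
    ("trna_binding", ("trna-binding", "thump")),
    ("unknown_function", ("hypothetical", "unknown", "uncharacterized")),
)

RETAINED_CATEGORIES = ("rna_methyltransferase", "trna_binding", "unknown_function")


def build_presence_matrix(
    reference: Proteome,
    others: Sequence[tuple[GenomeLabel, Proteome]],
    params: SearchParams | None = None,
    reciprocal: bool = False,
) -> PresenceMatrix:
    """Search every reference gene against every other proteome.

    presence[gene, genome] is true iff the gene has at least one hit with
    E-value at or below the threshold in that genome's protein set.  The
    reference genome occupies the first (all-true, positive) column.

    With ``reciprocal=True`` a stricter orthology-flavored criterion is
    applied: the gene's best hit in the target proteome must itself hit
    the gene best when searched back against the reference.
    """
    params = params or SearchParams()
    if not len(reference):
        raise ValidationError("reference proteome is empty")
    ids = [reference.genome_id] + [lab.genome_id for lab, _ in others]
    if len(set(ids)) != len(ids):
        raise ValidationError(f"duplicate genome_id among {ids}")
    for lab, prot in others:
        if not len(prot):
            raise ValidationError(f"proteome {lab.genome_id!r} is empty")

    genes = tuple(r.id for r in reference)
    labels = (GenomeLabel(reference.genome_id, POSITIVE),) + tuple(lab for lab, _ in others)
    pres = np.zeros((len(genes), len(labels)), dtype=bool)
    pres[:, 0] = True
    for j, (lab, proteome) in enumerate(others, start=1):
        for i, gene in enumerate(reference):
            hits = search(gene, proteome.records, params)
            if not hits:
                continue
            if reciprocal:
                best = next(r for r in proteome if r.id == hits[0].subject_id)
                back = search(best, reference.records, params)
                pres[i, j] = bool(back) and back[0].subject_id == gene.id
            else:
                pres[i, j] = True
    return PresenceMatrix(genes, labels, pres, params.evalue_threshold)


def presence_matrix_from_hits(
    reference_gene_ids: Sequence[str],
    genome_labels: Sequence[GenomeLabel],
    hits_per_genome: Mapping[str, Iterable[SimilarityHit]],
    evalue_threshold: float = 1e-10,
) -> PresenceMatrix:
    """Build the presence table from precomputed tabular hits.

    ``hits_per_genome`` maps each non-reference genome id to the hits of
    reference genes against that genome (e.g. parsed from BLAST outfmt 6
    files).  The first label is taken to be the reference genome.
    """
    genes = tuple(reference_gene_ids)
    gene_index = {g: i for i, g in enumerate(genes)}
    pres = np.zeros((len(genes), len(genome_labels)), dtype=bool)
    pres[:, 0] = True
    for j, lab in enumerate(genome_labels[1:], start=1):
        for hit in hits_per_genome.get(lab.genome_id, ()):
            if hit.evalue <= evalue_threshold and hit.query_id in gene_index:
                pres[gene_index[hit.query_id], j] = True
    return PresenceMatrix(genes, tuple(genome_labels), pres, evalue_threshold)


def subtractive_screen(matrix: PresenceMatrix) -> list[str]:
    """Genes present in all positive genomes and absent from all negatives.

    Output order follows the reference gene order.
    """
    phen = np.array([g.phenotype == POSITIVE for g in matrix.genome_labels])
    if not phen.any():
        raise ValidationError("at least one positive genome (the reference) is required")
    in_all_pos = matrix.presence[:, phen].all(axis=1)
    in_no_neg = ~matrix.presence[:, ~phen].any(axis=1) if (~phen).any() else np.ones(
        len(matrix.reference_gene_ids), dtype=bool
    )
    keep = in_all_pos & in_no_neg
    return [g for g, k in zip(matrix.reference_gene_ids, keep) if k]


def categorize(annotation: str, rules: Sequence[tuple[str, Sequence[str]]]) -> str:
    text = annotation.lower()
    for category, keywords in rules:
        if any(kw.lower() in text for kw in keywords):
            return category
    return "other"


def annotation_filter(
    candidates: Sequence[ProteinRecord | tuple[str, str]],
    rules: Sequence[tuple[str, Sequence[str]]] = DEFAULT_KEYWORD_RULES,
) -> list[CandidateGene]:
    """Keep candidates annotated as RNA methyltransferase, tRNA-binding,
    or function-unknown; drop everything else.  Input order is preserved
    and each retained gene carries its matched category.
    """
    if not rules:
        raise ValidationError("keyword rule list must not be empty")
    out: list[CandidateGene] = []
    for cand in candidates:
        if isinstance(cand, ProteinRecord):
            gene_id, annotation = cand.id, cand.description
        else:
            gene_id, annotation = cand
        category = categorize(annotation, rules)
        if category in RETAINED_CATEGORIES:
            out.append(CandidateGene(gene_id, annotation, category))
    return out


def screen_report(
    matrix: PresenceMatrix,
    candidates: Sequence[CandidateGene],
    annotations: Mapping[str, str],
    dest_tsv: Union[str, Path, TextIO, None] = None,
) -> dict:
    """Stage-count funnel and per-candidate table for a completed screen.

    Returns a JSON-serializable summary: total reference genes, genes
    shared with every positive genome, genes surviving subtraction, and
    genes surviving the annotation filter.  If ``dest_tsv`` is given the
    candidate table (gene, category, annotation, per-genome presence
    string) is written there.
    """
    phen = np.array([g.phenotype == POSITIVE for g in matrix.genome_labels])
    shared_pos = int(matrix.presence[:, phen].all(axis=1).sum())
    subtracted = subtractive_screen(matrix)
    summary = {
        "total_reference_genes": len(matrix.reference_gene_ids),
        "shared_with_positives": shared_pos,
        "after_subtraction": len(subtracted),
        "after_annotation_filter": len(candidates),
        "criterion_evalue": matrix.criterion,
        "genomes": [
            {"genome_id": g.genome_id, "phenotype": g.phenotype}
            for g in matrix.genome_labels
        ],
        "candidates": [
            {"gene_id": c.gene_id, "category": c.category, "annotation": c.annotation}
            for c in candidates
        ],
    }
    if dest_tsv is not None:
        gene_index = {g: i for i, g in enumerate(matrix.reference_gene_ids)}
        lines = ["gene_id\tcategory\tannotation\tpresence"]
        for c in candidates:
            row = matrix.presence[gene_index[c.gene_id]]
            pattern = "".join("+" if x else "-" for x in row)
            lines.append(f"{c.gene_id}\t{c.category}\t{c.annotation}\t{pattern}")
        text = "\n".join(lines) + "\n"
        if isinstance(dest_tsv, (str, Path)):
            Path(dest_tsv).write_text(text)
        else:
            dest_tsv.write(text)
    return summary


def summary_to_json(summary: dict) -> str:
    return json.dumps(summary, indent=2)
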