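"""Protein similarity search used by the subtractive genomic screen.

Implements seeded local alignment with affine gaps and Karlin–Altschul
E-values, i.e. a desk-scale stand-in for a BLASTP presence/absence
criterion, plus readers/writers for the 12-column tabular hit format so
externally produced hits can be substituted for the internal aligner.

Scoring convention: a gap of length L costs ``gap_open + L * gap_extend``
(the BLASTP convention).  Coordinates in hits are 1-based inclusive.
"""

from __future__ import annotations

import io
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence, TextIO, Union

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord
from skbio.alignment import pair_align
from skbio.sequence import SubstitutionMatrix

__all__ = [
    "AMINO_ACIDS",
    "ProteinRecord",
    "Proteome",
    "SearchParams",
    "LocalAlignment",
    "SimilarityHit",
    "SearchHits",
    "smith_waterman",
    "evalue",
    "search",
    "read_fasta",
    "write_fasta",
    "read_tabular_hits",
    "write_tabular_hits",
]

#: the 20 standard amino acids; X is additionally accepted as "unknown"
AMINO_ACIDS = frozenset("ACDEFGHIKLMNPQRSTVWY")

_TABULAR_COLUMNS = 12


class ValidationError(ValueError):
    """Raised when an input record violates a declared invariant."""


@dataclass(frozen=True)
class ProteinRecord:
    """A protein sequence with its identifier and free-text annotation."""

    id: str
    sequence: str
    description: str = ""

    def __post_init__(self) -> None:
        if not self.id:
            raise ValidationError("protein record id must be nonempty")
        if not self.sequence:
            raise ValidationError(f"protein {self.id!r}: sequence must be nonempty")
        for pos, letter in enumerate(self.sequence, start=1):
            if letter not in AMINO_ACIDS and letter != "X":
                raise ValidationError(
                    f"protein {self.id!r}: invalid letter {letter!r} at position {pos}"
                )

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class Proteome:
    """A named collection of protein records (one genome's protein set)."""

    genome_id: str
    records: tuple[ProteinRecord, ...]

    def __post_init__(self) -> None:
        ids = [r.id for r in self.records]
        if len(set(ids)) != len(ids):
            dup = sorted({i for i in ids if ids.count(i) > 1})
            raise ValidationError(
                f"proteome {self.genome_id!r}: duplicate record ids {dup}"
            )
        object.__setattr__(self, "records", tuple(self.records))

    def __iter__(self):
        return iter(self.records)

    def __len__(self) -> int:
        return len(self.records)

    @property
    def residue_count(self) -> int:
        return sum(len(r) for r in self.records)


def _default_matrix() -> SubstitutionMatrix:
    return SubstitutionMatrix.by_name("BLOSUM62")


@dataclass(frozen=True)
class SearchParams:
    """Parameters of the local-alignment search and its E-value statistics.

    Defaults mirror standard gapped BLASTP settings: BLOSUM62, gap open 11,
    gap extend 1, Karlin–Altschul lambda 0.267 and K 0.041, word size 3,
    inclusion threshold E <= 1e-10.
    """

    matrix_name: str = "BLOSUM62"
    gap_open: int = 11
    gap_extend: int = 1
    evalue_threshold: float = 1e-10
    seed_length: int = 3
    ka_lambda: float = 0.267
    ka_k: float = 0.041
    matrix: SubstitutionMatrix | None = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        if self.gap_open < 0 or self.gap_extend < 0:
            raise ValidationError("gap penalties must be nonnegative")
        if self.gap_extend > self.gap_open:
            raise ValidationError("gap_extend must not exceed gap_open")
        if not self.evalue_threshold > 0:
            raise ValidationError("evalue_threshold must be positive")
        if self.seed_length < 1:
            raise ValidationError("seed_length must be a positive integer")
        if not (self.ka_lambda > 0 and self.ka_k > 0):
            raise ValidationError("Karlin-Altschul lambda and K must be positive")
        if self.matrix is None:
            object.__setattr__(self, "matrix", SubstitutionMatrix.by_name(self.matrix_name))
        scores = self.matrix.scores
        if not (scores == scores.T).all():
            raise ValidationError("substitution matrix must be symmetric")

    def score(self, a: str, b: str) -> int:
        """Substitution score of aligning letter ``a`` with letter ``b``."""
        m = self.matrix
        return int(m.scores[m.alphabet.index(a), m.alphabet.index(b)])


@dataclass(frozen=True)
class LocalAlignment:
    """Best-scoring local alignment of two sequences.

    Ranges are 1-based inclusive; an alignment with raw_score 0 has empty
    ranges, represented as ``None``.
    """

    raw_score: int
    query_range: tuple[int, int] | None
    subject_range: tuple[int, int] | None
    identity_fraction: float

    @property
    def is_empty(self) -> bool:
        return self.query_range is None


@dataclass(frozen=True)
class SimilarityHit:
    """One query-vs-subject similarity hit (BLAST outfmt-6 equivalent)."""

    query_id: str
    subject_id: str
    raw_score: int
    evalue: float
    identity_fraction: float
    query_range: tuple[int, int]
    subject_range: tuple[int, int]

    def __post_init__(self) -> None:
        if not self.evalue > 0:
            raise ValidationError("evalue must be positive")
        if not 0.0 <= self.identity_fraction <= 1.0:
            raise ValidationError("identity_fraction must lie in [0, 1]")


class SearchHits(list):
    """Hit list returned by :func:`search`.

    Behaves as a plain list of :class:`SimilarityHit`, with the ids of
    subjects skipped by the seed filter (no shared seed word, hence never
    aligned) exposed on ``skipped_no_seed`` so that seeding is flagged
    rather than silent.
    """

    def __init__(self, hits: Iterable[SimilarityHit] = (), skipped_no_seed: Sequence[str] = ()):
        super().__init__(hits)
        self.skipped_no_seed: tuple[str, ...] = tuple(skipped_no_seed)


def _validate_protein_letters(seq: str, label: str) -> None:
    for pos, letter in enumerate(seq, start=1):
        if letter not in AMINO_ACIDS and letter != "X":
            raise ValidationError(f"{label}: invalid letter {letter!r} at position {pos}")


def smith_waterman(a: str, b: str, params: SearchParams | None = None) -> LocalAlignment:
    """Best local alignment of protein sequences ``a`` and ``b``.

    Returns the optimal Smith–Waterman score under affine gap scoring
    (gap of length L costs ``gap_open + L * gap_extend``), with 1-based
    inclusive aligned ranges and the identity fraction over aligned
    columns.  If no cell scores positively the result has score 0 and
    empty ranges.
    """
    params = params or SearchParams()
    if not a or not b:
        return LocalAlignment(0, None, None, 0.0)
    _validate_protein_letters(a, "query")
    _validate_protein_letters(b, "subject")

    res = pair_align(
        a,
        b,
        mode="local",
        sub_score=params.matrix,
        gap_cost=(params.gap_open, params.gap_extend),
        max_paths=1,
    )
    score = int(res.score)
    if score <= 0:
        return LocalAlignment(0, None, None, 0.0)
    path = res.paths[0]
    (q0, q1), (s0, s1) = path.ranges
    qaln, saln = path.to_aligned((a, b))
    ncols = len(qaln)
    nident = sum(1 for x, y in zip(qaln, saln) if x == y)
    return LocalAlignment(
        raw_score=score,
        query_range=(int(q0) + 1, int(q1)),
        subject_range=(int(s0) + 1, int(s1)),
        identity_fraction=nident / ncols if ncols else 0.0,
    )


def evalue(raw_score: float, m: int, n: int, params: SearchParams | None = None) -> float:
    """Karlin–Altschul expected number of chance hits, E = K·m·n·e^(−λS).

    ``m`` is the query length and ``n`` the total residue count of the
    database searched.  Strictly decreasing in the score and linear in
    the search space; no length corrections are applied.
    """
    params = params or SearchParams()
    if m < 1 or n < 1:
        raise ValidationError("search-space dimensions m, n must be >= 1")
    return params.ka_k * m * n * math.exp(-params.ka_lambda * raw_score)


def _kmer_set(seq: str, k: int) -> set[str]:
    return {seq[i : i + k] for i in range(len(seq) - k + 1)}


def search(
    query: ProteinRecord,
    database: Sequence[ProteinRecord],
    params: SearchParams | None = None,
    *,
    seeded: bool = True,
) -> SearchHits:
    """All subjects whose best local alignment to ``query`` passes the E-value
    threshold, sorted by ascending E-value (ties: higher score, then
    lexicographic subject id).

    With ``seeded=True`` (default) subjects sharing no exact seed word of
    length ``params.seed_length`` with the query are skipped without
    alignment; their ids are reported on ``SearchHits.skipped_no_seed``.
    """
    params = params or SearchParams()
    if not database:
        return SearchHits()
    n_db = sum(len(r) for r in database)
    m = len(query)
    qk = _kmer_set(query.sequence, params.seed_length) if seeded else None

    hits: list[SimilarityHit] = []
    skipped: list[str] = []
    for subject in database:
        if seeded and qk is not None and qk.isdisjoint(_kmer_set(subject.sequence, params.seed_length)):
            skipped.append(subject.id)
            continue
        res = pair_align(
            query.sequence,
            subject.sequence,
            mode="local",
            sub_score=params.matrix,
            gap_cost=(params.gap_open, params.gap_extend),
            max_paths=0,
        )
        score = int(res.score)
        if score <= 0:
            continue
        e = evalue(score, m, n_db, params)
        if e > params.evalue_threshold:
            continue
        aln = smith_waterman(query.sequence, subject.sequence, params)
        hits.append(
            SimilarityHit(
                query_id=query.id,
                subject_id=subject.id,
                raw_score=aln.raw_score,
                evalue=e,
                identity_fraction=aln.identity_fraction,
                query_range=aln.query_range,
                subject_range=aln.subject_range,
            )
        )
    hits.sort(key=lambda h: (h.evalue, -h.raw_score, h.subject_id))
    return SearchHits(hits, skipped)


# ---------------------------------------------------------------------------
# File formats


def read_fasta(source: Union[str, Path, TextIO], genome_id: str | None = None) -> Proteome:
    """Read a proteome from FASTA; ``genome_id`` defaults to the file stem."""
    if genome_id is None:
        genome_id = Path(source).stem if isinstance(source, (str, Path)) else "proteome"
    records = tuple(
        ProteinRecord(
            id=rec.id,
            sequence=str(rec.seq).upper(),
            description=rec.description[len(rec.id) :].strip(),
        )
        for rec in SeqIO.parse(source, "fasta")
    )
    return Proteome(genome_id=genome_id, records=records)


def write_fasta(proteome: Proteome, dest: Union[str, Path, TextIO]) -> None:
    recs = [
        SeqRecord(Seq(r.sequence), id=r.id, description=r.description)
        for r in proteome.records
    ]
    SeqIO.write(recs, dest, "fasta")


class TabularParseError(ValueError):
    """Raised for malformed tabular hit input; carries the line number."""

    def __init__(self, line_number: int, message: str):
        super().__init__(f"line {line_number}: {message}")
        self.line_number = line_number


def read_tabular_hits(source: Union[str, Path, TextIO]) -> list[SimilarityHit]:
    """Parse 12-column tab-separated hits (BLAST outfmt 6 dialect).

    Columns: query, subject, %identity, alignment length, mismatches,
    gap opens, qstart, qend, sstart, send, evalue, bitscore.  The bit
    score column is stored as ``raw_score`` (rounded to int).
    """
    if isinstance(source, (str, Path)):
        with open(source) as fh:
            return read_tabular_hits(fh)
    hits: list[SimilarityHit] = []
    for lineno, line in enumerate(source, start=1):
        line = line.rstrip("\n")
        if not line or line.startswith("#"):
            continue
        fields = line.split("\t")
        if len(fields) != _TABULAR_COLUMNS:
            raise TabularParseError(
                lineno, f"expected {_TABULAR_COLUMNS} tab-separated columns, got {len(fields)}"
            )
        try:
            pident = float(fields[2])
            qstart, qend = int(fields[6]), int(fields[7])
            sstart, send = int(fields[8]), int(fields[9])
            ev = float(fields[10])
            score = float(fields[11])
        except ValueError as exc:
            raise TabularParseError(lineno, f"non-numeric field: {exc}") from None
        hits.append(
            SimilarityHit(
                query_id=fields[0],
                subject_id=fields[1],
                raw_score=int(round(score)),
                evalue=ev,
                identity_fraction=pident / 100.0,
                query_range=(qstart, qend),
                subject_range=(sstart, send),
            )
        )
    return hits


def write_tabular_hits(hits: Iterable[SimilarityHit], dest: Union[str, Path, TextIO]) -> None:
    """Write hits in the 12-column tabular dialect read by :func:`read_tabular_hits`.

    Mismatch and gap-open counts are not tracked by the internal aligner
    and are written as 0; alignment length is taken from the query range.
    """
    if isinstance(dest, (str, Path)):
        with open(dest, "w") as fh:
            write_tabular_hits(hits, fh)
        return
    for h in hits:
        alen = h.query_range[1] - h.query_range[0] + 1
        dest.write(
            "\t".join(
                [
                    h.query_id,
                    h.subject_id,
                    f"{h.identity_fraction * 100:.3f}",
                    str(alen),
                    "0",
                    "0",
                    str(h.query_range[0]),
                    str(h.query_range[1]),
                    str(h.subject_range[0]),
                    str(h.subject_range[1]),
                    f"{h.evalue:.2e}",
                    str(h.raw_score),
                ]
            )
            + "\n"
        )


def hits_to_string(hits: Iterable[SimilarityHit]) -> str:
    buf = io.StringIO()
    write_tabular_hits(hits, buf)
    return buf.getvalue()
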