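"""Modification-aware in-silico ribonuclease digestion.

RNase T1 cleaves 3' of guanosine, RNase A 3' of pyrimidines; both act
through the ribose 2'-OH, so a 2'-O-methyl on the residue 5' of the
scissile bond blocks cleavage — the diagnostic "missed cleavage" used to
localize ribose methylations.  Base methylations (e.g. m5C) never block.
Products carry 5'-OH and a 3'-phosphate (linear by default, 2',3'-cyclic
by option); alkaline phosphatase strips all terminal phosphates.  A
three-step nucleoside digest (P1 nuclease, phosphodiesterase, alkaline
phosphatase) reduces the RNA to free nucleosides.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, TextIO, Union

from .rna import ModifiedRnaSequence, Residue, RnaValidationError, residues_to_string

__all__ = [
    "EnzymeSpec",
    "DigestOptions",
    "Fragment",
    "RNASE_T1",
    "RNASE_A",
    "ENZYMES",
    "cleavage_sites",
    "digest",
    "nucleoside_digest",
    "write_fragment_table",
    "read_fragment_table",
]


@dataclass(frozen=True)
class EnzymeSpec:
    """A ribonuclease's cleavage specificity."""

    name: str
    cleaves_after_bases: frozenset[str]
    blocked_by_ribose_methyl: bool = True
    product_3prime: str = "linear_phosphate"  # or "cyclic_phosphate"
    product_5prime: str = "OH"

    def __post_init__(self) -> None:
        object.__setattr__(self, "cleaves_after_bases", frozenset(self.cleaves_after_bases))
        if not self.cleaves_after_bases:
            raise RnaValidationError(f"enzyme {self.name!r} cleaves after no base")


RNASE_T1 = EnzymeSpec("RNase T1", frozenset({"G"}))
RNASE_A = EnzymeSpec("RNase A", frozenset({"C", "U"}))
ENZYMES = {"RNase T1": RNASE_T1, "RNase A": RNASE_A, "T1": RNASE_T1, "A": RNASE_A}


@dataclass(frozen=True)
class DigestOptions:
    """Options applied to every digest product.

    ``phosphatase`` converts all terminal phosphates (3' linear or
    cyclic, and 5' mono/tri) to hydroxyls, as calf intestinal alkaline
    phosphatase would.  ``partial_missed_cleavages`` additionally emits
    fragments spanning up to that many skipped cleavable sites
    (modification blocking is not a missed cleavage).
    """

    phosphatase: bool = False
    partial_missed_cleavages: int = 0

    def __post_init__(self) -> None:
        if self.partial_missed_cleavages < 0:
            raise RnaValidationError("partial_missed_cleavages must be >= 0")


@dataclass(frozen=True)
class Fragment:
    """A contiguous slice of a parent RNA with its own termini.

    ``start``/``end`` are 1-based inclusive parent coordinates; residues
    (with modifications) equal the parent slice.  ``missed_cleavages``
    counts deliberately skipped cleavable sites (partial digestion);
    sites blocked by 2'-O-methylation do not count.
    """

    parent_name: str
    start: int
    end: int
    residues: tuple[Residue, ...]
    five_prime: str = "OH"
    three_prime: str = "linear_phosphate"
    missed_cleavages: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "residues", tuple(self.residues))
        if not 1 <= self.start <= self.end:
            raise RnaValidationError(f"bad fragment coordinates {self.start}..{self.end}")
        if len(self.residues) != self.end - self.start + 1:
            raise RnaValidationError("fragment residues inconsistent with coordinates")

    def __len__(self) -> int:
        return len(self.residues)

    @property
    def bases(self) -> str:
        return "".join(r.base for r in self.residues)

    def to_string(self) -> str:
        return residues_to_string(self.residues)


def cleavage_sites(rna: ModifiedRnaSequence, enzyme: EnzymeSpec) -> list[int]:
    """Positions i such that the bond between residues i and i+1 is cleaved.

    A site exists where the base is in the enzyme's specificity set, the
    residue is not 2'-O-methylated (when the enzyme requires the 2'-OH),
    and a downstream residue exists.
    """
    sites = []
    for i, res in enumerate(rna.residues[:-1], start=1):
        if res.base not in enzyme.cleaves_after_bases:
            continue
        if enzyme.blocked_by_ribose_methyl and res.ribose_methyl:
            continue
        sites.append(i)
    return sites


def _strip_phosphates(frag: Fragment) -> Fragment:
    five = "OH" if frag.five_prime in ("monophosphate", "triphosphate") else frag.five_prime
    three = "OH" if frag.three_prime in ("linear_phosphate", "cyclic_phosphate") else frag.three_prime
    return replace(frag, five_prime=five, three_prime=three)


def digest(
    rna: ModifiedRnaSequence,
    enzyme: EnzymeSpec,
    options: DigestOptions | None = None,
) -> list[Fragment]:
    """Complete digest of ``rna``; fragments tile the parent exactly.

    Every cleavage-generated terminus gets the enzyme's product
    chemistry (5'-OH downstream, 3'-phosphate upstream); the parent's
    own termini are preserved on the outermost fragment ends.  With
    ``partial_missed_cleavages = k`` the full-digest fragments are
    followed by every fragment spanning 1..k skipped sites, in order of
    start position then missed-cleavage count.
    """
    options = options or DigestOptions()
    sites = cleavage_sites(rna, enzyme)
    bounds = [0] + sites + [len(rna)]  # fragment i spans bounds[i]+1 .. bounds[i+1]

    def make(seg_lo: int, seg_hi: int, missed: int) -> Fragment:
        start, end = bounds[seg_lo] + 1, bounds[seg_hi]
        five = rna.five_prime if start == 1 else enzyme.product_5prime
        three = rna.three_prime if end == len(rna) else enzyme.product_3prime
        frag = Fragment(
            parent_name=rna.name,
            start=start,
            end=end,
            residues=rna.residues[start - 1 : end],
            five_prime=five,
            three_prime=three,
            missed_cleavages=missed,
        )
        return _strip_phosphates(frag) if options.phosphatase else frag

    n_seg = len(bounds) - 1
    fragments = [make(i, i + 1, 0) for i in range(n_seg)]
    for k in range(1, options.partial_missed_cleavages + 1):
        for i in range(n_seg - k):
            fragments.append(make(i, i + 1 + k, k))
    fragments.sort(key=lambda f: (f.start, f.missed_cleavages, f.end))
    return fragments


def nucleoside_digest(rna: ModifiedRnaSequence) -> Counter:
    """Free-nucleoside composition after the three-step digestion.

    Every residue contributes one nucleoside; modified residues keep
    their codes (Cm counts as Cm, not C).  The total equals the length.
    """
    return Counter(r.code for r in rna.residues)


# ---------------------------------------------------------------------------
# Tab-separated fragment table (consumed by the mass module / CLI)

_HEADER = "parent\tstart\tend\tsequence\tfive_prime\tthree_prime\tmissed_cleavages"


def write_fragment_table(fragments: Iterable[Fragment], dest: Union[str, Path, TextIO]) -> None:
    if isinstance(dest, (str, Path)):
        with open(dest, "w") as fh:
            write_fragment_table(fragments, fh)
        return
    dest.write(_HEADER + "\n")
    for f in fragments:
        dest.write(
            f"{f.parent_name}\t{f.start}\t{f.end}\t{f.to_string()}\t"
            f"{f.five_prime}\t{f.three_prime}\t{f.missed_cleavages}\n"
        )


def read_fragment_table(source: Union[str, Path, TextIO]) -> list[Fragment]:
    from .rna import parse_residues

    if isinstance(source, (str, Path)):
        with open(source) as fh:
            return read_fragment_table(fh)
    fragments = []
    for lineno, line in enumerate(source, start=1):
        line = line.rstrip("\n")
        if not line or line == _HEADER:
            continue
        fields = line.split("\t")
        if len(fields) != 7:
            raise RnaValidationError(f"line {lineno}: expected 7 columns")
        fragments.append(
            Fragment(
                parent_name=fields[0],
                start=int(fields[1]),
                end=int(fields[2]),
                residues=parse_residues(fields[3]),
                five_prime=fields[4],
                three_prime=fields[5],
                missed_cleavages=int(fields[6]),
            )
        )
    return fragments
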