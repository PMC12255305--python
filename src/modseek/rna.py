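"""Modified RNA sequences, tRNA acceptor-stem numbering, and the
substrate-determinant rules of the tRNA:Cm6 methyltransferase.

Sequences are ordered residues, each a base A/C/G/U with an optional
modification code from the registry, plus explicit 5'/3' terminal
chemistries.  tRNA constructs additionally carry an annotation mapping
residue indices (1-based) to canonical cloverleaf position labels, the
set of arms present, and whether the discriminator is retained.

The substrate rules encode three experimental determinants of the
enzyme: the tRNA must end in CCA (the THUMP domain grips the 3' end),
the base at acceptor-stem position 6 must not be guanine (G6 is a
negative determinant), and the molecule must offer more than a bare
acceptor-stem micro-helix.  A position 6 that is already
2'-O-methylated is the reaction product, not a substrate.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Sequence, TextIO, Union

from .modifications import MODIFICATIONS, ModificationEntry

__all__ = [
    "Residue",
    "ModifiedRnaSequence",
    "TrnaAnnotation",
    "SubstrateVerdict",
    "RULE_CCA",
    "RULE_NO_G6",
    "RULE_BEYOND_MICROHELIX",
    "RULE_ALREADY_METHYLATED",
    "acceptor_pair_partner",
    "mutate_pair",
    "has_cca_terminus",
    "predict_trmts_substrate",
    "parse_residues",
    "residues_to_string",
    "read_sequences",
    "write_sequences",
]

BASES = ("A", "C", "G", "U")
WATSON_CRICK = {("A", "U"), ("U", "A"), ("G", "C"), ("C", "G")}

FIVE_PRIME_STATES = ("OH", "monophosphate", "triphosphate")
THREE_PRIME_STATES = ("OH", "linear_phosphate", "cyclic_phosphate")

ARMS = ("acceptor", "D", "anticodon", "T")

# substrate-rule codes
RULE_CCA = "R1"  # CCA terminus required
RULE_NO_G6 = "R2"  # guanine at position 6 is a negative determinant
RULE_BEYOND_MICROHELIX = "R3"  # more than a bare acceptor micro-helix required
RULE_ALREADY_METHYLATED = "PRODUCT"  # position 6 already 2'-O-methylated


class RnaValidationError(ValueError):
    pass


@dataclass(frozen=True)
class Residue:
    """One nucleotide: base plus optional modification code."""

    base: str
    mod_code: str | None = None

    def __post_init__(self) -> None:
        if self.base not in BASES:
            raise RnaValidationError(f"base must be one of A/C/G/U, got {self.base!r}")
        if self.mod_code is not None:
            entry = MODIFICATIONS.get(self.mod_code)
            if entry is None:
                raise RnaValidationError(f"unknown modification code {self.mod_code!r}")
            if entry.parent_base != self.base:
                raise RnaValidationError(
                    f"modification {self.mod_code!r} requires base "
                    f"{entry.parent_base!r}, found {self.base!r}"
                )

    @property
    def modification(self) -> ModificationEntry | None:
        return MODIFICATIONS[self.mod_code] if self.mod_code else None

    @property
    def ribose_methyl(self) -> bool:
        return bool(self.mod_code) and MODIFICATIONS[self.mod_code].ribose_methyl

    @property
    def code(self) -> str:
        """Display code: the modification code if present, else the base."""
        return self.mod_code if self.mod_code else self.base


@dataclass(frozen=True)
class ModifiedRnaSequence:
    """An RNA with per-residue modifications and terminal chemistries."""

    name: str
    residues: tuple[Residue, ...]
    five_prime: str = "OH"
    three_prime: str = "OH"

    def __post_init__(self) -> None:
        object.__setattr__(self, "residues", tuple(self.residues))
        if len(self.residues) < 1:
            raise RnaValidationError(f"sequence {self.name!r} must have length >= 1")
        if self.five_prime not in FIVE_PRIME_STATES:
            raise RnaValidationError(f"invalid 5' terminus {self.five_prime!r}")
        if self.three_prime not in THREE_PRIME_STATES:
            raise RnaValidationError(f"invalid 3' terminus {self.three_prime!r}")

    def __len__(self) -> int:
        return len(self.residues)

    @property
    def bases(self) -> str:
        return "".join(r.base for r in self.residues)

    def to_string(self) -> str:
        return residues_to_string(self.residues)

    @classmethod
    def from_string(
        cls,
        name: str,
        text: str,
        five_prime: str = "OH",
        three_prime: str = "OH",
    ) -> "ModifiedRnaSequence":
        return cls(name, parse_residues(text), five_prime, three_prime)


@dataclass(frozen=True)
class TrnaAnnotation:
    """Canonical cloverleaf labeling of a (possibly truncated) construct.

    ``canonical_position_map`` maps 1-based residue indices to canonical
    position labels (a subset of 1..76).  The acceptor arm is always
    present; truncated constructs list only the arms they retain.
    """

    canonical_position_map: dict[int, int]
    arms_present: frozenset[str] = frozenset({"acceptor"})
    has_discriminator: bool = True

    def __post_init__(self) -> None:
        object.__setattr__(self, "arms_present", frozenset(self.arms_present))
        if "acceptor" not in self.arms_present:
            raise RnaValidationError("the acceptor arm is always present")
        unknown = self.arms_present - set(ARMS)
        if unknown:
            raise RnaValidationError(f"unknown arms {sorted(unknown)}")
        labels = list(self.canonical_position_map.values())
        if len(set(labels)) != len(labels):
            raise RnaValidationError("canonical position labels must be unique")

    def index_of(self, canonical_position: int) -> int | None:
        """1-based residue index carrying a canonical label, or None."""
        for idx, label in self.canonical_position_map.items():
            if label == canonical_position:
                return idx
        return None


@dataclass(frozen=True)
class SubstrateVerdict:
    is_substrate: bool
    reasons: tuple[str, ...]  # codes of every failed rule (empty if substrate)


def acceptor_pair_partner(position: int) -> int:
    """Acceptor-stem pairing partner: position i (1..7) pairs with 73 - i.

    Position 6 pairs with 67, position 1 with 72.
    """
    if not 1 <= position <= 7:
        raise RnaValidationError(
            f"acceptor-stem position must be in 1..7, got {position}"
        )
    return 73 - position


def mutate_pair(
    trna: ModifiedRnaSequence,
    annotation: TrnaAnnotation,
    position: int,
    new_pair: str | tuple[str, str],
) -> ModifiedRnaSequence:
    """Replace the base pair at acceptor-stem ``position``/partner with a
    Watson-Crick pair, clearing any modifications on the two residues.

    ``new_pair`` gives (base at position, base at partner), e.g. "AU" to
    turn C6-G67 into A6-U67.  All other residues are untouched.
    """
    b1, b2 = tuple(new_pair)
    if (b1, b2) not in WATSON_CRICK:
        raise RnaValidationError(f"{b1}-{b2} is not a Watson-Crick pair")
    partner = acceptor_pair_partner(position)
    i = annotation.index_of(position)
    j = annotation.index_of(partner)
    if i is None or j is None:
        raise RnaValidationError(
            f"positions {position} and {partner} must both be mapped"
        )
    residues = list(trna.residues)
    residues[i - 1] = Residue(b1)
    residues[j - 1] = Residue(b2)
    return replace(trna, residues=tuple(residues))


def has_cca_terminus(trna: ModifiedRnaSequence) -> bool:
    """True iff the last three residues read C, C, A (bases only)."""
    if len(trna) < 3:
        return False
    return tuple(r.base for r in trna.residues[-3:]) == ("C", "C", "A")


def predict_trmts_substrate(
    trna: ModifiedRnaSequence, annotation: TrnaAnnotation
) -> SubstrateVerdict:
    """Apply the enzyme's substrate-determinant rules to a construct.

    The construct is a substrate iff it (R1) carries the 3'-CCA
    terminus, (R2) does not have guanine at acceptor position 6, and
    (R3) retains at least one arm (D, anticodon or T) beyond the
    acceptor stem.  A construct whose position 6 is already
    2'-O-methylated is the product state and is reported as a
    non-substrate with its own code.  ``reasons`` lists every failed
    rule; a substrate has an empty reason list.
    """
    extra_arms = annotation.arms_present - {"acceptor"}
    idx6 = annotation.index_of(6)
    if idx6 is None:
        if extra_arms:
            raise RnaValidationError(
                "canonical position 6 is unmapped but the annotation claims "
                "arms beyond the acceptor stem"
            )
        return SubstrateVerdict(False, (RULE_NO_G6,))
    res6 = trna.residues[idx6 - 1]

    reasons: list[str] = []
    if not has_cca_terminus(trna):
        reasons.append(RULE_CCA)
    if res6.base == "G":
        reasons.append(RULE_NO_G6)
    if not extra_arms:
        reasons.append(RULE_BEYOND_MICROHELIX)
    if res6.ribose_methyl:
        reasons.append(RULE_ALREADY_METHYLATED)
    return SubstrateVerdict(not reasons, tuple(reasons))


# ---------------------------------------------------------------------------
# Compact text representation: "GGGGGC{Cm}GU" writes residue 6 as a
# cytidine carrying the Cm modification.

_TOKEN = re.compile(r"([ACGU])(\{([A-Za-z0-9]+)\})?")


def parse_residues(text: str) -> tuple[Residue, ...]:
    residues: list[Residue] = []
    pos = 0
    text = text.strip()
    while pos < len(text):
        m = _TOKEN.match(text, pos)
        if m is None:
            raise RnaValidationError(
                f"cannot parse residue at character {pos + 1} of {text!r}"
            )
        residues.append(Residue(m.group(1), m.group(3)))
        pos = m.end()
    return tuple(residues)


def residues_to_string(residues: Sequence[Residue]) -> str:
    out = []
    for r in residues:
        out.append(f"{r.base}{{{r.mod_code}}}" if r.mod_code else r.base)
    return "".join(out)


# ---------------------------------------------------------------------------
# Record format: one construct per record —
#   >name five_prime=OH three_prime=OH [arms=acceptor+D] [discriminator=yes]
#   [posmap=1:1,2:2,...]
#   GGGGGC{Cm}GU...


def _format_header(seq: ModifiedRnaSequence, ann: TrnaAnnotation | None) -> str:
    parts = [f">{seq.name}", f"five_prime={seq.five_prime}", f"three_prime={seq.three_prime}"]
    if ann is not None:
        parts.append("arms=" + "+".join(a for a in ARMS if a in ann.arms_present))
        parts.append(f"discriminator={'yes' if ann.has_discriminator else 'no'}")
        posmap = ",".join(f"{i}:{p}" for i, p in sorted(ann.canonical_position_map.items()))
        parts.append(f"posmap={posmap}")
    return " ".join(parts)


def write_sequences(
    records: Iterable[tuple[ModifiedRnaSequence, TrnaAnnotation | None]],
    dest: Union[str, Path, TextIO],
) -> None:
    if isinstance(dest, (str, Path)):
        with open(dest, "w") as fh:
            write_sequences(records, fh)
        return
    for seq, ann in records:
        dest.write(_format_header(seq, ann) + "\n")
        dest.write(seq.to_string() + "\n")


def read_sequences(
    source: Union[str, Path, TextIO],
) -> list[tuple[ModifiedRnaSequence, TrnaAnnotation | None]]:
    if isinstance(source, (str, Path)):
        with open(source) as fh:
            return read_sequences(fh)
    records: list[tuple[ModifiedRnaSequence, TrnaAnnotation | None]] = []
    header: str | None = None
    for raw in source:
        line = raw.strip()
        if not line:
            continue
        if line.startswith(">"):
            if header is not None:
                raise RnaValidationError(f"header {header!r} has no sequence line")
            header = line
            continue
        if header is None:
            raise RnaValidationError("sequence line before any header")
        fields = header[1:].split()
        name = fields[0]
        kv = dict(f.split("=", 1) for f in fields[1:])
        seq = ModifiedRnaSequence(
            name,
            parse_residues(line),
            kv.get("five_prime", "OH"),
            kv.get("three_prime", "OH"),
        )
        ann = None
        if "posmap" in kv:
            posmap = {
                int(i): int(p)
                for i, p in (pair.split(":") for pair in kv["posmap"].split(","))
            }
            arms = frozenset(kv.get("arms", "acceptor").split("+"))
            ann = TrnaAnnotation(
                posmap, arms, kv.get("discriminator", "yes") == "yes"
            )
        records.append((seq, ann))
        header = None
    if header is not None:
        raise RnaValidationError(f"header {header!r} has no sequence line")
    return records
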