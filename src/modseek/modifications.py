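"""Registry of RNA modifications known to the toolkit.

Each entry records the parent base, the elemental delta relative to the
unmodified nucleoside, and whether the methyl group sits on the ribose
2'-oxygen (which is what blocks ribonuclease transesterification) or on
the base (which does not).
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = ["ModificationEntry", "MODIFICATIONS", "register_modification"]


@dataclass(frozen=True)
class ModificationEntry:
    code: str
    parent_base: str  # A, C, G or U
    delta_formula: dict[str, int]  # elemental delta vs the parent nucleoside
    ribose_methyl: bool

    def __post_init__(self) -> None:
        if self.parent_base not in "ACGU":
            raise ValueError(f"parent_base must be one of A/C/G/U, got {self.parent_base!r}")
        if self.ribose_methyl and self.delta_formula != {"C": 1, "H": 2}:
            raise ValueError(
                f"2'-O-methyl code {self.code!r} must have delta exactly CH2"
            )


_CH2 = {"C": 1, "H": 2}

MODIFICATIONS: dict[str, ModificationEntry] = {}


def register_modification(entry: ModificationEntry) -> None:
    MODIFICATIONS[entry.code] = entry


for _code, _base, _ribose in [
    ("Am", "A", True),
    ("Cm", "C", True),
    ("Gm", "G", True),
    ("Um", "U", True),
    ("m5C", "C", False),  # 5-methylcytidine: same +CH2, base methylation
    ("m5U", "U", False),
    ("m1A", "A", False),
]:
    register_modification(ModificationEntry(_code, _base, dict(_CH2), _ribose))
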