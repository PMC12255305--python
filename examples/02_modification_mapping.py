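"""Locate a 2'-O-methylation by modification-aware in-silico digestion.

A 2'-O-methyl on the residue 5' of a scissile bond blocks ribonuclease
transesterification.  Digesting the Cm6-modified transcript with RNase A
therefore yields a missed-cleavage octamer spanning the C6-G7 bond, and
RNase T1 yields a +14.0157 Da shifted trinucleotide — the two mass
signatures this example computes and then feeds to the localizer.
"""

import dataclasses

from modseek.digestion import DigestOptions, RNASE_A, RNASE_T1, digest
from modseek.masscalc import fragment_mass, localize_ribose_methyl, mz_negative
from modseek.rna import ModifiedRnaSequence
from modseek.simulate import make_wt_trna

modified, _ = make_wt_trna(cm6=True)
control, _ = make_wt_trna(cm6=False)
control = dataclasses.replace(control, name=modified.name)  # same parent

# RNase A + phosphatase: the missed-cleavage octamer
frags = digest(modified, RNASE_A, DigestOptions(phosphatase=True))
octamer = next(f for f in frags if (f.start, f.end) == (1, 8))
print(f"RNase A octamer {octamer.to_string()}  "
      f"M = {fragment_mass(octamer):.4f} Da  "
      f"[M-3H]3- m/z = {mz_negative(fragment_mass(octamer), 3):.4f}")

# RNase T1 on a C-Cm-G context: the mass-shifted trinucleotide
tri_parent = ModifiedRnaSequence.from_string("pro-like", "GCC{Cm}GU")
tri = next(f for f in digest(tri_parent, RNASE_T1) if f.to_string() == "CC{Cm}G")
print(f"RNase T1 trinucleotide {tri.to_string()}p  "
      f"[M-H]- m/z = {mz_negative(fragment_mass(tri), 1):.4f}")

# control-vs-modified comparison localizes the methyl
calls = localize_ribose_methyl(
    digest(control, RNASE_A, DigestOptions(phosphatase=True)),
    digest(modified, RNASE_A, DigestOptions(phosphatase=True)),
)
for c in calls:
    print(f"localization: position {c.position} "
          f"({c.evidence} evidence, fragment {c.fragment_range}, "
          f"mass delta {c.mass_delta:+.4f} Da)")
# Expect m/z ~876.80 and ~986.15 for the two diagnostic ions, and a
# blocking-evidence call at position 6 with a +14.0157 Da delta.
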