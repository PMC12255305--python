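"""Apply the substrate-determinant rules to the twelve-construct panel.

Three rules decide whether a construct can be methylated at acceptor
position 6: R1 — the 3' end must read CCA (the tRNA-gripping THUMP
domain requires it); R2 — guanine at position 6 is a negative
determinant; R3 — a bare acceptor-stem micro-helix is not enough.  A
construct already carrying the 2'-O-methyl is the product state.
"""

from modseek.rna import predict_trmts_substrate
from modseek.simulate import make_trna_panel, make_wt_trna

print(f"{'construct':<12} {'substrate':<10} {'failed rules':<14} expected")
for entry in make_trna_panel():
    v = predict_trmts_substrate(entry.sequence, entry.annotation)
    print(f"{entry.name:<12} {'yes' if v.is_substrate else 'no':<10} "
          f"{','.join(v.reasons) if v.reasons else '-':<14} "
          f"{'yes' if entry.expected_substrate else 'no'}")

seq, ann = make_wt_trna(cm6=True)
v = predict_trmts_substrate(seq, ann)
print(f"\nCm6-modified WT: substrate={v.is_substrate} reasons={v.reasons}"
      "  (already methylated: product, not substrate)")
# All twelve verdicts should match the expected column; the nine
# substrates have no failed rules.
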