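"""Assemble an RNA-binding motif from tripartite recognition motifs.

Each Puf repeat reads one base through the residues at window positions
1 and 5 (position 2 stacks).  The repeat array runs antiparallel to the
RNA, so the N-terminal repeat binds the 3'-most base.  The TRM list below
is the Puf3-type assignment that yields the canonical complete motif.
"""

from pufsf import TRM, assemble_motif, default_code_table, write_motif_meme

table = default_code_table()
print("Packaged TRM code (pos1, pos5) -> base:")
for (p1, p5), base in table.entries.items():
    print(f"  ({p1}, {p5}) -> {base}")

trms = [TRM(*t) for t in [
    ("C", "R", "Q"), ("N", "Y", "Q"), ("N", "Y", "Q"), ("N", "Y", "Q"),
    ("C", "R", "Q"), ("N", "Y", "Q"), ("S", "N", "E"), ("N", "Y", "Q"),
]]
m = assemble_motif(trms, table=table, orientation="antiparallel")
print(f"\nTRMs (N->C): {[f'{t.pos1}{t.pos2}..{t.pos5}' for t in trms]}")
print(f"assembled motif: 5'-{m.motif}-3' (completeness {m.completeness:.0%})")
print("repeat contributing each position (5'->3'):", m.source_repeats)

print("\nMEME minimal format:")
print(write_motif_meme({"Puf3_type": m.motif}))
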