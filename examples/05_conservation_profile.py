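"""Per-column conservation profile of a small nucleotide alignment.

The fraction is the modal non-gap, non-ambiguous symbol count over the
number of rows; bins follow the >80 / >60 / >40 percent-identity display
convention used to colour alignment figures.
"""

from pufsf import conservation_profile

alignment = [
    "UGUAAAUA-A",
    "UGUAUAUAAA",
    "UGUACAUA-A",
    "UGUAUAUACA",
    "UGCAUAUA--",
]
prof = conservation_profile(alignment, ambiguous=frozenset("N"))
print("col  fraction  bin")
for i, (f, b) in enumerate(zip(prof.fractions, prof.bins), 1):
    print(f"{i:3d}  {f:8.2f}  {b}")
print("\nColumns 1-8 hold the conserved core motif; the gapped tail scores low.")
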