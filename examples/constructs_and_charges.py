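"""Assemble the Cdc12-derived peptide constructs and inspect their charges.

Builds the extended AH (34 aa) and the three tandem constructs from their
canonical segments, then prints per-construct length and net side-chain
charge at pH 7.4 (capped termini) and the residue-class composition of
the extended AH.  The +3 of the C-terminal 8-mer is the charge that
drives its electrostatic attraction to phosphate headgroups.
"""

from septah import build_construct, net_charge
from septah.constructs import CONSTRUCT_NAMES, residue_class_table

for name in CONSTRUCT_NAMES:
    spec = build_construct(name)
    print(f"{name:24s} {len(spec):3d} aa  net charge {net_charge(spec.sequence):+d}")
    print(f"  {spec.sequence}")

ext = build_construct("extended_AH")
counts: dict[str, int] = {}
for _, _, cls, _ in residue_class_table(ext.sequence):
    counts[cls] = counts.get(cls, 0) + 1
print("\nextended AH residue classes:", counts)
print("C-terminal 8-mer", ext.sequence[-8:], "net charge",
      f"{net_charge(ext.sequence[-8:]):+d}")
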