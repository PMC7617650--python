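"""Decoy design: swap protein-binding elements for a microRNA element.

Starting from a scaffold carrying three PRE (Pumilio recognition
element, UGUANAUA) sites, replace each with the let-7 response element
CUACCUCA — the rule used to convert a Pumilio decoy into a microRNA
sponge while keeping the structural scaffold.
"""

import chimeramap as cm

unit = "GAAAAUUGUAUAUAAAUCAA"  # tandem repeat unit carrying one PRE
linker = "GGCUACGGAUCC"
scaffold = linker + unit + linker + unit + linker + unit + linker

sites = []
pos = len(linker)
for _ in range(3):
    start = pos + unit.index("UUGUAUAUA") + 1  # the PRE octamer
    sites.append((start, start + 8))
    pos += len(unit) + len(linker)

print(f"scaffold: {len(scaffold)} nt, PRE count = {cm.count_motif(scaffold, 'UGUANAUA')}")
decoy = cm.design_decoy(scaffold, sites, "CUACCUCA")
print(f"decoy:    {len(decoy)} nt, PRE count = {cm.count_motif(decoy, 'UGUANAUA')}, "
      f"MRE count = {cm.count_motif(decoy, 'CUACCUCA')}")
print(f"G/C content: scaffold {cm.gc_content(scaffold):.3f} -> decoy {cm.gc_content(decoy):.3f}")
# Three PREs become three let-7 MREs; the rest of the scaffold (and its
# fold) is untouched.
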