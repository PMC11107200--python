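"""Glutathionyl-ligand transplant and steric-clash screening.

Superposes the corrin of a source complex onto a target pocket and moves
only the glutathione across. An open pocket accepts the ligand with zero
clashes; a pocket with a blocking atom 1.0 Å above the ligand's terminal
oxygen shows exactly one overlap of r_C + r_O − soft_tol − 1.0 = 1.82 Å.
"""

from cblpocket import transplant
from cblpocket.synthetic import make_pocket

source = make_pocket(seed=0)
open_pocket = make_pocket(seed=1)
blocked_pocket = make_pocket(block_offset=1.0, seed=0)

for label, target in (("open", open_pocket), ("blocked", blocked_pocket)):
    rep = transplant(source, target)
    print(f"{label:8s} pocket: {rep.n_clashes} clash(es), "
          f"worst overlap {rep.worst_overlap:.2f} A, "
          f"corrin fit rmsd {rep.corrin_fit_rmsd:.3f} A")
    for c in rep.clashes:
        print(f"  ligand {c.ligand_atom} vs {c.res_name}{c.res_seq}/{c.atom}: "
              f"overlap {c.overlap:.2f} A{' (severe)' if c.severe else ''}")

print()
print("A clash means the transplanted ligand atom penetrates the target's")
print("van der Waals envelope beyond the 0.4 A soft tolerance — the pocket")
print("cannot accommodate the beta-ligand without rearrangement.")
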