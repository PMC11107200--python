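"""Corrin butterfly fold angle and axial coordination on a synthetic cobalamin.

Builds an idealized corrin with a prescribed 6.6° fold and a thiolate sulfur
2.4 Å above cobalt (the glutathionyl-cobalamin arrangement), then recovers
the geometry with the analysis code.
"""

from cblpocket import corrin_report
from cblpocket.synthetic import make_corrin

structure = make_corrin(fold_angle=6.6, beta_ligand_dist=2.4, seed=0)
report = corrin_report(structure)

print(f"fold angle      : {report.fold_angle:.2f} deg")
print(f"Co–DMB-N (alpha): {report.co_alpha_dist:.2f} A")
print(f"Co–S (beta)     : {report.co_beta_dist:.2f} A  ({report.beta_ligand_identity})")
print(f"base-on         : {report.base_on}")
print()
print("The fold angle is the tilt between the two corrin half-ring planes")
print("(shared atom C10); 6.6 deg is a gently folded, base-on cobalamin with")
print("a thiolate occupying the upper axial site.")
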