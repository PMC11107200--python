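# Methods

This note records the models, numerical choices and limitations behind each
analysis stage, and what the synthetic generators do and do not emulate.

## Atom model and element parameters

Structures are parsed with gemmi (PDB and mmCIF) into a flat, ordered list
of atom records; all ATOM/HETATM records are kept, including waters,
alternate locations and insertion codes. Geometry always runs on a
single-conformer view: per (chain, residue, atom) the highest-occupancy
altloc is kept, ties broken by altloc identifier order, so results are
reproducible for residues modelled in two conformations (the β-face
histidine loop of transcobalamin is the motivating case). Hydrogens are
retained in the model but carry no radius weight: surface areas and clash
checks use a united-atom picture.

Van der Waals radii (Å): C 1.70, N 1.55, O 1.52, S 1.80, P 1.80, Co 1.26,
fallback 1.70, overridable per element. Cobalt uses an ionic/metallic
radius because only coordination geometry and packing are modelled, not
electronic structure. Polar atoms are all N and O; sulfur is excluded from
the polar-contact fingerprint by default (thioether and metal-bonded
sulfurs dominate in this system).

Cobalamin is located chemically — one cobalt with ≥ 4 nitrogens within
2.5 Å — rather than by component code, because the hydroxo-, glutathionyl-
and cyano- forms are deposited under different three-letter codes. The
α-axial (DMB) nitrogen is the non-equatorial coordinating N; the β-axial
atom is the nearest non-ring heavy atom within 3.0 Å on the opposite face.
The base-on call uses a 2.5 Å α-distance threshold; both cutoffs bracket
the 2.1–2.4 Å coordination bonds seen in high-resolution cobalamin
structures with margin and are configurable.

## Corrin fold angle

Each half-ring plane is fitted by total least squares (eigenvector of the
coordinate covariance with smallest eigenvalue); the fold angle is the
angle between the two normals folded into [0°, 90°], so the sign of the
fold and the labelling of the halves are immaterial (both are tested
properties). C10 participates in both planes, exactly as the atom-list
definition implies. Collinear point sets are rejected rather than silently
fitted.

## Superposition

Kabsch via SVD of the cross-covariance of centered coordinates. The
reflection case (det < 0) is corrected by flipping the smallest singular
vector — only proper rotations are chemically meaningful. Cross-structure
Cα RMSD uses every mutually aligned residue pair with both Cα atoms
present; there is no outlier trimming or iterative rejection, so values for
diverged orthologs sit slightly above what trimming protocols report.
Domain profiles fit the transform on one residue interval and report
per-residue deviations over another.

## Surface areas and interfaces

Shrake–Rupley quadrature with a deterministic golden-spiral point lattice,
960 points per atom and a 1.4 Å water probe by default. The quadrature
error for an isolated sphere is below 1%, and the two-sphere buried patch
agrees with the closed-form lens-cap area and an independent Monte-Carlo
surface-sampling oracle to within 2% (both are acceptance checks). Waters
are excluded from interface components — interface areas are computed
solvent-free, the convention interface servers use — but participate in
contact analysis. Buried area is symmetrized exactly by computing the
union SASA over a canonically sorted atom list.

The α/β-domain split is a configuration input (residue intervals). The
default heuristic takes the β-domain as the C-terminal ubiquitin-like
segment after the interdomain linker (split at residue 330 in full-length
rat-transcobalamin numbering); no structure-derived boundary detection is
attempted.

Polar contacts are distance-only (3.5 Å donor–acceptor cutoff, no angular
term): dashed-bond contact counts in structure figures are conventionally
distance-based, and angle criteria would add a parameter the analysis
cannot calibrate. Each (ligand atom, protein atom) pair counts once; a
water bridge counts once per (ligand atom, water, protein atom) triple, and
a pair already in direct contact is not re-counted through a water.
Contacts are counted per atom pair, not per residue. Disulfides are Cys
Sγ–Sγ pairs within 2.5 Å, paired greedily by ascending distance so no
cysteine is used twice.

## Ligand transplantation

The corrins of source and target are matched by atom name over the 13
butterfly atoms plus cobalt (≥ 8 matches required; fit RMSD above 1.5 Å is
an error, not a warning). Only the glutathione atoms move; the target keeps
its own cobalamin, mirroring how such comparisons are constructed
graphically. Clash targets exclude waters and the target's own cobalamin
and β-ligand. The soft tolerance of 0.4 Å is a conventional van der Waals
overlap allowance; overlaps whose raw vdW interpenetration reaches 0.6 Å
are tiered "severe". No side-chain repacking or minimization is attempted —
a clash therefore means "not accommodated as-is", not "cannot bind".

## Spectra

Comparisons interpolate both spectra linearly onto a common 1 nm grid over
the overlap of their supports, then area-normalize (trapezoidal integral of
|A| = 1). Band metrics are the per-window argmax position and height; the
default windows are γ 340–370 nm and α/β 490–580 nm, the standard cobalamin
band regions, both configurable. A flat window yields a warning value at
the window midpoint rather than an arbitrary argmax. Stability series
report the L2 distance of each area-normalized spectrum from the reference
plus the Kendall tau of drift against time; tau near +1 indicates steady
decay, near 0 a stable sample. Inputs are assumed blank-corrected; no
scatter or baseline modelling is applied.

## MST fitting

Fnorm is the hot/cold fluorescence ratio in per-mil. The binding model is
the 1:1 quadratic (probe-depletion) isotherm; fitting uses
Levenberg–Marquardt least squares over (baseline, amplitude, log10 K_D)
with five log-spaced K_D starts spanning the concentration range, keeping
the best final cost. Requirements: ≥ 6 concentrations spanning ≥ 3 decades.
If the fitted amplitude is below 3× the residual SD the fit raises a
no-binding error instead of reporting a meaningless K_D. A fitted K_D at or
below the probe concentration is flagged `kd_is_lower_limit`: with probe
above K_D the titration midpoint is set by the probe and tighter affinities
are indistinguishable. In the low-probe limit the model reduces to the
hyperbolic isotherm (tested at probe = K_D/1000, 1% agreement).

## Sequence analysis

Pairwise global alignment uses biopython's PairwiseAligner (BLOSUM62, gap
open 10, extend 0.5, end gaps scored); scores are verified against an
exhaustive alignment enumeration on short sequences. Identity is identical
columns over mutually aligned columns, excluding terminal overhangs. This
is not byte-identical to every MSA tool's convention; published identity
values computed with other tools should be compared with a ±2-point
allowance. Conservation mapping is pairwise against the chosen reference
(full-length rat-transcobalamin numbering); no multiple-sequence alignment
is built, since every question in scope is reference-anchored.

## Synthetic generators

The generators exist to give every analysis a controlled truth, not to be
realistic:

* **Corrin**: canonical planar template (Co at origin, equatorial N at
  1.9 Å, ring carbons at in-plane positions following the macrocycle
  connectivity, DMB nitrogen 2.2 Å below Co). Folding rotates the
  C11–C19/N23/N24 half about the Co–C10 axis, so the generated butterfly
  angle equals the parameter exactly; optional Gaussian coordinate jitter
  (0.01 Å in the headline computation, the coordinate-precision scale of
  atomic-resolution structures) perturbs it realistically. No conformational
  strain, substituents, or crystallographic noise model.
* **Pocket**: the corrin plus a 7-atom glutathione-like chain with one
  direct H-bond (2.9 Å), one water bridge (2.8 Å legs) and a deliberately
  isolated terminal oxygen, so a blocking atom placed above it produces
  exactly one hand-computable overlap; a 180-atom pseudo-protein shell at
  16 Å guarantees the far field is inert. Real pockets bury the ligand on
  all sides; passing these tests shows the bookkeeping is right, not that
  real interface areas are reproduced.
* **Spectra**: Gaussian band sums on a 300–700 nm, 1 nm grid. The
  glutathionyl-like preset conserves total band area (intensity lost from γ
  reappears under α/β) so the γ-collapse ratio under area normalization
  equals the generated ratio exactly.
* **MST**: 16-point two-fold dilution from 800 nM, probe 625 pM — a
  standard assay layout; i.i.d. Gaussian noise on ΔFnorm (real error bars
  are SDs over repeated measurements). Traces are piecewise-linear
  cold/ramp/hot profiles whose Fnorm reproduces the isotherm exactly when
  noiseless.
* **Sequences**: substitution-only homologs, so identity is exactly
  (L − k)/L.

All generators are bit-deterministic under a fixed seed.

## Problem sizes

The shipped tests and the acceptance script run entirely on these synthetic
inputs: ~220-atom pockets, 16-point titrations, 25–200 seeded repeats for
recovery statistics, 960-point SASA quadrature (240 points for the
three-component interface demonstration). These sizes make every recovery
statistic stable at the tolerances asserted while the whole suite completes
in well under a minute.

## Known limitations

* Regressions against deposited crystal structures and UniProt sequences
  require the user to supply those files locally; the package never
  downloads by default.
* No symmetry expansion or biological-assembly handling; analyses use the
  deposited asymmetric unit.
* Clash screening is rigid; no energetics, flexibility or repacking.
* Polar contacts are distance-only; no donor/acceptor chemistry beyond the
  N/O classification, no salt-bridge discrimination.
* MST fitting assumes 1:1 stoichiometry and a concentration-independent
  amplitude; no aggregation or photobleaching diagnostics.
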