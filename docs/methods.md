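# Methods

## Physical model

A titratable sidechain is treated as a two-state unit: neutral (all charge
atoms at 0 e) or ionised, with the formal charge split over the
charge-bearing atoms (Asp/Glu: −0.5 on each carboxylate oxygen; His: +0.5
on ND1 and NE2; Lys: +1 on NZ; Arg: +1/3 on NE, NH1, NH2). Only these
five types titrate; Cys, Tyr and chain termini are deliberately excluded,
and non-site protein atoms carry no partial charges. This is a pKa-*shift*
model: everything that is identical between the protein environment and
the isolated-residue reference cancels, so the absence of a full
force-field charge set costs far less accuracy than it would in an
absolute free-energy calculation. Retained HETATM ions (Ca²⁺, Zn²⁺, Mg²⁺,
Na⁺, K⁺, Cl⁻) are the only background charges; by default all of them —
and waters, which the continuum already represents — are stripped before
any calculation, and stripping is logged per ion.

The electrostatic response is linearised Poisson–Boltzmann:

    ∇·(ε(r)∇φ) − ε_w κ²(r) φ = −4π·332.064·ρ(r)

with ε_p = 4 inside the union of united-atom spheres (C 1.7, N 1.5,
O 1.4, S 1.85, P 1.9 Å; hydrogens implicit), ε_w = 78.4 outside, mobile
ions excluded from the protein interior plus a 2 Å Stern layer, and
κ = 0.127 Å⁻¹ at the default 0.15 M, 298.15 K. Linearisation is adequate
because site charges are ±1 e and only energy *differences* enter the pKa;
it also makes Coulomb and screened-Coulomb closed forms exact limits of
the solver, which the test suite exploits as oracles.

## Numerics

The equation is discretised on a cubic grid (7-point stencil, harmonic
mean edge dielectrics) and solved by diagonally preconditioned conjugate
gradients to a relative residual of 1e-8. The dielectric at each node is
antialiased: the node's protein-volume fraction is estimated from the
signed distance to the nearest atom surface over one grid cell and mixed
linearly between ε_p and ε_w. A convergence study on a half-buried
aspartate (the regime the frustration call depends on) showed the binary
in/out assignment drifting by >1 kcal/mol between 0.8 and 0.4 Å spacing,
while the smoothed boundary moves ~0.1 kcal/mol; the smoothed form is
therefore the implementation and the suite pins the halving-stability
property at <0.7 kcal/mol.

Grids: a structure whose bounding box plus 10 Å solvent padding fits in
34 Å is solved on a single 0.6 Å grid with analytic Debye–Hückel boundary
potentials; larger systems use two-level focusing (1.2 Å coarse grid over
the whole molecule with DH boundaries, then a 30 Å / 0.6 Å fine box on
the site whose boundary is interpolated from the coarse solution).
Source charges are spread trilinearly; the singular grid self-energy
cancels exactly because the protein-environment and reference solutions
share one grid and one charge spreading.

Energy terms per site:

- `dG_desolv = ½ Σ q·[φ_protein(r) − φ_reference(r)]` over the site's own
  ionised charges, where the reference calculation keeps only the site's
  residue as dielectric material — the in-silico model compound. For a
  fully exposed single residue the two systems coincide and the shift is
  exactly zero, which is why the pipeline recovers 4.0/4.4/6.3/10.4/12.0
  on the synthetic model compounds.
- `dG_back = Σ q_bg·φ_protein(r_bg)` over retained formal ion charges.
- `W_ij`: the FDPB field of site i evaluated at site j's charges when the
  charge centroids are within 12 Å (both directions averaged, enforcing
  reciprocity), and the analytic DH energy between net site charges
  beyond. 12 Å is where the dielectric heterogeneity correction to DH
  falls below the grid noise for typical sites, and it keeps every
  short-range pair inside the 30 Å fine box.

## Titration statistics

Microstate energies in units of ln10·RT are
`E(x, pH) = Σ x_i γ_i (pH − pKa_intr,i) + Σ_{i<j} x_i x_j W_ij`. Up to 15
sites the 2ⁿ sum is evaluated exactly (this is also the oracle for the
sampler); beyond that, single-flip Metropolis Monte Carlo runs 10⁵
recorded sweeps after 10⁴ burn-in per pH point with a per-pH seed offset,
making results bit-reproducible for a fixed seed (default 42).
Enumeration is refused above 25 sites. The protonated species is the
neutral form for acids and the charged form for bases, so every curve is
non-increasing in pH; curves violating monotonicity beyond the sampler's
noise tolerance (0.02) raise instead of silently reporting a pKa. pKa½ is
the linear interpolation of the θ = 0.5 crossing on the default pH grid 0
to 14 in 0.2 steps; a curve that never crosses reports a bound ("> 14",
"< 0"). Reported ΔpKa magnitudes are capped at 5 for display (a capped
acid shift prints as pKa "> model+5"); raw values are kept internally and
in the TSV output.

## Frustration encoding and verdicts

Scaled score = 10·ΔpKa·s with s = −1 for acids and +1 for bases, clamped
to [−50, 50], so negative always reads "ionised form destabilised". The
score is written into the fixed-format B-factor column of a standard PDB
file (all atoms of a scored residue carry the residue score, everything
else 0.00) for colour ramping in any viewer. Sites are categorised
destabilised/neutral/stabilised at |scaled| > 5 (0.5 pKa units) — a
reporting convenience over the continuous score, threshold exposed in the
API.

The holo/apo comparison pairs sites by author residue label (or an
explicit map for renumbered homologues; sequence alignment is out of
scope), always strips the metal from both arms, and computes per-residue
`relaxation_delta` = holo destabilising shift − apo destabilising shift
(0 when the apo side is disordered). Verdict, at a threshold of 1.5 pKa
units (about the smallest shift worth calling functionally meaningful;
configurable): **pH-coupled** if any ordered apo site retains a
destabilising shift ≥ threshold; **decoupled-by-disorder** if every
holo-frustrated site is missing from the apo model; **decoupled-by-
relaxation** if all apo sites are ordered and relaxed; **mixed**
otherwise. Raising the threshold can only move a comparison away from
pH-coupled, never towards it.

Residues in the selection sphere whose charge-bearing atoms are absent
from the model are reported as "disordered", never silently dropped —
missing density at a binding site is itself the signal that drives the
decoupled-by-disorder verdict.

## Synthetic benchmark structures

The generators produce the four regimes the method must rank correctly,
with ground truth known by construction:

- **model compound** — one ideal-geometry blocked residue (internal
  torsion-space templates; no rotamer library), fully exposed: ΔpKa = 0.
- **charge pair** — two exposed residues at an exact centroid separation:
  coupling must approach the DH closed form and vanish by 30 Å.
- **buried site** — a residue inside a ball of neutral carbon pseudo-atoms
  (lattice spacing 1.8 Å, clearing the residue by 2.6 Å) covering a
  chosen solid-angle fraction: desolvation must grow monotonically from
  ~0 to between the exposed and infinite-medium Born limits.
- **clasp** — n carboxylates with centroids ringing a Ca²⁺ position at
  3.2 Å (the centroid distance implied by bidentate Ca–O coordination at
  ~2.4 Å), sidechains pointing inward, half-buried by a pseudo-atom cap;
  the apo partner has the same residues displaced outward to twice the
  ring radius, unburied, ion-free. Defaults (4 acids, ring 3.2 Å, burial
  0.5) were fixed from coordination geometry considerations. Run through
  the full pipeline, the ion-stripped holo arm yields uniformly
  destabilised carboxylates holding ~2 protons at pH 7.4, the apo arm
  titrates at reference values, and the comparison returns
  decoupled-by-relaxation.

What these fixtures do *not* emulate: real sidechain conformational
heterogeneity, backbone dipoles and the full fixed-charge background,
crevice-scale solvent structure, or membrane environments. Passing the
synthetic suite therefore demonstrates the machinery (solver, statistics,
encoding, comparison logic) and the qualitative mechanism, not agreement
with experimental pKas on deposited structures, which additionally
depends on the charge/radius parameterisation and is exercised separately
by the accession regression checks when those files are present.

## Problem sizes and determinism

Default grids keep desk-scale analyses fast: a model compound solves in
under a second, the full clasp comparison in ~15 s, and a 15-site Monte
Carlo titration in a few seconds. All pipeline outputs are deterministic
for fixed inputs and seed; TSVs are written with fixed float formatting
so repeated runs are byte-identical.

## Known limitations

- Two-state sites without His tautomer resolution or coupled proton
  positions; no conformational relaxation is simulated — relaxation
  enters only through comparing experimentally determined structure
  pairs, which is the point of the design.
- The linear PB + united-atom + formal-charge combination is a screening
  tool: per-residue errors of ±1–2 pKa units against experiment are
  expected for buried sites, and bound values ("> 9") should be read as
  "well above neutral pH" rather than as numbers.
- Ion placement enters only through deposited HETATM records; no site
  prediction.
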