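# Methods

This note documents the models, conventions and numerical choices behind
`pprkit`, in the order a design-and-validate workflow uses them. Coordinates
are 1-based and inclusive throughout, matching crystallographic residue
numbering.

## The PPR code as a probabilistic table

A PPR repeat's base preference is represented as a probability profile over
{A, C, G, U} keyed by the amino-acid pair at repeat positions 5 and 35. The
literature supports qualitative specificity only (which base(s) a code
reads, not by how much), so profiles are generated from a single
*specificity mass* parameter: an exact code entry places 0.90 (default,
configurable) on its recognized base set — split equally when the set is
degenerate, e.g. NN → 0.45/0.45 on U/C — and spreads the remainder uniformly
over the other bases. 0.90 keeps the per-position argmax unambiguous while
leaving the profiles soft enough for log-odds site scoring.

Codes without an exact entry fall back on position-5 chemistry, which is the
chief determinant of specificity: asparagine at 5 → pyrimidine-weighted
(U = C = 0.35), serine or threonine at 5 → purine-weighted (A = G = 0.35),
alanine/glycine at 5 → a mild purine tilt only (A = G = 0.30), reflecting
that small residues accommodate purines without conferring real
specificity. Anything else scores uniform (0.25 each). Consequences that
hold for every one of the 400 possible pairs: profiles are simplex-valid,
N-at-5 codes always satisfy P(U)+P(C) > P(A)+P(G), and S/T-at-5 codes the
converse. The table is a documented YAML dialect; the packaged default
ships with the seven literature codes (ND, NS, SN, TD, NN, TN, SD).

Relative affinities among the four canonical codes are not resolved in the
available data, so exact-code profiles are deliberately uniform across
codes. T in RNA-typed input is silently mapped to U with a logged warning
(DNA-typed input tolerated); other non-ACGU characters are rejected with
the offending position named.

## Designer construct assembly

A design is NTD + one 35-aa repeat per target nucleotide + CTD, N-to-C
matching 5′-to-3′. Each repeat is the scaffold template with positions 5/35
substituted by the canonical design code of its nucleotide (U→ND, C→NS,
A→SN, G→TD), or by an explicit per-position override. Only the pyrimidine
ambiguity code Y is accepted (behind a flag), mapping to NN — the only
degenerate code with support; other IUPAC codes have no supported
counterpart and are rejected. Targets outside the natural 2–30 repeat range
assemble with a warning rather than an error.

**The packaged scaffold is synthetic.** The repeat template is a constructed
consensus-style helical-hairpin sequence, not a published one: it has the
architectural features the toolkit's logic depends on — exactly 35 residues,
free code slots at 5/35, a hydrophobic clamp valine at position 2 and the
phosphate-binding lysine at position 13 — and the caps are synthetic helical
sequences of 51 (NTD) and 49 (CTD) residues, sized so that the documented
numbering offset of 122 reproduces the crystal-construct convention
(construct 123–572, repeats 174–523 for a ten-repeat design). Every
sequence-level result in the test suite is scaffold-relative (architecture,
code placement, round-trip identity) and holds for any user-supplied
scaffold YAML; none depends on the synthetic letters themselves. What
passing tests therefore do *not* show is anything about the folding,
solubility or affinity of a construct built on the synthetic letters — for
wet-lab use, supply the real template and caps as a scaffold file.

## Repeat detection and target prediction

Detection uses a 35×20 log-odds PSSM (bits, uniform 1/20 background) built
from the scaffold template: non-slot columns are pseudocount-smoothed
one-hot distributions, p(aa) = (1[aa = template] + α/20)/(1 + α) with
α = 0.1; columns 5 and 35 are identically zero because the code slots carry
no detection information. Every 35-residue window (stride 1) is scored;
windows above 0.6 × the maximum attainable score (configurable) become
candidates, chained greedily N-to-C at spacing 35 ± 1 residue; chains
shorter than two repeats are dropped. Designed arrays hit exact 35 spacing
and the maximum score outside the slots; the ±1 tolerance and the
pseudocount exist for natural, degenerate repeats — on which the
consensus-derived PSSM is best-effort, not trained (no P-type alignment
behind it). The 0.6 threshold was chosen to pass two opposing property
suites: exact recovery of designed arrays and zero arrays on
composition-matched shuffles of them.

Target prediction reads the (5,35) residues of each detected repeat and
stacks their code profiles into a position probability matrix; transcript
scanning scores every sense-strand window by Σ log2(p_row(base)/background)
with uniform background (PPRs bind ssRNA, so no reverse complement), breaks
ties by transcript order then position, and can attach empirical p-values
from seeded mononucleotide shuffles, p = (1 + #null ≥ s)/(1 + #null).
Mismatch count is not calibrated to binding affinity: the soft PPM scores
rank sites but do not predict K_d.

## Superposition

Cα pairs come from a global sequence alignment (match 1, mismatch 0, gap
−1) of the first protein chains, or from deposited residue numbering behind
a flag (the two can differ on engineered constructs; alignment is the
default). The rigid fit is closed-form Kabsch (SVD with the proper-rotation
sign correction). Because published RMSDs for this family are quoted "over
N Cα atoms" with N below the chain length, the fit prunes iteratively:
pairs deviating more than 2.0σ × the current RMSD are discarded and the fit
repeated, up to 5 cycles or convergence (both configurable); an RMSD below
1 × 10⁻⁶ Å short-circuits as converged so identical inputs keep all pairs.
Correctness is checked against an independent quaternion-eigenvalue oracle
(Horn's method, no rotation matrix formed) to 10⁻⁸ Å on small instances,
plus self-superposition and rigid-transform invariance.

## Superhelix geometry

Repeat centroids are mean Cα positions per segmented repeat (35-residue
tiling from an anchor residue, default 174). The axis direction comes from
the centroid *bisectors* b_i = c_{i−1} + c_{i+1} − 2c_i, which are exactly
radial (perpendicular to the axis) for points on a circular helix: the axis
is the smallest right singular vector of the stacked bisectors, oriented
along the repeat progression. This is unbiased for short or partial-turn
solenoids, where the principal component of the centroid cloud is not the
axis. The axis position is a least-squares (Kåsa) circle fit of the
centroids projected onto the normal plane. Rise is the mean consecutive
axial spacing; twist the mean signed angle between consecutive radial
vectors (right-hand rule about the axis, so positive twist = right-handed
along 5′→3′); period = rise × 360/|twist|; diameter = 2 × mean centroid
radius — the definition used here, since published "diameter" and "polar
axis" figures come with no stated definition (the axis length is therefore
not tested against). Fewer than 4 repeats, collinear centroids, or zero
twist raise explicit degenerate-geometry errors. Recovery is exact on
generated ideal solenoids (the generator places repeat centroids exactly on
the helix by giving each repeat zero-sum atom offsets) and is swept over
rise 3–10 Å, twist 10–60°, radius 10–40 Å, 5–15 repeats at a 1% tolerance.

## Recognition contacts

Crystal structures of this family (2.2–2.6 Å) resolve no hydrogens, so a
hydrogen bond here is a heavy-atom criterion only: donor/acceptor N/O pairs
within 3.5 Å (configurable), with no angle term — a documented relaxation
of stricter geometric definitions. Repeat i is paired with the i-th
nucleotide of the RNA chain in 5′→3′ order. Direct bonds are searched
between position-5/35 side-chain N/O atoms and the Watson–Crick-face atoms
(pyrimidine O2/N3/O4(N4); purine N1/N2/N3/O6/N6); donor/acceptor roles are
assigned from a fixed polarity table (e.g. U N3 donates, C N3 accepts, G
N1/N2 donate, A N1 accepts) — the chemistry that lets a single water
discriminate U from C. A *water bridge* is a water oxygen within cutoff of
both the base N3 and a polar position-35 side-chain atom. The contact
report adds Val2 sandwiches (any residue-2 side-chain heavy atom within
4.5 Å of the base ring of its own and of the preceding nucleotide) and
Lys13 salt bridges (NZ within 4.0 Å of any phosphate oxygen); repeats whose
position-2/13 side chains are unmodelled are flagged incomplete rather than
scored absent. All cutoffs are config-exposed. Altlocs resolve to the
highest-occupancy conformer, ties to file order.

These rules are exercised on a packaged *synthetic* two-repeat complex with
hand-planted geometry (one direct Asn5–O2 bond, one Asp35 water bridge, one
Val2 sandwich, one Lys13 salt bridge, plus an empty/incomplete second
repeat); tests against the deposited dPPR–RNA structures run only when
those files are locally available, since they cannot be redistributed here.

## Binding isotherm

The quantitation model is the protein-excess isotherm
f = [P]^h/(K_d^h + [P]^h) with h = 1 by default (monomeric 1:1 complexes;
free-h fitting behind a flag). The free-protein ≈ total-protein
approximation is appropriate because the labelled probe (~2 nM) sits well
below the K_d range of interest (≳15 nM); an exact ligand-depletion
quadratic solution is available behind a flag and is the better choice when
K_d approaches the probe concentration. Fitting is bounded nonlinear least
squares initialized at the concentration nearest half-maximal binding.
Input curves must have ≥4 points including a zero-protein lane, strictly
increasing concentrations, and fractions in [0,1]; all-zero fractions raise
a no-binding error rather than returning a boundary estimate.

Uncertainty uses a **residual bootstrap**: the titration design is fixed,
so centred residuals — inflated by √(n/(n−2)) for the fitted parameter and
the centring — are resampled onto the fitted curve and the fit repeated
(seeded); the 95% interval is the 2.5/97.5 percentile range, widened if
necessary to contain the point estimate (a type invariant; percentile
intervals can otherwise exclude it in edge cases). Case resampling was
rejected because duplicating lanes of a 10-point fixed design measurably
undercovers. The simulator adds Gaussian noise (default σ = 0.05, the
realistic scale of gel densitometry) clipped to [0,1] on the standard
0–200 nM lane series, deterministic under a seed. Published K_d values for
these proteins come from gels that are not available numerically; they
anchor the simulator's default truths (15/25/75 nM) but cannot themselves
be re-derived, so the binding suite validates estimator properties
(exact noiseless inversion, ≤10% median error at gel noise, bias → 0 with
noise, ≥85% bootstrap coverage) rather than reproducing printed numbers.

## Problem sizes and determinism

All stochastic steps take explicit seeds (CLI `--seed`), and identical
invocations are byte-identical. The standard verification run uses 200
random round-trip targets, 50 superposition-oracle instances, a 20-point
superhelix sweep, 200 titration replicates per K_d level and 20 planted
transcripts of 1 kb — sizes at which every stochastic check is stable
across seeds while the whole suite stays interactive.

## Known limitations

* Repeat detection is consensus-derived from the design scaffold; natural
  PPR arrays with low template similarity may need a lower threshold and
  results there are best-effort.
* PPM site scores are uncalibrated to affinity; no RNA secondary-structure
  accessibility weighting.
* H-bond detection has no angle term and no hydrogen placement.
* The repeat↔nucleotide pairing assumes chain order; deposits with offset
  RNA numbering should be segmented explicitly.
* No codon/DNA output, no 3D model building of designed constructs, no
  kinetic (k_on/k_off) or cooperative binding models.
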