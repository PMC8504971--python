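# Methods

This note documents the models, conventions, defaults, and numerical
choices behind `tcrtilt`, and what the synthetic-data tests do and do not
establish.

## Coordinate and unit conventions

Coordinates are stored in nm (PDB Å ÷ 10).  The membrane normal is the +z
axis of the frame; the complex is assumed to have been aligned along z as is
standard for membrane simulation boxes, so no per-frame normal estimation is
performed.  The bilayer midplane defaults to z = 0 unless supplied.  All
angles are reported in degrees; only the force model converts to radians
internally.  RMSD values are in Å, labelled as such in every output.
Residue identity is (chain id, residue index); insertion codes are rejected
at parse time.  Angles between vectors are computed as arccos of dot
products clamped to [−1, 1].

## Domain annotation

Residue spans for the ten EC domains, eight TM helices, and the Ig
loop/strand elements ship as an editable YAML file rather than hard-coded
constants, because published structure-level analyses rarely print them and
they must be auditable against the user's numbering.  The packaged default
(`data/domain_map_synthetic.yaml`) is a *synthetic* stand-in: it follows the
eight-chain layout and the standard Ig-domain element naming, but its
numbers are an internal convention used by the fixture generator, not the
deposition's numbering.  Validation enforces: non-overlapping domain/TM
spans per chain, every element inside its parent domain, and the element
name prefix (e.g. `Cbeta` in "Cbeta FG loop") agreeing with that parent.

## Orientation measures

* Axis A = normalize(COM(Vα∪Vβ) − COM(Cα∪Cβ)); axis B =
  normalize(COM(Vβ) − COM(Vα)).  COMs are mass-weighted over *all* atoms of
  the selection including hydrogens; a documented switch restricts to heavy
  atoms (the choice is a convention — for complete structures the two
  differ negligibly).
* Tilt = angle(axis A, z).  Rotation = angle(axis B, n̂) folded to
  [0°, 90°], where n̂ = normalize(A × z); its sign is positive when
  |z(COM Vα) − z_mid| < |z(COM Vβ) − z_mid|.  When axis A is parallel to z
  within 10⁻⁶ rad the rotation is undefined and reported as NaN with the
  tilt still valid.
* TM inclination: the helix span is split into two halves (first half gets
  ⌊n/2⌋ residues — deterministic for odd spans); the inclination is the
  angle between z and the line joining the half-COMs, folded to [0°, 90°].
* Superposition is Kabsch least squares (SVD with determinant correction,
  no reflections) on atoms paired by (chain, residue, atom name); embedding
  a membrane-free reference structure uses the Cα atoms of all eight TM
  spans jointly — the minimal standard choice where the exact atom set is
  not otherwise specified.

## Contacts

Contact: minimum non-hydrogen distance < 0.45 nm, *strict* inequality.
Hydrogens are identified by the element column, falling back to an
atom-name heuristic (leading letter H after stripping digits).  Only
inter-dimer pairs (TCRαβ/CD3εδ/CD3εγ) are tested; intra-dimer pairs never
are.  Ensemble probabilities are occurrence fractions; the reported map
keeps pairs strictly above the 0.5 % threshold, while raw counts are always
written so other thresholds can be re-derived without recomputation.

Clustering is an artifact decision: published contact-map clusters are
drawn by eye, so this package uses connected components of reported pairs
under a Chebyshev radius of 2 in (residue i, residue j) index space within
one chain-pair map, numbered by ascending minimum residue index with maps
ordered TCRαβ < CD3εδ < CD3εγ.  The radius is a config knob; the published
cluster numbering is treated as a labelling aid, not ground truth.
Cluster–cluster Pearson correlations use per-frame occupancy counts;
correlations with constant series are reported as NaN, not zero.

## Tilt-binned statistics

Bins are [edge, edge + 5°) by default (the binning of published profiles is
not stated; 5° is a config knob).  Errors follow the five-subset design:
trajectories are split into five contiguous blocks (round-robin available by
flag), and the error of a bin mean is SD(subset means)/√k over the k ≤ 5
subsets with data in that bin; k < 2 yields NaN ("undefined"), and empty
bins are NaN, never zero-filled.  The 2D tilt × rotation histogram density
is normalized to unit integral on its grid; Gaussian smoothing exists but is
off by default since it is unknown whether published densities were
smoothed.  Distribution modes use a Gaussian KDE (Silverman bandwidth)
evaluated on a 0.1° grid to avoid histogram bin-width artifacts.  Analyses
of an "equilibrated" ensemble consume only frames with time > 0.5 µs; the
gate is an explicit filter with an override flag.

## Force–tilt model

The force-free tilt density P₀(τ) defines an effective energy
E₀(τ) = −k_B T ln P₀(τ).  A transversal force f on a complex of extension
h ≈ 13 nm adds −f·h·sin τ (τ in radians), assuming the complex rotates to
align its tilt direction with the force — hence a 1D model with no
azimuthal degree of freedom — and assuming the partner's membrane anchoring
is the more flexible one.  The reweighted density is
P_f(τ) ∝ P₀(τ)·exp(f·h·sin τ / k_B T), normalized by trapezoid on a uniform
radian grid over [0°, 90°] (0.05° step; the mode converges to < 0.1°
against a 10× finer grid, which is a test).  Tilt beyond 90° is
geometrically excluded, which fixes the otherwise unstated normalization
domain.  k_B = 0.0138065 pN·nm/K, so k_B T = 4.183 pN·nm at the default
T = 303 K; the constant is centralized, never inlined.  Reweighting is done
in log space with the maximum exponent subtracted.  Modes are grid argmaxes
refined by local quadratic interpolation; flat densities or ties warn and
report the smallest-τ maximum.

P₀ can be empirical (KDE of ≥ 100 tilt samples, Silverman bandwidth,
renormalized on the grid) or a truncated-Gaussian surrogate built from a
mean and SD.  With the surrogate from (33.4°, 8.9°) the reweighted modes at
2 and 5 pN are ≈ 40.0° and ≈ 47.8° — about 1° below the values obtained
from an empirical simulation density, an expected residual of the surrogate
approximation.  The membrane-surface separation spanned by the tilted
complex is h·cos τ; 13 nm tilting 34° → 49° gives a 2.25 nm decrease.

## Membrane annulus

A POPC lipid is in the annulus when its heavy-atom minimum distance to any
TM-helix heavy atom is < 0.5 nm (strict).  Leaflets are assigned by
headgroup COM z against the frame's mean headgroup z.  Thickness is the
|Δz| of the two leaflets' annulus headgroup COMs.  The headgroup atom set
defaults to phosphate + choline heavy atoms in Lipid14 naming
(P, O11–O14, N, C11–C15) and is configurable; cholesterol and any non-POPC
residue are excluded.

## Synthetic-data generator

The generator emulates *statistical structure*, not physics.  Defaults are
the stated world of an equilibrated ensemble: 120 trajectories × 50 frames
at 0.51–1.00 µs; tilt ~ N(33.4°, 8.9°) truncated to [1°, 89°]; rotation =
0.8·tilt + N(0, 8°) (slope and intercept anchored to the observed coupling
— most probable rotation ≈ 32° at tilt 40°, ≈ 40° at 50° — with the noise
SD an 8° package choice for the conditional band width, documented here
once and not tuned); per-chain inclination laws anchored to the observed
profiles (TCRα 11.5° → 8.5°, CD3γ 15.5° → 24°, CD3ε(γ) 19° → 22° over tilt
15–50°, others flat); element contact occupancies as logistic functions of
tilt with the Vα loops hard-gated to zero at tilt ≤ 30° and the Cβ FG loop
decreasing with midpoint 30°.  An optional exponential relaxation of the
tilt mean emulates equilibration for gate/convergence tests.

Coordinates realize the sampled values exactly: the four TCR EC domain
clusters are placed so that the measured axes reproduce tilt and rotation
to machine precision (offsets are mass-weighted because the clusters have
unequal masses); contact-bead residues sit on spikes off the domain bodies
with their CD3 partner residues at 0.40 nm (occupied) or 0.60 nm
(unoccupied), planted *geometrically* so the contact detector itself is
exercised; spike directions are chosen perpendicular to the within-dimer
separation axes so planted beads can never collide with other domains; TM
helices are straight CA traces (half-COM lines recover the inclination
exactly); the toy bilayer has headgroup beads at ±1.9 nm with 0.1 nm
scatter, four annulus and four bulk lipids per leaflet.

What a green synthetic test establishes: the estimators recover known
parameters, the detectors find planted features exactly, and the pipeline's
plumbing is correct.  What it does not establish: behaviour on real
all-atom geometry (side-chain packing, correlated frames, partial
occupancies of real loops), the actual residue numbering of any deposition,
or any physical claim; the inter-axis angle of the synthetic complex is 90°
by construction rather than the ~86.5° of real ensembles.  Benchmarks
against the deposited simulation ensemble therefore exist as a separate,
optional test layer that activates only when those data are supplied.

## Degenerate inputs and tie-breaks

Axes shorter than 0.1 nm before normalization are degenerate-geometry
errors; one-residue helix spans, empty selections, hydrogen-only residues,
one-sided annuli, and correspondence mismatches in superposition all raise
with specific messages.  A pair present in exactly 0.5 % of frames is *not*
reported (strict threshold), and a residue pair at exactly 0.45 nm is *not*
a contact (strict cutoff).  Binning uses half-open intervals so a tilt
exactly on a bin edge opens the next bin.

## Known limitations

No trajectory formats (DCD/XTC) — the deposited data this targets are PDB
structures.  No autocorrelation-time correction: the SEM-over-trajectories
error design is reproduced as stated.  No atomic interaction typing, helix
kink analysis, cholesterol statistics, or intracellular-signaling claims.
The cluster definition approximates a visual grouping and its numbering
should not be compared 1:1 against published labels.
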