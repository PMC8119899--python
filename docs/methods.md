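# Methods

This note records the models, conventions and design choices behind
`helixmd`, in the spirit of the methods documentation of mature
analysis packages: what each statistic assumes, which knobs matter, what
the synthetic fixtures do and do not emulate, and where genuinely open
choices were settled.

## Data model and pooling conventions

A `Topology` is an ordered atom table annotated from a residue template
table (shipping with the package, user-overridable via YAML): aromatic
rings per residue type (one for Phe/Tyr/His, two for Trp — the pyrrole
and benzene moieties of the indole, handled separately), hydrogen-bond
donor (heavy atom, hydrogen) pairs including the backbone amide,
acceptor atoms including the backbone carbonyl, and anionic carboxylate
oxygens (Asp OD1/OD2, Glu OE1/OE2). Molecule classes (protein, POPC,
POPE, cholesterol, water, ion, ligand) are inferred from residue names;
unknown names fall back to "ligand" with a warning. Subunits come from
PDB chain IDs when present, otherwise protein residues are split into
five contiguous equal blocks — appropriate because the pentamer has five
identical chains.

Trajectories carry uniformly spaced frame times (50 ps by default). The
z axis is taken as the membrane normal / channel axis exactly as stored
in the input; no reorientation is performed.

Replica pooling uses half-open windows: a frame at time t belongs to the
window `[t_start, t_end)` iff `t_start ≤ t < t_end`. This avoids double
counting at window joins and makes the frame arithmetic exact: a 200 ns
window at 50 ps sampling contains exactly 4000 frames, so two 250 ns
replicas pooled over their 50–250 ns windows give 8000 frames. Pooled
frames keep replica order then time order and stay tagged with their
replica of origin, because some statistics (correlations, lifetime
distributions) are replica-resolved while others (RMSF, interaction
frequencies) average over the pool.

## RMSF

Per residue and subunit, over backbone atoms {N, CA, C, O}:
`RMSF = sqrt( mean over frames and atoms of |x(t) − x_ref|² )`. The
reference defaults to the first frame of the analysis window (the
post-equilibration positions); a supplied coordinate set or the time
mean can be used instead (the time mean is what makes the isotropic
Gaussian ground truth exact: E|x−μ|² = 3σ², so σ = 1 Å gives √3 ≈
1.732 Å). No global superposition is applied by default — the intended
inputs are positionally restrained simulations where superposition would
remove signal; an optional least-squares (Kabsch) fit onto a chosen
selection is available. The cross-subunit error is the maximum
semidifference, (max − min)/2 over the five subunit values.

## Dynamical correlation

For two residue selections with representative 3-vector series r_i(t),
r_j(t):

    C_ij = ( ⟨r_i·r_j⟩ − ⟨r_i⟩·⟨r_j⟩ )
           / sqrt( (⟨r_i²⟩ − ⟨r_i⟩²)(⟨r_j²⟩ − ⟨r_j⟩²) )

computed per subunit and per replica over the analysis window, then
summarized as grand mean ± SD. The default representative is the
backbone centroid of the residue; an `atom_pair_mean` mode (mean of
C over matched atom pairs) exists because "correlate the backbone atoms
of two residues" does not by itself fix the reduction. The formula is
evaluated in centered (two-pass) form, which is algebraically identical
and numerically stable far from the origin; a zero-variance series
raises rather than returning a conventional value.

The statistic is signed and lies in [−1, 1]; values are reported
unclamped. (Descriptions of this quantity sometimes state a [0, 1]
range; the formula as written is a correlation coefficient and can be
negative — anti-correlated rigid motion gives exactly −1, which the test
suite pins.)

## Interaction detectors

All cutoffs are strict inequalities and live in one configurable record
(`InteractionCriteria`), with defaults: H-bond donor–acceptor < 3.5 Å
and D-H-A angle > 120°; generic contact < 3.5 Å; π-π ring-center
distance < 6.0 Å with normals angle < 45° or > 135°; anion-π
center–charged-atom distance < 5.0 Å with normal/axis angle < 40° or
> 140°. Ring planes are least-squares planes via SVD of the centered
ring coordinates; the normal's sign is arbitrary and every angle test is
symmetric under flipping it (hence the paired angle bands).

Design choices:

* Hydrogen-bond detection requires explicit hydrogens (the criteria
  involve the D-H-A angle); topologies without them raise a capability
  error rather than silently degrading to a distance-only criterion.
  Backbone donors/acceptors are included by default; a side-chain-only
  flag exists because backbone participation is often reported
  separately.
* The anion-π event for a ring fires if **any** charged oxygen of the
  partner satisfies the criteria (the criterion is per charged atom).
* Multi-ring residues (Trp) contribute per-ring frequencies computed
  separately and then summed. The sum can in principle exceed 1 if both
  rings hit simultaneously; it is reported as computed.
* Frequencies are fractions of frames with ≥ 1 detection, per subunit
  and replica. The pooled error propagates the per-series standard
  deviations of the indicator over time as `sqrt(Σ sd²)/n`, the error of
  a mean of independent per-subunit estimates. This is an
  interpretation of "error propagation from the per-subunit standard
  deviations" — the most natural reading, and the one used throughout.
* Minimum-image periodic distances are not applied: the intended
  analyses concern intra-subunit geometry far from box edges. A
  minimum-image option would be the first extension needed for
  inter-molecular analyses near boundaries.
* His rings are annotated but excluded from π tallies by default
  (configurable), since protonation-state ambiguity makes His π
  interactions a judgment call.

## Lipid environment

A lipid is proximal to a residue in a frame iff any heavy-atom pair is
closer than the cutoff; the default reuses the 3.5 Å generic contact
cutoff (exposed in config — analyses in the literature rarely state the
lipid cutoff explicitly). POPC and POPE are merged as "phospholipid"
because at the depth of membrane-facing residues their tails are
chemically indistinguishable.

Residence events are maximal runs of proximal frames; by default a
single non-proximal frame terminates an event (a configurable gap
tolerance of ≤ k frames supports sensitivity analysis). Event durations
are run length × frame interval; events truncated by the series edges
are counted at their observed duration and flagged censored — the naive
run-length reading of a finite trajectory, which understates true dwell
times for events comparable to the span.

Lifetime histograms report events at or above a minimum residence
(default 5 ns; shorter events are dominated by the crossing statistics
of the cutoff rather than by binding). Error bars come from re-running
the event extraction in overlapping windows (default length 50 ns)
shifted by 5 ns and taking per-bin mean ± SD across windows. The 5 ns
shift is the convention of the field; the window length is this
package's own default, since shifted-window statistics require choosing
one.

z-offsets are mass-weighted center-of-mass differences in the z
component only. Leaflets are assigned from head-group z (phosphorus for
phospholipids, hydroxyl oxygen for cholesterol) relative to the midplane
(midpoint of extreme head z); a head exactly at the midplane goes to the
lower leaflet, and a head spread under 10 Å is treated as a single
leaflet with a warning.

## Distance distributions

Per (subunit, replica) histograms of a one-atom-per-side distance,
pooled as the mean of the per-group densities and density-normalized
(this choice is labeled in the output; frequency normalization is the
other defensible option). Default bin width 0.25 Å — peaks of interest
in this problem domain are quoted at ~0.5 Å precision, so quarter-Å
bins resolve them without starving bins of counts. Per-bin errors
propagate the per-group standard deviations over time of the
density-scaled bin indicator. Modes are strict local maxima of the
3-bin moving-average-smoothed pooled density; no kernel density
estimation or formal bimodality testing is attempted.

## Pharmacology

`HillModel` fits y = a + (b − a)/(1 + 10^(nH(logEC50 − x))) with
x = log10[agonist] (M), by unweighted nonlinear least squares
(scipy `curve_fit`), initialized at a = min response, b = max response,
pEC50 = −x at half range, nH = 1. `SaturationModel` fits one-site
specific binding B = Bmax·L/(Kd + L) (L in nM) — specific binding is
assumed computed upstream (total minus non-specific), and no Hill
coefficient is included, the standard choice for single-site antagonist
saturation. Monotone-decreasing curves fit with a > b (or equivalently
nH < 0); no convention is forced. An optional normalization flag divides
responses by the maximum observed response before fitting
(normalization to max ΔF); note the observed maximum sits slightly
below the true asymptote, so the normalized plateau fits marginally
above 1.

Standard errors are asymptotic (from the fit covariance); when a
replicate column is present, per-replicate fits additionally supply
across-replicate SEMs, since published tables may report either.
Reported EC50 and pEC50 satisfy EC50 = 10^(−pEC50) exactly.

## Synthetic fixtures — what they do and do not show

The generators provide exact, recoverable ground truth:

* Gaussian-fluctuation trajectories displace each residue rigidly by an
  isotropic zero-mean Gaussian 3-vector, i.i.d. across frames; pairwise
  correlation targets are realized exactly in expectation by an
  eigendecomposition-based mixing of shared components (ρ = 1 produces
  identical series by construction). Defaults: σ = 1 Å, 1000–10000
  frames depending on the statistic's sampling-error budget.
* Constructed H-bond and ring-pair geometries place atoms at exact
  distances/angles (hexagons with 1.39 Å C–C; the indole as a regular
  pentagon fused to a regular hexagon, planar).
* Occupancy series alternate bound/unbound dwells (exponential or
  fixed law) starting bound; a frame is bound iff its midpoint lies in
  a bound interval, which is unbiased for dwells ≫ the 50 ps sampling
  interval (a warning fires when the interval exceeds a tenth of the
  shortest dwell scale).
* Assay curves add Gaussian noise to the exact logistic / hyperbola.
  Default simulation truths use representative wild-type-receptor
  values (pEC50 6.76, nH 3.7; Kd 0.18 nM, Bmax 1.2 pmol/mg) so the
  recovered numbers are on the scale practitioners expect.

None of this emulates real protein mechanics, lipid diffusion physics,
membrane electrostatics, or correlated experimental error. Passing
tests therefore demonstrate that the estimators are correct and
well-calibrated on data satisfying their assumptions — not that a given
real system satisfies those assumptions. In particular, frame-to-frame
independence in the fluctuation generator makes sampling errors smaller
than for autocorrelated MD data at equal frame counts.

## Problem sizes

The test suite and the acceptance script use deliberately small
problems chosen so each statistic's sampling error sits well inside its
tolerance: 5-subunit toy pentamers of 1–4 residues per subunit,
5000 frames for RMSF (3% tolerance vs ~1% sampling error), 10000 frames
for correlation recovery (±0.03 vs ~0.01 standard error), 1000 random
geometries per detector, 10 μs of occupancy at τ = 10 ns (~300 reported
events), and 100 replicate fits for noisy pharmacology recovery.

## Known limitations

* No PCA/normal-mode analysis; the correlation API is pairwise (a full
  matrix is a trivial loop but is not a tested surface).
* No periodic-boundary imaging; inputs are assumed whole and centered.
* Censored residence events bias lifetime means downward for dwells
  comparable to the window length; the censored flags allow downstream
  survival-style corrections, which this package does not itself apply.
* The XTC/DCD readers trust the declared frame stride rather than
  per-frame timestamps when formats disagree.
* Coarse-grained models are out of scope.
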