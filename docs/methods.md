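# Methods

This note records the models, parameter choices and numerical decisions
behind `helixcov`, and what the synthetic study conditions do and do not
demonstrate about real data.

## Coupling estimation

The alignment is encoded over 21 states (20 amino acids plus gap).
`mf_dca` computes the weighted one-hot column covariance C with the gap
state as the dropped reference, shrinks it as C + λI with λ = 0.5·mean
diag(C), and takes J = −C⁻¹.  Each residue pair's 20×20 block is put in
the zero-sum gauge and summarised by its Frobenius norm; the average
product correction (APC) removes per-column background, negatives are
clamped to zero and the diagonal to zero.  `mi_apc` replaces the
inverse-covariance step by plain mutual information.  Neither estimator
claims numerical agreement with any particular published DCA
implementation — the detector only needs the qualitative stripe structure,
which both estimators reproduce (a perfectly covarying column pair is the
top-ranked entry against a random background; see the tests).  Columns
with a single observed state are defined to have zero coupling.  Optional
inverse-cluster-size sequence weights (80% identity) are off by default;
the intended workflow filters redundancy at 90% identity instead, with the
identity denominator counting columns where both sequences are non-gap.

## Detector

**Pattern template.**  Cell (i, j) of the parallel grid (size 17,
odd, centred) carries w = clip(cos(2π·dist/p), 0), where dist is the
distance of the offset i−j to the nearest multiple of the period
p = 3.5 residues/turn; weights are normalised so Σ|w| = 1.  The
antiparallel grid is the parallel grid with rows reversed (rows = first
helix N→C, columns = second helix N→C).  Optional shape parameters —
amplitude (total evidence scale), width (period stretch) and a Gaussian
centre-decay envelope — define a low-dimensional family over which
`optimize_pattern_weights` runs coordinate ascent on a labelled training
set; 289 free per-cell weights would be unidentifiable at the data sizes
the package targets, so per-cell optimisation is deliberately not offered.

**Evidence model.**  Coupling strengths at interacting and
non-interacting residue pairs are modelled as two-parameter gamma
densities fitted by maximum likelihood (zero-variance input is an error).
The per-cell evidence is the log-likelihood ratio, clipped to ±30, with
strengths floored at half the background mean before evaluation.  The
floor matters twice: exact zeros (APC clamping, and zero-padding where
the sliding window overhangs the inter-helix block) contribute
background-typical rather than unboundedly negative evidence, and the
heavy left tail of the log-gamma ratio — which would otherwise dominate
the window sums with noise — is suppressed.  Truncating overhanging
windows instead of padding is available behind the window evaluator.

**Aggregation.**  The raw pair score is the maximum of the Bayes
posterior over all window centres and both orientations, matching the
semantics "the helices touch at *some* register"; a log-sum-exp soft
maximum is available (`aggregation="logsumexp"`).  The window sums are
computed as a 2-D correlation of the llr field with the weight grid.

**Calibration.**  cal(r) = a + (b−a)·σ(c·(logit r − d)) with
0 ≤ a ≤ b ≤ 1 and c > 0 (hence monotone), fitted by unbinned Bernoulli
maximum likelihood via Nelder–Mead on an unconstrained reparameterisation
(a = σ(α), b = a + (1−a)σ(β), c = e^γ), multi-started over two slope and
two offset initialisations.  The characteristic bin size (60 predictions)
is used only for the diagnostic reliability plot.  Curves calibrated on
several datasets are combined as a dataset-size-weighted average of the
calibrated values.  The four-parameter sigmoid-on-logit form is this
package's interpretation of a "transformed Bernoulli" calibration; it is
flexible enough to recover planted parameters (a, b within ±0.05, c
within 15%) at n = 5000 and reduces to near-identity on perfectly
calibrated scores.

## Constraint building

The top-k (default 50) off-diagonal couplings, normalised to i < j with
ties broken lexicographically, pass through exclusion rules in priority
order: **indel** (a pair partner that is an alignment indel, or a residue
in a user-supplied indel set) > **intrahelical** (both residues in the
same helix segment) > **topology violation** > retained.  The topology
test assigns each residue an approximate membrane-normal coordinate
(linear interpolation across TM segments between ±15 Å, loops just
outside at ±18 Å, cytoplasm negative) and fires when |Δz| > 12 Å or when
both residues sit outside the membrane on opposite sides.  The published
YidC exclusion list states reasons but not the quantitative criterion, so
a strict mode reproduces curated labels verbatim; the bundled table then
yields exactly 39 retained and 11 excluded pairs.  Retained pairs are
emitted as Cβ–Cβ restraints, 0–8 Å by default — the community convention
for covariation contacts; the bound is configurable.

## Bundle construction

Helix axis positions minimise Σ_contacts (‖p_a−p_b‖ − D)² plus a
one-sided repulsion (D − ‖p‖)²₊ for non-contact pairs, D = 10 Å, by
L-BFGS from a circular start plus seven seeded random restarts; helices
and edges are canonically ordered so the selected minimum of the
(degenerate) stress landscape does not depend on input order.  Gauge:
centroid at the origin, first helix on +x, first off-axis helix at
positive y.  Helix rotation about the axis maximises
Σ_lipid cos θ − Σ_protein cos θ (θ = angle between a residue's radial Cβ
direction and the outward direction); the optimum is the circular-mean
closed form, with a warning and phase 0 when the label resultant
vanishes.  Ideal helices are generated by propagating a rigid residue
template (N, CA, C, O, CB; template offsets extracted from a
NeRF-built ideal α-helix) along an exact screw of 100°/residue and
1.5 Å/residue, with the Cα radius set so consecutive Cα–Cα distances are
exactly 3.8 Å.  This keeps intra-residue geometry ideal while making
rise and twist exact; the peptide C–N distance absorbs the ~2%
difference (1.36 Å vs 1.33 Å ideal), an acceptable trade for a model
whose purpose is approximate helix packing, not stereochemistry.  Axes
are perpendicular to the membrane plane, running +z or −z per the
segment's N-side label (cytoplasm = −z); loops are not built.

## Structure geometry

PDB input goes through biotite with the highest-occupancy altloc rule.
Geometry operations run on a float64 copy of the coordinates.  Cβ
distances fall back to Cα for glycine.  Superposition is the Kabsch SVD
solution restricted to proper rotations; when the determinant correction
triggers, a warning notes that a reflection would fit better.  The
independent check in the test suite is Theobald's quaternion
characteristic polynomial.  Cross-species residue maps default to a
Needleman–Wunsch global alignment (BLOSUM62, gap open 11 / extend 1);
explicit mapping files override.  Smoothed Cα profiles use a centred
moving average whose window shrinks at the edges.

## Membrane observables

* **Thickness**: per frame and per 2 Å grid bin that has a probed-leaflet
  phosphate within one bin radius in-plane, the distance recorded is the
  3-D minimum from that nearest phosphate to any opposite-leaflet
  phosphate; bins are averaged over frames, unoccupied bins are reported
  as missing, and minimum-image distances apply when box dimensions are
  present.  A |Δz|-projection variant sits behind a flag because the
  published description ("shortest distance between the head groups from
  opposite leaflets") is ambiguous between the two readings.
* **Flexibility**: per-residue mean over backbone atoms of the
  time-variance of atom position about its trajectory mean, with *no*
  prior superposition — rigid-body helix displacements are part of the
  signal, which distinguishes this quantity from an RMSF.
* **Hydrogen bonds**: donor-heavy→acceptor distance ≤ 3.8 Å and
  deviation of H–D···A from linearity — measured at the donor between
  D→H and D→A — ≤ 20°, both inclusive.
* **Hydropathy profile**: residues binned by Cα z; hydrophobic iff the
  Kyte–Doolittle index is positive; out-of-range residues land in
  explicit overflow bins so counts are conserved.
* **Energy smoothing**: per-residue time averages, then the mean over
  residues whose Cα lies within 10 Å (inclusive, self included).
  Force-field energies are an input table — the analysis here is the
  averaging, not the energy function.

## Synthetic study conditions

The generators are pure functions of their parameters including the seed.
A planted interaction writes a stripe along the register (anti-)diagonal
of the inter-helix block whose cells are gamma draws modulated by
0.25 + 0.75·clip(cos(2πt/3.5), 0) — one amplitude peak per helical turn,
emulating the periodic interface stripes of real coupling matrices.
Defaults: background gamma(1, 0.05), interacting gamma(4, 0.1), signal
scale 2.0, chosen once so the planted stripes are clearly visible
(stripe mean ≈ 8× background) and the default detector, after
calibration on generated labelled data, pushes planted pairs above and
background pairs below the conventional 0.57/0.15 decision thresholds —
a self-consistency design, not a claim about any real protein.  Under
these conditions the seven planted pairs occupy the top seven posterior
ranks in ≥ 95 of 100 replicates, and the planted 8 Å bilayer depression
is recovered within 1 Å from five jittered frames.

What passing these tests does *not* show: real alignments have phylogenetic
structure, gaps and finite depth that the independent-draw generator does
not emulate, real coupling estimators leak transitive signal, real
training sets (the CATH-derived helix-pair datasets used to train such
detectors in practice) differ from gamma-stripe blocks, and real bilayer
thinning magnitudes require long MD trajectories.  Published posterior
values on YidC and the 7–10 Å thinning are therefore not reproduction
targets of the synthetic suite; the published numbers the package does
recompute are the exclusion counts (39/11) and the distance-table
summaries (mean Cβ–Cβ 9.3 Å in the model, 8.1 Å in the 3WO6 crystal
form over the retained pairs).

## Problem sizes

Test and acceptance runs use 18-residue helices (L ≈ 150 matrices),
100 detection replicates, n = 5000 calibration samples, 10⁴-frame jitter
trajectories for the variance closed form and 5-frame bilayers on a
110 × 110 Å patch — sizes chosen so the full suite completes in well
under a minute while keeping every statistical check comfortably powered.
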