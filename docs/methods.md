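# Methods

This note documents the models, numerical choices and known limitations
of the package. Nothing here states an empirical result that the test
suite or `scripts/acceptance.py` does not itself compute.

## Combined activity (threshold method)

Three endpoints are modelled per congener: bioconcentration factor
(BCF, dimensionless), vapor pressure at 25 °C (mmHg, a proxy for
long-range atmospheric transport) and the highest infrared signal
intensity (arbitrary units). Raw endpoints span orders of magnitude, so
each is log10-transformed, then min–max scaled to 0–100 over the working
table (`Y_i = 100·(X_i − min)/(max − min)`), and combined with the 5:4:1
weight ratio, `Z = 0.5·Y1 + 0.4·Y2 − 0.1·Y3`. The scaling parameters
always come from the input table (no reference ranges exist); when new
molecules are scored against a trained model, values are clamped to the
training range and flagged rather than extrapolated. The negative IR
weight makes a *detectable* congener lower Z: high Z = bioaccumulative,
mobile, hard to detect.

The dependent variable for PLS modelling is log10 Z by default, which
presumes Z > 0 for every congener; tables violating this are rejected
with the offending congeners named. `Z` itself can be selected instead
(`RunConfig.dependent = "z"`), and the planted-signal recovery analysis
does so (see below).

Change rates between a parent and a derivative are reported as
percentages of the parent value in three conventions — signed,
increase, decrease — rounded to 2 decimals, matching how such tables
are conventionally quoted. Published comparison tables for the PBB-153
derivatives are bundled (`reference_tables`); a handful of their printed
rates were evidently computed upstream from unrounded source values and
differ from printed-input recomputation by ≤ 0.02 — these are flagged
per cell (`reproduced_exactly`) rather than forced, and the LC50 rates
(quoted from unrounded concentrations, deviating far more) are exempt
from the consistency guard.

## Congener structures

Congeners are built as idealized rigid geometries: two regular hexagons
(C–C 1.39 Å) joined by a 1.48 Å pivot bond, C–Br 1.89 Å, C–H 1.08 Å,
with a configurable inter-ring dihedral (default 44°, the free-biphenyl
twist; the conformation the original commercial force-field minimization
produced is not recoverable, and CoMFA on a rigid congener series is
insensitive to small relaxations). Substituent groups (–NO, –ONO, –OCN,
–OCHO) attach through their linker atom with standard bond lengths and
in-plane anti-periplanar zig-zag geometry, the first bend tie-broken
toward the lower neighbouring ring position. Partial charges are
iterative Gasteiger (PEOE) via RDKit — a documented approximation to the
Gasteiger–Hückel variant of commercial packages, whose π correction is
proprietary.

Enumeration of bromination patterns deduplicates the 2^10 position
subsets under the order-8 graph-automorphism group of biphenyl
(independent flips of either ring about the pivot axis, ring swap),
yielding the canonical 209 congeners; congener numbers are assigned by
sorting canonical locant sequences within homolog level, which
reproduces the standard numbering at the anchors used here (PBB-1/2/3,
PBB-153 = 2,2′,4,4′,5,5′).

## Alignment

Every congener is superimposed on the template (the congener with the
largest Z; ties to the lowest congener number) by a Kabsch least-squares
fit of the 12 labelled skeleton carbons only — the biphenyl core is the
only substructure shared by all congeners. The four proper rigid
symmetries of the twisted skeleton (identity, both-ring flip, ring swap,
their product) are searched exhaustively and the minimum-RMSD
correspondence kept. Because the bare skeleton is symmetric, all four
correspondences tie whenever two molecules share a dihedral; a tie
tolerance of 1e-6 Å makes the identity relabeling win deterministically
instead of letting floating-point noise pick an arbitrary symmetry image
of the substituents.

## Fields

CoMFA descriptors are sampled on an axis-aligned lattice covering the
aligned ensemble plus a 4 Å margin at 2 Å spacing (the canonical CoMFA
protocol; the source study reports no lattice parameters). Probes:
steric, an sp³ carbon (R = 1.70 Å, ε = 0.107 kcal/mol), Lennard-Jones
`ε_ij[(r_m/r)¹² − 2(r_m/r)⁶]` with `r_m = R_i + R_probe`,
`ε_ij = √(ε_i ε_probe)`, net attractive values floored at 0 and
everything clamped at E_cut = 30 kcal/mol; electrostatic, a +1 e probe
with distance-dependent dielectric ε(r) = r, `332.0636·Σ q_i/r_i²`
kcal/mol, clamped to ±E_cut. Element Lennard-Jones parameters follow
Tripos-style values (C 1.70/0.107, H 1.50/0.042, N 1.55/0.095,
O 1.52/0.116, Br 1.85/0.434). At lattice points inside a molecule's
steric envelope (steric = E_cut) the electrostatic value is replaced by
that column's mean over the non-excluded molecules (standard CoMFA
practice; `envelope_mode="keep"` retains the clamped Coulomb value
instead).

Columns with raw standard deviation < 0.05 kcal/mol are masked; each
block is divided by the RMS of its retained column standard deviations
(CoMFA-STD scaling) so neither field dominates the PLS step. Filtering
and scaling are refittable (`ComfaScaler`) so cross-validation folds can
honestly refit the preprocessing; a config flag allows the faster
fixed-preprocessing variant. All of these are config keys.

## PLS and validation

The regression backend is NIPALS PLS (scikit-learn), centered,
unit-variance scaling off (the block scaling already equalizes the
fields). "Leave-one-out" is taken as the standard cross-validation of
the original CoMFA software. Statistics:

- q² = 1 − PRESS/SS_tot with PRESS from N single-molecule-out refits
  (preprocessing refit inside each fold), SS_tot about the full-sample
  mean; SDEP = √(PRESS/N).
- Component count n = argmax of q² over 1..10 (bounded by rank and
  N − 2), ties to the smaller n.
- R² = 1 − RSS/SS_tot, SEE = √(RSS/(N − n − 1)), and the regression F
  with (n, N − n − 1) degrees of freedom — the convention validated by
  its internal consistency with the published (R² = 0.95, F = 67.79,
  N = 35, n = 8) tuple.
- Field contributions: per block, Σ|coefficient|·column-stdev over the
  scaled descriptors, normalized to percentages.
- Progressive scrambling (Clark's procedure, the published method behind
  the Q²/cSDEP/dq²/dr²yy outputs): the response is permuted within
  similarity bins (contiguous blocks of the y-sorted order) over a bin
  ladder 2..10 with 20 replicates each, seeded; quadratics of q² and
  SDEP against the scrambled-response correlation r²yy′ are evaluated at
  the critical point 0.85, and the slope statistic is the derivative of
  the q² quadratic there rescaled by 1/(2·r_yy′).
- External validation: r²pred = 1 − PRESS_test/SD with
  SD = Σ(y_test − ȳ_train)²; SEP = √(PRESS_test/N_test).

Quality gates follow the conventional CoMFA acceptance thresholds
(q² > 0.5, R² > 0.9, SEE < 0.95, r²pred > 0.6, dq²/dr²yy < 1.2);
`ValidationReport.quality_flags()` reports exactly which are violated.

## Contours and derivative design

Contour maps carry STDEV·COEFF per retained grid point (scaled-descriptor
stdev × PLS coefficient — invariant to the block-scaling constant).
Favored regions are positive values at or above the 80th percentile of
the positive mass, disfavored regions negative values at or below the
20th percentile of the negative mass (the common default levels; the
source study names colored regions but no levels). Both are config keys
and export as Gaussian cube files.

Derivatives are designed by swapping substituents at named ring
positions of the parent (PBB-153 and the four standard plans: 5,5′-NO;
5-NO-5′-ONO; 5-NO-5′-OCN; 2-OCHO-5-NO). The modified molecule is
rebuilt, recharged, re-aligned to the training template, and its field
row — computed on the training grid with the training envelope means and
preprocessing, no refit — is dotted with the frozen coefficients.
Because the training ensemble contains only Br/H substituents, scoring
the nitrogen/oxygen design groups is an extrapolation; predicted change
rates for them are larger in magnitude than a model trained on such
groups would give, and should be read as directional.

## Synthetic studies and what they show

The generator emulates a 45-congener study with a known planted
structure: congeners are selected (PBB-153 always included, the rest a
seeded draw), built, aligned and their fields computed; the three log
endpoints are then affine functions of a small set of planted descriptor
columns plus i.i.d. Gaussian noise (default sd 0.05 log units).
Endpoint anchors put PBB-153 exactly at the literature exemplars
(log BCF 2.22, log VP −7.67, log IR 2.84) and the across-congener
spreads (0.5, 1.5, 0.3 log units) reflect the order-of-magnitude ranges
such series span. The recorded planted map (columns, coefficients,
intercepts, effective Z-coefficients and contribution shares) makes
recovery assertable; equal seeds reproduce a study byte for byte.

Planting in a congener field matrix needs care, because the descriptors
are dominated by a single bromination factor and are heavily collinear:

- planted columns are chosen greedily to be mutually weakly correlated
  (|r| < 0.5) and weakly correlated with the leading principal component
  (|r| < 0.5) — a signal planted on near-duplicate or global-factor
  columns collapses into one latent and cannot be localized;
- each endpoint owns a disjoint subset of the columns, subset sizes
  proportional to the 5:4:1 weights and coefficient magnitudes inversely
  proportional to column spread, so every planted column carries a
  comparable, material share of the combined-activity signal (after
  min–max scaling, an endpoint's share of Z is pinned at its weight, and
  an immaterial planted coefficient is unrecoverable in principle);
- coefficient draws whose noiseless Z would fall below 5 anywhere are
  rejected and redrawn, since log Z must exist.

Recovery is assessed with the model fitted on Z — the scale on which the
planted relation is linear; the log transform is kept as the default for
real data, where no such ground-truth scale exists. Contour recovery is
scored as a symmetric-coverage Jaccard between the materially planted
columns and the equally many strongest mutually distinct contour
features, with identification up to descriptor correlation
(|r| ≥ 0.8): the electrostatic potential is long-range and smooth, so
the exact lattice point of a planted electrostatic column is not
identifiable by any method — only its correlation cluster is. Under the
study conditions (45 congeners, 2 Å lattice) this coincidence score
sits at about 0.5: roughly half of the distinct contour features map
onto planted clusters and vice versa, while a univariate
correlation-ranking baseline reaches only about 0.3. Passing tests on
these simulations show that the pipeline recovers planted linear signal
and localizes it as well as the data allow; they do not show that real
PBB endpoint tables are linear in field columns, that real endpoints are
as weakly correlated as the planted ones, or anything about the accuracy
of the idealized geometries and PEOE charges relative to the original
study's force-field minimized, Gasteiger–Hückel-charged structures. The
published model statistics of the original study depend on its
commercial field implementation and an unpublished activity appendix and
are not reproducible here; the package's own numbers are what
`scripts/acceptance.py` computes.

## Numerical choices and degenerate inputs

Tie-breaks: template selection → lowest congener number; component
selection → smallest n; alignment correspondence → identity within a
1e-6 Å RMSD tolerance; substituent first-bend → lower neighbouring
position. Degenerate inputs raise typed errors: empty activity tables,
non-positive raw endpoints (named congener), degenerate scaling ranges,
constant responses, ensembles whose field columns are all constant,
n_train ≥ table size, substitution at the bridgehead positions 1/1′.
Energies are clamped rather than special-cased at singular points
(probe on an atom). Problem sizes in the tests (20-congener fixtures,
reduced scrambling replicates) and the acceptance script (45 congeners,
full scrambling, 5 recovery seeds) were chosen to keep a complete run in
tens of seconds on one CPU; all statistics are computed at the stated
sizes, never cached.

## Known limitations

- Idealized rigid geometry; no conformational search or minimization.
- Pure PEOE charges (no Hückel π correction); charge quality for the
  nitroso/nitrite/cyanate/formate groups is untested against experiment.
- Derivative scoring extrapolates outside the Br/H training domain.
- Congener numbering is validated at the anchors above, not against the
  full historical list, whose ordering has documented idiosyncrasies.
- Only steric and electrostatic fields (no hydrophobic/H-bond fields);
  no QM electrostatics.
- The external property tables (docking scores, half-lives, BDEs, LC50)
  are ingested as published numbers; the tools that produced them are
  out of scope.
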