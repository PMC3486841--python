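# Methods

## The two-state shuttle model

The object of analysis is a *shuttle motif*: a central basic side-chain
group (ammonium, guanidinium or — at low pH — imidazolium) that forms a salt
bridge with exactly one of two acidic carboxylate partners at a time.  The
motif defines a two-state conformational equilibrium:

| state      | interface bridge | remote bridge | meaning            |
|------------|------------------|---------------|--------------------|
| OPEN       | broken           | formed        | binding-competent  |
| BRIDGED    | formed           | broken        | binding-impaired   |
| BIFURCATED | formed           | formed        | transient          |
| UNBOUND    | broken           | broken        | transient          |

BIFURCATED and UNBOUND occur as short-lived intermediates during an
exchange; they are kept as explicit labels rather than folded into the core
states so that occupancies remain honest fractions of observed frames.

A salt bridge is scored on the **minimum** distance between the
charge-bearing terminal atoms of the two groups (e.g. Lys NZ against Asp
OD1/OD2), which is the quantity that is bimodal when a bridge forms and
breaks; centroid or Cβ distances blur the two modes.

## Bridge calling: hysteresis

State calling uses two thresholds: FORMED below `d_on` = 4.0 Å, BROKEN above
`d_off` = 6.0 Å, previous label held inside the gap.  4 Å is the common
structural-biology criterion for an N–O salt-bridge contact; 6 Å lies well
inside the gap between the formed (~3 Å) and broken (~8–9 Å) modes of the
distance traces, so any cutoff in between separates the modes and the exact
values are not critical — both are configurable.  Hysteresis exists to make
*kinetic* quantities robust: with a single cutoff, noise at the boundary
generates spurious state flips that inflate exchange counts and fragment
dwell times; with a 2 Å dead band a flip requires a genuine excursion to the
other mode.  The first frame, if it falls inside the gap, is labelled by the
midpoint rule (FORMED iff below (d_on+d_off)/2).

Frames earlier than `exclude_ps` = 1000 ps are discarded before any
statistic, the conventional equilibration discard for MD output.

## Charged groups and protonation

Group definitions: Asp/Glu carboxylate (OD1/OD2, OE1/OE2), Lys ammonium
(NZ), Arg guanidinium (NE/NH1/NH2), His imidazolium (ND1/NE2), plus opt-in
chain termini (N; O/OXT).  Histidine is counted as charged when pH < 6 —
relevant for systems characterised in yeast cytosol, which sits near pH 5.5
where solvent-exposed histidines are expected to be protonated — and the
call is overridable globally or per residue.  No pKa prediction is
attempted.  A residue whose charge atoms are entirely missing is skipped
with a warning; partial groups (e.g. a single carboxylate oxygen in reduced
toy models) are kept with the atoms found.

## Network, motif screening, role assignment

The salt-bridge network has an edge for every opposite-sign pair whose
FORMED occupancy reaches `min_occupancy` = 0.05; the filter removes
incidental grazing contacts, and 5% is a screening default, not a physical
claim.  Every basic hub with ≥ 2 acidic partners is screened: a partner pair
is a motif when the Pearson correlation of the two raw central–partner
distance series is ≤ `rho_max` = −0.5.  A genuinely exclusive shuttle with
well-separated distance modes produces rho near −0.9, and independent
bridges produce rho near 0, so −0.5 separates the hypotheses with a wide
margin on both sides.

Which partner is the *interface* one is not decidable from geometry — it
reflects knowledge of the binding surface — so roles are taken from the
`interface_residues` annotation; without it, partners are reported in
sequence order and flagged unassigned.

## The anticorrelation statistic

rho is the Pearson product-moment coefficient, computed on **raw** retained
frames.  Running-average smoothing (default window 100 ps, the conventional
presentation smoothing for such traces) is applied only for plotting/export:
averaging removes independent noise while preserving the state signal and
therefore inflates |rho| mechanically; reporting the raw-frame value is the
conservative choice.  The smoother uses the largest odd frame window whose
span fits the requested width, truncated symmetrically at the edges so the
time axis and endpoints are preserved.

Uncertainty comes from a circular moving-block bootstrap on paired frames
(percentile 95% CI).  Frames are serially correlated with correlation time
1/(k_ob + k_bo); the pipeline's default block length spans 1 ns of frames,
several times that correlation time for any kinetics fast enough to sample
at 200 ns.  Block length is configurable; the CI widens with block length up
to the correlation time and stabilises after, which `analysis/03` shows
empirically.  The bootstrap is deterministic given the seed; the percentile
interval is widened (rarely, by machine epsilon amounts) to contain the
point estimate.

## Superposition and cross-RMSD

Kabsch superposition with uniform weights and the proper-rotation convention:
when the SVD of the covariance gives a reflection (det < 0), the smallest
singular direction is sign-flipped, so the result is always a rotation.
Inputs with fewer than 3 atoms or a collinear atom set are rejected (the
optimum is not unique).  The cross-RMSD matrix evaluates the post-fit RMSD
for every unordered frame pair over a named atom selection (default "CA,CB").
It is O(n²) in frames, so the pipeline subsamples to at most
`cross_rmsd_max_frames` = 150 evenly strided frames — a frame-resolution
choice, since the matrix is read as a coarse stability heatmap (low, flat
values = no major conformational change).

## The synthetic generator

The generator emulates exactly the features the pipeline measures:

- **Kinetics**: a two-state CTMC with rates k_ob, k_bo (ns⁻¹), simulated
  exactly by Gillespie (exponential waiting times, stationary initial
  state).  The path is discretized to frames by the state at each frame
  interval's **midpoint**; endpoint sampling systematically lags transitions
  by half a frame, midpoint sampling is unbiased to first order at coarse dt.
  If the fastest rate implies more than 0.5 expected transitions per frame,
  an aliasing warning is logged.
- **Emissions**: per frame, Gaussian distances conditioned on the state —
  formed 3.0 ± 0.4 Å, broken 8.5 ± 1.2 Å by default, truncated at a 0.5 Å
  floor.  These place the modes where real N–O salt-bridge traces sit
  (contact at ~3 Å, excursions to ~8–9 Å) and give a separation of 6.15
  pooled standard deviations, i.e. well-separated modes.  Optional AR(1)
  noise (coefficient φ) adds serial correlation within a state for
  bootstrap stress-testing; the default is white noise.
- **Scenarios** (`CASE_PRESETS`): `wt_ubch6_like` balanced and fast
  (k_ob = k_bo = 5/ns), `wt_ubch8_like` biased to BRIDGED and slower
  (k_ob = 3, k_bo = 1/ns → stationary BRIDGED 0.75), `k117h_like` with
  interface bridging disabled (emission forced to the broken mode —
  the short-side-chain perturbation), `d145k_like` locked BRIDGED
  (k_ob = 10, k_bo = 0.01/ns), and `uncoupled_control` with two independent
  CTMC bridges (rho ≈ 0).  Rates are chosen for statistical power at the
  default 20 000 frames × 10 ps = 200 ns of sampled time (hundreds of
  exchange events), and to reproduce the qualitative contrasts of the
  biological system, not its unknown true rates.
- **Embedding**: `embed_toy_trajectory` places the central atom at the
  origin, the interface oxygen at (d_i, 0, 0) and the remote oxygen at
  120° in the plane, plus three static CA/CB anchors, so the emitted
  distances are exactly the inter-group minimum distances of a real
  multi-model PDB file (to the format's 3-decimal precision, ≈ 2×10⁻³ Å
  after rounding).

What the generator does **not** emulate: force-field geometry (carboxylates
are single oxygens, there is no excluded volume or side-chain rotamer
structure), coupling of the two distances *within* a state (they are
conditionally independent given the state), distance autocorrelation across
state changes, and any coupling between the shuttle and global backbone
motion (the anchors are rigid, so cross-RMSD on toy data is exactly zero).
Passing tests on synthetic data therefore validate the *measurement
machinery* — calling, counting, correlation, I/O — not the realism of any
particular MD system.

## Problem sizes and numerical choices

Default study conditions: 20 000 frames at 10 ps (200 ns) per scenario;
recovery checks aggregate 10 independent seeds; the PDB round-trip check
uses 2 000 frames (the suite writes PDB copies truncated to 2 000 frames —
the statistics run on the full-length series; the PDB exists to exercise the
I/O path).  At these sizes the whole test suite runs in well under a minute
and the acceptance script in seconds.

Other numerics: distances use exact pairwise minima (no cutoffs or cell
lists — group sizes are ≤ 3 atoms); Pearson sums run in float64 with no
special compensation (agreement with an independent direct-sum oracle to
1e-12 is enforced in tests); PDB coordinates are written at the format's
fixed 3-decimal precision, bounding the round-trip error at 5×10⁻⁴ Å per
coordinate; report JSON is key-sorted with no timestamps, so identical
config + seed reproduces it byte-for-byte.

## Known limitations

- Exchange counting is gap-tolerant (intermediates do not reset a
  transition) but dwell times are strict contiguous runs; a dwell split by a
  one-frame intermediate counts as two dwells.  With hysteretic calling such
  splits are rare, but dwell means carry a small downward bias in noisy
  regimes, plus an O(dt) discretization bias.
- Occupancy is a frame fraction; no correction for the initial-state
  transient beyond the 1 ns exclusion.
- Role assignment (interface vs remote) is annotation-driven, never
  inferred.
- The PDB reader accepts blank/'A' altlocs only and rejects insertion
  codes; it is a trajectory-interchange dialect, not a general PDB
  archive parser.  Binary trajectory formats are out of scope.
- The trajectory time axis is caller-supplied metadata (`dt_ps`, default
  10 ps); the PDB format itself carries no time information.
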