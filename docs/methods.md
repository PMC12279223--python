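# Methods

## Constructs and regions

A construct is N17 (17 residues) + polyQ tract + tail (the five-proline P5,
the full proline-rich domain, or nothing). The shipped N17 and PRD sequences
are editable constants taken from the human huntingtin reference; the one
hard constraint — enforced by tests — is that default N17 positions 14–17
read `LKSF`, since the four-residue motif variants (`LKAA`, `LLLF`, `LKGG`)
are defined as substitutions of exactly those positions. Residue numbering
is 1-based and inclusive everywhere.

Default region annotations: `n_terminal_n17` = aa 3–10, `central` =
aa 11–17, `polyq` = 18..17+n, `tail` = the remainder. The central region is
sometimes taken to extend into the first polyQ turn (aa 11–23); both are
supported (`default_regions(..., central=(11, 23))`), with 11–17 as the
default so that "central" and "polyQ" never overlap.

## Secondary-structure statistics

α-helical means DSSP `H` only. 3-10 (`G`) and π (`I`) helices are excluded
by default because helical fractions in this field are routinely compared
against NMR α-propensities; any code set can be passed explicitly.

The SS-map counts, per frame, membership in **maximal runs of exact length
L**. This convention was chosen over cumulative (≥ L) counting because it
yields an exact conservation law — Σ_L P[i][L] equals the per-residue
helical fraction, since each helical residue in each frame belongs to
exactly one maximal run — which makes the implementation testable against a
brute-force per-frame oracle with zero tolerance. The cumulative variant is
provided (`mode="cumulative"`) for comparison with tools that report it.

Ensemble profiles report the mean of per-trajectory fractions and the
standard error of that mean across trajectories (ddof = 1). A single
trajectory yields SEM 0 with a warning rather than NaN.

Secondary chemical-shift differences are SCSD_i = ΔδCα − ΔδCβ relative to a
random-coil reference table (a standard Wishart-style set is built in;
users can supply their own as CSV). Glycine lacks Cβ, so its SCSD uses the
Cα term only and is flagged `ca_only` instead of being dropped — dropping
it would put a hole in the profile at every glycine.

## Initiation times and the Monte Carlo region comparison

Frame k (1-based) is assigned time k·Δt, so the earliest possible
initiation time is one frame interval and no residue initiates at t = 0.
Mean and SEM are taken over the trajectories in which the residue is
defined; residues helical in no trajectory are flagged undefined and are
excluded from region averages (with a loud warning) rather than imputed —
imputation would require inventing a censoring model the data cannot
support.

The Monte Carlo treats each residue's time as Normal(t̄_i, se_i) and
averages residues with equal weights within each region. Negative sampled
times are allowed: the normal assumption is taken literally, and truncation
would bias the region averages. Sampling runs in chunks of 10⁵ trials to
bound memory at the default 10⁶ trials; the per-trial Δt samples feed a
100-bin histogram plus exact mean/SD accumulators. With all SEMs zero the
comparison degenerates to a deterministic inequality, and P lands on
exactly 0, ½ (identical regions) or 1.

## Contacts, hydrogen bonds, β-conformers

Contact: any heavy-atom pair within 0.6 nm, counted once per residue pair
per frame (a binary predicate, not an atom-pair count). Intramolecular maps
zero the |i−j| ≤ 3 band; intermolecular maps average over all ordered chain
pairs, which is symmetric for identical chains. The cutoff is wide enough
to cover hydrogen bonds (<0.35 nm), van der Waals packing and salt bridges.

Hydrogen-bond geometry: donor–acceptor distance ≤ 0.35 nm and H–D–A angle
≤ 30° — the defaults of the standard MD tooling for this analysis; both are
parameters. Because the coordinate container carries no bond topology,
donor hydrogens are assigned to the nearest N/O within 0.12 nm in the first
frame; ensembles without hydrogens are rejected with a pointer to the
precomputed-table path (`HBondTable` CSV), which is the expected route when
an MD engine's own H-bond tool has already run.

Bifurcated-H-bond occupancy gates frames at >30% helical residues (helix
must exist for the i→i−4 geometry to be meaningful), then requires the
sidechain(i)→backbone(i−4) and backbone(i)→backbone(i−4) bonds in the
**same frame** — coexistence is read strictly, with no tolerance window.
Zero eligible frames yields NaN occupancies and a warning, not zeros.
Occupancies above 5% are styled "prevalent".

β-conformer extraction requires strictly more than 4 residues in `E` per
frame — a two-stranded sheet needs at least two strands of ≥2–3 residues,
and the strict inequality keeps borderline 4-residue frames out. Isolated
β-bridges (`B`) never count toward extraction but are tallied separately,
since a lone bridge is a qualitatively different (weaker) signal.
Classification is `n17_direct` when any β residue index ≤ 17, else
`polyq_internal`.

## Dimer order parameters and the PMF

The inter-helical angle fits each selection's Cα coordinates with the
dominant principal axis (SVD), oriented N→C by the first-to-last Cα vector,
and returns arccos of the axis dot product in [0°, 180°]. A two-atom
`end_vector` mode exists for cross-checking but is coarser, because
terminal Cα positions carry the helix spiral's phase. Parallel/antiparallel
labels follow the angle < 90° / > 90° convention; that mapping is an
interpretation, not a measurement.

The 2D PMF histograms (contact count, angle) with default bin widths of 2
contacts and 10°, normalizes over occupied bins, and reports
F = −ln(P/P_max) in kT so the global minimum is exactly 0. Empty bins hold
NaN — a sentinel, never a capped "barrier height" that the data do not
contain. Re-exponentiating F over occupied bins reproduces the histogram to
machine precision (tested).

Association/dissociation segmentation is a hysteresis state machine:
bound→unbound when the contact count drops below 1, unbound→bound at ≥ 10
residue pairs (both configurable and echoed in every output). The gap
suppresses spurious event pairs from counts oscillating around a single
threshold. The initial state is read from the first frame against the
bound threshold and entering bound at frame 0 is initialization, not an
event.

## The synthetic-data generators

`gen_ss_trajectory` is a lattice process: with no active helix, a nucleus
of 4 residues appears with probability k_nuc = 0.02 per frame, uniformly
placed inside the nucleation region; each end then extends with
p_ext = 0.20 and retracts with p_ret = 0.15 per frame, and the helix
dissolves when it shrinks past zero length. One frame = 1 ns. These
defaults were chosen once as the simplest rates that reproduce the
qualitative phenomenology the analyses assume — nucleation localized to a
chosen site, bidirectional propagation into flanking sequence, long-lived
helices with net growth — giving mean nucleation around 50 ns and arrival
at distal polyQ residues a few hundred ns later, i.e. a cleanly separated
central-vs-polyQ initiation ordering for parameter-recovery tests. Default
dynamics are single-nucleus; `multi_nucleus=True` allows concurrent
helices.

`gen_beta_frames` selects frames i.i.d. with probability β and rewrites the
given strand ranges to `E`, so the injected population is binomial and the
recovery tests use exact 3σ bounds.

`gen_dimer_coords` builds two ideal Cα-trace helices (3.6 residues/turn,
0.15 nm rise, 0.23 nm radius) at a requested inter-helical angle,
separation and axial offset. A trace covering a non-integer number of turns
has its spiral slightly correlated with the axis, which would bias a fitted
principal axis by ~1.7° per chain; the generator projects the
axis-correlated component out of the transverse coordinates so the nominal
angle is exactly recoverable and the generator can serve as geometric
ground truth. Optional isotropic Gaussian jitter (`noise`) and an overlap
check (minimum inter-chain distance ≥ 0.1 nm) are provided.

`gen_hbond_fixture` emits the backbone i→i−4 record in every frame and adds
the coexisting sidechain record only in designated frames, so B-HB
occupancy equals |designated| / |eligible| by construction.

All generators are bit-reproducible from their seed.

### What the generators do and do not emulate

They reproduce the *statistical structure* the estimators consume: DSSP
matrices with a plantable nucleation site, controlled rare-event
populations, controlled dimer geometry, and H-bond coexistence patterns.
They have no energetics, no solvent, no sequence dependence beyond the
nucleation region, and no correlation between secondary structure and
coordinates. Passing tests therefore demonstrate that the estimators
recover known ground truth under the stated models — not that any
particular force field or real ensemble behaves this way.

## Problem sizes

Default test and reproduction runs use five 5000-frame trajectories for
kinetics (10⁶ Monte Carlo trials), 10⁴ frames for rare-event recovery, and
30-residue / 20-frame ensembles for contact-map oracle equivalence — sizes
at which every closed-form and oracle comparison is sharp while a full run
completes in seconds on one CPU.

## Known limitations

- The SS-map convention (maximal exact-length runs) may differ from other
  scripts in the literature; use `mode="cumulative"` when comparing to ≥ L
  reports.
- Hydrogen assignment by proximity assumes a sensible first frame; exotic
  geometries should use precomputed H-bond tables.
- `detect_hbonds` is O(donors × acceptors) per frame in Python — fine for
  the fixture scale it targets, not for millions of frames; production MD
  pipelines should feed `HBondTable` CSVs from their engine's tooling.
- Undefined initiation times are excluded, not modelled; regions dominated
  by never-helical residues will produce optimistic SEMs.
- SSP scores are consumed as published values; the package does not compute
  them from shifts.
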