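# httex1

Trajectory-ensemble analysis for huntingtin exon-1 (Httex1) conformational
ensembles — the intrinsically disordered N17–polyQ–PRD architecture whose
polyglutamine tract drives Huntington's disease when expanded beyond
~36 repeats.

Simulation studies of Httex1 revolve around a small set of recurring
questions: where along the N17–polyQ sequence do α-helices nucleate and how
cooperatively do they propagate; how often do rare β-sheet conformers appear
as the tract lengthens; which hydrogen-bond motifs (in particular the
bifurcated Gln sidechain/backbone i→i−4 pair) stabilize polyQ helices; and
how do two N17-led chains orient and associate. This package implements
those analyses as a reusable library for people running or re-analyzing
atomistic MD of polyQ constructs, together with a synthetic-trajectory
generator that provides controlled ground truth for validating every
estimator.

## What it computes

**SS-maps (helix cooperativity).** From a frames × residues matrix of DSSP
codes, the SS-map is `P[i][L]` — the probability that residue *i* belongs to
a maximal contiguous α-helical segment of exactly length *L*. It satisfies
the conservation law Σ_L P[i][L] = f_H(i), the per-residue helical fraction,
which the test suite enforces to machine precision. A cumulative (≥ L)
variant is available.

**Helix-initiation kinetics.** A residue's initiation time is the earliest
frame time at which it first shows a helical code (frame *k*, 1-based, maps
to *k*·Δt ns); residues never helical are flagged undefined. To compare two
regions, each residue's time is modelled as Normal(t̄_i, se_i) and a Monte
Carlo (default 10⁶ trials) over equally-weighted region averages yields the
distribution of Δt = t_avg(B) − t_avg(A) and

P(A before B) = fraction of trials with t_avg(A) < t_avg(B),

which matches the closed form Φ(Δμ / √(Σse²_A/m_A² + Σse²_B/m_B²)) within
binomial error.

**Contacts and β-conformers.** Residues i, j are in contact in a frame iff
any two heavy atoms lie within 0.6 nm (intramolecular maps exclude
|i−j| ≤ 3); intermolecular maps average over ordered chain pairs. Frames
with strictly more than 4 residues in DSSP 'E' are extracted as β-conformers
and classified by whether N17 participates directly; isolated β-bridges
('B') are tallied separately.

**Bifurcated hydrogen bonds.** Over frames whose helical-residue fraction
exceeds 30%, the occupancy at glutamine *i* is the fraction of eligible
frames in which the sidechain(i)→backbone(i−4) bond coexists with the
backbone i→i−4 bond; occupancies above 5% are marked prevalent.

**Dimer landscapes.** Per-frame inter-chain N17 contact counts and the
inter-helical angle (dominant principal axis of each chain's Cα selection,
oriented N→C) feed a 2D potential of mean force, F = −ln(P/P_max) in kT
min-shifted to zero with empty bins left as NaN, plus a hysteresis state
machine that counts dissociation/reassociation events.

## Worked example

```python
import numpy as np
from httex1 import (ConstructSpec, HelixKineticsParams, default_regions,
                    gen_ss_trajectory, initiation_times, mc_region_compare,
                    ss_fraction_ensemble, ss_map)

spec = ConstructSpec(polyq_length=16)            # N17-Q16-P5, 38 residues
regions = default_regions(spec)
trajs = [gen_ss_trajectory(
            HelixKineticsParams(nucleation_region=regions["central"],
                                n_frames=5000, seed=k), spec)
         for k in range(3)]

profile = ss_fraction_ensemble(trajs)
print(f"peak helicity {profile.mean.max():.3f} at residue {profile.mean.argmax() + 1}")

times = initiation_times(trajs)
mc = mc_region_compare(times, regions["central"], regions["polyq"],
                       n_trials=1_000_000, seed=0)
print(f"P(central before polyQ) = {mc.p_a_before_b:.4f}")
print(f"mean initiation-time lag dt = {mc.delta_mean:.0f} ns")
```

prints

```
peak helicity 0.989 at residue 13
P(central before polyQ) = 1.0000
mean initiation-time lag dt = 160 ns
```

Here helicity peaks at residue 13 — inside the central region (aa 11–17)
where the generator confines nucleation — and the Monte Carlo says the
central region reliably becomes helical before the polyQ tract, lagging by
~160 ns on average under the generator's default rates. That is the
parameter-recovery loop the package is built around: the generator plants a
nucleation site, the kinetics analysis finds it.

The same operations are exposed as a CLI (`httex1 synth`, `ssmap`,
`helicity`, `shifts`, `helix-kinetics`, `contacts`, `bifurcated-hb`, `beta`,
`dimer-pmf`); every subcommand reads plain-text/CSV/PDB inputs and writes
CSV/JSON.

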