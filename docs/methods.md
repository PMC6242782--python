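# Methods

## Model

A genomic locus is coarse-grained into a bead-spring chain, one bead per
`resolution` bp (default 1 kbp; 400 bp and 3 kbp are supported). Lengths
are measured in σ (one bead diameter), energies in kBT, masses in bead
masses; the natural time unit is τLJ = σ√(m/kBT). Positions evolve under
the Langevin equation with friction γ = 2 (Brownian time τB = 2 τLJ, so
the dynamics are overdamped) and uncorrelated Gaussian noise obeying the
fluctuation–dissipation relation.

Interactions:

| term | form | defaults |
|---|---|---|
| backbone bond | FENE + WCA core | K = 30 kBT, R0 = 1.6 σ |
| sterics (all pairs) | WCA | cutoff 2^(1/6) σ |
| bending | Kratky–Porod K(1 − cos θ) | K = 4 kBT → l_p = 4 σ |
| TF–chromatin | truncated+shifted LJ | ε = 8 (binding) / 2 (other) kBT, r_cut = 1.8 σ |
| extruder bond | harmonic K(r − r0)² | K = 40 kBT, r0 = 1.5 σ |
| compaction bond (i,i+2) | harmonic K(r − r0)² | K = 40 kBT, r0 = 1.5 σ |

Harmonic conventions carry no ½ factor. The extruder bond's short-range
repulsion is supplied by the WCA sterics that every non-bonded pair
already has; the bonded i,i+1 pair is excluded from the non-bonded loop
because the FENE term contains its own WCA core.

**Bridging proteins (TFs).** `n_tf` freely diffusing beads of the same
diameter as chromatin. Each switches between a binding and a non-binding
state as a symmetric Poisson process at rate k_sw = 1.25×10⁻⁴ τLJ⁻¹;
non-binding TFs interact with chromatin purely sterically. Switching
makes the TF clusters that form at marked regions dynamic: members turn
over while the cluster persists.

**Loop extrusion.** A fixed pool of extruders (default ⌈n_beads/100⌉; the
published parameter set fixes the pool-size concept but not the count).
An unbound extruder binds at rate k_on (default 10⁻³ τLJ⁻¹, also not
pinned by the published set) across a random free (i, i+2) span —
(i, i+3) in heteromorphic mode, since i,i+2 is already bridged by a
compaction spring. Both sides then step outward at regular intervals set
by the extrusion speed k_ex = 2 bp/τLJ (one two-bead enlargement per
2·resolution/k_ex = 1000 τLJ at 1 kbp/bead). A side is blocked by the
chain ends and by beads occupied by other extruders (extruders cannot
pass), and halts permanently — while bound — at a realized anchor whose
motif orientation opposes its direction of motion; `both`-oriented
anchors halt either direction. Unbinding (k_off = 2.5×10⁻⁵ τLJ⁻¹) is
unaffected by halting; processivity k_ex/k_off = 80 kbp. Candidate
binding spans containing any occupied bead are rejected, which together
with single-bead steps keeps spans nested-or-disjoint at all times.

**Heteromorphic fiber.** Compaction springs are placed on every i,i+2
pair whose *both* endpoints lack the H3K27ac mark. Acetylated regions
keep the plain 4 σ-persistence fiber. The spring constants are taken
equal to the extruder bond (40 kBT, 1.5 σ) — the published account gives
the functional form but not the values, and this choice is the single
most consequential free parameter of the package (see *Crumpled-fiber
persistence length* below).

## Input annotation

Coordinates are 0-based half-open; bead i covers [start + i·r,
start + (i+1)·r). H3K27ac peaks mark beads *open* on ≥1 bp overlap.
TF-binding beads come either from the same any-overlap rule
(`mode="acetylation"`) or from the bead containing each accessibility
peak centre (`mode="accessibility"`). CTCF/cohesin peaks become anchors:
a 3-kbp window around the peak centre is scanned with a log-odds PWM on
both strands; the better strand sets the orientation unless it is less
than 2% (relative) better, in which case the anchor halts both
directions. Occupancy is linear in peak height normalised by the tallest
peak (a rank-based mapping would also be consistent with the published
description; linear is the simpler choice), and each anchor is realized
independently per replicate with that probability.

## Integration

BAOAB splitting: half kick, half drift, exact Ornstein–Uhlenbeck velocity
refresh (factor e^(−γΔt/m), noise amplitude √((1−e^(−2γΔt/m)) kBT/m)),
half drift, half kick, at Δt = 0.01 τLJ. For a free particle this
discretisation gives the exact Maxwell velocity distribution and a
diffusion constant within 10⁻⁵ of kBT/γ, which the test suite checks via
equipartition and Einstein-relation assertions. Non-bonded forces use a
periodic cell list with a 0.4 σ skin rebuilt every 10 steps (verified
against an all-pairs oracle); the attraction cutoff 1.8 σ is applied to
both specific and non-specific TF interactions. Positions are kept
unwrapped with minimum-image displacements, valid while the chain extent
stays below half the box side (enforced at construction).

A replicate is initialised as a random walk (bond 0.97 σ) with TFs placed
uniformly; 50 τLJ of force-capped dynamics (|F| ≤ 200 kBT/σ) relax
random-walk overlaps, followed by `t_equil` of bare-polymer dynamics
(attractions and extruders off), then the production run. Snapshots of
bead positions are taken every `t_snapshot`; analyses discard
t ≤ `t_discard`. The default schedule (50×10⁴ τLJ, snapshots every
2×10³ τLJ, first 10×10⁴ discarded) retains 200 snapshots per replicate.
TF-switching and extrusion kinetics are applied between MD chunks every
`t_kinetic` = 10 τLJ (≪ all kinetic timescales). Trajectories are
bit-reproducible for a given seed.

## Assays and scores

*Capture-C.* Per snapshot and viewpoint, N−1 random beads are accepted
with probability f(d) = exp(−d²/d0²), d0 = 3.5 σ; the same number of
attempts per viewpoint makes rejected attempts stand for out-of-region
interactions (the rejected fraction is reported). A variance-free
expected-count mode ((attempts/N)·f(d) summed over snapshots) exists
alongside the stochastic sampler; the sampler is the default, the
expected mode is used where sampling noise would obscure a comparison.
Counts are collected into 3-kbp bins fed from centred 6-kbp windows
(each interior count lands in exactly two bins; edge windows are
truncated). Simulated profiles are scaled by one joint factor so their
grand total matches the experimental total, preserving relative
variation. Contact maps use the mean of f(d) over snapshots with the
same d0, for internal consistency; distance maps are mean pairwise
distances.

*FISH.* Probe positions are centres of mass of the probe's bead range;
one separation sample per retained snapshot.

*Unit calibration.* σ(nm): coarse-to-fine grid search (final lattice
0.01 nm) minimising the summed two-sample KS statistics between scaled
simulated and experimental probe-pair distributions. τLJ(ms):
least-squares scaling of the simulated bead MSD onto a reference curve
in log–log coordinates.

*K-score* = 1 − mean KS statistic over matched probe pairs ("normalised"
is read as the KS statistic's intrinsic [0,1] range); the SD of the
per-pair statistics is reported as dispersion. *Q-score*: profiles are
truncated (values < 0.35 in scaled units → 0; the threshold rescales
with the reference total), smoothed with a 5-bin moving average, and
peaks found as local maxima with prominence ≥ 5% of the profile maximum,
widths at half prominence — the published procedure names a peak finder
but no settings, so these are package defaults, all exposed. Peak
overlap is closed-interval intersection; q_ij = (n_se + n_es)/(n_s +
n_e), Q = mean over viewpoint×cell-type with peak-free pairs excluded.
Randomized controls: Q — the simulated peak count per profile scattered
uniformly over the locus with a peak at the viewpoint always present and
widths set to the mean experimental width; K — separations drawn
uniformly over each simulated distribution's range; both Monte-Carlo
averaged.

## Ensemble analysis

Γ(A,B) = √[Σ_{i≠j}(d_ij(A) − d_ij(B))²/(n(n−1))] over an analysis region
(1000 beads in production use); average-linkage hierarchical clustering
with the cophenetic correlation reported, flat clusters by cut height
(groups are interpreted manually; no automatic count is promised). Size
and shape: radius of gyration and relative shape anisotropy κ² from the
positional gyration tensor (κ² is the standard measure; the published
account only fixes its endpoints, 0 = sphere, 1 = line). Three-probe
summaries: locus size S = ⅓√(d₁²+d₂²+d₃²) (equals the 3-point Rg);
variability volume = product of the principal moments of the
conformation-space gyration tensor, which equals det of the covariance
matrix of the separation triples (algebraic identity, tested). Contact
grouping at 6 σ: the five groups are (1) no contacts, (2) promoter–URR,
(3) promoter–DRR, (4) URR–DRR only, (5) all three; conformations where
the promoter contacts both enhancers while the enhancers are mutually
apart are counted in group 5 (the published five-way scheme has no
separate slot for them). Activity T = 1/d_URR + 1/d_DRR, heterogeneity =
SD(log(T/⟨T⟩)).

## Crumpled-fiber persistence length

For a uniform fully compacted chain the contour is smoothed with a
5-bead sliding average, subchains of w smoothed points are extracted at
all start positions (stride w/4), and the ensemble mean Rg²(L) over
subchain contour length L is fitted with the Benoit–Doty worm-like-chain
expression Rg²(L) = L·l_p/3 − l_p² + 2l_p³/L − (2l_p⁴/L²)(1−e^(−L/l_p)).
The choice of Benoit–Doty is ours; subchains are averaged over both
start position and snapshots. On ideal discrete worm-like chains with a
known l_p the unsmoothed fit recovers the planted value within a few
percent; the 5-bead smoothing, applied to an already-smooth chain,
biases l_p upward (≈ +25% at l_p = 4 σ bond-lengths) — it is used only
on crumpled fibers, matching the published procedure, where the raw
zig-zag has no measurable contour without it.

Desk-scale production setting: a 512-bead chain in an 80 σ box,
1.2×10⁴ τLJ equilibration, 1.2×10⁴ τLJ production with snapshots every
500 τLJ and the first 4×10³ discarded, two replicates pooled; subchains
up to 120 smoothed points, long enough for a stable fit and short enough
that their relaxation time sits well inside the equilibration run.

Two calibration facts bound what this estimate can show. First, a
discrete Kratky–Porod chain does not have l_p = K/kBT exactly: the
tangent correlation per bond is ⟨cos θ⟩ = coth K − 1/K, so
l_p = −b/ln(coth K − 1/K) ≈ 3.5 bond lengths at K = 4 (the K/kBT
identity is the large-K limit). An open-fiber control simulated to
steady state indeed measures l_p ≈ 3.4–3.8 σ by the Rg(L)/WLC
procedure, validating both the engine and the estimator against the
exact discrete result. Second, the estimate depends directly on the
assumed compaction-spring parameters (40 kBT, 1.5 σ), which the
published account does not state. With these choices the package
measures l_p ≈ 3.2–3.5 σ for the crumpled fiber, below the published
4.7 σ — consistent with the spring stiffness/rest length (and fit
range) being the unpublished degrees of freedom. The honestly computed
estimate, not the published value, is what `scripts/acceptance.py`
reports.

## Synthetic data

`generate_synthetic_locus` lays out a gene flanked by upstream and
downstream regulatory clusters: acetylated blocks, accessibility peaks
(±200 bp around each binding site), oriented CTCF anchors with heights,
three probes (±5 kbp around URR/promoter/DRR) and matching viewpoints.
It emits BED-style tables whose re-annotation reproduces the model
exactly. `generate_pseudo_experiment` turns a reference trajectory into
experimental-format data: expected-value Capture-C profiles with
per-bin lognormal noise, and FISH samples scaled by a chosen σ(nm) with
multiplicative Gaussian jitter; at zero noise the K/Q scores against the
reference sit at their self-consistency ceilings (limited only by the
0.01 nm σ lattice), and they degrade monotonically with noise. What the
synthetic locus does not emulate: replicate structure, mappability and
visibility biases of real Capture-C, optical measurement error in FISH,
or any sequence-level realism — passing tests demonstrate internal
consistency of the pipeline, not predictive power on real loci.

## Numerical and degenerate-input choices

FENE bonds at r ≥ R0 abort the run (signals too large a timestep);
non-finite coordinates abort with a diagnostic. Profiles with zero peaks
on both sides are excluded from Q with a warning; zero distances are
rejected by the activity score (regularisation is the caller's choice);
degenerate all-zero Γ matrices yield a single cluster with undefined
cophenetic coefficient; probe/anchor coordinates outside the locus are
errors, CTCF windows without an admissible motif position drop the site
with a warning. The KS statistic is computed by direct ECDF evaluation
(equivalent to `scipy.stats.ks_2samp`, asserted in tests) so the 0.01 nm
grid search stays cheap.

## Known limitations

No hydrodynamics, no GPU path, no replica exchange. The engine targets
desk-scale systems (≲10³ beads, ≲10⁴ TFs); production-scale runs
(5000 beads, 50×10⁴ τLJ × 10 replicates) are feasible but slow on one
core. Experimental Capture-C inputs are consumed pre-normalised;
sequencing-read processing is out of scope. The K/Q headline values of
any real-locus study depend on the experimental datasets and full-scale
ensembles; this package reproduces the *procedures* and verifies them on
synthetic data.
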