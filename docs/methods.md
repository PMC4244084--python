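# Methods

`oligotraj` analyzes trajectories of systems in which several short
amyloidogenic peptides (the reference system: ten copies of Aβ17–42, the
26-residue p3 fragment) diffuse, oligomerize and bind a single inhibitor
protein — either a dimer of the α-crystallin core domain (ACD, residues
66–150 of αB-crystallin) or human lysozyme — inside an orthorhombic
periodic box. This note records the conventions the package uses, the
reasoning behind the genuinely open design choices, and what the synthetic
generators do and do not emulate.

Units are fixed everywhere: Å for length, ns for time, kcal/mol for energy,
e for charge, mM for concentration.

## Contact definition

Two residues are in contact when **any pair of their heavy atoms is within
5 Å**, boundary inclusive, with the minimum-image convention applied in the
orthorhombic box. Hydrogens are excluded at load time (element field, with
an atom-name fallback). The "number of contacts" between two chains is the
number of **residue pairs** in contact; a heavy-atom-pair count is also
available (`ContactConfig.count_atom_pairs`) because some published
contact-count distributions are ambiguous about which convention they use,
but the residue-pair reading follows directly from the residue-level
definition of a contact and is the package default everywhere.

The fast path is a periodic k-d tree (`scipy.spatial.cKDTree` with
`boxsize`); below 200 atoms a vectorized O(n²) minimum-image computation is
used directly, and the same O(n²) route doubles as an independent oracle
(`residue_contacts_brute`) that the test suite checks the tree path against
on hundreds of randomized fixtures. Boxes smaller than twice the cutoff
trigger a warning (image ambiguity), not an error. Triclinic boxes are not
supported.

## Oligomer and complexation classification

Per frame, the peptide graph has an edge between two peptides sharing
**strictly more than 5** residue contacts (so ≥ 6; the threshold is strict
everywhere in the package). Oligomers are the connected components of this
graph; isolated peptides are monomers. A peptide is **complexed** when it
forms strictly more than 5 contacts with the inhibitor entity, where a
multi-chain inhibitor (the two ACD domains) counts as one logical entity;
an oligomer is complexed as soon as at least one member peptide is bound —
the per-member rule identifies the attaching peptide, not all members.

Species classes: monomer (n = 1), small oligomer (n = 2–5), large oligomer
(n > 5), each split free/complexed, plus an "uncomplexed inhibitor"
indicator (1 when no peptide is bound). Classification is a pure function
of each frame's contact record; species time series are per-frame counts
averaged inside time bins (default 50 ns), not majority votes. A trailing
partial bin is reported with its own frame count and flagged in the
metadata. Multi-run averaging is an unweighted mean per bin.

## Free-energy surfaces

For every peptide in every frame the pair (x, y) = (contacts with the
inhibitor, contacts with all other peptides) is sampled; samples are pooled
across peptides, frames and runs, histogrammed at 1 contact per bin, and
Boltzmann-inverted:

    W(x, y) = −kB·T · ln[ P(x, y) / Pmax ],   kB = 0.0019872041 kcal/mol/K

so the most populated bin defines W = 0 and empty bins are masked (infinite
W, excluded from the minimum). The default temperature is 325 K, giving
kBT = 0.6459 kcal/mol; both values are recorded in the output metadata.
`region_population` reports the fraction of samples in an arbitrary (x, y)
region, e.g. the inhibitor-bound-monomer basin {x ≥ 5, y < 5}. No
reweighting or WHAM-style estimators are attempted; the surface is a plain
Boltzmann inversion of the sampled histogram.

The test oracle for this stage is analytic: samples drawn from a
discretized 2D Gaussian must invert to a quadratic surface whose value in
the 2σ bin matches the normal density integrated per bin (≈ 2 kBT = 1.292
kcal/mol at 325 K).

## Survival-time kinetics

Each peptide yields a binary bound series b(t) (contacts with the inhibitor
> 5). Before correlation, interior unbound gaps of duration **strictly
less than t0 = 1 ns** that are flanked by bound frames are bridged
("short excursions"); leading/trailing gaps are never bridged, and the
strictness at exactly t0 is a declared convention (a gap lasting exactly
t0 survives). Bridging is applied once, up front — equivalent to, and much
easier to test than, on-the-fly allowances during origin scanning.

The survival correlation is

    S(Δ) = ⟨ Σ_j 1[ b_j ≡ 1 on [t, t+Δ] ] ⟩_t

averaged over every time origin t of one run (stride 1 by default; for
stride 1 the computation reduces to a closed form over maximal bound runs).
S(0) is therefore the mean number of simultaneously complexed peptides, and
S is reported in absolute peptide counts with S/S(0) alongside. Curves from
independent runs are averaged unweighted after the per-run average, never
by pooling origins across runs. Mean residence times come from either a
least-squares exponential fit of ln(S/S(0)) over lags with S > 5 % of S(0),
or a trapezoidal integral of S/S(0) flagged as a lower bound when the curve
has not decayed below that floor.

## Structural metrics

Superposition is the standard Kabsch algorithm (SVD of the weighted
covariance, reflection-corrected to a proper rotation); near-collinear
point sets trigger a conditioning warning. RMSD series align every frame to
a fixed reference over a selection (default: Cα atoms of the inhibitor
chains). RMSF uses the iteratively aligned mean structure as reference
(two align→average cycles), then reports per-residue
√⟨|r_i − ⟨r_i⟩|²⟩ over the residue's selected atoms; a fixed native
reference can be supplied instead. The independent oracle for Kabsch in the
tests is a multi-start numerical minimization over rotation vectors.

## Contact probability maps

All maps are conditioned fractions over pooled observations:

* **Inhibitor × peptide** maps: an observation is one (frame, peptide) with
  the peptide complexed (> 5 inhibitor contacts); cell (i, j) is the
  fraction of observations with residues i and j in contact.
  Unconditioned maps are available by flag. The per-residue profile is the
  probability of contacting *any* inhibitor residue, computed from
  per-observation bookkeeping rather than from map cells (any-contact
  dominates every pair cell). Per-type profiles average the any-contact
  probability over residues of one amino-acid type; types absent from the
  sequence are reported as absent, not zero.
* **Tertiary** maps: intra-peptide contacts with sequence separation ≥ 3
  (the i±1, i±2 band is masked), over the complexed or the free population.
* **Quaternary** maps: cross-chain contacts over interacting peptide pairs
  (> 5 mutual contacts), where for the complexed population at least one
  member must be inhibitor-bound and for the free population neither may
  be. Cells are binarized per dimer observation and symmetrized by
  construction, so a persistent contact reads 1.0.

Observations are pooled across runs before probabilities are computed
(per-run maps remain available for dispersion estimates).

## Synthetic data

Two generators with deliberately opposite trade-offs:

**Markov placement generator.** Each peptide's bound state is an
independent two-state Markov chain (per-frame switch probabilities
1 − exp(−k·dt)). Bound peptides are docked at one of several verified
surface patches of a static inhibitor bead lattice (two 5×17 sheet domains
for the ACD dimer, a compact block for lysozyme); free peptides are
re-placed uniformly each frame at ≥ 15 Å from the inhibitor and ≥ 10 Å from
every other peptide; all coordinates get σ = 0.3 Å Gaussian jitter.
Peptides are 26-residue single-bead-per-residue blobs numbered 17–42, so
residue-indexed maps carry the Aβ17–42 labels. Optional dimerization rates
pair peptides; only a dimer's first member may dock (the attaching-member
picture). Ground truth — per-frame bound flags, oligomer partition,
realized residence intervals — is exact by construction and, by default,
re-derived from the emitted coordinates with the package's own contact
definitions and required to match frame by frame (the generator
self-check). Default scenario: 10 peptides, 124 Å box, dt = 0.2 ns over
200 ns, k_off = 0.01/ns (≈ 100 ns mean residence), k_on = 0.02/ns
(stationary occupancy 2/3).

What this generator does *not* emulate: diffusion (free peptides teleport),
conformational change, partial/graded binding, many-body oligomers beyond
dimers, or any energetics. Passing tests on it demonstrate that the
analysis stack measures what it claims on data whose answer is known — not
that real trajectories behave this way.

**Brownian toy.** An overdamped Langevin integrator over bead chains with
harmonic bonds, soft-core repulsion and Gaussian-well attraction; the
inhibitor bead cluster is held static with per-bead stickiness, either
uniform ("lysozyme-like") or patchy ("ACD-like"). It produces *emergent*
aggregation for integration tests, checked only for direction of effect
(no attraction → monomeric; strong peptide–peptide attraction → large
oligomers). A stability heuristic rejects time steps that would not relax
the bond term, and a per-step displacement guard (5 Å) aborts with a
diagnostic on blow-up. Defaults (D = 10 Å²/ns, k_bond = 2 kcal/mol/Å²,
dt = 5 ps) are chosen for integrator stability at toy scale, not for
physical realism.

## Problem sizes used in the automated checks

Parameter-recovery runs use 10 peptides, 2000 ns at dt = 0.5 ns
(4001 frames), k_on = 0.05/ns, five seeds per k_off ∈ {0.01, 0.05, 0.2}/ns,
analyzed fully end-to-end (geometry → contacts → bridging → survival →
exponential fit); these sizes give a few hundred binding events per sweep
point, enough for the 15 % recovery tolerance with margin. The
Boltzmann-inversion check uses 10⁵–10⁶ Gaussian samples at σ = 6 bins.
Oracle-equivalence suites use 200 randomized 50-residue fixtures of 3–6
atoms per residue (above the brute-force crossover, so the tree path is
what is being checked).

## Known limitations

* Orthorhombic boxes only; no triclinic minimum image.
* The survival estimator assumes uniformly spaced frames (it refuses
  otherwise); origin stride > 1 falls back to a slower explicit scan.
* The exponential residence fit is unweighted in log space; for strongly
  non-exponential decays prefer the integral estimator and treat flagged
  values as lower bounds.
* Binary trajectory formats (DCD/XTC) require mdtraj, an optional
  dependency; the plain-text fallback format is always available.
* Secondary-structure analysis and any energetic decomposition are out of
  scope.
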