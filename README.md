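# oligotraj

Trajectory analysis of early amyloid-peptide oligomerization and its
inhibition by a binding protein.

`oligotraj` is for computational biophysicists who simulate systems of
several short aggregating peptides (the reference system is ten copies of
Aβ17–42, the 26-residue p3 fragment) together with one inhibitor protein —
an α-crystallin core-domain (ACD) dimer or human lysozyme — in a periodic
box, and want the standard readouts of such simulations as a tested,
reusable pipeline:

* **Contacts** — residue-level heavy-atom contacts (any heavy-atom pair
  within 5 Å, minimum-image corrected), with a periodic k-d-tree fast path
  cross-checked against a brute-force oracle.
* **Species classification** — per-frame oligomer detection (connected
  components of the peptide graph; edge = strictly more than 5 contacts),
  inhibitor complexation flags (> 5 contacts with the inhibitor entity),
  and time-binned counts of free/complexed monomers, small (n = 2–5) and
  large (n > 5) oligomers.
* **Free-energy surfaces** — 2D potentials of mean force
  W(x, y) = −kBT ln P(x, y)/Pmax over (inhibitor contacts, inter-peptide
  contacts) per peptide, plus basin populations.
* **Residence-time kinetics** — the survival correlation
  S(t) = ⟨Σ_j 1[peptide j continuously bound over t]⟩ with bridging of
  unbound excursions shorter than t0 = 1 ns, and exponential/integral
  mean-residence estimators.
* **Contact-probability maps** — inhibitor × peptide pairwise maps,
  per-residue and per-amino-acid-type binding profiles, and tertiary
  (|i−j| ≥ 3, intra-chain) and quaternary (inter-chain, conditioned on
  complexation) maps.
* **Structural metrics** — Kabsch superposition, Cα RMSD series, per-residue
  RMSF about the aligned mean structure.
* **Synthetic data** — a Markov placement generator with exact,
  self-validated ground truth and a Brownian bead-chain toy with emergent
  aggregation, so the whole pipeline is testable without external
  trajectories.

## Worked example

Generate a synthetic binding trajectory with known kinetics and recover the
residence time end-to-end:

```python
from oligotraj.model import molar_concentration, formal_charge
from oligotraj import sequences
from oligotraj.synthetic import KineticScenario, markov_binding_generator
from oligotraj.kinetics import (KineticsConfig, bound_series,
                                survival_correlation, mean_residence_time)

# system-preparation arithmetic for the reference box
print(f"{molar_concentration(10, 124.0):.2f} mM")       # 8.71 mM
print(formal_charge(sequences.ABETA_17_42))             # -1  (e, at pH 7)

# ten peptides, one ACD-like dimer, 2 µs at 0.5 ns/frame, 1/k_off = 20 ns
sc = KineticScenario(n_peptides=10, n_frames=4001, dt=0.5,
                     k_on=0.05, k_off=0.05, seed=42)
traj, truth = markov_binding_generator(sc, validate=False)

series = bound_series(traj, config=KineticsConfig())    # contacts -> 0/1 series
curve = survival_correlation(series, KineticsConfig(max_lag=60.0))
est = mean_residence_time(curve)
print(f"S(0) = {curve.S[0]:.2f}; tau = {est.tau:.1f} ns")
# S(0) = 5.19; tau = 22.4 ns
```

`S(0) = 5.19` is the mean number of simultaneously complexed peptides
(stationary occupancy k_on/(k_on+k_off) = 1/2 of ten peptides, plus noise);
`tau = 22.4 ns` is the fitted mean residence time for this seed, to be
compared with the generator's 1/k_off = 20 ns. Averaged over seeds the
estimator recovers 1/k_off to within a few percent (see the acceptance
script below).

The same analyses run from the shell via a YAML config:

```bash
oligotraj simulate --kind markov --seed 1 --outdir sim
oligotraj -v all --config sim/config.yaml     # contacts, species, pmf,
                                              # survival, maps, rmsd, rmsf
```

Every stage writes a TSV with a one-line header plus a JSON sidecar
carrying the configuration, its hash and the package version.

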