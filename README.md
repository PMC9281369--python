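# g4validate

Validation of molecular-dynamics ensembles of quadruplex–duplex DNA
against NMR observables.

G-quadruplexes (G4s) are four-stranded DNA motifs of stacked guanine
tetrads held by cyclic Hoogsteen hydrogen bonds and stabilized by
cations (K⁺, Na⁺) in the central channel. Hybrid systems such as the
HIV LTR-III promoter element add a duplex stem hanging off a long
diagonal loop, joined to the quadruplex through a flexible two-residue
junction — a challenging target for force fields and an attractive one
for ligand design. MD simulations of such systems are only as useful
as their agreement with solution NMR data, and this package implements
the full desk-side comparison loop for people running those
simulations:

- **NOE back-calculation and violation accounting.** Each interproton
  restraint is back-calculated over the equilibrated frames as the
  ensemble average d = ⟨r⁻⁶⟩^(−1/6) (pooling all equivalent-proton
  pairs before the −1/6 power), and a restraint counts as violated when
  a bound is exceeded by more than a tolerance (1 Å by default).
  Violations are attributed per residue.
- **Hydrogen-bond statistics** for the tetrad network (four N1–O6 and
  four N2–N7 Hoogsteen bonds per tetrad), the Watson–Crick G·C stem
  (O6–N4, N1–N3, N2–O2), and the bifurcated N1–N7 geometry monitored
  as a force-field artifact; a bond is formed when the donor–acceptor
  distance is ≤ 3.0 Å and the donor–H–acceptor angle is ≥ 135°.
- **Backbone torsion occupancy matrices** (α β γ δ ε ζ per residue,
  15° bins over [−180°, 180°), normalized) with per-model NMR-bundle
  overlays.
- **Element-wise RMSD and RMSF**: quadruplex bases, whole backbone and
  duplex backbone measured separately against every model of the NMR
  bundle, with 1000-point running averages; fluctuations per residue
  about the average structure.
- **Ion-atmosphere analyses**: center-of-mass RDFs g(r) =
  n(r)/(ρ·4πr²dr) with the bulk density ρ taken from a 30 Å reference
  shell, voxelized spatial distribution functions (0.125 Å³ voxels,
  normalized to water-like density), per-frame channel-state
  classification (bulk → approach → in-plane → cavity), and an
  occupancy-based binding free energy ΔG = −RT ln K from bound/unbound
  counting.
- **Duplex-flexibility clustering**: frames aligned on the quadruplex,
  pairwise RMSD on the duplex, hierarchical agglomerative clustering,
  medoid representatives reported to 80% cumulative population.

Every stage is exercisable without any downloads through a synthetic
generator that builds an idealized tetrad stack (all Hoogsteen
donor–acceptor distances solved into the 2.8–3.0 Å band), a GC duplex
stem, Gaussian-fluctuating trajectories with known per-group
amplitudes, scripted ion-entry events and self-consistent restraint
tables — so analyses can be checked against ground truth.

## Worked example

```python
from g4validate import RunConfig, SyntheticSpec
from g4validate.pipeline import run_validation, run_ions

cfg = RunConfig(
    seed=1, output_dir="out",
    synthetic=SyntheticSpec(
        n_frames=200,
        ion_schedule=[(0, "bulk"), (20, "approach"), (30, "cavity")]),
)
print(run_validation(cfg))
print(run_ions(cfg))
```

prints (reports land in `out/` as TSV/JSON):

```
{'config_hash': 'c4b6a06f50bf9d08', 'n_restraints': 483, 'n_violations': 0,
 'violation_tolerance': 1.0, 'violations_per_residue': {},
 'n_hbond_definitions': 33, 'hbond_mean_persistence': 0.202,
 'rmsd_g4_final_running_avg': 0.521, 'n_frames': 200}
{'state_fractions': {'bulk': 0.05, 'approach': 0.025, 'in-plane': 0.0,
 'cavity': 0.925}, 'bound_fraction': 0.925,
 'delta_g_kj_mol': -6.27, 'one_sided': False, 'n_events': 2}
```

Reading this: the 483 restraints were derived from the generated
ensemble itself, so none is violated at the 1 Å tolerance — the
self-consistency check a real study would run before trusting its
violation counts. The quadruplex-base RMSD settles near 0.5 Å (the
imposed σ_G4 = 0.3 Å per coordinate, times √3, after superposition).
One ion follows the scripted entry path — bulk for 20 frames, an
approach pause above the outer tetrad plane, then stable cavity
binding — while the second sits in the channel throughout; counting
cavity frames as bound gives ΔG = −RT ln(0.925/0.075) ≈ −6.3 kJ/mol at
300 K. H-bond persistence is low because uncorrelated Gaussian noise,
unlike a force field, does not preserve hydrogen bonds; on a static
ideal structure every monitored bond scores persistence 1.0.

The same stages run from the shell:

```bash
g4validate all --config config.yaml
g4validate manifest --config config.yaml   # systems x replicates totals
```

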