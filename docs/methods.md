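# Methods

This note documents the models, conventions and numerical choices
behind each analysis stage, what the synthetic generator does and does
not emulate, and the known limitations.

## Conventions

Coordinates are Å, times ps, angles degrees, energies kJ/mol. Residue
indices are 1-based (G1…G28 style); frame indices are 0-based with
half-open ranges. Atom masks use a small documented selection grammar
(`resid` ranges, `name`/`resname`/`element` lists, `heavy`, `all`,
combined left-to-right with `and`/`or`/`not`) rather than an external
selection language, because every mask the pipeline needs is a residue
range plus an atom-name list.

## NOE back-calculation

Interproton distances are compared with restraint bounds through the
ensemble average

    d = ( ⟨ r⁻⁶ ⟩_{frames, pairs} )^(−1/6)

where the average pools all equilibrated frames and all inter-group
proton pairs of an ambiguous restraint **before** the −1/6 power.
Averaging (not summing) over equivalent protons treats a pseudoatom
group as interchangeable positions and preserves the identity
d = r for a constant distance; users comparing against sum-averaging
conventions should expect systematically shorter distances from those.
A restraint is violated when d exceeds a bound by more than the
tolerance (default 1 Å, the conventional allowance for the
uncertainties in NOE-derived bounds); each violation is attributed
once to both participating residues, matching per-residue violation
histograms. Violation counts are monotonically non-increasing in the
tolerance by construction.

Equilibration is a predicate over frames. Default: discard the first
10% — a plateau detector (first frame after which the all-atom RMSD
running average stays within 0.5 Å of its final value) and arbitrary
callables are available, since "equilibrated part" is inherently a
judgement call. Pseudoatom names in restraint files (QH2′, H5′#, QM7,
…) are expanded to explicit protons at parse time from a packaged
nomenclature map; unmapped wildcard-like names are a hard error, and
restraint-dialect sniffing is refused outright — silently misparsing
distance bounds is the worst failure mode a validation tool can have.

## Hydrogen bonds

Distance is donor–acceptor; the angle is donor–H–acceptor (the most
linear choice when an amino donor carries two candidate protons —
physically, "the proton involved"). A bond is formed when distance
≤ 3.0 Å **and** angle ≥ 135°; persistence is the formed fraction of
frames. Per tetrad the cyclic Hoogsteen pattern defines four N1–O6 and
four N2–N7 bonds in donor order; per G·C pair the three Watson–Crick
bonds O6–N4, N1–N3, N2–O2; optionally four bifurcated N1–N7 bonds per
tetrad, monitored because force fields are known to over-stabilize
that geometry.

## Torsion matrices

The six backbone torsions follow the IUPAC atom quadruples; the 5′
residue (no phosphate) lacks α and β, the 3′ residue lacks ε and ζ —
standard deposition practice, so a 28-mer has 28·6 − 4 = 164 defined
angles. Histograms use left-closed 15° bins over [−180°, 180°) after
reduction to the principal value and are normalized per (residue,
angle); combinations with missing atoms are marked undefined (NaN),
never zero-filled, so absence of data cannot masquerade as zero
occupancy. NMR-bundle torsions are attached per model as overlay
points.

## Superposition, RMSD, RMSF

Superposition is Kabsch (SVD with reflection guard), the global
least-squares optimum. RMSD series are computed against every model of
a reference bundle, with independent align and measure masks (e.g.
align on all heavy atoms, measure on quadruplex bases) so that element
contributions can be separated; running averages use centered,
edge-shrunk windows (output length equals input length). RMSF
superposes frames onto their mean structure, recomputes the mean once,
then takes per-atom root-mean-square deviations and averages them per
residue. For isotropic per-coordinate Gaussian noise of amplitude σ
the expected per-atom RMSF is σ√3, which the generator recovers within
a few per mil at 5000 frames — the basis of the calibration test. The
default RMSD mask is heavy-atom; all-atom is a flag away.

## Ion analyses

**RDF.** g(r) counts selected particles in shells around the per-frame
solute center of mass under the minimum-image convention, normalized
by ρ·4πr²dr with the bulk density ρ measured in a thin reference shell
(default [30, 31) Å — the shell must fit inside the periodic box).
The un-normalized cumulative count n(<r) is returned alongside; for a
channel permanently holding two cations it integrates to exactly 2
beyond the first peak. The spherical-shell scheme has a known
excluded-volume bias near irregular solutes (it underestimates g just
outside the molecular surface); no correction is applied, and the
limitation is recorded in the profile metadata. Peak positions are
unaffected; peak heights are qualitative.

**SDF.** Frames are aligned on the solute, particle positions
histogrammed on a cubic grid (0.125 Å³ voxels), time-averaged, and
normalized by a reference density so that 1 means bulk-water-like.
The default reference density is 0.033456 Å⁻³, the number density of
water at ≈1.0 g/mL; any other convention can be passed explicitly.
Grids export as OpenDX text for visualization.

**Channel states.** Tetrad O6 centroids define the channel geometry
per frame: an ion is *in-plane* when within 1.0 Å of a tetrad
O6-centroid plane and inside that tetrad's in-plane radius, *cavity*
when within 2.0 Å of an inter-plane midpoint, *approach* when on the
solvent side of an outer plane by at most 4.5 Å and near the axis,
otherwise *bulk*. The in-plane slab is tested **before** the cavity
sphere: at the canonical 3.4 Å stacking rise a point lying exactly in
a tetrad plane is only 1.7 Å from the nearest midpoint, i.e. inside
the cavity cutoff, so the reverse order could never label an in-plane
ion. All thresholds are configuration, not fixed truth — the
three-stage entry picture (approach, in-plane pause, cavity
coordination) motivates the defaults, but no experimental thresholds
exist.

**Binding free energy.** K = (bound ion-frames)/(unbound ion-frames)
and ΔG = −RT ln K with R = 8.314 J mol⁻¹ K⁻¹ at a stated temperature
(default 300 K). Bound defaults to the cavity state only — stable
positioning between two tetrad planes is what binding means here;
in-plane visits count as unbound. An empty class on either side yields
a flagged one-sided result, never a number. ΔG is antisymmetric under
swapping the class definition.

## Clustering

Frames are aligned on the quadruplex and pairwise RMSD is measured on
the duplex; each (i, j) entry averages both superposition orientations
so the matrix is exactly symmetric. Agglomerative clustering uses
average linkage by default (robust to chaining; single/complete are a
parameter away) with either a cluster-count or a merge-distance
stopping criterion. Representatives are medoids (minimum summed
intra-cluster distance, ties to the lowest frame index), reported in
descending population until the cumulative population reaches the
coverage target (default 80%). Trajectories longer than 10⁴ frames
are strided (default 10) before the O(n²) matrix, with the stride
recorded in the output.

## Synthetic generator

The generator emulates the three inputs of a validation study.
*Structures*: guanine and cytosine bases use standard planar
reference-frame heavy-atom geometry with the minimal atom set the
analyses touch, plus sp2-placed protons and a schematic sugar–
phosphate chain (geometrically plausible, chemically approximate —
sufficient for masks, torsions and interproton distances, not for
force-field work). The tetrad placement (radius and base orientation
under C4 symmetry) is solved numerically at import so both Hoogsteen
donor–acceptor distances are exactly 2.9 Å on the sterically open
branch; the Watson–Crick cytosine placement is a soft-band fit holding
all three pair distances inside [2.82, 2.98] Å. Channel cations sit
exactly midway between adjacent O6-centroid planes. Defaults — 3
tetrads, 3 GC pairs, 2 channel ions, 3.4 Å rise, 30° tetrad twist,
36° duplex twist — are the canonical stacking geometry of the system
class this package targets.

*Trajectories* add isotropic per-coordinate Gaussian noise with
per-group amplitudes (defaults σ_G4 = 0.3 Å, σ_duplex = 0.6 Å,
σ_ions = 0.05 Å: a rigid core with a duplex about twice as mobile,
the flexibility ordering such systems show), frames every 10 ps in an
80 Å cubic box (large enough to hold the 30 Å bulk reference shell).
Scripted ion-entry schedules rewrite one ion's coordinates onto
per-frame geometric anchors of the four channel states, so a
classifier must recover the schedule exactly. *Restraints* derive from
a reference structure or ensemble: every proton pair within a cutoff
becomes a restraint with target = (ensemble r⁻⁶ average) distance and
bounds target ∓ padding.

What the generator does **not** emulate — and what passing tests
therefore do not show about real data: correlated motions, anisotropic
fluctuations, energetically maintained hydrogen bonds (persistence
under Gaussian noise is far below force-field values; static
structures score 1.0), conformational transitions, explicit water,
and force-field physics of any kind. Self-consistency results (zero
violations on self-derived tables, exact state recovery) validate the
bookkeeping and the estimators, not any simulation.

## Problem sizes

The test suite and the acceptance script run synthetic systems of a
few hundred atoms with 10–5000 frames: large enough for the
closed-form checks (σ√3 within 5%, ideal-gas g(r) within three
Poisson standard errors, 10⁵-sample torsion histograms within three
binomial standard errors) and small enough that the entire suite
completes in seconds. Headline per-condition numbers from
microsecond-scale simulation studies (specific violation counts per
solvent environment, plateau RMSD values, ΔG in the −1 to −3 kJ/mol
range) require real MD sampling and are intentionally not asserted.

## Known limitations

- No excluded-volume or ellipsoidal RDF correction (metadata-flagged).
- No NOE intensity simulation (spin relaxation, spectral densities),
  order parameters, or chemical-shift back-calculation.
- DNA only, no RNA; no automatic G4 topology classification
  (parallel/antiparallel/hybrid).
- mmCIF writing and velocity/force trajectory channels are out of
  scope; XTC round-trips are lossy at the format's 10⁻³ nm precision.
- The NMR-STAR reader targets distance-constraint loops only; it is
  not a general STAR parser.
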