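# Methods

## Physical model

The simulator transports photons only, under the **kerma approximation**:
at every collision the energy transferred to secondary electrons is
deposited at the collision site. At Cs-137 energies the CSDA range of
secondary electrons in water is ≲ 3 mm and charged-particle equilibrium
holds everywhere except within a fraction of a millimetre of the
bone–water interfaces, so collision kerma is an adequate surrogate for
absorbed dose at the 0.1 cm tally resolution used here. Electron
transport, bremsstrahlung, and bound-Compton (Doppler) corrections are
not modelled.

The source is a bare isotropic point emitter of monoenergetic 0.662 MeV
photons at the centre of a water sphere (default radius 15 cm, chosen so
that ≥ 5 cm of backscattering water surrounds the outermost 10 cm tally
shell, approximating full-scatter conditions). No encapsulation or cable
is modelled. The optional heterogeneity is a single concentric shell of
ICRP cortical bone (ρ = 1.85 g/cm³) spanning [d, d + t); *d* — "the
distance of the layer from the source" — always denotes the **inner
radius** of the shell, for both the tables and the thin-layer factor.

Transport is **analog**: no variance reduction, so the energy-deposition
estimator retains its plain physical meaning. Histories terminate by
photoelectric absorption, escape, or the 0.01 MeV cutoff (the photon's
remaining energy is deposited locally; the mean free path of a 10 keV
photon in water is ~2 mm and shrinking fast, so this truncation is
sub-resolution). Energy bookkeeping is exact: deposited + escaped equals
emitted to ~1e-12 relative, and the suite asserts 1e-6.

## Interaction data

Each material carries tables of μ/ρ (total mass attenuation), μ_en/ρ
(mass energy-absorption) and the photoelectric interaction fraction on a
16-point energy grid covering 0.01–0.8 MeV, shipped as plain-text files
with provenance headers. μ/ρ and μ_en/ρ are transcribed from the
NIST/Hubbell–Seltzer compilations for liquid water and ICRP cortical
bone. Coefficient lookups interpolate **log–log** (exact for power-law
segments, the standard choice for photon cross sections).

Compton scattering uses the free-electron **Klein–Nishina** cross
section, sampled by the standard two-branch rejection method on
ε = E′/E; the scattering angle follows from Compton kinematics. Coherent
(Rayleigh) scattering is not modelled as a scattering channel; because
the tabulated μ/ρ includes it, its attenuation share is folded into the
absorption channel by defining the photoelectric fraction as
1 − σ_KN·N_A·(Z/A)/(μ/ρ). This slightly overstates low-energy absorption
(where coherent scattering is a few percent of the total) and keeps the
transport's total interaction coefficient equal to the tabulated μ/ρ.

## Dose estimators and the kerma coefficient

Three per-shell estimators are scored in the same run:

* **track-length kerma**: Σ segment-length · E · κ(E)/V over all photon
  path segments in the shell;
* **analog energy deposition**: Σ energy handed to electrons at
  collisions in the shell, / shell mass;
* **binned-fluence fold**: track-length fluence accumulated in energy
  bins (default width 10 keV), folded with κ at bin midpoints.

Here κ(E) is the **model-consistent collision-kerma coefficient**
μ/ρ · [f_pe + (1 − f_pe)(1 − ⟨E′/E⟩_KN)], i.e. the expected energy
transfer per unit path *of this transport model*. Using the tabulated
μ_en/ρ instead would mix two inconsistent physics descriptions (the NIST
values include binding, coherent and radiative effects the transport does
not simulate) and would shift the track-length and binned-fluence
estimators several percent away from the analog one for reasons that have
nothing to do with estimator behaviour. With a common κ the three
estimators agree in expectation; their observed discrepancies isolate
exactly the effects of interest — Monte Carlo variance for the analog
estimator, and energy-discretisation error for the binned fold, which
grows where the local spectrum is soft (far shells) and with bin width
(the bin width is a configuration knob, and halving it demonstrably
shrinks the gap). μ_en/ρ remains available through `lookup_coefficient`.

## Uncertainties and determinism

Histories are processed in fixed order from one seeded generator and
split into 20 consecutive batches; every reported relative standard error
is the batch-mean SE divided by the mean, and derived quantities (layer
averages, ΔD%) propagate from per-batch values so intra-shell
correlations are respected. Identical (config, histories, seed) give
bit-identical results; the compiled kernel is single-threaded.

## Dose-difference tables

ΔD%(d, t) is evaluated **inside** the bone layer: both the heterogeneous
and the homogeneous-reference dose are volume-weighted averages over the
0.1 cm tally cells spanning [d, d + t) (the cells share one material, so
mass weighting reduces to volume weighting), using the track-length
estimator. One homogeneous run per table serves as the common reference;
each (d, t) gets an independent stream seeded by a stable hash of
(base seed, d, t), recorded in the metadata. The layer-averaged
convention (one number per (d, t)) feeds the correction table; per-cell
profiles remain available from the simulation output. The production
grid is d = 0.1–10 cm step 0.5, t = 0.2–1.8 cm step 0.1 (the schema
accepts any lattice-aligned grid, e.g. extension to t = 2.0 cm); tests
and the validation study use a reduced 5 × 3 grid.

Tables serialise to a single long-format CSV (`d,t,delta_pct,sigma_pct`)
with `# key=value` metadata headers; reads are strict (complete
rectangular grid, increasing axes, required metadata) and round-trip
exactly.

## Correction engine

* **Dispatch**: t < 0.4 cm → thin path; t ≥ 0.4 cm → thick path. The
  threshold tie goes to the thick path (the thin model is stated for
  layers *below* 0.4 cm). The seam at t = 0.4 is a genuine model
  discontinuity and is reported, not smoothed.
* **Thick path**: bilinear interpolation on the (d, t) grid (bicubic is
  available behind a keyword for sensitivity checks). Queries outside
  the grid hull are clamped to it, flagged on the result, and warned
  about — never silently extrapolated.
* **Thin path**: CF(x) = −0.00003 x³ + 0.006 x + 0.956 with x = d; the
  coefficients are stored exactly as published and the model can be
  refitted to a freshly simulated thin-layer dose-ratio curve by least
  squares with the quadratic coefficient constrained to zero.
* **Validation**: leave-one-out — each interior node is re-predicted
  after deleting its row and column (equivalently, from its four
  diagonal neighbours) and compared to its directly simulated value.
  The reported error subtracts a per-node noise floor: the quadrature
  sum of the node's own σ and the bilinear-weighted corner σ's.

## Synthetic fixture surfaces

`generate_fixture_table` samples analytic ΔD% surfaces (`bilinear`,
`cubic`, `paper_like`) with optional seeded Gaussian noise. The
`paper_like` surface reproduces the qualitative physics (negative near
the source, monotone in d, sign flip near 7.5 cm, deficit deepening with
thickness) but none of the Monte Carlo noise correlation structure,
material physics, or tally geometry of real builds — tests against it
verify interpolation and I/O machinery, not transport physics, which is
exercised by the Monte Carlo studies.

## Problem sizes

Per-shell statistics drive the choice of history counts. The analog
deposition estimator's relative SE at the outermost 0.1 cm shells is
≈ 1.8 % per 10⁶ histories, so an estimator-agreement study at the 1 %
level needs that noise pushed to ≈ 0.3 %: the homogeneous
estimator-comparison study uses 4 × 10⁷ histories (≈ 3 min on one CPU
with the compiled kernel). Table builds use 10⁶ histories per run
(layer-average σ ≈ 0.03–0.1 percentage points), which keeps a full
reduced-grid build with validation under two minutes. Unit tests use
0.05–1 × 10⁶ histories.

## Numerical choices

* Kernel physics lookups are resampled onto a 256-point dense log-energy
  grid (0.01–0.7 MeV) at setup; inside the kernel, interpolation is
  linear in (log E, log value).
* Boundary stepping tracks the shell index explicitly; points landing
  numerically on a boundary hop to the neighbour shell, and degenerate
  (≤ 1e-12 cm) crossing distances are nudged, so rays cannot stall.
* The Klein–Nishina sampler exists twice by design: a vectorised NumPy
  implementation behind the public API and a scalar compiled version
  inside the kernel; a chi-square test validates each against the
  analytic density.
* Shell membership is half-open [inner, outer), outermost shell closed.

## Known limitations

* Absolute doses are "MeV/g per source photon" in an idealised geometry;
  no TG-43 anisotropy/radial-dose-function formalism, no absolute
  calibration (Gy h⁻¹ U⁻¹), no encapsulated source model.
* Free-electron Compton and the coherent-into-absorption lumping bias
  low-energy transport slightly; trends and internal comparisons are
  robust to this, absolute ΔD% values at the deepest points may shift by
  fractions of a percentage point with better cross-section data.
* One heterogeneity shell, one material (cortical bone), one source
  energy per run; the table schema, not the physics, is the only part
  that generalises beyond that without new code.
* The thin/thick dispatch is discontinuous at t = 0.4 cm; users needing
  continuity should build tables that cover thin layers too.
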