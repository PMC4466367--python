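# Methods

`dnadamage` simulates the *direct* (physical-stage) induction of DNA strand
breaks by ionizing radiation in coarse-grained geometric models of the three
canonical DNA conformations — right-handed A and B, left-handed Z — packed
into a chromatin-fiber region of interest (ROI). Indirect (radical-mediated)
chemistry is deliberately out of scope.

## Geometric model

Five organisation levels are modelled analytically:

1. **Base pair.** An inner "base" cylinder of diameter `bp_diameter` carries
   two sugar-phosphate **targets**, each an angular sector of the hollow
   cylinder between the base radius and the helix radius:
   `V = (aperture/360)·π·(r_max² − r_min²)·h`. Per-conformation dimensions
   (helix diameter, bp diameter, axial step, pitch, bp/turn, aperture, target
   height, inter-strand axial shift) are tabulated in
   `geometry.CONFORMATION_TABLE`. Target heights are below the axial step so
   that bending the helix around the histone cannot make adjacent targets
   touch.
2. **Double helix.** Base pair *i* is twisted by `i·(±360°/bp_per_turn)`
   about the local helix axis — negative for the left-handed Z form. Strand 2
   is strand 1 rotated by 180°. The tabulated "helix axial shift" is recorded
   but not applied by default (see *Design choices*).
3. **Nucleosome.** The helix axis is wound into two stacked circular loops of
   radius `ρ = bp_per_nucleosome·step/(4π)` (≈5.2 nm for all three forms,
   consistent with a 10.5 nm external nucleosome diameter), their planes
   offset by ±¼ of the nucleosome height (5.25 nm, i.e. a disk-shaped
   nucleosome of 10.5 × 5.25 nm). Base pairs are placed by arc length; each
   loop carries exactly half the base pairs, closing the circle exactly.
4. **30 nm fiber.** Six nucleosomes per 10.5 nm axial level, at 60° spacing
   on a ring of radius 8.0 nm about the fiber axis, *alternating between two
   z sub-levels* (a two-start, solenoid-like zigzag), with a configurable 30°
   ring rotation per level. The ring radius and the zigzag were chosen so
   that — provably, via bounding-torus arithmetic executed at model-build
   time — all ~3400 targets of a level are pairwise disjoint and contained in
   the fiber cross-section for every conformation. A flat ring of six
   nucleosomes cannot satisfy both constraints inside a 30 nm fiber.
5. **ROI.** A thin annulus of central diameter 10 μm, radial thickness 30 nm
   and height 5.25 μm, filled with water at 1.06 g/cm³, tiled azimuthally by
   900 fragments (0.4° each) of 500 levels. Each fragment's interior is a
   straight vertical fiber expressed in fragment-local coordinates
   (arc-length, radial offset, z); the local↔lab map is an exact bijection,
   and its ≤0.3 % volume distortion averages out by symmetry. The 30 nm
   radial thickness is a reconstruction: it is the fiber diameter, and it is
   the unique thin-annulus thickness that reproduces the reference volume
   ratios from the tabulated dimensions.

Totals: 900·500·6 = 2.7·10⁶ nucleosomes; 7.722/5.346/4.644·10⁸ bp and
1.54/1.07/0.93·10⁹ targets for A/B/Z.

### Torus-coordinate targets

Targets are defined in the torus coordinates of their loop: an arc-length
window of width `target_height` centred on the bp's arc position, a radial
shell `r_min ≤ r < r_max` about the bent helix axis, and an angular sector of
width `aperture` about the bp's twist angle. This makes the event locator an
*exact* analytic inverse of target placement (no straight-prism
approximation at the ends of a window). The per-target Jacobian of the bent
frame, `1 + d_r/ρ`, cancels *exactly* between the two strands of a bp (their
sectors are 180° apart), so the summed target volume — and hence every
volume ratio — equals the analytic sector formula.

All interval membership tests are half-open (`[low, high)`) in angle, radius,
arc length and height, which makes the 0°/360° seams exact and tie-breaking
deterministic (lower index wins on a measure-zero boundary).

## Event location and damage scoring

`locate_points` inverts the placement hierarchy analytically (annulus →
fragment → level → six nucleosome candidates → loop → arc window → shell →
sector) and is vectorised; 10⁵ points locate in ≈0.15 s on one core.

Scoring rules:

- **SSB**: any located event with energy transfer ≥ 8.23 eV (inclusive); a
  target hit *n* times contributes *n* SSBs. Because the minimum event energy
  is 9 eV, every in-target event qualifies, and the site-hit probability
  (breaks / in-ROI inelastic events) reduces to the in-target event fraction.
- **DSB**: two SSBs on opposite strands of the same nucleosome separated by
  ≤ 10 bp; each SSB joins at most one DSB. Pairing is greedy nearest-first in
  (bp, strand) order with ties to the lower bp index; tests enforce equality
  with an exhaustive maximum-cardinality matching on all clusters of ≤ 8
  SSBs. No linker DNA is modelled, so cross-nucleosome DSBs are impossible
  (documented limitation). Complex DSBs are not classified; a 4-SSB cluster
  counts as two adjacent DSBs.
- **TSB**: all SSBs including those consumed by DSBs.
- **Yields**: `n_X / (dose · total_bp)` per bp per Gy; the factorised form
  (site-hit probability × events per unit dose / bp) is kept as an algebraic
  cross-check.

## Synthetic event generators

The generators replace a condensed-history transport engine; they produce
event *lists*, not physics.

- **Uniform mode** — positions i.i.d. uniform in the annulus (uniform in z,
  azimuth and r²). This is the geometry-validation condition: the expected
  hit fraction equals the total-target/ROI volume ratio.
- **Track mode** — complete vertical primary trajectories at uniform annulus
  positions; events per trajectory ~ Poisson with linear density
  LET/ε̄ (LET in keV/μm ≡ eV/nm); a fraction of events (default 0.70) is
  assigned to secondary electrons, displaced laterally by an isotropic
  exponential distance (scale 5 nm) and grouped into geometric-size clusters
  (mean 3) with 1 nm isotropic Gaussian intra-cluster jitter; histories are
  generated until the cumulative in-ROI dose reaches the target (default
  100 Gy), always completing the final history. Events displaced outside the
  annulus are discarded from dose and from all event counts.

Parameter defaults and their provenance: mean energy per inelastic event
ε̄ = 55 eV overall (quasiconstant for light ions and their electrons);
electron-class mean 48 eV (secondary-electron mean energy ≈50 eV), which
fixes the primary-class mean at ≈71.3 eV and puts 0.7·48/55 ≈ 61 % of the
dose on electrons — reproducing both reported electron shares (≈70 % of
events, ≈61 % of dose) from two inputs rather than asserting them
independently. Minimum event energy 9 eV (the minimum inelasticity of the
transport model being emulated). The lateral scale (5 nm), cluster size
(mean 3) and jitter (1 nm) are free parameters of the surrogate with no
printed reference values; they were fixed once at electron thermalisation
length scales in liquid water.

What the surrogate does *not* emulate: stopping-power evolution along the
track, charge-transfer cycles, phantom depth and beam energy selection, δ-ray
energy spectra, or absolute event-per-dose calibrations. Consequently,
passing the trend tests shows that the *geometry and scoring* respond to
clustering, LET and conformation the way the reference analysis reports —
not that the event lists are physically accurate tracks.

### Clustering enrichment

With purely translation-invariant sampling the expected hit fraction equals
the volume ratio regardless of clustering (the event-position marginal is
uniform), so the surrogate's site-hit enrichment above the analytic
prediction arises from a boundary mechanism: trajectories near the annulus
edges lose part of their laterally displaced electron events (discarded) and
also traverse target-poor columns, so the pooled breaks/events ratio
overweights target-rich central trajectories. At 100 Gy and LET
66.9 keV/μm this measures ≈ +7–10 % for all three conformations. The
per-run site-hit probability is heavy-tailed (a run contains only ~10
primary trajectories at this LET), so the enrichment test averages 40
replicate seeds; 10 replicates cannot resolve a ~8 % effect against ~12 %
per-run scatter.

## Dosimetry and uncertainties

Absorbed dose = Σ in-annulus energy deposits / ROI mass
(4.948·10⁹ nm³ × 1.06 g/cm³ = 5.245·10⁻¹⁵ kg; 100 Gy ↔ 3.274·10⁶ eV).
All stochastic quantities carry one standard deviation of the mean. The
site-hit SEM uses per-history batch ratios in track mode and ten equal
batches in uniform mode (the batching scheme is a package choice, recorded in
outputs). The site-hit probability is defined as breaks over in-ROI inelastic
events — the definition that reproduces the reference magnitudes — with
out-of-annulus events excluded from both numerator and denominator.

## Numerical and reporting choices

- One 64-bit-seeded `numpy` generator per run; every sampled quantity flows
  from it; the seed is echoed in all outputs. Fixed seed ⇒ byte-identical
  event sets and result CSVs.
- Reference three-decimal volume ratios are printed *truncated* (0.03879 →
  0.038, 0.01851 → 0.018); the reporting script follows that convention, the
  library always returns full precision.
- Problem sizes: 10⁵ uniform points per conformation for Monte Carlo
  validation (statistical error ≈2 % relative); 100 Gy per track-mode run
  (~6·10⁴ events); 40 seeds for enrichment/ordering means, 10 seeds per LET
  for the LET sweep.

## Known limitations

- No linker DNA, histone atoms, hydration shell or atomistic (van der Waals)
  target definitions; no bent-fiber curvature inside a fragment.
- Z-DNA's dinucleotide zigzag is averaged into a uniform −30°/bp twist (the
  tabulated aperture/height already average the repeat).
- The meaning of the tabulated inter-strand "helix axial shift" is undefined
  in the source material; applied literally it would make strand-2 targets
  overlap strand-1 neighbours, so the default keeps it at zero (volumes and
  all validated ratios are insensitive to it).
- Track mode is a statistical surrogate; its absolute yields are not
  comparable to transport-code results, only its trends are meaningful.
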