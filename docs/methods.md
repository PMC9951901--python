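# Methods

## 1. Pseudophase kinetic model

The emulsion is partitioned conceptually into oil, interfacial and aqueous
pseudophases with volume fractions Φ_O + Φ_I + Φ_W = 1.  For an
oil-insoluble antioxidant the distribution is fully described by one
partition constant P_W^I = (AO_I)/(AO_W), the ratio of effective (per-litre-
of-region) concentrations.  A probe reaction whose rate is proportional to
the interfacial antioxidant concentration gives

    k_obs(Φ_I) = [AO_T] · k_I · P / (Φ_I · P + Φ_W),      Φ_W = 1 − Φ_O − Φ_I.

**Fitting.**  Two estimators are exposed:

* `reciprocal-linear` — because Φ_W is itself affine in Φ_I, the reciprocal
  1/k_obs = [(P−1)Φ_I + (1−Φ_O)] / ([AO_T]·k_I·P) is exactly linear in Φ_I;
  ordinary least squares on (Φ_I, 1/k_obs) back-transforms to (P, k_I), with
  standard errors propagated from the slope/intercept covariance by the
  delta method.  Exact on noiseless data, but the reciprocal transform
  reweights multiplicative noise.
* `nonlinear` (default) — unweighted least squares of the rate law directly
  on k_obs, initialized from the reciprocal-linear estimates plus five
  seeded multiplicative restarts (log-normal, σ = 0.3) with the lowest-SSE
  solution retained.  Standard errors are asymptotic, from the Jacobian at
  the optimum.  No bootstrap is attempted by default; the ±-style
  uncertainty reported is therefore an asymptotic SE and makes no claim to
  be a confidence interval or replicate spread.

Only the composite [AO_T]·k_I is identifiable from a k_obs series; k_I is
reported relative to the user-supplied [AO_T].

**Distribution quantities.**  %AO_I = 100·Φ_I·P/(Φ_W + Φ_I·P);
(AO_I) = [AO_T]·(%AO_I/100)/Φ_I, and the aqueous analogue with Φ_W.  The
percentage enters the effective-concentration formula as a fraction —
this is the only reading under which the module's mass-balance identity
Φ_I·(AO_I) + Φ_W·(AO_W) = [AO_T] holds, and it reproduces the ~70-fold
interfacial enhancement at Φ_I = 0.005 with [AO_T] = 1e-4 M.  The oil
fraction defaults to Φ_O = 0.10 (a 1:9 v/v formulation), giving Φ_W = 0.86
at Φ_I = 0.04 and hence 81.2 % interfacial at P = 93.

## 2. Synthetic droplet generator

The generator emulates the *radial structure* of an equilibrated
surfactant-stabilized oil droplet, not molecular packing or dynamics — no
force field, thermostat or excluded volume.  Defaults are the reference
composition: 200 oleic acid, 20 polysorbate 80, 8 gallic acid, 33,804
water sites, core radius 20 Å, interfacial thickness 17 Å (midpoint of the
16–18 Å band), bulk water extending 23 Å beyond the interface.

* **Oleic acid** — one COM site per molecule, volume-uniform in the core
  sphere.  The cloud is recentred so its mass-weighted COM is *exactly* the
  origin; the analysis reference point then coincides with the generative
  origin and placement laws round-trip to machine precision.
* **Surfactant** — three sites per molecule on one radial ray: oleate tail
  at R_core − 3 Å, sorbitan ring at R_core + 2 Å, ethylene-oxide hydroxyl
  termini at R_water − 2 Å (Gaussian radial jitter, σ = 0.8 Å), reproducing
  the tail-inward / headgroup-outward layering.
* **Water** — point sites with *uniform radial density* (uniform in R, not
  in volume).  Only water's radial profile is ever analyzed, and the
  default profile normalization is a per-Å histogram; uniform-in-R makes
  the bulk profile flat, which is what the plateau-based boundary detector
  expects.  The 3-D density this implies is not physical and is not used.
* **Gallic acid** — rigid placements of an idealized heavy-atom template:
  regular aromatic hexagon (C–C 1.39 Å), hydroxyl oxygens O0/O3 (meta) and
  O4 (para), carboxyl carbon C7 with O1/O2; the para axis O4–C4–C1–C7 is
  exactly collinear and the ring exactly planar.  Hydrogens are omitted —
  every downstream observable depends on heavy-atom geometry only.  The
  COM radius is drawn from a configurable law (default Gaussian, mean 31 Å,
  sd 6 Å: the mode matches the observed radial maximum, and the sd was set
  once so that the implied core/interface/water occupancy lands near the
  reported ≈79/19/<2 split for 20/37 Å boundaries).

**Orientation sampling.**  A rigid orientation has three degrees of
freedom; once the body-frame direction of the radial vector is fixed (two
angles), α, β and γ are all determined, and the remaining spin about the
radial vector changes none of them.  The three angles therefore cannot be
imposed independently.  The sampler supports: a joint (α, β) draw (solve
for the body-frame radial direction analytically, γ implied; infeasible
pairs — those violating the spherical triangle inequality with the fixed
α̂–b̂ separation of ≈74.5° — are rejection-resampled); a γ-only draw
(uniform in-plane azimuth, α/β implied); single-angle α or β draws
(uniform azimuth about the respective axis); mixtures of joint (α, β)
components; or isotropic.  The default is a two-component equal-weight
mixture centred at (55.5°, 64.5°) and (82.5°, 154.5°), the two reported
orientational maxima.  After the body-frame solve, the template is rotated
so that direction maps onto the inward radial direction, spun uniformly
about it, and translated to the sampled radius.

All generators derive their streams from a single integer seed via labelled
`SeedSequence` children, so every artifact is reproducible bit for bit and
stages are statistically independent.

## 3. Structural observables

* **Reference point** — the droplet COM is the mass-weighted centre of the
  *oleic-acid* sites only; including water would make it box-dependent.
* **Radial profiles** — per-molecule reference points (COMs; surfactant
  sites kept separate) pooled over frames and histogrammed at 1 Å (default)
  into a per-Å probability density (unit integral).  This raw normalization
  is the default because it is the one under which bulk water plateaus; a
  shell-volume-corrected variant (density/4πr², renormalized) is available
  behind `volume_corrected=True`.
* **Region boundaries** — core radius: first bin edge where the oleic
  cumulative *strictly exceeds* `core_cut` (default 0.95; the strict
  comparison makes a sharp-edged uniform core report its full support).
  Water onset: left edge of the first bin reaching `bulk_cut` (default
  0.90) of the bulk plateau, the plateau being the mean density over the
  outer 20 % of bins; a linear trend over that window exceeding 15 % of the
  plateau raises a boundary-estimation error (profile still rising — box
  too small).  Both cuts are configurable because the underlying notion
  ("decreases drastically", "reaches a constant value") is qualitative.
* **Region occupancy** — per-frame classification of molecule COM radii
  into [0, core), [core, onset), [onset, ∞), percentages averaged over
  frames; sums to 100 by construction.
* **Oxygen insertion depths** — per-label nucleus distances to the droplet
  COM pooled over molecules and frames (nucleus, not O–H group COM).
* **Orientation angles** — R points from the molecule COM to the droplet
  COM.  α: angle to the para axis estimated as the total-least-squares
  (SVD) line through O4, C4, C1, C7, oriented O4→C7 (the orientation
  convention resolves the α ↔ 180−α ambiguity).  β: angle to COM→C6.
  γ: 90° minus the acute angle between R and the SVD plane normal of the
  six ring carbons, folded to [0°, 90°] because the plane is unsigned;
  γ = 90° when the ring is parallel to the droplet surface.  Degenerate
  inputs (zero-length R, collinear ring) raise geometry errors.
* **Angle histograms** — default 3° bins, chosen so every half-degree
  reported maximum (55.5, 64.5, 82.5, 154.5) is a bin centre.  1-D maxima:
  bins exceeding both neighbours; 2-D maxima: bins strictly dominating
  their 8-neighbourhood, ranked by density.
* Frames are assumed pre-imaged (droplet whole, no periodic wrapping) and
  are treated as an unordered ensemble; no dynamical observables.

## 4. Oxidation kinetics

The simulator integrates (LSODA, rtol 1e-8) the mass-action scheme

    initiation   → ROO·            rate r_init
    ROO· + RH    → ROOH + ROO·     k_prop   (alkyl + O2 → peroxyl taken as
                                             instantaneous, O2 in excess)
    2 ROO·       → products        k_term
    ROO· + ArOH  → ROOH + ArO·     k_inh    (n_stoich radicals per ArOH)

with the conjugated-diene signal proportional to cumulative hydroperoxide.
Defaults (hours, mol/L): r_init = 6.7e-6, k_prop = 200, k_term = 1e6,
k_inh = 1e7, RH₀ = 0.32 (≈10 % v/v oleic oil), ArOH₀ = 1e-4, n = 2 — chosen
so the inhibition rate dominates propagation during the lag
(k_inh·ArOH₀ ≫ k_prop·RH₀) and the antioxidant-depletion time
n·ArOH₀/r_init ≈ 30 h, a realistic accelerated-assay induction period.
With ArOH₀ = 0 the curve has no lag (the model has no hydroperoxide-
decomposition autocatalysis), so a control's two-line fit legitimately
reports "no breakpoint"; the pipeline records this rather than failing.

**Induction time.**  For every interior breakpoint leaving ≥ 3 points per
side (2 for slope + intercept, 1 for residual estimation), straight lines
are least-squares fitted to each side; the split minimizing total SSE wins
and τ_IND is the intersection abscissa.  The search is exhaustive — no
smoothing, no multi-segment models.  Ties in SSE resolve to the smallest
breakpoint index.  Errors: < 6 points; parallel lines (relative slope
difference ≤ 1e-12); propagation slope not exceeding lag slope;
intersection farther than one observed time-range outside the data.
τ_IND is invariant under affine maps of the signal axis and equivariant
under affine maps of the time axis, so raw absorbance and the relative
%ΔCD signal (implemented as 100·(A_t − A₀)/A₀, the standard method's exact
oil-mass/path-length factors being irrelevant under that invariance) give
identical induction times.

## 5. What the synthetic data do and do not show

The generator produces the *study conditions* with known ground truth, so
passing round-trip tests demonstrate that the estimators recover what was
put in (boundaries within one bin, occupancies within CLT bands, angle
maxima at generating bin centres, fits unbiased to ≈1 % under 5 %
multiplicative noise).  They do not demonstrate anything about real
interfacial physics: no excluded volume, no hydrogen bonding, no
correlation between frames, surfactant reduced to three sites, water to
radii.  Equally, the large-scale simulation-derived quantities (the
79/19/<2 split, the 16–18 Å thickness, the specific angle maxima) are
emulated by construction here, not re-derived — re-deriving them would
require a multi-hundred-nanosecond trajectory of the full system.
Electronic-structure energetics (H-transfer barriers, reactive events) are
entirely outside scope.

## 6. Problem sizes used in the shipped checks

The test suite and acceptance script run ensembles of 25–50 frames with
1–8 antioxidant molecules, 100–150 oil sites and 0.5–3k water sites, 200
Monte-Carlo fit replicates, and 40–240-point kinetic curves — sizes chosen
as the smallest at which the statistical tolerances above are comfortably
resolved.
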