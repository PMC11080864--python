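# Methods

This note records the models implemented in `evstereo`, the assumptions they
make, the defaults and why, and the numerical choices that a maintainer would
otherwise have to reverse-engineer from the code.

## Geometric model

**Cell.** Adherent endothelial cells are idealised as pancakes (flat
cylinders): diameter *d* = 24 μm, height *H* = 4 μm by default, giving a total
membrane area `A = 2π(d/2)² + πdH = 1206.4 μm²` (two faces plus lateral
wall).  A protrusion site is a band on the lateral wall with vertical extent
*h* = 2 μm.  The band area is `πdh = 150.8 μm²`; the band fraction
`p = πdh/A = 0.125` is the probability that a single *en face* section
samples one site.  The 2-μm extent is read as a z-extent on the lateral wall
(not an arc length): that is the only reading under which the band-area
arithmetic `πdh` is meaningful.

**Vesicles.** MCMVs, MVBs and ILVs are spheres, nested with strict
containment and non-overlap of siblings.  Ellipsoids are out of scope; the
measured mean axes (1.08 μm MCMV, 367 nm MVB) are used as sphere diameters
directly, with no Wicksell unfolding — profile majors are treated as true
diameters, matching how the measurements are used in the estimators.

**Sections.** Serial sections are contiguous half-open slabs
`[kT, (k+1)T)`, *T* = 70 nm, cut from the coverslip plane (z = 0) upward.
Half-openness makes "the first section in which a structure appears"
unambiguous; a sphere merely tangent to a slab boundary from outside is not
in the slab (measure-zero contact).  The profile a slab shows of a sphere is
the largest in-slab circular cross-section — the full diameter if the
equator is inside, otherwise the chord circle `2√(r² − δ²)` at the nearest
in-slab plane — because a microscopist measures the widest visible extent.

## Synthetic culture generator

The generator is the study-condition stage: its defaults *are* the model
conditions, and the estimators are validated by recovering the generator's
parameters rather than by re-deriving unavailable data.

| parameter | default | rationale |
|---|---|---|
| site rate λ | 0.75 /cell | the band-model estimate "about ¾" |
| site z-extent | 2 μm | conservative protrusion-site extent |
| MCMV diameter | 1.08 μm, lognormal CV 0.2 | mean of measured axes; only a mean is reported, so a lognormal with a conventional CV is a stated assumption |
| MVB per MCMV μ_N | 1.0, Poisson | "about one per MCMV"; only the mean is reported |
| MVB diameter | 367 nm, lognormal CV 0.2 | measured mean major axis |
| ILV occupancy | 0.65 | fraction of MVBs containing ≥1 ILV |
| ILVs per occupied MVB | 1 + Poisson(2) | MVBs typically hold several ILVs; only occupancy is reported |
| ILV diameter | uniform 50–100 nm | reported range |
| omega rate | −ln(0.57) ≈ 0.562 /MCMV, Poisson | calibrated so P(≥1 omega) = 43% |
| bottom jitter | 0.7 μm | see below |

**Site placement.** Per-cell site counts are Poisson(λ).  Each site lands on
the faces or the lateral wall with probability proportional to area (the
lateral wall carries 25% of a default cell's surface); only lateral-wall
sites are detectable *en face*.  A lateral site's centre is uniform over
`[h/2, H − h/2]`, i.e. the band always lies wholly on the wall.  This is the
choice that makes the single-section detection probability of one site
exactly the band fraction `p = (πdH/A)·(h/H) = 0.125`; allowing sites to
straddle the wall edges and truncating them would shrink the mean covered
extent to 1.75 μm and silently break the equivalence between the generator
and the band-sampling model that the whole validation rests on.  A 2-μm
cluster sitting wholly on a 4-μm wall is also the physically natural picture.

**MCMV placement.** MCMV centres rest above the coverslip (z ≥ radius;
the generator never cuts a body by the substrate).  Each body's bottom is
lifted by U(0, 0.7 μm): block faces are never perfectly flat relative to the
knife, so each structure has a random phase with respect to the section
grid.  0.7 μm is ten section thicknesses, which makes that phase exactly
uniform at the default *T* — the condition under which a sphere of diameter
*D* spans `(D+T)/T` sections on average.  Lateral (x, y) positions do not
affect *en face* statistics and are uniform over a field auto-scaled to keep
bodies sparse; MCMV–MCMV overlap is not modelled.

**Nested packing.** MVBs (and ILVs) are placed by rejection sampling:
position uniform over the allowed centre ball, diameter redrawn per attempt,
non-overlap with siblings enforced, 1000 attempts per body.  Unconditional
size and count draws can produce physically impossible broods (three 367-nm
MVBs "assigned" to a 0.5-μm MCMV), which real cultures avoid because vesicle
sizes correlate with available space.  The generator reproduces that
correlation as a fallback: when rejection exhausts its attempts in
random-size mode, the brood is retried with progressively capped diameters,
and individual children may be placed at the best-clearance pocket with a
diameter drawn from the same law truncated to that pocket — but never below
the law's −4σ quantile (163 nm for the default MVB law), so crowding shrinks
children modestly rather than inventing arbitrarily small bodies.  Fixed-size
mode (used by the exact-arithmetic oracles) never shrinks; a packing that
cannot be realised raises a `PackingError` naming the offending container.
Consequences to keep in mind: realised MVB diameters in crowded MCMVs run a
few percent below the nominal mean, and an occupied MVB whose lumen cannot
hold its drawn ILV brood keeps as many ILVs as fit (at least one).  The
count distributions themselves are untouched.

**Determinism.** One master integer seed; per-component streams (cells,
bodies, omegas) are spawned via `numpy.random.SeedSequence`.  Identical
(params, seed) gives byte-identical scene JSON.

## Virtual microtome

`serial` mode emits every slab from z = 0 to the tallest object;
`single_random_per_cell` mode draws one slab per cell at uniform z in
[0, *H*) — the single-section frequency survey.  A lateral site is sighted
iff its z-interval intersects the slab; a body yields a profile iff its
in-slab chord is at least the detection floor (20 nm by default — caps
thinner than the membrane scale are invisible in real sections; the floor is
the main bias knob for the correction's small-cap losses, and at the default
geometry it shortens visible spans by under 0.2%).  An MVB profile "contains
an ILV" only when a child ILV yields a profile in the *same* slab, because
that is all a single section can show.  Omega marks are points on the MCMV
limiting membrane, sighted when their z falls in the slab; an optional
2-slab reach models figures straddling two sections.

Because the sighting rule is interval-vs-slab overlap, the effective
single-section detection probability is slightly larger than the plane-
sampling value *p* (the classic overprojection term: ≈ 0.1293 vs 0.125 at
the defaults, partially offset in the sighted-cell fraction by the
multi-site Jensen term).  The package keeps the estimators on the model
value *p* — that is the survey arithmetic being implemented — and treats
the ≈0.2-percentage-point forward discrepancy as part of Monte-Carlo
tolerance; recovery tests bound it at 3 SE.

Field-of-view cropping (the partial-cell exclusion rule applied to real
sections) is off by default — the simulation sees whole cells, so the bias
the rule removes does not arise — but a square FOV with edge exclusion is
available for studying its effect.

## Estimators

* `site_rate`: default method `linear` (`λ̂ = f/p`) because it is literally
  the survey arithmetic; `poisson_inversion` (`λ̂ = −ln(1−f)/p`) is the
  statistically exact alternative under the Poisson placement model.  The
  linear reading is biased low by `(1−e^{−λp})/(λp)` (≈0.5% at λp = 0.09).
  Confidence intervals: Wilson on *f*, propagated through the (monotone)
  chosen map.  Wilson rather than Wald because the observed fractions sit
  near zero.
* `mvbs_per_mcmv`: `N̂ = n̄·(d+T)/(D+T)`.  The formula is this package's
  reconstruction of the standard span-ratio adjustment (the method field
  says `reconstructed_profile_ratio`); it is validated against the
  virtual-microtome oracle — for known μ_N the per-section mean matches
  `μ_N·(D+T)/(d+T)` within 3 SE and the corrected estimate recovers μ_N
  within 10%, the margin covering small-cap losses at the 20-nm floor and
  size-dispersion Jensen effects.  Uncertainty by bootstrap over MCMVs when
  per-MCMV rows are supplied.  Note an ambiguity the package does not
  resolve: a reported "about one MVB per MCMV" can be read as the raw
  per-section mean or as the corrected count; both are computable
  (`CountsTable.mean_mvb_profiles_per_mcmv` vs `mvbs_per_mcmv`).
* `proportion_ci`: Wilson 95% via statsmodels.

Correction-oracle validation runs use fixed diameters and exactly-μ_N
counts: the span-ratio identity is linear in N, so fixed counts test the
same quantity while keeping sphere packing far from jamming at μ_N = 4.

## Lumen classifier

"Clear separation of two histogram peaks" is operationalised as Ashman's
`D ≥ 2` computed from mask statistics rather than literal peak-finding,
which is bin-width fragile; D ≥ 2 is the classical resolvability bound for
a two-Gaussian mixture and the threshold is exposed in `ClassifierParams`.
The size rule is strict (> 200 nm) and uses the caller's measured major
axis, not mask geometry — sizes are measured on the micrograph in the real
workflow.  Grey convention: higher value = lighter (electron-lucent);
`inverted=True` flips the comparison for raw acquisitions with opposite
polarity.  Degenerate input: zero variance in both masks with equal means
gives D = 0; with distinct means, D = ∞.  The decision is exactly invariant
to adding a constant to all pixels (as long as nothing clips).

The patch renderer draws a two-mean disk with Gaussian noise, quantised to
8 bits, with annotator-style masks that exclude a one-pixel membrane band.
It emulates lumen-vs-surround contrast only — no membranes, textures or
neighbouring organelles — so the classifier's ≥99% operating accuracy on
rendered patches demonstrates correctness of the decision rule at a given
separation, not performance on real micrographs.

## What the synthetic validation does and does not show

Passing tests show that (i) the closed-form arithmetic is implemented
exactly; (ii) the estimators invert the generative model they assume, to
Monte-Carlo precision, at the study's sample sizes (2·10⁴ cells for the
site survey, hundreds of MCMVs for the correction); (iii) the pipeline is
deterministic and self-consistent.  They cannot show that real protrusion
sites are Poisson-placed bands, that MCMVs are spheres, or that the
measured 367 nm is the true mean MVB diameter — the observed survey
fractions (9%, 43%, 65%, one MVB per MCMV) enter the package as forward
model parameters, not as reproduced results.

## Problem sizes

Default validation sizes — 20,000 cells per site-rate run, 600 MCMVs per
correction run, 1000 patches for the classifier operating test, 10⁴ draws
for distributional goodness-of-fit — were chosen so that 3-SE Monte-Carlo
bands are a few percent of the quantities under test; each run completes in
seconds on one core.
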