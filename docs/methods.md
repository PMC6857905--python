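# Methods

This note records the model equations, constants and conventions implemented
by `reefbudget`, in the order the pipeline applies them. Units are
kg CaCO₃ m⁻² yr⁻¹ unless stated otherwise.

## Survey model

A site is surveyed with six 10 m line-intercept transects. Each transect
records contiguous segments (taxon, intercept length along the
substrate-following tape), its contour length (1000 cm) and its planar
projection; rugosity r = contour / planar ≥ 1. Per transect, a taxon's
planar percent cover is

    x = 100 · (summed intercept) / contour length

Each segment's planar extent is intercept/r, and dividing by the planar tape
length r⁻¹·contour gives the same ratio, so covers sum to exactly 100 within
a transect; the rugosity correction then enters the production equation once,
not per segment. Site-level covers and rugosity are transect means. The mean
skeletal density D (g cm⁻³) is the cover-weighted mean over live coral taxa.

Belt surveys per site (six transects): urchins 6 m² per transect (36 m²
total), *Acanthaster* 50 m² (300 m²), parrotfish 120 m² (720 m²).

## Gross production

Coral calcification with per-taxon morphology m, skeletal density d
(g cm⁻³) and vertical extension g (cm yr⁻¹):

    gross = r · ( Σ_j (m_j · x_j / 100) · d_j · g_j · 10  +  ca )
    ca    = 0.018 · p_ca · 10

with p_ca the crustose-coralline-algae cover as a proportion and 10 the unit
conversion from g cm⁻² yr⁻¹. The CA term sits inside the rugosity factor,
matching its position in the production equation's braces. A signed
sedimentation term of ±0.4 is added to net production: positive where the
sediment supply is calcareous, negative where heavy terrigenous sediment
smothers corals.

The shipped trait table is a synthetic default with representative values
from the coral-trait literature (flagged in its header); real analyses should
supply their own table.

## Bioerosion

Parrotfish, per fish of fork length L (cm) with species bite-rate
coefficient brc (default 20):

    bite volume   v  = exp(1.32 + 0.06·L) / 1000        (cm³)
    scar fraction sp = 1 / (1 + exp(−(−2.46 + 0.089·L)))
    bite rate     br = max(0, 60·((4.31 + brc − 0.36) − 0.045·9·L))  (day⁻¹)

with 9 h of daily foraging time. Site erosion is
Σ v·sp·br · D · 365 · 0.001 / (fish belt area).

Urchins, per individual of test diameter t (cm), scaled by 0.365 days and a
0.57 carbonate fraction, summed and divided by the urchin belt area:

    Diadema      1e−6 · t^3.42 · 0.365 · 0.57
    Echinometra  4e−4 · t^1.98 · 0.365 · 0.57
    other        1e−4 · t^2.32 · 0.365 · 0.57

Macroboring: 10 · (macroborer cover proportion), i.e. a capacity of
10 kg m⁻² yr⁻¹ at full cover.

## Acanthaster predation

With live coral cover R (%), the mean inter-coral search distance is
(100 − R + ε)/10 m (ε = 1e−10 guards full cover), giving an attack rate over
a 12 h foraging day at 504 m h⁻¹ search speed:

    a  = 12 / ( ((100 − R + ε)/10 / 2)² · π ) / 504
    RI = (a·R / (1 + a·3.5·R)) · 4.53          (Holling type II, h = 3.5)

Transect consumption from the belt count C over n transects:

    tc = (C/n) · 0.01 · D · 10 · 365

and the budget reduction is tc · RI / 50 (belt area), clamped to [0, gross].
Densities above 30 ha⁻¹ are flagged as outbreak-level. `density_threshold`
inverts the (count-linear) reduction to the smallest belt count that would
consume the whole gross production.

## Vertical accretion and sea level

Net production Cp converts to potential vertical accretion (mm yr⁻¹) via the
concave curve

    accretion = Cp + Cp·(Cp·α),   α = −0.01949

whose maximum sits at Cp = −1/(2α) ≈ 25.65. A site "keeps up" with a
sea-level scenario when accretion ≥ the scenario's rise rate; the default
scenario set is RCP 2.6/4.5/6.0/8.5 at 5 / 6.5 / 6.7 / 9 mm yr⁻¹.

## Threshold model

Site-level net production G_i is modelled as

    G_i = β₀ + f(cover_i) + habitat offsets + b_site(i) + ε_i

with f a penalized cubic O'Sullivan spline: a B-spline basis (interior knots
at cover quantiles, boundary knots at 0 and 100) with the exact
second-derivative roughness penalty ∫f″², rewritten in mixed-model form
(two-dimensional fixed null space — constant and linear — plus random spline
coefficients). Because the penalty integral's integrand is piecewise
quadratic, Simpson's rule per inter-knot interval evaluates it exactly.

Priors: improper flat-with-large-variance normals on fixed effects,
half-Cauchy(5) on the spline, site and residual standard deviations via the
inverse-gamma auxiliary representation. The fully Gaussian conditional
structure admits a conjugate block Gibbs sampler (one joint multivariate
normal draw of all coefficients per iteration, then the variance updates),
implemented in the package; `arviz` supplies split-R̂ diagnostics.

With one observation per site, σ_site and σ_resid are only identified
through their sum; their split mixes slowly without affecting the curve
posterior. Convergence is therefore gated on the reported quantities (fixed
effects and the expected curve at covers 10/25/40); the σ R̂ values are still
reported. Non-convergence warns and is surfaced through the CLI exit code.

The threshold for a habitat is, per posterior draw, the smallest cover in
[0, 100] at which the expected curve (site effect 0) becomes non-negative —
0 if the draw is positive everywhere, censored at 100 if never non-negative —
located by grid bracketing plus bisection. Reported: posterior mean, central
95 % credible interval, censored fraction; habitat differences are computed
per draw (and are therefore antisymmetric).

## Synthetic generator

The generator emulates the survey geometry only; its distributions are
configurable stand-ins: Dirichlet taxon mixtures and truncated-normal total
cover per site, multinomial allocation into segments along each 1000 cm tape,
uniform per-transect rugosity, Poisson urchin/fish/sea-star counts, lognormal
body sizes. `GroundTruth` carries each site's analytically expected gross
production, so pipeline output can be checked against it with sampling error
that shrinks as the transect count is raised. The `paper_like_config` preset
(48 sites, two islands, inner/patch/outer habitats, a block of outbreak
sites, gross ≈ 7–9 kg m⁻² yr⁻¹) is synthetic and labelled as such: passing
tests demonstrate internal consistency of the arithmetic and recovery of
known generator truths, not agreement with any field dataset.

## Limitations

- Trait values (m, d, g, brc) ship as synthetic defaults.
- The sea-star model saturates at 4.53/3.5 ≈ 1.29 kg per individual-hour
  equivalent; counts required to zero a healthy site's production greatly
  exceed the 30 ha⁻¹ outbreak convention (see `examples/03`).
- The threshold model assumes Gaussian errors and one observation per site;
  the variance split between site and residual components is reported but
  not interpretable in that design.
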