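# Methods

`warburgflux` implements a constraint-based analysis of aerobic
glycolysis (the Warburg effect) in proliferating cells: it builds
expression-tailored flux models of cell lines, measures how strongly each
line is committed to fermentative ATP production, and screens reaction
knockouts for perturbations that revert that commitment without blocking
growth. This note records the model, the defaults, and the design choices
made where the design was genuinely open.

## Flux balance analysis

A network of *m* metabolites and *n* reactions is held as a
stoichiometric matrix `S` (m x n). A feasible steady-state flux
distribution is any `v` with `S v = 0` and `lb <= v <= ub`
(irreversibility and capacity bounds); flux balance analysis (FBA)
maximises the export flux of a `biomass` pseudo-metabolite over that
polytope. Linear programs are solved with scipy's HiGHS interface.
Growth media act on exchange reactions only and can only tighten their
uptake bounds.

Contractual quantities are LP *optima* (objective values, flux extrema
at a fixed optimum); individual flux vectors at degenerate optima are
not. "Fixing" a reaction at a previously solved optimum uses a two-sided
relative band of `1e-9`. A reported optimal solution must satisfy mass
balance to `1e-6` per metabolite and bounds to `1e-9`; these two numbers
are asserted throughout the test suite.

Gene-protein-reaction rules are boolean trees (`or` = isoenzymes,
`and` = complex subunits). A gene knockout closes every reaction whose
rule evaluates false; a reaction knockout sets both bounds to zero.
Biomass is a single export of a `biomass` pseudo-metabolite; fixture
networks define their own biomass stoichiometry, since the method's
logic does not depend on a realistic biomass composition. ATP/ADP and
NAD/NADH are closed internal cycles with no maintenance drain by
default — this closure is what couples redox disposal to ATP demand and
is the load-bearing assumption behind forced fermentation in the
fixtures.

## Forced lactate secretion and oxygen calibration

A line is *forced* Warburgian when the minimal feasible lactate export at
maximal biomass is strictly positive (tolerance `1e-6`): the optimum is
unreachable without fermenting. Because yield-maximising models given
unlimited oxygen always find a respiratory optimum with zero lactate,
the simulated normoxic state caps oxygen uptake at the largest bound
under which the minimal lactate secretion stays positive. The
calibration brackets that edge geometrically (forcing may vanish at very
low oxygen too, where growth itself is impossible, so the search probes
a grid rather than assuming forcing at zero oxygen) and bisects to a
relative resolution of `1e-3`. Hypoxia scales the calibrated oxygen cap,
by 0.5 by default.

## Expression tailoring

Cell-line models are derived from a generic network by capping the
maximal flux of a designated growth-associated reaction subset in
proportion to enzyme expression. Per-reaction expression aggregates the
gene rule with `or -> sum`, `and -> min` (the additive-isoenzyme /
limiting-subunit convention, declared rather than inherited from any
published rule). Aggregated values are min-max normalised per reaction
across the cohort and mapped linearly onto
`base_bound * (eps + (1 - eps) * x_hat)` with floor `eps = 0.1` and
`base_bound = 24` flux units by default. Zero cross-line spread means no
penalty (`x_hat = 1`). Tailoring touches upper bounds only, never loosens
a generic bound, and is deterministic; ranks of tailored caps equal ranks
of aggregated expression by construction.

The exact bound-setting rule of published context-specific reconstruction
methods is not public; this linear map is the package's explicit
stand-in and preserves the one property the analysis needs: expression
sets maximal capacities on a growth-associated subset. Whether such
methods normalise per gene or per reaction, and what their floor
parameter is, cannot be inferred here; both choices are therefore
declared defaults, not claims.

When two cohorts are compared (cancer vs normal proliferating lines),
their expression matrices are concatenated and tailored against a single
joint normalisation. This matters: min-max scaling within each cohort
separately would erase the systematic glycolytic shift between the two
populations and make every cohort look internally identical.

## Sampling the optimal face

All bioenergetic read-outs are means over feasible flux distributions on
the *optimal face* — the sub-polytope with biomass fixed at exactly 100%
of its optimum. The sampler:

1. computes flux variability at the fixed optimum;
2. declares the face degenerate when every reaction's range is below
   `1e-6` relative width (the fixing band alone produces ~`1e-9`
   numerical thickness), returning `n` copies of the box midpoint,
   flagged;
3. otherwise restricts the walk to the affine subspace
   `{S v = 0, v_bio = opt, v_j = c_j for pinned j}` — coordinates whose
   face width is below the degeneracy threshold are promoted to
   equalities so the walk never pushes against a zero-width box
   dimension;
4. starts from the centroid of the flux-variability extreme points and
   runs hit-and-run with isotropic directions in the null space,
   burn-in 1000 and thinning 100 by default, emitting samples clipped
   into the face's bounding box.

Uniformity of hit-and-run is asymptotic and never contractual; tests pin
down degenerate-face exactness, interval containment, row-wise
feasibility and seed determinism instead. Two runs with one seed are
bit-identical.

## Bioenergetic metrics

Over a sample set: **ECAR** is the mean lactate-export flux (the
modelling proxy of extracellular acidification), **OCR** the mean
oxygen-uptake flux, **EOR** their ratio, and **AFR** the ratio of summed
mean ATP production of the declared glycolytic reactions to that of the
declared OXPHOS reactions, each weighted by its ATP stoichiometric
coefficient (with unit coefficients this is the plain summed mean flux;
the weighting makes lumped fixture reactions scale correctly). Undefined
ratios (zero denominators) are flagged, never silently zeroed. The
**BEC index** is the transcript-level proxy: expression of GAPDH over
the ATP-synthase beta subunit.

Dose-response curves lower a target reaction's upper bound linearly from
its current value to zero over 21 levels (the number of levels is a
declared default), re-solving and re-sampling at each level with
identical sampler settings and seed; zero-growth levels record zeros,
flagged.

## The knockout screen

Every candidate reaction (internal non-exchange reactions by default;
the biomass export is never tested) is closed in every cohort line:

1. **lactate abolition** — knockout minimal lactate at maximal growth
   `<= 1e-6` in all lines;
2. **growth sparing** — knockout growth strictly `> 10%` of wild type in
   all lines (a config switch relaxes to the cohort mean);
3. **AFR reduction** — sampled knockout AFR strictly `< 60%` of the
   wild-type AFR, compared on the mean AFR fraction across lines
   (per-line unanimity available via config). The sampled AFR is
   computed only for knockouts that pass stages 1–2, as in the screening
   procedure these thresholds come from.

Ties at either threshold fail (strict inequalities as printed). An
optional normal-proliferating cohort must additionally keep `> 10%`
growth under the knockout. Survivors map to the genes of their rules,
annotated by whether a single-gene knockdown closes the reaction
(no isoenzyme sibling). The target-expression check is a one-sided
Wilcoxon rank-sum on per-gene mean expression across lines, target set
versus background metabolic genes.

## Statistics

Spearman correlations carry permutation p-values: exhaustive over all
`n!` orderings for `n <= 9`, seeded Monte-Carlo with 1e5 draws and the
add-one estimator otherwise (the exhaustive distribution is infeasible
at cohort sizes; the switch point and draw count are declared policy).
Ties get mid-ranks throughout. Partial Spearman correlates the rank
residuals of `x` and `y` after regressing each on the ranks of `z`; its
permutation p permutes `x`'s ranks. A variable fully explained by the
control leaves nothing to correlate and reports rho 0, p 1. BH-FDR uses
the statsmodels step-up.

The drug-response summary computes per-compound Spearman permutation
p-values against the measure, BH-FDR at alpha 0.05, the significant
fraction and its sign split. The cohort-level empirical p shuffles each
compound's responses across lines 1000 times and counts shuffles whose
significant fraction reaches the observed one; inside that loop the
per-compound statistic is a fast analytic one (vectorised t-approximation
Spearman by default, or a median-split rank-sum "Wilcoxon" variant via
config), applied identically to observed and shuffled data so the
comparison is like for like. Empirical p-values use the add-one
estimator and are never zero.

## Synthetic data

**warburg-mini** (10 reactions) is fixed stoichiometry chosen so every
pipeline quantity has a closed form, re-derived in the test suite by an
exact-rational vertex-enumeration LP oracle: glycolysis
`glc + 2 adp + 2 nad -> 2 pyr + 2 atp + 2 nadh` capped at glucose 10,
respiration `nadh + 0.5 o2 + 2 adp -> nad + 2 atp` capped at oxygen 2.5,
lactate dehydrogenase as the only alternative NADH sink, a TCA lump, and
biomass `pyr + 6 atp`. The ATP/NADH/pyruvate balances pin the optimum to
a single point: biomass 5, forced lactate 15, AFR 2, EOR 6; with
unbounded oxygen, biomass 110/7 and zero forced lactate; the LDH
knockout grows at 55/26 (42.3%) with AFR fraction 7/52 (13.5%) — the
worked screen example returns exactly {LDH}.

**toy-core** (29 reactions, 23 metabolites, two compartments) is the
desk-scale stand-in for a genome-scale cancer model. Its structure is
requirement-driven and re-verified at build time: forced lactate 15 at
biomass 8 under the default oxygen cap 6 (R1); no forcing with the cap
lifted (R2); a glutamine substrate whose ATP-expensive biosynthetic
by-routes make minimum oxygen consumption at the optimum rise under full
glycolytic inhibition (R3); serine- and methionine-like branches with
NADH-producing glycolytic routes and glutamine-fed alternatives whose
knockout abolishes forced lactate while sparing half of wild-type growth
(R4); isoenzyme and complex rules (R5). Three stoichiometric devices
make R1–R3 coexist, and each is biologically motivated: a capped
low-NADH glycolytic bypass, a capped glycerol-like reduced-overflow
valve (without it, fermentative ATP cannot substitute for respiratory
ATP at fixed biomass, because lactate disposal consumes pyruvate 1:1,
and the wild-type OCR would be pinned at the oxygen cap), and a
glutamine uptake cap of exactly 9 that pins respiration at the oxygen
cap when glycolysis is fully inhibited. The construction is fully
deterministic; the generator's seed argument exists for interface
uniformity only. The ground-truth screen survivor set at canonical
settings (1000 samples, seed 0) is {GLNt, LACt, LDH, SER2, MET2} — the
lactate-disposal route plus glutamine/serine/methionine metabolism; the
NADH-producing branch routes SER1/MET1 pass the lactate and growth
filters but not the AFR filter.

**Cohorts.** Each synthetic cell line carries a glycolytic character
`w` (uniform on [0,1] in cancer mode; normal mode concentrates `w` near
0.5 with SD 0.05). Expression maps linearly onto gene classes with a
systematic between-population offset — cancer glycolytic genes at
`100 (1.5 + w)`, respiratory at `100 (1.2 - w)`, branch genes at
`100 (0.8 + 0.4 w)`; normal lines at 50 / 240 / 100 respectively; all
other genes at 100 — times log-normal noise (sigma 0.1). The offsets
encode the biological claim under study: cancer lines over-express the
glycolytic machinery relative to normal proliferating cells at every
internal rank `w`, which is what lets joint tailoring force lactate in
all cancer lines while leaving all normal lines free of forcing.
Phenotypes: growth `1 - 0.5 w`, migration `10 + 20 w` plus Gaussian
noise (SDs 0.03 and 1.0); drug responses: a planted 30% of 100 compounds
equal `w` plus noise (SD 0.25, higher response = more resistant), the
rest standard normal noise. Cohort simulations run the tailored models
under an environmental oxygen cap of 12, so that per-line forcing is
decided by the tailored respiratory capacity rather than by a shared
oxygen bottleneck. Everything is deterministic given the seed.

What the generator does *not* emulate: genome-scale network size,
realistic gene identifiers, measurement platforms and batch effects,
growth-rate-guided selection of the tailored subset, and any
pharmacology beyond monotone response-vs-character relations. Passing
tests therefore demonstrate that the pipeline's logic and statistics
recover planted structure of the stated form — not that the biology of
any real cohort is captured.

## Problem sizes and determinism

Default analyses use 1000 flux samples per face (burn-in 1000, thinning
100), 21 dose-response levels at 500 samples, 20-line cancer and 10-line
normal cohorts, 100 compounds with 30 planted, 1e4–1e5 permutation
draws and 1000 response shuffles. All randomness flows from explicit
seeds; repeated runs are byte-identical.

## Known limitations

- The tailoring map is a declared stand-in, not a reconstruction of any
  published bound-setting algorithm.
- Hit-and-run uniformity is approximate; metrics are means over an
  approximately uniform sample and inherit a small, seed-stable bias on
  non-degenerate faces.
- Monotonicity checks on sampled dose-response curves use a 0.02
  absolute tolerance for sampling noise in face means.
- ECAR proxies lactate export only; explicit proton export and
  non-mitochondrial oxygen sinks are not modelled (the toy networks have
  a single oxygen consumer, so OCR is unambiguous here, but the
  distinction matters for real models).
- The partial AFR–migration correlation on synthetic cohorts is positive
  but *smaller* than the plain correlation, because the generator drives
  growth and migration from the same single character `w`; only the sign
  is a contract.
- Loopless/thermodynamic constraints and solvent-capacity constraints
  are out of scope; the latter would need kinetic data unavailable at
  genome scale.
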