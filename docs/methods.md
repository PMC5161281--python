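# Methods

This note documents the model implemented by `demeflow`, the choices
made where the design was genuinely open, and what the synthetic study
system can and cannot show.

## Model

### Time and scheduling

The simulation advances in yearly steps. Within a step the order is:
deaths (evaluated at current ages), aging, replenishment of source
demes, actions of unmarried mature agents in a freshly randomized order,
births, and arrival-log updates. Deaths precede aging so a newborn faces
the age-0 hazard exactly once. All randomness flows through a single
`numpy` generator per run, so a run is bit-reproducible from its seed.

### Demography

Mortality is a Siler hazard h(a) = a₁e^{−b₁a} + a₂ + a₃e^{b₃a} with
(a₁, b₁, a₂, a₃, b₃) = (0.11, 1.0, 0.001, 5·10⁻⁵, 0.095), evaluated on a
0–108-year axis, compressed onto 0–55 years, doubled, clipped to [0, 1]
and capped at 1 at the terminal age. The parameters were calibrated
analytically, before any simulation was run, against two constraints:
discrete life expectancy at birth in the 25–30-year band typical of
prehistoric farming communities (achieved: 27.8 y), and a stationary age
structure near the archaeologically estimated 40% children (0–15), 25%
youth (16–25), 25% prime (26–35), 10% middle age (36–50) (achieved:
43.5/25.3/21.6/9.6 from the life table). Fertility is a natural-fertility
curve of annual birth probabilities for married women aged 18–45,
peaking at 0.37 around ages 22–24; its sum, a completed-fertility proxy,
is 6.54, inside the plausible 3.5–7 band for traditional groups. Both
schedules are explicit proxies for unknown prehistoric values and can be
replaced from two-column CSV files.

Populations are founded with ages allocated 30/30/30/10 across the four
brackets by deterministic largest-remainder counts (so small demes
initialize reproducibly) with uniform ages within brackets. Within
roughly a generation the profile relaxes to ≈ 43/25/21/10 and stays
there — the closed-deme acceptance test and `scripts/acceptance.py`
measure this directly.

### Actions, marriage and the weighting M

Each unmarried mature agent takes one action per year. A uniform draw
enters the move branch with probability m_A or m_P (by the agent's
current ancestry classification) — only if the agent has never moved,
is unmarried, and its deme has neighbours; otherwise a marriage is
attempted with probability p_marry = 0.9, else the agent stays. A move
draws v ~ Beta(1, 5) and selects rank ⌊v·n⌋ among the neighbours sorted
by distance (ties broken by index); a destination at carrying capacity
is redrawn up to 5 times, after which the move fails and the action is
consumed. The Beta(1, 5) default makes near moves dominant while the
tail produces the occasional long leapfrog; it is configurable.

Marriage candidates are same-deme, opposite-sex, unmarried, mature and
within ±6 years. Union classes are weighted 0.25 (within-group),
0.25 + M (Papuan man × Asian woman) and 0.25 − M (Asian man × Papuan
woman). Two mechanisms apply the weights: the partner is sampled
proportionally to the weight of the resulting class, and the chosen
union is then consummated with probability w/max(w). The second step is
essential: at the expansion front a lone Asian migrant typically faces
candidates of a single class, where proportional sampling alone is
weight-blind; scaling the consummation rate makes realized class
frequencies track the weights everywhere, which is what produces the
observed step-like excess of Asian ancestry on female-inherited systems.
At M = 0 all classes carry 0.25 and the acceptance step is the identity.
On marriage the couple fuses into a family whose maximum number of
children is Poisson(f_A or f_P, by the wife's classification); widowhood
dissolves the family and the survivor re-enters the unmarried pool
(retaining any used move).

### Genomes

Ancestry is tracked as binary alleles (Papuan 0 / Asian 1): 25 unlinked
diploid autosomal markers, 25 partially linked X markers at fixed map
positions (k + 0.5)/25 on a unit map of 1.8 Morgans per female meiosis
(≈ the published human female X map; configurable), one mtDNA and one Y
marker. The maternal X gamete starts on a random copy and switches at
Poisson-distributed crossover points; sons receive only the maternal
gamete, daughters also the father's X intact. There is no mutation. The
engine's batched transmission draws per-interval Poisson crossover
counts, the restriction of the uniform-breakpoint process to the marker
grid; tests verify its distributional agreement with the explicit
breakpoint construction. An individual is Asian when ≥ 50% of all
alleles it carries are Asian, evaluated integer-exactly
(2·asian ≥ total) over per-sex denominators (101 alleles for women, 77
for men); diploid and haploid compartments are pooled without weighting.

### Geography and founding layouts

Demes are nodes at lon/lat coordinates, connected when their haversine
distance is ≤ 650 km (R = 6371 km). Carrying capacity follows
K(t) = min(K_max, round(K₀·e^{rt})); defaults K₀ = 150, K_max = 500 and
r = ln2/steps, so capacity doubles over a full run — weak population
growth with demes founded at 120. Mainland source demes hold a fixed
occupancy target: each year after deaths they are topped back up with
fresh unadmixed founders of their founding ethnicity (ages drawn from
the founding age-class spec). Being always full, they accept no
in-migration and act as perpetual reservoirs. Founding layouts (the
start distribution D) seed a chosen set of demes Asian and the rest
Papuan; libraries of layouts are enumerated by adding four-deme island
blocks cumulatively onto the mainland base along configured island
orders, keeping only connected configurations containing every source.

### Summaries and spread rates

Individual ancestry per marker system is the Asian-allele fraction of
that compartment; deme ancestry is the unweighted mean over occupants,
and regional ancestry pools individuals across the region's demes (so
deme sizes weight naturally). The inference vector interleaves regional
autosome and X means in a fixed region order. First arrival of (i) any
Asian allele and (ii) any Asian-classified agent is logged per deme;
expansion speed divides distance from the nearest initially Asian deme
by arrival time. The default aggregation is total distance over total
time across reached demes — a wavefront speed. The per-deme mean of
distance/time quotients is available as an option but is dominated by
demes adjacent to the founding area, whose year-one arrivals make the
quotient explode (hundreds of km/yr); it is not a meaningful expansion
speed on any geography we examined. A shortest-path ("per hop") distance
variant is also provided.

### ABC

Priors: m_A, m_P ~ U[0.1, 0.8], f_A, f_P ~ U[3.5, 7], M ~ U[0, 0.25], D
uniform over the layout library. The reference table stores one row per
completed run (parameters, run seed, summary vector); run seeds derive
from a master seed by a counter. Rejection keeps the ⌈tolerance·n⌉
closest rows by Euclidean distance (missing summaries dropped pairwise;
ties broken by row index). Local linear regression adjustment
(Epanechnikov weights on distance, parameters regressed on centred
summaries, adjusted draws clipped to the prior support) is available;
summary columns that are constant among accepted runs — regions pinned
at ancestry 1 beside the mainland — are dropped from the design, and a
singular or undersized design falls back to unadjusted rejection with a
warning. With very small accepted sets (tolerance 0.01 of a few thousand
rows ≈ 20 draws) the regression is near-saturated and unstable, so the
recovery experiments in the test suite use plain rejection; at
production table sizes the adjustment behaves as intended (verified on
synthetic linear tables). Prediction error is the leave-one-out
variance-normalized squared error of the posterior-mean estimate, ≈ 1
for a parameter the summaries say nothing about. Credible regions are
central 2.5–97.5 percentiles; the mode is a Gaussian KDE with reflection
at the prior bounds. D is summarized by its frequency among accepted
runs and never regression-adjusted.

## The synthetic study system

`generate_fixture_archipelago` builds a west-to-east chain of island
clusters of four coastal demes each (one region per island), spaced so
that neighbouring clusters stay inside the 650-km radius, with two
mainland source demes at the western end. The geometry mirrors the real
region's scale — cluster centres ≈ 470 km apart, intra-island spacing
100–250 km, total span of several thousand km — and was fixed from those
scale considerations, not fitted to any output. Pseudo-observed data are
produced by the simulator itself at known parameters, giving exact
ground truth for recovery experiments.

What the fixture does not emulate: the real region's irregular island
sizes and deme densities (the real map has 116 demes with more demes on
larger islands and dense short-hop corridors), coastline-hugging
placement, the full 82-layout founding library, and real genotype data
with ascertainment noise. Passing tests on the fixture therefore
demonstrate the mechanisms (sex-biased flow, capacity-gated growth,
identifiable migration/marriage parameters), not quantitative agreement
with any particular real geography. The clearest casualty is the allele
wavefront speed: on the fixture it is ≈ 5 km/yr, below the 7.8–28.7
km/yr interval reported for the real island map, while the
agent-wavefront speed (≈ 4 km/yr) matches the reported value closely.
The corresponding marker-rate acceptance test documents this and is
expected to pass only with the real deme map.

## Problem sizes in the shipped experiments

Chosen once, as the package's own desk-scale study conditions:

* Closed-deme demography: 120 founders, K = 150 fixed, 200 steps,
  20 replicates, 50-step burn-in (also `scripts/acceptance.py`).
* Fitted-regime behavior (ordering, variance, spread): 8-island fixture,
  real deme sizes (founding 120, K₀ 150), 1000 steps, 20 replicates.
* Recovery and identifiability: 4-island fixture, populations scaled to
  0.17 of real size, 220 steps, 2000-run reference table, tolerance
  0.01, rejection ABC. The horizon matters: below ≈ 150 steps the
  expansion has not shaped regional gradients and no parameter is
  identifiable; 220 steps is the longest horizon keeping the table build
  inside a desk-scale budget.

## Numerical and degenerate-input choices

Ethnicity ties at exactly 50% classify Asian (inclusive threshold);
with 77/101-allele denominators an exact tie cannot occur, but the rule
is implemented inclusively. Equal-distance neighbours order by deme
index. The rank draw maps v to ⌊v·n⌋ clipped to n − 1. Empty demes
produce NaN summaries that propagate into pairwise-excluded ABC
coordinates with a warning. An empty candidate set, a blocked
destination after five retries, or a failed consummation all consume the
year's action. M > 0.25 is clipped with a warning (larger values are
indistinguishable from 0.25); M < 0 is an error. Parameters outside
their prior ranges warn rather than fail, since exploratory runs may
legitimately step outside.

## Known limitations

No mutation, selection, marker ascertainment, divorce, polygamy,
household structure, endogamy, land-vs-sea mobility differences, or
more than two ancestries. Fecundity is weakly identifiable at desk
scale (as at production scale). Marriage search is same-deme only.
The exact supplementary inputs of the original study (real deme
coordinates, its mortality/fertility tables, the 82-layout library)
are approximated by the documented proxies.
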