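# Methods

This note documents the models implemented by trophoweb, the conventions
and defaults they rely on, and the design choices made where the
literature leaves the procedure open.

## Food-web representation and aggregation

A food web is a simple binary directed graph with edges in the direction
of energy flow (prey → predator). Edge-list files use the common
`predator,prey` column convention and are swapped on read. Analysis-ready
webs have no self-loops and form a single connected component once links
are treated as undirected; both conditions are validated before any
metric is computed.

Functional-group aggregation maps raw taxa many-to-one onto group nodes.
An aggregated edge exists whenever any member-to-member edge existed;
within-group feeding would become a self-loop and is dropped, because the
density formula 2L/N(N−1) and the clustering coefficient assume a simple
graph. Aggregated biomass is the sum of member biomasses. For body mass
no published rule exists, so the package uses the biomass-weighted mean
over members that have both values — the mean individual mass of the
pooled population under the assumption that members contribute
individuals proportionally to their biomass. Categories must agree within
a group (a producer merged with an animal is a hard error, not a silent
choice); period labels are unioned.

Symmetrization joins i and j whenever either feeds on the other. Mutual
predation therefore collapses to a single undirected link, and the
undirected link count L counts unordered pairs. Although symmetrization
can be phrased as the sum x_ij + x_ji, with binary input the only
possible weights are 1 and 2, and all indices here treat the symmetrized
web as binary; this is consistent with every reproduced global value.

## Global and node indices

On the symmetrized web: density D = 2L/N(N−1); degree-weighted overall
clustering CL = Σ k_i·c_i / Σ k_i with c_i = 2t_i/(k_i(k_i−1)) and
c_i = 0 for degree < 2; average distance d = mean geodesic length over
unordered pairs of distinct nodes (on an undirected web the ordered-pair
mean is identical, which the tests assert); small-world index SW = CL/d.
Node centralities: nDC = k/(N−1) and betweenness with exact geodesic
counting (Brandes accumulation via networkx — exact σ counts, never
sampling or arbitrary tie-breaks), reported as percent of the undirected
maximum (N−1)(N−2)/2 to match the magnitudes conventional in the
ecological literature (e.g. 36.93); a flag returns the [0, 1] fraction
instead. Report files round global metrics to 3 decimals and node metrics
to 2, the precision at which such tables are customarily printed.

The published global-metrics table shipped with the package contains one
internal inconsistency: the POST row prints D = 0.221 alongside N = 23,
L = 52, but 2·52/(23·22) = 0.206 (0.221 would require L = 56). The
package always reports the formula value and emits a machine-greppable
`WARN:` line when a published density disagrees with its own counts; the
POST density is excluded from every assertion.

## Trophic levels

Producers, cyanobacteria and detritus are basal, fixed at TL = 1.
Detritus stays basal even when it receives donor links (egestion or
death); such links are excluded from the trophic system. An animal with
no prey is a dangling consumer: the solver warns and treats it as basal
so the system stays solvable. Consumers satisfy
TL_i = 1 + Σ_j Q_ji TL_j with Q uniform over prey, because the webs are
binary — equal diet shares are the only defensible weighting. A
flow-weighted variant (shares proportional to prey biomass) exists behind
a flag but is unused in the binary analyses. Cannibalistic self-loops are
excluded from diet shares.

The system is solved by dense LU with a residual check at 1e-10; a diet
cycle with no basal input makes the system singular and raises an error
naming the unsupported nodes. On acyclic webs the solve provably equals
bottom-up dynamic programming, and with omnivory loops it equals the
limit of the fixed-point iteration TL ← 1 + Q·TL; both equivalences are
enforced in the test suite. Literature cross-checks use a default band of
±0.3, the variance conventionally attached to diet-based trophic-level
estimates.

## Energy fluxes

The flux model balances every consumer's energy budget at steady state:
efficiency-weighted inflow equals metabolic loss plus outflow to
predators, with assimilation efficiency set by the prey's category
(animal 0.906, producer/cyanobacteria 0.545, detritus 0.158 — literature
values for these prey types). Feeding preferences are biomass-scaled:
W[i,j] = B_i / Σ_{k∈prey(j)} B_k. Metabolic loss is X = a·M^b·B with the
metabolic-theory defaults a = 0.71, b = −0.25 per gram; the coefficients
are exposed in `FluxParameters` because published applications differ and
the sources for this class of model do not pin them down. Outputs are in
whatever energy/area/time unit the inputs imply (conventionally
kJ/m²/day); no internal unit conversion is attempted.

Basal nodes are treated as unlimited sources: placeholder biomass 1 and
metabolic rate 0. The placeholder also enters consumers' preference
weighting — this matches the biomass-scaled preference setting, but it
means basal diet shares are sensitive to the placeholder value, which is
why the convention is stated loudly here. Non-basal nodes missing biomass
or body mass cannot enter the budget and are dropped with a logged
warning before solving; dropping is generic, never a hard-coded node
list.

Writing G_j for the total consumption of consumer j, the balance is
linear: G_j·Σ_i W_ij e_i − Σ_k W_jk G_k = X_j. The package solves it with
a dense exact solve (webs of a few dozen nodes make sparsity irrelevant)
and distributes F[i,j] = W[i,j]·G_j. A solved consumption below −1e-9 is
an infeasible parameterization and raises; roundoff negatives in
(−1e-9, 0) are clipped to zero. Conservation is enforced to a relative
residual of 1e-9 at every consumer. The log-scale display matrix maps
positive fluxes through log10, renders structural zeros as missing (never
−∞), and orders rows and columns by ascending trophic level. Flux
summaries report the count of positive fluxes, the total, and the Shannon
diversity H = −Σ p ln p of the normalized flux distribution.

## Synthetic webs

The generator emulates the statistical shape of aggregated lagoon webs:
a few dozen nodes, undirected density near 0.2, a handful of basal
sources, lognormal biomasses and body masses. Topology follows the niche
model: niche values uniform on [0, 1]; each consumer eats every species
inside a contiguous interval whose width is beta-distributed and whose
centre keeps the interval inside [0, 1]; the species with the smallest
niche value eats nothing. The interval-width mean is calibrated so the
expected number of directed links equals C·N(N−1) exactly, accounting for
the forced-basal minimum-niche species; the `connectance` parameter is
therefore the target directed connectance (links over ordered pairs,
self-loops excluded). The realized undirected density is roughly twice
that, minus the collapse of mutual pairs.

A draw is accepted only if the web (i) is a single connected component,
(ii) has at least `n_basal_min` basal nodes, (iii) supports every
consumer from some basal node through diet links, and (iv) admits a
feasible default-parameter flux balance. Conditions (iii) and (iv) exist
because the trophic and flux linear systems are singular or infeasible
otherwise: in particular, tight mutual-predation loops can demand more
energy than assimilation supplies, solving to negative consumption, and
about 6% of raw niche draws at the default size contain one. Rejection
sampling is bounded (1000 retries, then a loud error with the last
failure reason). The selection slightly favours better-connected draws;
at the default parameters the measured effect on realized connectance is
below Monte-Carlo resolution at 200 replicates, which the calibration
test asserts.

Attributes: basal nodes draw a category from a configurable
producer/cyanobacteria/detritus distribution and receive biomass exactly
1 (the flux placeholder); consumers are animals with lognormal biomass
(log-mean 2.0, log-sd 1.5 — median ≈ 7 g with a realistic heavy tail) and
body mass (log-mean 0, log-sd 2 — median 1 g spanning copepods to fish).
One integer seed drives topology, attributes and perturbation through
named substreams, so a web and its attributes never depend on call order
and reruns are byte-identical.

Disturbance pairs re-draw the niche position and identity of a fraction
of basal nodes (renamed and switched to a replacement category,
cyanobacteria by default — the regime-switch signature) and a fraction of
consumers, then rebuild all diets from the new configuration. Retained
consumers may rewire, which is the intended analogy to diet switching
after a regime shift. Zero perturbation returns two identical webs.

What synthetic webs do *not* emulate: empirical degree correlations,
body-mass–niche correlations (niche position is independent of the drawn
body mass), seasonal or demographic variation, and any fitted
correspondence to a specific lagoon. Passing tests on synthetic webs
therefore demonstrates correctness of the algorithms under realistic
sizes and densities, not ecological fidelity of any particular web.

## Comparison pipeline

Percent change is (post − pre)/pre × 100; detection-limit bounds such as
`<1.00` are parsed as their bound. Shared-node trophic shifts are
classified after rounding to 2 decimals (the reporting precision), so
|Δ| < 0.005 counts as no change. The pipeline writes every intermediate
table (webs, adjacency, metrics, levels, fluxes, comparison) plus a run
log that materializes all effective parameters; no timestamps enter any
output, so a rerun with the same configuration — including the synthetic
branch at a fixed seed — is byte-identical. Warnings (dropped flux nodes,
density inconsistencies) carry a `WARN:` prefix.

## Problem sizes in tests

The shipped suite exercises webs of 15–23 nodes, 200-replicate generator
calibration, the full atlas of connected graphs up to 7 nodes for the
betweenness oracle, and 100 seeded end-to-end runs; the whole suite
completes in well under a minute, chosen so the checks stay cheap enough
to run on every change.

## Known limitations

- The raw Comacchio predator–prey interaction lists are distributed as
  spreadsheet attachments elsewhere and are not shipped here; the packaged
  tables cover the environmental, global-metric and taxon-to-group data
  only, so raw-web centralities and trophic levels cannot be recomputed
  from this repository alone.
- Flux magnitudes depend on the allometric coefficients and on the units
  of the biomass inputs; only the balance structure, not absolute scale,
  is validated.
- No statistical testing of metric differences is performed (none is
  standard for single pre/post web pairs), and no dynamics: the flux
  model is a steady-state snapshot.
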