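# Methods

## Scope and model

The package analyses flux shifts between two conditions of one cell type
at steady state. The metabolic model is a plain stoichiometric network —
metabolites, reactions with bounds and GPR rules, subsystem labels, a
biomass pseudo-reaction — read and written in the COBRA community JSON
dialect. Flux units are treated as dimensionless consistent units
(nominally mmol·gDW⁻¹·h⁻¹); no unit conversion is performed.

A *maximum doubling time* T_d is interpreted as a growth-rate cap
μ ≤ ln 2 / T_d on the biomass flux (defaults: 24 h untreated, 36 h under
treatment). The cap reading — rather than an equality or lower bound —
was chosen because a maximum doubling time bounds how fast the culture is
assumed to grow while leaving slower states feasible; the consistency
MILP and the sampler then explore the slower states freely. Inorganic
species (h2o, h, o2, co2, pi, nh4, so4 analogues; the list is
configurable) are opened for uptake and secretion when an environment is
applied, since a medium recipe names the organic nutrients but not the
freely exchanged inorganics.

## Deregulation calling

Replicate fold changes are averaged in log space (geometric mean of
per-replicate ratios `(b_i + δ)/(a_i + δ)`); the symmetric treatment of
up and down shifts is the reason for the geometric rather than arithmetic
mean. δ defaults to 1 on the linear normalised scale for count-derived
data and can be set to 0 for data already on a ratio-faithful scale.
GPR aggregation uses AND = min (a complex is limited by its scarcest
subunit) and OR = max (isozymes back each other up); unmeasured genes are
skipped and a rule with no measured gene yields no call. Thresholds are
strict: enzyme FC > 1.3 is up, < 0.77 is down, and 1.30/0.77 exactly are
unclassified — 0.77 is taken literally, not as 1/1.3. The gene-level
variant used for sparse single-cell data filters genes two-sided
(FC ≥ 1.2 or ≤ 1/1.2) with p ≤ 0.5 before GPR mapping.

## Consistency MILP

Condition A is the control, condition B the treated state; "up" with
ratio k is enforced on activities as t_B ≥ k·t_A. Activities t = |v| are
linearised by forward/backward splits with one direction binary per
reversible reaction, so a net-zero cycle cannot inflate t. Each call gets
a binary y with big-M indicator semantics; per-reaction big-M constants
come from FVA activity ranges times a 1.1 margin, keeping the relaxation
tight enough for MILP numerics at toy scale. ε = 1e-3 flux units on the
control-side activity prevents vacuous 0 ≥ 0 satisfaction. The MILP is
solved with HiGHS via scipy at mip_gap = 0, so the reported maximum
is proved. Alternative optima are enumerated by fixing Σy at the optimum
and adding one set-exclusion integer cut per found set until infeasible
(exhausted) or a cap (default 50) is hit; the consensus is the
intersection of the family. A subset-enumeration oracle
(`brute_force_consistency`, ≤ 12 calls, orthants enumerated per reversible
constrained reaction so each feasibility check is a pure LP) provides an
implementation-independent check used throughout the tests.

## Flux sampling

The consensus is re-solved with every call forced on; the witness flux
pair pins the sign (orthant) of each constrained reaction per condition,
making |v| linear in the sampled region. Consensus ratios are then fixed
as equalities t_B = k·t_A (the one-sided inequality form is available via
`mode="inequality"`); equality is the default because fixing a ratio, as
opposed to re-imposing a bound, is what carries the integration result
into the sampled state. Sampling runs in null-space coordinates of the
equality system (steady state for both conditions plus ratio rows), so
equalities hold to machine precision by construction, and uses
artificial-centering hit-and-run: warmup vertices from LPs along random
directions (2 × subspace dimension by default), directions through the
running centre, uniform steps on the chord cut by the inequalities.
Degenerate chords are resampled and counted in the diagnostics; a
zero-volume region is detected from the warmup spread and returned as a
point mass. Summaries use fold change `(|mean_B| + δ)/(|mean_A| + δ)`
with δ = 1e-6 × max |bound| to keep near-zero means finite, flag mean
sign flips, and roll log2 fold changes up by subsystem (the violin-ready
table). Default sample counts follow the study conditions (100,000);
tests and the acceptance script use 1,200–20,000 points, which is ample
for the first-moment checks they make on 2–15-dimensional polytopes.

## Metabolic tasks and MiNEA

Task targets are declared in model metadata (precursor class lists, ATP
hydrolysis species, superoxide and lipid-droplet species) rather than
inferred from metabolite names, because name conventions do not transfer
across model namespaces. Seven canonical tasks are derived when all
targets exist: protein/lipid/DNA/RNA synthesis demands, a generic
ATP → ADP + Pi hydrolysis demand, superoxide production, lipid-droplet
production; classes absent from the model or carrying a zero biomass
coefficient are skipped with a warning. Each task's minimal network is a
MILP (binary per reaction, v bounded by z·bounds, steady state, demand ≥
ε_task = 0.1) minimising Σz, with alternatives enumerated at the fixed
minimum size; an ascending subset-enumeration oracle covers models up to
15 reactions. The enrichment statistic is a design choice of this
package: expression mode uses the exact hypergeometric upper tail of the
deregulated-reaction overlap with the union of a task's minimal networks
(union rather than per-alternative, so alternative routes count once),
BH-adjusted across tasks; flux mode reports the mean log2 flux fold
change over the union with a seeded permutation p (10,000 equally sized
random reaction sets by default).

## Readouts

Signatures take the top-k (default 63) genes with FDR < 0.05 and linear
FC > 1, ranked by ascending FDR with ties broken by descending fold
change then gene id; the FDR-first order reads "top significant genes"
literally. Per-cell AUC is the area under the step recovery curve within
the top 5% of the ranking, normalised by its maximum; 5% is the standard
recovery-threshold default. ssGSEA uses rank weights |rank|^α with
α = 0.25 (the standard weighting; α = 0 reduces to the plain ECDF
difference). Repertoire entropy is in natural log; the base cancels in
Pielou evenness H/ln R, which is defined as 1 for a single clone so
clonality is 0 for both the uniform and the degenerate repertoire.
Expanded-clone thresholds are inclusive (frequency ≥ 10× / 100× the
median clone frequency, median taken after filtering).

## Synthetic data: what it emulates, and what not

The toy network (~45–80 reactions, 10 subsystems) covers glycolysis,
pentose phosphate, TCA with anaplerosis, oxidative phosphorylation, a
glutathione/ROS couple, amino acid handling, nucleotide and lipid
synthesis with β-oxidation, transport/exchange, and a biomass reaction
consuming all four macromolecule classes plus ATP. GPRs mix single genes,
two-gene complexes, isozyme pairs and complex-of-isozyme patterns, with
genes private to each reaction so planted gene fold changes cannot
collide. Planted truths solve one joint LP over (v_A, v_B) so every
planted ratio holds *exactly* on the truth, which makes equality-mode
sampling of the planted consensus feasible by construction; contradictory
calls demand opposite directions on fully coupled pairs (citrate
synthase/isocitrate dehydrogenase, glucose transport/hexokinase,
ribonucleotide reductase/DNA synthesis), each verified at generation time
to be individually satisfiable next to the planted set. Expression noise
is multiplicative lognormal (positivity, symmetric log-scale errors).

What passing tests therefore show: the integration, enumeration,
consensus and sampling machinery is exact on instances where the truth is
known. What they do not show: behaviour under genome-scale degeneracy,
GPRs shared across many reactions, compositional expression biases, or
thermodynamically infeasible loops — none of which the toy generator
emulates.

## Numerical choices and limitations

All LPs/MILPs run through scipy's HiGHS interface, single-threaded and
deterministic; steady-state residuals are asserted below 1e-6 and
witness slacks above −1e-6. The brute-force consistency oracle is
exponential and guarded at 12 constraints; the minimal-network oracle at
15 reactions. The joint MILP shares one bound set between conditions
(condition-specific bounds would only differ in the growth cap here, and
the cap is not active in the sampled interior). Alternative-optima
enumeration is exact but can be capped; capped runs are flagged rather
than silently truncated. The sampler provides two-seed agreement as its
only convergence diagnostic — no formal MCMC machinery — which is
adequate for the first/second-moment claims made, not for tail
quantities.
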