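# Methods

This note documents the models, algorithms, defaults and design
choices behind `nmrcase`, and states what the packaged simulations do
and do not demonstrate.

## Data model and input assumptions

The engine consumes spectroscopist-curated tables, not raw spectra:
a Hill-notation molecular formula, a 1D ¹³C peak list (shift,
CHn multiplicity from DEPT/edited HSQC, intensity, and an integer
degeneracy for symmetry-coincident peaks), a ¹H peak list, and 2D
records given as chemical-shift pairs with an intensity class. 2D
coordinates are snapped to the nearest 1D peak within tolerances of
0.1 ppm (¹³C) and 0.01 ppm (¹H) — configurable, since instruments and
processing differ. When two peaks fall within tolerance, the
correlation keeps *all* candidates as a disjunctive group; ties are
never broken silently, because mis-assignment at this stage poisons
everything downstream.

Coupling-length defaults per record type: COSY 2–3 bonds for strong
peaks, 3–4 for weak; HMBC (and ¹H–¹⁵N HMBC) 2–3 bonds. A `[policy]`
file section overrides them per (kind, intensity class). Translation
to skeletal heavy-atom distances: COSY n-bond coupling → carrier
distance n−2 (clamped to ≥ 1 for distinct atoms; pure-geminal records
carry no skeletal information and are dropped); HMBC → n−1. Duplicate
records for one atom-pair merge by interval intersection; an empty
intersection is reported as a data contradiction naming both records.

## Atom properties (APCT)

The packaged Atom Property Correlation Table (`data/apct.yaml`) bins
the 0–240 ppm range into windows assigning each carbon a hybridization
possibility set and a heteroatom-neighbour verdict. The table is
deliberately conservative: a window never excludes a state that a real
carbon resonating there could have, so property pruning is sound. The
window edges (25, 58, 90, 115, 166, 230 ppm) follow standard empirical
shift charts: e.g. 58–90 ppm admits both O-bearing sp³ and alkyne sp
carbons; 90–115 ppm reads "not sp" because anomeric sp³ and olefinic
sp² carbons overlap there; above 166 ppm a sp² carbon is always
carbonyl/carboxyl-like and must carry a heteroatom neighbour. The
table is configuration, not code; a unit test asserts its soundness
over every fixture carbon.

Hybridization states translate to exact per-atom π-bond budgets during
generation: sp³ 0, sp² 1, sp 2 (sets of states give sets of allowed
budgets). Heteroatoms are unconstrained (they carry no shift).

## The structure generator

The search walks all atom pairs (i, j), i < j, in row-major order,
deciding each bond order 0–3 exactly once, so every *labeled* graph is
visited once. Admissible pruning only:

* remaining-valence caps and end-of-row exactness (Σ orders + H =
  valence, exactly);
* π-budget membership and *fb*/*ob* checks when an atom's row closes;
* dead-component detection (a saturated component that is not the
  whole skeleton);
* distance bounds: a constrained pair already closer than its lower
  bound can never recover (bonds only shorten distances), and a pair
  farther in the *potential graph* (current bonds plus every still
  decidable pair between atoms with spare valence) than its upper
  bound can never comply;
* symmetry breaking: consecutive atoms that are interchangeable in the
  MCD (same element, H count, properties, constraint roles, no fixed
  bonds — e.g. atoms expanded from one degenerate peak, or the
  formula's four equivalent oxygens) must have lexicographically
  non-increasing adjacency rows. Any solution can be bubble-sorted
  into this form by adjacent swaps, so at least one representative per
  isomorphism class survives; the brute-force equivalence suite
  checks this empirically on every run of the tests.

Hydrogens not fixed by the data (heteroatoms; formula-only runs) are
distributed over an outer loop. Outputs are deduplicated on the fly by
canonical key; caps (`max_structures`, node budget, optional wall-time)
truncate the search with an explicit `complete=False` flag, never
silently. Constraints over degenerate atom groups are satisfied
disjunctively: some pair of distinct atoms drawn from the two groups
must lie inside the interval. This under-constrains symmetric molecules
relative to per-atom data — the price of peak collapsing — but is
sound, and termination plus exact dedup is what matters there.

Canonicalization is colour refinement (element, H count, bond orders)
with backtracking over the first non-singleton cell, taking the
minimal adjacency encoding; orbits are computed exactly by marking
each atom (the mark enters the atom label) and comparing canonical
forms. The independent cross-check in the tests is networkx's VF2
matcher, which shares no code with the canonicalizer.

`brute_force_enumerate` is the in-package oracle: dumb enumeration of
all bond-order assignments with only valence bookkeeping, leaf-filtered
by the same from-scratch candidate checker, guarded to small skeletons
(≤ 7 heavy atoms by default; the symmetric-fixture check passes 8
explicitly with hydrogens fixed).

## Consistency checking and fuzzy generation

`check_consistency` runs three stages. (1) Pigeonhole: forced
distance-1 partners may not exceed an atom's free valence. (2)
Interval propagation: min-plus closure of the pairwise upper bounds
(triangle inequality over the constraint graph) against every lower
bound. (3) Bounded trial generation, which fires on either signature
of non-standard correlations taken at face value: the search exhausts
with zero structures, or every surviving structure deviates grossly
from the observed shifts (best fast-prediction deviation > 5.5 ppm —
the same threshold that flags a suspicious final answer). Stage 3's
trial result is attached to the report so the pipeline can reuse it
instead of regenerating. Detection is heuristic by construction: a
constraint set that a wrong structure satisfies with plausible shifts
is undetectable by any sound method, and fuzzy generation is the
remedy either way.

Fuzzy structure generation iterates subsets of size 0..m of the
eligible connectivity set — the suspicious set when detection
localized one, else all N — relaxing each chosen connectivity by a
bonds (or deleting it; a = 16 is honoured literally as the deletion
sentinel) and re-running generation, unioning and deduplicating the
results. Infeasible combinations are skipped by stages 1–2 before any
search. Accounting: n_math = Σ_{i=1..m} C(N, i) (1 when m = 0, the
single common-mode run), n_real = combinations actually generated,
n_skipped = pre-test rejections, and the k chain
generated → filtered → unique. The automatic mode escalates
m = 1, 2, … (default cap 3) until the result file is non-empty.

## Shift prediction and ranking

*Fast (d_I)*: an additive increment scheme (`data/increments.yaml`)
with textbook-style values — Grant–Paul α/β/γ/δ carbon counts with
per-element heteroatom corrections for sp³ carbons; substituent
increments with ipso/ortho/meta/para resolution plus aza corrections
for ring carbons; same-side/far-side increments for olefinic carbons;
carbonyl classes by heteroatom neighbourhood; alkyne/nitrile bases.
Deterministic and linear in molecule size. The table is editable
configuration; the code interprets only the environment classes.

*Accurate (d_A)*: HOSE-style canonical sphere codes to depth 4 (rooted
environment trees, children ordered by their own encodings, bond-order
marks, no immediate backtracking) keyed into a ShiftDB built from
assigned structures, with sphere-by-sphere fallback 4→3→2→1 and
count-weighted means per code. Leave-in prediction reproduces stored
shifts exactly; precision on unknowns grows with the reference corpus.
The DB persists as a sorted text table.

*Deviation*: mean |Δδ| under the optimal assignment of predicted to
observed shifts, solved as a min-cost bipartite assignment
(`scipy.optimize.linear_sum_assignment`), with observed peaks expanded
by degeneracy. Predictions may only map onto peaks of the same CHn
class when multiplicities are known (configurable off); incompatible
pairings cost 10³ ppm, so structurally impossible candidates score far
outside the plausible range instead of erroring. Tested against the
exhaustive-permutation minimum up to 8 carbons.

*Protocol*: d_I for all candidates → duplicate removal keeping each
family's best representative → sort by d_I → HOSE re-scoring of the
top k (default 50) and re-ranking by d_A, with d_H computed on the
head when ¹H peaks are present (rectangular assignment, since
hetero-bound protons have no predicted counterpart). Ties break on the
canonical key, making ranking order-independent. A best d_A above
5.5 ppm marks the result suspicious.

## Fragment mode

User fragment databases are cut from assigned structures as
atom-centred spheres of radius 1–3 and complete rings with their first
shell (capped at 12 atoms) — the same environments the HOSE predictor
keys on, which keeps fragments predictor-compatible. "Chemically
reasonable cutting" has no canonical definition; this sphere+ring rule
is this package's stated choice. Isomorphic fragments merge with
position-wise shift averaging in canonical order.

A fragment is *found* if an injective carbon→peak map exists with
|Δδ| ≤ E per carbon (default E = 1.5 ppm), compatible multiplicities,
peak capacities respected, and no resolved 2D correlation between
mapped peaks whose lower bound exceeds the fragment's internal
distance (internal distances only shrink in the full molecule, so
that is a genuine contradiction; exceeding the upper bound is not,
since the closing path may run outside the fragment). Assignment
enumeration is branch-and-bound ordered by |Δδ| with a per-fragment
cap (default 10⁵); overflowing fragments are skipped and logged.

Found fragments embed into the MCD as fixed internal bonds, one MCD
variant per compatible non-overlapping combination of at least
`min_fragments_per_mcd` fragments, ranked by skeleton coverage,
screened by the cheap consistency stages and capped (default 50
variants) — the cap-and-rank policy is an artifact decision, as no
canonical rule exists for how many variants to spawn.

## Stereochemistry from NOE classes

Distance classes: strong 1.8–2.5 Å, medium 2.5–4.0 Å, weak
4.0–5.0 Å, absence beyond 5.0 Å. The printed sources disagree on the
weak window; [4.0, 5.0] is the only reading consistent with the
absence cutoff and is configurable. Configurations are enumerated
exhaustively (cap 2¹⁴) via RDKit with symmetry-unique filtering, then
quotiented by the global mirror (inverting all parities), since NOE
data determine relative configuration only. Each configuration is
embedded as up to 8 ETKDG conformers with MMFF (UFF fallback)
refinement; the energy proxy is the lowest force-field energy.

Effective distances use r_eff = (⟨r⁻⁶⟩_conformers)^(−1/6) with r the
closest H–H approach between the two heavy atoms' protons — on a
single rigid conformer this is exactly the geometric distance. The
penalty is Σ (r_eff − nearest window bound)² over violated
constraints, zero inside the windows. The quadratic form is this
package's choice (no canonical functional exists); it is validated by
correct discrimination on rigid fixtures, e.g. the Z/E-2-butene pair
under one strong vinylic NOE. Candidates sort by (penalty, energy
proxy); embedding failures are flagged and sorted last, never dropped.

## The simulator and the fixture corpus

`simulate_correlations` inverts the data model: HSQC per protonated
carbon orbit (never dropped — it anchors the CHn partition), COSY per
proton pair coupled over 3 bonds (²J geminal off by default), HMBC per
proton–carbon pair over 2–3 bonds, all collapsed over automorphism
orbits with degeneracy counts. Optional per-record drop probability,
Gaussian coordinate noise (¹³C sd, ¹H sd/10), and NSC injections:
records for pairs whose true coupling length is ≥ 4 bonds, written
indistinguishably from ordinary records.

Reference shifts are the package's own incremental predictions plus
fixed per-molecule curated offsets (seeded by the molecule name,
|offset| ≤ 0.4 ppm ¹³C / 0.15 ppm ¹H), then spaced so distinct orbits
stay resolvable at the matching tolerances (0.25 ppm ¹³C, 0.04 ppm
¹H). This makes the ground truth internally consistent and the closed
loop exact; it makes **no claim of matching literature spectra**.

The corpus (12 molecules, 8–14 heavy atoms): 4-methylanisole and
p-cresol (symmetric para-disubstituted benzenes), anisole, quinoline,
indole, N-methylindole, acetanilide, methyl benzoate, dimethyl
acetylenedicarboxylate (proton-deficient, H-free alkyne/diester core),
2-methylcyclohexanone, 5-methylhexan-2-one, 2,6-dimethylheptan-1-ol.
The suite provides, per molecule, a clean case, a +1-NSC case (one
injected 4-bond HMBC, chosen so that no element/H-compatible peak
assignment reconciles the data with the true constitution — otherwise
the false record is absorbable by reassignment and no contradiction
exists), and a noisy case (5% drops, 0.02 ppm coordinate noise).
Everything is regenerable from a seed (`nmrcase simulate`).

What passing these conditions shows: the constraint pipeline, the
generator's soundness/completeness, NSC detection/repair and the
ranking protocol work end to end on realistic topologies. What it does
not show: robustness to real spectral pathologies (severe overlap,
artifacts, wrong multiplicity edits, solvent effects), predictor
accuracy on real spectra (the closed loop uses the predictor's own
shift scale), or performance on large proton-deficient natural
products (tens of heavy atoms with sparse data), where fragment-mode
prior knowledge becomes essential rather than an accelerator.

## Numerical choices and problem sizes

* Generation node budgets: 5×10⁶ default, 12×10⁶ in the acceptance
  script; the largest fixture search (the proton-deficient diester)
  exhausts in ~0.8×10⁶ nodes.
* Trial generation in the consistency check caps at 4000 kept
  structures; hitting a cap yields "inconclusive", never a verdict.
* Valences C 4, N 3, O 2 (S 2, P 3, halogens 1 accepted); optional
  exploration of N(V) skeletons per run. Charges, isotopes and
  radicals are not modelled; half-integer DBE warns instead of
  failing.
* Deviation infeasible-pair cost 10³ ppm; suspicion threshold 5.5 ppm;
  fragment tolerance E = 1.5 ppm; HOSE depth 4.
* The oracle-equivalence suite uses the C4–C7 alkane series plus 50
  random constrained instances of 2–5 heavy atoms; brute-force
  enumeration beyond 7 atoms is used only for the symmetric fixture
  with hydrogens fixed. These sizes are chosen so the whole
  verification runs on a laptop-class single core in minutes.
* Determinism: fixed atom ordering, canonical-key tie-breaks, seeded
  RNGs everywhere (simulator, stereo embedding, acceptance script);
  re-running any stage with the same inputs reproduces its output
  byte for byte.

## Known limitations

* The generator's labeled-search design is exponential in principle;
  it is exact and fast on correlation-dense desk-scale problems but
  not a competitor to specialized generators on 50+ atom skeletons.
* Aromaticity is represented by alternating Kekulé bond orders; two
  Kekulé forms of one substituted ring are distinct graphs by design
  (the ranking treats them as separate candidates).
* Tautomers are distinct constitutions; no tautomer merging.
* The incremental scheme is a compact textbook-style model: adequate
  for ranking internally consistent data, not a state-of-the-art
  predictor.
* ¹H–¹⁵N HMBC constraints target the nitrogen set disjunctively
  (nitrogens carry no shift), which is weak when several nitrogens
  are present.
* NOE classes assume rigid or modestly flexible molecules; no
  mixing-time/relaxation modelling, no ensemble reweighting beyond
  r⁻⁶ averaging.
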