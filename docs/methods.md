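# Methods

## Category generation

Eligible anchors are the non-obsolete ontology terms in the
`biological_process` and `molecular_function` namespaces that carry no
regulates-family out-edge. Each anchor *X* yields exactly two categories,
`FTC_P<id>` ("Pro-X agent") and `FTC_A<id>` ("Anti-X agent"), where `<id>`
is the 7-digit numeric part of the term id. Regulation terms are *folded*,
not reified: no "Anti-positive-regulation-of-X agent" class exists — a
perturbation reaching "positive regulation of X" contributes to Pro-/Anti-X
directly via sign multiplication. This matches the intended reading of the
regulator pattern, where an inhibitor of a coagulation activator is an
anti-coagulant, not an "anti-activator-of-coagulation" agent. Obsolete
terms and terms outside the two namespaces anchor nothing.

## Polarity algebra

Perturbation signs: a versioned action-term table maps
{inhibitor, antagonist, blocker, suppressor, negative modulator} → −1 and
{agonist, activator, inducer, stimulator, potentiator, positive modulator}
→ +1 (case-insensitive, user-extensible via `BuildConfig.action_signs`).
Unmapped actions (e.g. `binder`) are retained as `unknown` and are inert in
classification: with no directional information the safe inference is none.

Regulation forms: a term with no regulates-edge is its own anchor (form
`(term, DIRECT)`). A regulation term contributes one form per regulated
target, signed +1/−1/0 by the edge type. Chains of regulation terms
("positive regulation of negative regulation of X") compose
multiplicatively up to `regulation_chain_depth` edges (default 2 — one
level beyond the single-level decomposition, the natural extension); the
neutral sign 0 absorbs, and chains deeper than the cap are dropped rather
than guessed. Neutral "regulation of X" never produces a membership:
double assignment to both Pro-X and Anti-X would assert directions the data
does not support.

Membership rule: for link sign `p ∈ {+1, −1}` and form `(X, r)`, the drug
joins `category(polarity = p·r, anchor = X)` (with `r = +1` for DIRECT).
Memberships are boolean — binding strength and dosage are deliberately out
of the model — and a drug is assumed to perturb *all* annotated functions
of its target, a known simplification that over-generates candidate MoAs by
design (the false positives are the repurposing hypotheses).

## Taxonomy

Pro-X ⊑ Pro-Y (and Anti-X ⊑ Anti-Y) exactly when Y is reachable from X
along the propagation relations (default `is_a`, `part_of`; configurable;
regulates-family edges never propagate), with the edge set transitively
reduced. Anchors with no categorised ancestor attach to one of four
synthetic roots (`FTC_{P,A}_ROOT_{BP,MF}`, "Pro-/Anti-biological process
agent", "Pro-/Anti-molecular function agent"). The result is a DAG with
possibly multiple parents; acyclicity is asserted on every build. Indirect
memberships are the taxonomy ancestors (roots included) of a drug's direct
categories, minus the direct set; the union is closed under ancestors and
the closure is a fixed point.

The rule-based classifier is mirrored by a brute-force oracle that
re-derives everything by naive path search over the raw edge list; the test
suite keeps the two set-identical across randomized fixtures. Identical
inputs yield identical sorted membership lists, and input-row order never
matters.

## Similarity and significance

A drug's MoA profile is its direct ∪ indirect category set; the four roots
are excluded by default (every classified drug carries them, so they only
compress the dynamic range — `include_roots` restores them). Similarity is
the plain Jaccard index: 1 iff the profiles coincide, 0 iff disjoint, and
1 − J is a metric. Two drugs "in the same category" score 1 only when
their *full* profiles coincide; sharing one category among many scores
lower — this is the sharpest reading consistent with the stated identity
and range properties.

The within-class test: for each therapeutic class (ATC code truncated at
the requested level; drugs mapping to several classes are labelled
`multiple`, drugs without codes `NoCategory`, both excluded), the statistic
is the mean off-diagonal similarity among members. The null shuffles the
drug→label assignment preserving class sizes — implemented per class as
random same-size member subsets, the exact marginal of a global shuffle —
and the p-value uses the add-one estimator `(1 + #{null ≥ obs}) / (1 +
n_perm)`, so a finite permutation count never yields p = 0. Classes with
fewer than two members are skipped. A class containing every drug has
observed = null by construction, hence p = 1.

## Evaluation

An evaluation point equates one FTC category with one or more ATC codes at
any level; ATC levels are prefixes, so matching is prefix matching. The
universe is the intersection of the build's drugs with the ATC-annotated
drugs: drugs absent from the gold standard cannot be false positives (they
are hypotheses, not errors). Per point, TP/FP/FN are counted over the
universe with FTC membership meaning direct *or* indirect; totals are
element-wise sums (a drug in two overlapping points counts once per point,
and `covered_drugs` additionally reports unique drugs). Precision and
recall use the usual ratios with a 0 convention for empty denominators;
headline percentages are rounded to integers, full precision is kept in the
JSON.

## Synthetic fixtures

The generator emulates the shape of the real inputs at toy scale: a
rank-layered term DAG (edges only point to earlier ranks — acyclic by
construction, ~20 % `part_of`, ~20 % molecular-function terms), single-level
regulation terms attached with signed edges (45 % positive, 45 % negative,
10 % neutral), proteins annotated to 1–2 random terms, and drugs with 2
random links drawn from a vocabulary that includes the inert `binder`.
Planted clusters give each cluster's drugs an identical core link set
(`cluster_targets` dedicated proteins on dedicated terms, inhibitor links)
and a shared ATC class; cluster drugs carry no extra noise links by default
(`cluster_noise_links = 0`), which is what makes a planted cluster *tight*
— within-cluster similarity exactly 1. Expected direct memberships are
recorded constructively from the planted chains during generation, never by
running the classifier, so classifier tests are falsifiable.

What the generator does **not** emulate: realistic GO topology (depth,
fan-out, annotation bias), DrugBank action-term frequencies, correlated
pharmacology between clusters, or multi-level regulation chains. Passing
tests therefore establish the correctness of the algebra, closure,
counting and test calibration — not performance on the real 20 000-term
ontology, whose headline magnitudes depend on a specific historical data
snapshot.

## Numerical and scale choices

Default problem sizes in the test suite and analytics: 30–50 terms, 8–12
drugs, 8–12 proteins — large enough for multi-parent DAGs and mixed
namespaces, small enough that the brute-force oracle runs in milliseconds.
Permutation counts: 20 000 by default in the CLI (the published analysis
scale); 1 000–2 000 in tests, where the calibration check pools ~600
null p-values across 200 replicates and expects the fraction below 0.05 to
sit in [0.02, 0.08]. Ties in the permutation null count as ≥ observed
(tolerance 1e−12), which keeps the degenerate all-drugs class at exactly
p = 1. Jaccard of two empty profiles is NaN (undefined, excluded from
matrices) rather than an arbitrary 0 or 1.

## Known limitations

* Unknown-action links are inert; a resource built from a source where most
  links lack action terms will under-classify.
* The taxonomy places Pro-X and Anti-X under separate roots only; no common
  "X-perturbing agent" parent is created.
* Evidence codes are parsed and kept but not filtered by default
  (`exclude_evidence` opts in, e.g. `IEA`).
* ATC codes are stored at full resolution; truncation is a view operation,
  and a drug whose codes disagree at the tested level is excluded from the
  significance analysis as `multiple`.
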