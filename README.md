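# ftc — a Functional Therapeutic Chemical classification toolkit

`ftc` builds a drug **mode-of-action (MoA) classification** from public-style
molecular data: a GO-like ontology of biological processes and molecular
functions, protein→term annotations (GAF), and a drug→target table with
pharmacological action terms. It is aimed at computational drug-repositioning
work, where the question is not *what a drug is prescribed for* but *what it
does* — every process a compound can plausibly push up or down through its
protein targets.

## The model

For every eligible ontology term *X* (non-obsolete, biological-process or
molecular-function, and not itself a regulation term) the toolkit creates two
categories:

* **Pro-X agent** (`FTC_P<nnnnnnn>`) — agents promoting *X*
* **Anti-X agent** (`FTC_A<nnnnnnn>`) — agents attenuating *X*

where `<nnnnnnn>` is the zero-padded numeric part of the term id
(`GO:0042730` → `FTC_P0042730`, "Pro-fibrinolysis agent").

A drug *d* is a **direct member** of a category when some chain

```
d —(perturbation, sign p ∈ {+1, −1})→ protein —(annotation)→ term T
T decomposes to regulation form (X, r)
```

satisfies `polarity = p · r`. The perturbation sign comes from the action
vocabulary (`inhibitor`, `antagonist`, … → −1; `agonist`, `activator`, … →
+1; anything else is inert). The *regulation form* folds GO's regulation
terms into a sign: `positive regulation of X` ⇒ (X, +1), `negative
regulation of X` ⇒ (X, −1), plain `regulation of X` ⇒ neutral (no
membership), and a term with no regulates-edge is its own anchor (r ≡ +1).
So an *inhibitor* of a protein annotated to *positive regulation of blood
coagulation* is an **Anti-blood coagulation agent** (−1 · +1).

Categories inherit the term hierarchy polarity-wise (`is_a`/`part_of`,
transitively reduced), rooted in four abstract classes (Pro/Anti ×
process/function agent). **Indirect memberships** are the taxonomy ancestors
of the direct ones.

On top of the build the package provides the downstream analytics:

* **MoA similarity** — Jaccard index over (direct ∪ indirect) category
  profiles, the all-pairs matrix, and an ATC-sorted export;
* **significance** — a within-ATC-class permutation test on the mean
  within-class similarity (label shuffling, add-one p-value);
* **evaluation** — precision/recall against ATC gold annotations through
  curated FTC↔ATC "evaluation points";
* **synthetic fixtures** — seeded toy knowledge bases with planted,
  constructively-known ground truth (`ftc.synthetic`), so everything above
  is testable without downloads.

A rule-based classifier (`ftc.classify`) does the reasoning; a deliberately
naive enumerator (`ftc.brute_force_oracle`) recomputes the same result by
raw path search and is kept set-identical to it in the test suite.

## Worked example

The canonical chain — ximelagatran inhibits prothrombin, prothrombin is
annotated to *positive regulation of blood coagulation*:

```python
>>> from ftc import classify, make_figure1_fixture
>>> build = classify(make_figure1_fixture().kb)
>>> [(m.category_id, m.kind) for m in build.memberships]
[('FTC_A0007596', 'direct'), ('FTC_A_ROOT_BP', 'indirect')]
>>> build.taxonomy.categories['FTC_A0007596'].label
'Anti-blood coagulation agent'
>>> build.memberships[0].provenance[0]
'DB04898-[inhibitor:-1]->P00734-[annotated]->GO:0030194-[reg+1]->GO:0007596'
```

One direct membership: the inhibitor of a coagulation *activator* is an
anti-coagulant, and the provenance string records the full chain.

The same from the shell, on a seeded synthetic knowledge base with three
planted drug clusters:

```console
$ ftc simulate --seed 42 --n-terms 40 --n-drugs 12 --clusters 3 --out kb
$ ftc classify --obo kb/ontology.obo --gaf kb/annotations.gaf \
               --targets kb/drug_targets.tsv --out build
{
  "n_categories": 60,
  "n_categories_direct": 13,
  "n_categories_direct_or_indirect": 32,
  "n_drugs": 12,
  "n_drugs_classified": 12,
  ...
}
$ ftc similarity --build kb --atc kb/atc.tsv --nperm 2000 --seed 7 --out sim
A       n=3     observed=1.000  null=0.402      p=0.01049
B       n=3     observed=1.000  null=0.404      p=0.009495
C       n=3     observed=1.000  null=0.412      p=0.01799
```

60 categories (two per eligible term), 13 of them directly populated, 32
once ancestors are inherited. Each planted cluster's drugs share identical
MoA profiles (observed within-class mean similarity 1.0 vs ≈0.4 under label
shuffling), so all three therapeutic classes come out significant at
p < 0.05 — the toy-scale version of "drugs with similar MoAs have similar
indications".

`ftc evaluate --build kb --atc kb/atc.tsv --points points.tsv --out eval`
scores the build against ATC codes through evaluation points and prints
TP/FP/FN with precision and recall.

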