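"""MoA-profile similarity and the within-ATC-class permutation test.

A drug's MoA profile is the set of FTC categories it belongs to (direct
plus inherited; the four abstract roots are excluded by default since every
classified drug carries them).  Profiles are compared with the Jaccard
index |A∩B| / |A∪B|, which is 1 for identical profiles and 0 for disjoint
ones.  Whether drugs sharing a therapeutic class (ATC) have higher MoA
similarity than expected by chance is assessed with a label-shuffling
permutation test on the mean of the within-class off-diagonal similarities.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .classifier import FtcBuild
from .ontology_io import AtcAnnotation

#: Pseudo-classes excluded from significance testing.
EXCLUDED_CLASSES = ("multiple", "NoCategory")

#: ATC hierarchy level -> code prefix length.
ATC_LEVEL_CHARS = {1: 1, 2: 3, 3: 4, 4: 5, 5: 7}


def moa_profiles(
    build: FtcBuild, include_indirect: bool = True, include_roots: bool = False
) -> dict[str, frozenset[str]]:
    """MoA category sets per drug; drugs without memberships are omitted."""
    kind = None if include_indirect else "direct"
    by_drug = build.memberships_by_drug(kind)
    profiles: dict[str, frozenset[str]] = {}
    for drug in build.drugs:
        cats = by_drug.get(drug.drug_id, set())
        if not include_roots:
            cats = {c for c in cats if not build.taxonomy.is_root(c)}
        if cats:
            profiles[drug.drug_id] = frozenset(cats)
    return profiles


def jaccard(profile_a: frozenset[str], profile_b: frozenset[str]) -> float:
    """Jaccard index of two MoA profiles; NaN when both are empty."""
    if not profile_a and not profile_b:
        return math.nan
    inter = len(profile_a & profile_b)
    union = len(profile_a | profile_b)
    return inter / union


def pairwise_matrix(build: FtcBuild, include_indirect: bool = True) -> pd.DataFrame:
    """Symmetric drug-by-drug Jaccard matrix with unit diagonal.

    Rows follow the build's drug order restricted to drugs with at least
    one (non-root) membership.
    """
    profiles = moa_profiles(build, include_indirect=include_indirect)
    order = [d.drug_id for d in build.drugs if d.drug_id in profiles]
    if not order:
        return pd.DataFrame(dtype=float)
    cats = sorted(set().union(*(profiles[d] for d in order)))
    cat_idx = {c: i for i, c in enumerate(cats)}
    binary = np.zeros((len(order), len(cats)), dtype=float)
    for i, drug in enumerate(order):
        for c in profiles[drug]:
            binary[i, cat_idx[c]] = 1.0
    inter = binary @ binary.T
    sizes = binary.sum(axis=1)
    union = sizes[:, None] + sizes[None, :] - inter
    values = inter / union
    np.fill_diagonal(values, 1.0)
    return pd.DataFrame(values, index=order, columns=order)


def atc_class_labels(
    atc: Mapping[str, AtcAnnotation], drugs: Sequence[str], level: int = 1
) -> dict[str, str]:
    """Therapeutic class per drug at the given ATC level.

    Drugs whose codes truncate to several distinct classes are labelled
    'multiple'; drugs with no ATC code at all 'NoCategory'.
    """
    chars = ATC_LEVEL_CHARS[level]
    labels: dict[str, str] = {}
    for drug in drugs:
        ann = atc.get(drug)
        if ann is None or not ann.atc_codes:
            labels[drug] = "NoCategory"
            continue
        truncated = {code[:chars] for code in ann.atc_codes}
        labels[drug] = truncated.pop() if len(truncated) == 1 else "multiple"
    return labels


def sort_matrix_by_class(matrix: pd.DataFrame, labels: Mapping[str, str]) -> pd.DataFrame:
    """Reorder rows/columns by class label (heat-map layout), then by id."""
    order = sorted(matrix.index, key=lambda d: (labels.get(d, "NoCategory"), d))
    return matrix.loc[order, order]


@dataclass(frozen=True)
class PermutationResult:
    atc_class: str
    n_members: int
    observed_mean: float
    null_mean: float
    null_sd: float
    p_value: float
    n_permutations: int
    seed: int


def _within_mean(values: np.ndarray, idx: np.ndarray) -> float:
    sub = values[np.ix_(idx, idx)]
    k = len(idx)
    return (sub.sum() - np.trace(sub)) / (k * (k - 1))


def within_class_permutation_test(
    matrix: pd.DataFrame,
    labels: Mapping[str, str],
    n_perm: int = 20000,
    seed: int = 0,
    exclude: Sequence[str] = EXCLUDED_CLASSES,
) -> list[PermutationResult]:
    """One-sided permutation test per therapeutic class.

    The observed statistic is the mean off-diagonal similarity among the
    class members.  The null shuffles the drug-to-label assignment while
    preserving class sizes (equivalently: random same-size member sets),
    and the p-value uses the add-one estimator
    p = (1 + #{null >= observed}) / (1 + n_perm), so p is never exactly 0.

    Classes with fewer than two members are skipped.
    """
    drugs = list(matrix.index)
    values = matrix.to_numpy()
    n = len(drugs)
    classes: dict[str, list[int]] = {}
    for i, drug in enumerate(drugs):
        label = labels.get(drug, "NoCategory")
        if label not in exclude:
            classes.setdefault(label, []).append(i)

    rng = np.random.default_rng(seed)
    results: list[PermutationResult] = []
    for label in sorted(classes):
        members = np.asarray(classes[label])
        k = len(members)
        if k < 2:
            continue
        observed = _within_mean(values, members)
        # vectorised label shuffle: each permutation draws a random k-subset
        draws = np.argsort(rng.random((n_perm, n)), axis=1)[:, :k]
        sub = values[draws[:, :, None], draws[:, None, :]]
        diag = sub[:, np.arange(k), np.arange(k)].sum(axis=1)
        null_means = (sub.sum(axis=(1, 2)) - diag) / (k * (k - 1))
        p = (1 + int(np.sum(null_means >= observed - 1e-12))) / (1 + n_perm)
        results.append(
            PermutationResult(
                atc_class=label,
                n_members=k,
                observed_mean=float(observed),
                null_mean=float(null_means.mean()),
                null_sd=float(null_means.std()),
                p_value=float(p),
                n_permutations=n_perm,
                seed=seed,
            )
        )
    return results
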