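"""Test for non-random combinations of chain types within ester lipid classes.

A lipid of a k-chain class carries an unordered multiset of k chain-type
categories (e.g. a DG with an M0 and an M1 chain is the combination
``M0_M1``).  Under random association, chains combine independently according
to the class's marginal category frequencies, so the probability of a
combination is multinomial:

    P(m) = k! / prod_t n_t! * prod_t p_t^{n_t}

for a multiset m using category t exactly n_t times.  This module computes,
per replicate sample, the abundance-weighted marginal category probabilities
``p_t`` of a class, the observed combination frequencies, and the multinomial
expectations; it then compares observed and expected per combination with a
paired one-sample t-test over replicates (Bonferroni-corrected within the
class x group family) and screens for large biases (absolute
observed-expected difference above a percentage-point threshold with a
consistent direction in both groups).

Three category schemes are supported: the nine joint length x saturation
categories (``joint9``), length only (``length3``) and saturation only
(``bond3``).

The test is defined for multi-chain *ester* classes only (DG, TG, CL, PC, PE,
PG, PI, PS): single-chain classes have no combinations and ether classes mix
chemically distinct linkage types.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace
from itertools import combinations_with_replacement
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from .lipidome import ConcentrationTable
from .nomenclature import (
    BOND_ORDER,
    CATEGORY_ORDER,
    CLASS_CHAIN_COUNT,
    ESTER_MULTI_CHAIN_CLASSES,
    LENGTH_ORDER,
)

__all__ = [
    "SCHEMES",
    "GroupResult",
    "CombinationTestResult",
    "combination_key",
    "category_probs",
    "observed_combination_freqs",
    "expected_combination_freqs",
    "run_combination_test",
    "large_bias_screen",
]

#: scheme name -> ordered category alphabet
SCHEMES: dict[str, tuple[str, ...]] = {
    "joint9": CATEGORY_ORDER,
    "length3": LENGTH_ORDER,
    "bond3": BOND_ORDER,
}


def _scheme_label(joint_label: str, scheme: str) -> str:
    if scheme == "joint9":
        return joint_label
    if scheme == "length3":
        return joint_label[0]
    if scheme == "bond3":
        return joint_label[1]
    raise ValueError(f"unknown scheme {scheme!r}")


def combination_key(labels: Sequence[str], scheme: str = "joint9") -> str:
    """Canonical key of an unordered combination: labels sorted in scheme
    order and joined with underscores (e.g. ``S0_M0_M1``)."""
    order = {lab: i for i, lab in enumerate(SCHEMES[scheme])}
    try:
        return "_".join(sorted(labels, key=order.__getitem__))
    except KeyError as e:
        raise ValueError(f"label {e.args[0]!r} not in scheme {scheme!r}") from None


def _class_species(table: ConcentrationTable, class_code: str) -> list[str]:
    if class_code not in ESTER_MULTI_CHAIN_CLASSES:
        raise ValueError(
            f"combination analysis is defined for multi-chain ester classes "
            f"{ESTER_MULTI_CHAIN_CLASSES}, not {class_code!r}"
        )
    return [
        n for n in table.species_of_class(class_code)
        if table.species[n].chain_specified
    ]


def _sample_weights(
    table: ConcentrationTable, names: list[str], sample: str, weighting: str
) -> np.ndarray:
    """Per-species weights within the class's chain-specified species for one
    sample: relative abundance (default) or equal over detected species."""
    conc = table.values.loc[sample, names].to_numpy(dtype=float)
    if weighting == "species":
        conc = (conc > 0).astype(float)
    elif weighting != "abundance":
        raise ValueError(f"unknown weighting {weighting!r}")
    total = conc.sum()
    if total <= 0:
        raise ValueError(
            f"sample {sample!r} has no detected chain-specified species"
        )
    return conc / total


def category_probs(
    table: ConcentrationTable,
    class_code: str,
    sample: str,
    scheme: str = "joint9",
    weighting: str = "abundance",
) -> dict[str, float]:
    """Abundance-weighted marginal frequency of each chain-type category among
    the class's chains in one sample: p_t = sum_l w_l * n_t(l)/k."""
    names = _class_species(table, class_code)
    w = _sample_weights(table, names, sample, weighting)
    k = CLASS_CHAIN_COUNT[class_code]
    probs: dict[str, float] = {}
    for n, wl in zip(names, w):
        for lab in table.species[n].category_labels():
            lab = _scheme_label(lab, scheme)
            probs[lab] = probs.get(lab, 0.0) + wl / k
    return {lab: probs[lab] for lab in SCHEMES[scheme] if lab in probs}


def observed_combination_freqs(
    table: ConcentrationTable,
    class_code: str,
    sample: str,
    scheme: str = "joint9",
    weighting: str = "abundance",
) -> dict[str, float]:
    """Abundance-weighted frequency of each observed combination (multiset of
    chain-type categories) of the class in one sample; sums to 1."""
    names = _class_species(table, class_code)
    w = _sample_weights(table, names, sample, weighting)
    freqs: dict[str, float] = {}
    for n, wl in zip(names, w):
        labels = [_scheme_label(l, scheme) for l in table.species[n].category_labels()]
        key = combination_key(labels, scheme)
        freqs[key] = freqs.get(key, 0.0) + wl
    return freqs


def expected_combination_freqs(
    probs: Mapping[str, float], k: int
) -> dict[str, float]:
    """Multinomial probability of every unordered combination of k chain
    types under random association from marginal probabilities ``probs``.

    P(m) = k!/prod(n_t!) * prod p_t^{n_t}; the distribution sums to 1.
    """
    if k not in (2, 3, 4):
        raise ValueError(f"k must be 2, 3 or 4, got {k}")
    total = math.fsum(probs.values())
    if abs(total - 1.0) > 1e-9:
        raise ValueError(f"probabilities sum to {total}, not 1")
    scheme = _infer_scheme(probs.keys())
    labels = [lab for lab in SCHEMES[scheme] if lab in probs]
    out: dict[str, float] = {}
    for combo in combinations_with_replacement(labels, k):
        counts: dict[str, int] = {}
        for lab in combo:
            counts[lab] = counts.get(lab, 0) + 1
        coef = math.factorial(k)
        p = 1.0
        for lab, n in counts.items():
            coef //= math.factorial(n)
            p *= probs[lab] ** n
        out["_".join(combo)] = coef * p
    return out


def _infer_scheme(labels) -> str:
    labels = set(labels)
    for scheme, alphabet in SCHEMES.items():
        if labels <= set(alphabet):
            return scheme
    raise ValueError(f"labels {sorted(labels)} fit no category scheme")


# -- the replicate-level test --------------------------------------------------


@dataclass(frozen=True)
class GroupResult:
    """Observed vs expected statistics for one combination in one group."""

    group: str
    n_replicates: int
    observed_mean: float
    expected_mean: float
    ratio: float
    ratio_se: float
    diff_pp: float           # observed - expected, percentage points
    t: float
    df: int
    p_raw: float
    p_bonferroni: float
    significant: bool
    degenerate: bool = False


@dataclass(frozen=True)
class CombinationTestResult:
    class_code: str
    scheme: str
    combination: str
    groups: dict[str, GroupResult] = field(default_factory=dict)
    large_bias: str = "none"  # excess | deficit | none


def _group_matrices(
    table: ConcentrationTable,
    class_code: str,
    group: str,
    scheme: str,
    weighting: str,
):
    """Per-replicate weight matrix and per-species category structure.

    Returns (combo_keys, O, E, n_used) where O and E are combos x replicates
    arrays of observed and multinomial-expected frequencies.  Samples without
    any detected chain-specified species of the class are excluded with a
    warning.
    """
    names = _class_species(table, class_code)
    k = CLASS_CHAIN_COUNT[class_code]
    alphabet = list(SCHEMES[scheme])
    lab_index = {lab: i for i, lab in enumerate(alphabet)}

    ids = table.group_sample_ids(group)
    conc = table.values.loc[ids, names].to_numpy(dtype=float)  # reps x species
    if weighting == "species":
        conc = (conc > 0).astype(float)
    totals = conc.sum(axis=1)
    usable = totals > 0
    if not usable.all():
        dropped = [i for i, u in zip(ids, usable) if not u]
        warnings.warn(
            f"excluding {len(dropped)} sample(s) with no detected "
            f"chain-specified {class_code} species: {dropped[:4]}"
        )
    conc = conc[usable]
    if conc.shape[0] < 2:
        raise ValueError(
            f"need >=2 usable replicates for {class_code} in {group}"
        )
    W = (conc / conc.sum(axis=1, keepdims=True)).T  # species x reps

    # Species -> category count vector and combination key.
    counts = np.zeros((len(names), len(alphabet)))
    keys = []
    for i, n in enumerate(names):
        labels = [_scheme_label(l, scheme) for l in table.species[n].category_labels()]
        for lab in labels:
            counts[i, lab_index[lab]] += 1
        keys.append(combination_key(labels, scheme))

    P = (counts / k).T @ W  # categories x reps, columns sum to 1

    # All multisets over categories with any marginal mass.
    active = [i for i in range(len(alphabet)) if P[i].max() > 0]
    combos = list(combinations_with_replacement(active, k))
    combo_keys = [
        "_".join(alphabet[i] for i in combo) for combo in combos
    ]
    E = np.empty((len(combos), W.shape[1]))
    for j, combo in enumerate(combos):
        cnt: dict[int, int] = {}
        for i in combo:
            cnt[i] = cnt.get(i, 0) + 1
        coef = math.factorial(k)
        prod = np.ones(W.shape[1])
        for i, n in cnt.items():
            coef //= math.factorial(n)
            prod *= P[i] ** n
        E[j] = coef * prod

    key_to_row = {key: j for j, key in enumerate(combo_keys)}
    O = np.zeros_like(E)
    for i, key in enumerate(keys):
        if key not in key_to_row:
            # Species carrying no weight in this group (categories inactive).
            continue
        O[key_to_row[key]] += W[i]

    # Family: combinations with observed or expected mass somewhere.
    family = (O.max(axis=1) > 0) | (E.max(axis=1) > 0)
    return (
        [key for key, f in zip(combo_keys, family) if f],
        O[family],
        E[family],
        conc.shape[0],
    )


def _test_rows(
    keys: list[str],
    O: np.ndarray,
    E: np.ndarray,
    group: str,
    null: str,
    test: str,
    alpha: float,
) -> dict[str, GroupResult]:
    n = O.shape[1]
    if null == "day-pooled":
        E = np.repeat(E.mean(axis=1, keepdims=True), n, axis=1)
    elif null != "per-replicate":
        raise ValueError(f"unknown null {null!r}")
    D = O - E
    mean_o, mean_e = O.mean(axis=1), E.mean(axis=1)
    bonf = len(keys)
    out: dict[str, GroupResult] = {}
    for j, key in enumerate(keys):
        if test == "paired":
            d = D[j]
            sd = d.std(ddof=1)
            df = n - 1
            degenerate = sd == 0
            if degenerate:
                t = math.inf if d.mean() != 0 else 0.0
                p = 0.0 if d.mean() != 0 else 1.0
            else:
                t = d.mean() / (sd / math.sqrt(n))
                p = 2 * stats.t.sf(abs(t), df)
        elif test == "two-sample":
            df = 2 * n - 2
            sp2 = (O[j].var(ddof=1) + E[j].var(ddof=1)) / 2
            degenerate = sp2 == 0
            if degenerate:
                t = math.inf if mean_o[j] != mean_e[j] else 0.0
                p = 0.0 if mean_o[j] != mean_e[j] else 1.0
            else:
                t = (mean_o[j] - mean_e[j]) / math.sqrt(sp2 * 2 / n)
                p = 2 * stats.t.sf(abs(t), df)
        else:
            raise ValueError(f"unknown test {test!r}")

        if mean_e[j] > 0:
            ratio = mean_o[j] / mean_e[j]
            if (E[j] > 0).all():
                r = O[j] / E[j]
                ratio_se = float(r.std(ddof=1) / math.sqrt(n))
            else:
                # Delta method on the ratio of means.
                var = (
                    O[j].var(ddof=1)
                    + ratio**2 * E[j].var(ddof=1)
                    - 2 * ratio * np.cov(O[j], E[j], ddof=1)[0, 1]
                )
                ratio_se = float(math.sqrt(max(var, 0.0) / n) / mean_e[j])
        else:
            ratio, ratio_se = math.inf, math.nan
        p_bonf = min(1.0, p * bonf)
        out[key] = GroupResult(
            group=group,
            n_replicates=n,
            observed_mean=float(mean_o[j]),
            expected_mean=float(mean_e[j]),
            ratio=float(ratio),
            ratio_se=ratio_se,
            diff_pp=float((mean_o[j] - mean_e[j]) * 100.0),
            t=float(t),
            df=df,
            p_raw=float(p),
            p_bonferroni=float(p_bonf),
            significant=bool(p_bonf < alpha),
            degenerate=bool(degenerate),
        )
    return out


def run_combination_test(
    table: ConcentrationTable,
    class_code: str,
    groups: Sequence[str] | None = None,
    scheme: str = "joint9",
    weighting: str = "abundance",
    null: str = "per-replicate",
    test: str = "paired",
    alpha: float = 0.05,
) -> list[CombinationTestResult]:
    """Observed vs multinomial-expected combination frequencies per group.

    For every combination with observed or expected mass in a group, the
    per-replicate differences d_s = O(s) - E(s) are tested against zero with
    a two-sided one-sample t-test (``test='two-sample'`` compares the O and E
    series instead; ``null='day-pooled'`` replaces each replicate's
    expectation with the group mean expectation).  p-values are
    Bonferroni-corrected by the number of combinations in the class x group
    family.  The ratio mean(O)/mean(E) is reported with an SE from
    per-replicate ratios when every E > 0, else from the delta method.
    """
    if groups is None:
        groups = table.groups
    per_group: dict[str, dict[str, GroupResult]] = {}
    all_keys: dict[str, None] = {}
    for group in groups:
        keys, O, E, _ = _group_matrices(table, class_code, group, scheme, weighting)
        per_group[group] = _test_rows(keys, O, E, group, null, test, alpha)
        for key in keys:
            all_keys.setdefault(key, None)
    order = {lab: i for i, lab in enumerate(SCHEMES[scheme])}
    sorted_keys = sorted(
        all_keys, key=lambda key: [order[lab] for lab in key.split("_")]
    )
    return [
        CombinationTestResult(
            class_code=class_code,
            scheme=scheme,
            combination=key,
            groups={
                g: per_group[g][key] for g in groups if key in per_group[g]
            },
        )
        for key in sorted_keys
    ]


def large_bias_screen(
    results: Sequence[CombinationTestResult],
    threshold_pp: float = 5.0,
) -> list[CombinationTestResult]:
    """Flag combinations whose |observed - expected| exceeds ``threshold_pp``
    percentage points in at least one group with the same direction of effect
    in both groups.  Requires results computed for two groups."""
    out = []
    for res in results:
        if len(res.groups) < 2:
            raise ValueError(
                f"large-bias screen needs both groups for {res.combination}"
            )
        diffs = [g.diff_pp for g in res.groups.values()]
        flag = "none"
        if max(abs(d) for d in diffs) > threshold_pp and (
            all(d > 0 for d in diffs) or all(d < 0 for d in diffs)
        ):
            flag = "excess" if diffs[0] > 0 else "deficit"
        out.append(replace(res, large_bias=flag))
    return out
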