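"""Chain-level composition profiles per lipid class.

All operations here work on the *chain-specified* species of a class detected
in a group: mean carbons/double bonds per chain (separately for acyl and
ether-linked chains), proportions over the nine joint length x saturation
categories and their marginals, common-chain detection at a frequency
threshold, and the overlap coefficient between the acyl and alkyl/alkenyl
chain complements of an ether class.

By default each detected species contributes its chains once (species-count
weighting); abundance weighting — each species' chains weighted by the
species' mean relative abundance in the group — is available everywhere.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .lipidome import ConcentrationTable, relative_abundance
from .nomenclature import (
    BOND_ORDER,
    CATEGORY_ORDER,
    ETHER_CLASSES,
    LENGTH_ORDER,
    categorize_chain,
)

__all__ = [
    "ChainStat",
    "mean_chain_stats",
    "category_profile",
    "chain_frequencies",
    "common_chains",
    "dichotomy_overlap",
]

LINKAGE_GROUPS = ("acyl", "alkyl_or_alkenyl")


@dataclass(frozen=True)
class ChainStat:
    """Mean carbons and double bonds per chain for one class / group /
    linkage group.  ``computable`` is False when the class has no detected
    chain-specified species (the means are then NaN).  SEs are across the
    contributing species (NaN when only one species contributes)."""

    class_code: str
    group: str
    linkage_group: str
    n_species: int
    mean_carbons: float
    se_carbons: float
    mean_double_bonds: float
    se_double_bonds: float

    @property
    def computable(self) -> bool:
        return self.n_species > 0


def _specified_species(
    table: ConcentrationTable, class_code: str, group: str
) -> list[str]:
    detected = set(table.detected_in_group(group))
    return [
        n
        for n in table.species_of_class(class_code)
        if n in detected and table.species[n].chain_specified
    ]


def _species_weights(
    table: ConcentrationTable,
    names: list[str],
    group: str,
    weighting: str,
) -> np.ndarray:
    """Normalised per-species weights under 'species' or 'abundance'
    weighting (abundance = mean relative abundance over the group)."""
    if weighting == "species":
        return np.full(len(names), 1.0 / len(names))
    if weighting == "abundance":
        rel = relative_abundance(table)
        ids = table.group_sample_ids(group)
        w = rel.loc[ids, names].mean(axis=0).to_numpy()
        total = w.sum()
        if total <= 0:
            raise ValueError("zero total abundance for weighting")
        return w / total
    raise ValueError(f"unknown weighting {weighting!r}")


def mean_chain_stats(
    table: ConcentrationTable,
    class_code: str,
    group: str,
    weighting: str = "species",
) -> dict[str, ChainStat]:
    """Average carbons and double bonds per chain, by linkage group.

    For each chain-specified detected species the per-species mean over its
    chains in the linkage group is taken first; the reported mean and SE are
    then across species (weighted for ``weighting='abundance'``).  Ester
    classes report 'acyl' only; ether classes report 'acyl' and
    'alkyl_or_alkenyl' separately.
    """
    names = _specified_species(table, class_code, group)
    groups = LINKAGE_GROUPS if class_code in ETHER_CLASSES else ("acyl",)
    out: dict[str, ChainStat] = {}
    for lg in groups:
        rows = []
        for n in names:
            chains = table.species[n].chains_by_linkage(lg)
            if chains:
                rows.append(
                    (n,
                     np.mean([c.carbons for c in chains]),
                     np.mean([c.double_bonds for c in chains]))
                )
        if not rows:
            out[lg] = ChainStat(class_code, group, lg, 0,
                                np.nan, np.nan, np.nan, np.nan)
            continue
        used = [r[0] for r in rows]
        carb = np.array([r[1] for r in rows])
        dbl = np.array([r[2] for r in rows])
        w = _species_weights(table, used, group, weighting)
        mc, sc = _weighted_mean_se(carb, w)
        md, sd = _weighted_mean_se(dbl, w)
        out[lg] = ChainStat(class_code, group, lg, len(rows), mc, sc, md, sd)
    return out


def _weighted_mean_se(x: np.ndarray, w: np.ndarray) -> tuple[float, float]:
    mean = float(np.sum(w * x))
    n = len(x)
    if n < 2:
        return mean, float("nan")
    # Unbiased weighted variance across species; SE on sqrt(n) like the
    # unweighted SD/sqrt(n) convention.
    var = np.sum(w * (x - mean) ** 2) / (1.0 - np.sum(w**2))
    return mean, float(np.sqrt(var / n))


def category_profile(
    table: ConcentrationTable,
    class_code: str,
    group: str,
    linkage_group: str = "acyl",
    weighting: str = "species",
) -> dict[str, pd.Series]:
    """Proportions of the class's chains over the nine joint categories, plus
    the 3-length and 3-bond marginals (marginals are sums of the joint)."""
    names = _specified_species(table, class_code, group)
    names = [n for n in names if table.species[n].chains_by_linkage(linkage_group)]
    if not names:
        raise ValueError(
            f"no detected chain-specified {class_code} species with "
            f"{linkage_group} chains in {group}"
        )
    w = _species_weights(table, names, group, weighting)
    joint = pd.Series(0.0, index=list(CATEGORY_ORDER))
    for n, wl in zip(names, w):
        chains = table.species[n].chains_by_linkage(linkage_group)
        for c in chains:
            joint[categorize_chain(c).label] += wl / len(chains)
    joint /= joint.sum()
    length = pd.Series(
        {l: joint[[f"{l}{b}" for b in BOND_ORDER]].sum() for l in LENGTH_ORDER}
    )
    bond = pd.Series(
        {b: joint[[f"{l}{b}" for l in LENGTH_ORDER]].sum() for b in BOND_ORDER}
    )
    return {"joint": joint, "length": length, "bond": bond}


def chain_frequencies(
    table: ConcentrationTable,
    class_code: str,
    group: str,
    linkage_group: str = "acyl",
    weighting: str = "species",
) -> pd.Series:
    """Frequency of each chain identity ("C:D") among the class's chains in
    the linkage group; sums to 1."""
    names = _specified_species(table, class_code, group)
    names = [n for n in names if table.species[n].chains_by_linkage(linkage_group)]
    if not names:
        return pd.Series(dtype=float)
    w = _species_weights(table, names, group, weighting)
    freq: dict[str, float] = {}
    for n, wl in zip(names, w):
        chains = table.species[n].chains_by_linkage(linkage_group)
        for c in chains:
            key = f"{c.carbons}:{c.double_bonds}"
            freq[key] = freq.get(key, 0.0) + wl / len(chains)
    s = pd.Series(freq).sort_index()
    return s / s.sum()


def common_chains(
    table: ConcentrationTable,
    threshold_pct: float = 5.0,
    weighting: str = "species",
) -> pd.DataFrame:
    """Chain identities at >= ``threshold_pct`` % of the chains in at least
    one (class, linkage group, group) cell, with the full frequency matrix.

    Returns a DataFrame indexed by chain identity with one column per
    (class, linkage_group, group), frequencies in percent, restricted to the
    common chains.
    """
    cols: dict[tuple[str, str, str], pd.Series] = {}
    classes = sorted({sp.class_code for sp in table.species.values()})
    for cls in classes:
        groups = LINKAGE_GROUPS if cls in ETHER_CLASSES else ("acyl",)
        for lg in groups:
            for grp in table.groups:
                s = chain_frequencies(table, cls, grp, lg, weighting)
                if len(s):
                    cols[(cls, lg, grp)] = s * 100.0
    if not cols:
        raise ValueError("no chain frequencies computable")
    mat = pd.DataFrame(cols).fillna(0.0)
    keep = mat.max(axis=1) >= threshold_pct
    out = mat.loc[keep].copy()
    out.index.name = "chain"
    out.columns = pd.MultiIndex.from_tuples(
        out.columns, names=["class", "linkage_group", "group"]
    )
    order = sorted(out.index, key=lambda c: tuple(map(int, c.split(":"))))
    return out.loc[order]


def dichotomy_overlap(
    table: ConcentrationTable,
    class_code: str,
    group: str,
    weighting: str = "species",
) -> float:
    """Overlap coefficient sum_chain min(freq_acyl, freq_alkyl/alkenyl)
    between the two chain complements of an ether class: 0 = complete
    dichotomy, 1 = identical complements."""
    if class_code not in ETHER_CLASSES:
        raise ValueError(f"{class_code} is not an ether class")
    acyl = chain_frequencies(table, class_code, group, "acyl", weighting)
    alk = chain_frequencies(table, class_code, group, "alkyl_or_alkenyl", weighting)
    if not len(acyl) or not len(alk):
        raise ValueError(
            f"no chain-specified {class_code} species detected in {group}"
        )
    both = acyl.index.union(alk.index)
    return float(
        np.minimum(
            acyl.reindex(both, fill_value=0.0), alk.reindex(both, fill_value=0.0)
        ).sum()
    )
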