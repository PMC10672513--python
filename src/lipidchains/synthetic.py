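"""Synthetic replicate-level lipidome tables with known chain-usage structure.

The generator emulates the design of a two-age, 16-replicate-per-age shotgun
lipidomics study of adult male Queensland fruit flies: ~15 lipid classes,
~400 species, concentrations on a ng/uL scale, and a chain pool dominated by
the six major medium acyl chains 16:0, 16:1, 18:0, 18:1, 18:2 and 18:3 with
a tail of rarer short, long and odd-carbon chains.

Chain-combination structure is controlled per class by an association
parameter theta in [-1, 1].  Each k-chain ester class has a chain-identity
pool p; the law of a species' unordered chain multiset is the mixture

    theta = 0:  Q = M(p)                    (i.i.d. chains, multinomial law)
    theta > 0:  Q = (1-theta) M(p) + theta H(p)      (excess of homogeneous
                multisets; H draws one chain type and repeats it k times)
    theta < 0:  Q = (1-|theta|) M(p) + |theta| M(p | not homogeneous)

Crucially, theta also governs *abundance*: the class's concentration mass is
distributed over multisets proportional to Q ("mass-action" abundances), so
that at theta = 0 the abundance-weighted combination frequencies satisfy the
random-association null exactly, not merely on average over species draws.
Replicate-to-replicate variation is multiplicative lognormal noise applied
independently per species and sample — the biological/technical variation
between individual flies.  The species list realises every multiset over the
class's dominant "core" chains plus a sample of rare-chain multisets, giving
class diversities matching the emulated study design.

Everything is deterministic given the seed, and a ground-truth record of each
species' chain draws and theta is returned alongside the table.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from itertools import combinations_with_replacement
from math import factorial
from typing import Mapping

import numpy as np
import pandas as pd

from .lipidome import ConcentrationTable, SampleInfo
from .nomenclature import (
    CLASS_CHAIN_COUNT,
    ESTER_MULTI_CHAIN_CLASSES,
    ETHER_CLASSES,
    ChainSpec,
    LipidSpecies,
    categorize_chain,
    parse_lipid_name,
)

__all__ = ["ClassPlan", "SyntheticConfig", "default_config", "generate"]


def _chain(term: str, linkage: str = "acyl") -> ChainSpec:
    c, d = term.split(":")
    return ChainSpec(int(c), int(d), linkage)


@dataclass
class ClassPlan:
    """Generation plan for one lipid class.

    For multi-chain ester classes the species list is the closure of all
    multisets over ``core_pool`` plus ``n_rare`` distinct multisets containing
    at least one ``rare_pool`` chain.  ``theta`` tilts both the multiset law
    and the abundance mass (see module docstring).  Ether classes draw
    ``n_species`` species with k-1 acyl chains from ``core_pool``/``rare_pool``
    and one ether-linked chain from ``ether_pool``; a ``unresolved_fraction``
    of them are reported as sum compositions only.  ``fixed_species`` lists
    explicit shorthand names generated verbatim (e.g. a single known PCe).
    """

    abundance_pct: float
    core_pool: dict[str, float] = field(default_factory=dict)
    rare_pool: dict[str, float] = field(default_factory=dict)
    n_rare: int = 0
    theta: float = 0.0
    ether_pool: dict[str, float] = field(default_factory=dict)
    n_species: int = 0
    unresolved_fraction: float = 0.0
    fixed_species: list[str] = field(default_factory=list)
    abundance_sigma: float = 1.0  # lognormal spread of ether/LPC species sizes

    def __post_init__(self) -> None:
        if not -1.0 <= self.theta <= 1.0:
            raise ValueError(f"theta must lie in [-1, 1], got {self.theta}")
        if self.abundance_pct < 0:
            raise ValueError("abundance_pct must be non-negative")


@dataclass
class SyntheticConfig:
    """Full parameterisation of a simulated lipidome experiment."""

    seed: int = 0
    groups: dict[str, int] = field(
        default_factory=lambda: {"Day1": 16, "Day19": 16}
    )
    replicate_sigma: float = 0.35  # lognormal sdlog of per-replicate noise
    total_concentration: float = 500.0  # ng/uL, median per-sample total
    class_plans: dict[str, ClassPlan] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return asdict(self)


# Shared tail of rarer chains (short, long, odd-carbon), small total mass.
_RARE_TAIL = {
    "10:2": 1.0, "12:0": 1.0, "14:0": 2.0, "14:1": 1.5, "15:0": 0.7,
    "17:0": 0.7, "20:0": 1.0, "20:1": 1.0, "20:4": 2.0, "22:6": 2.0,
    "24:2": 1.0,
}


def _rare(mass: float, extra: Mapping[str, float] | None = None) -> dict[str, float]:
    pool = dict(_RARE_TAIL)
    if extra:
        pool.update(extra)
    total = sum(pool.values())
    return {k: v * mass / total for k, v in pool.items()}


def default_config(seed: int = 0) -> SyntheticConfig:
    """Default plan mirroring the emulated study's class diversities and
    abundances (e.g. ~200 TGs at ~36%, 36 CLs, a single PCe) with random
    chain association (theta = 0) everywhere."""
    plans = {
        # Ester classes: the species list is the full multiset closure of the
        # pool, so pool sizes are chosen to make the closure match the
        # emulated class diversities (e.g. 10 TG chain types -> 220 TGs).
        "TG": ClassPlan(
            abundance_pct=36.1,
            core_pool={"16:0": .26, "16:1": .16, "18:0": .05,
                       "18:1": .25, "18:2": .14, "18:3": .07,
                       "14:0": .02, "14:1": .015, "20:1": .02, "22:6": .015},
        ),
        "DG": ClassPlan(
            abundance_pct=0.4,
            core_pool={"16:0": .30, "16:1": .20, "18:1": .30, "18:2": .20},
        ),
        "CL": ClassPlan(
            abundance_pct=4.1,
            core_pool={"16:1": .20, "18:1": .25, "18:2": .35, "18:3": .20},
        ),
        "PC": ClassPlan(
            abundance_pct=9.0,
            core_pool={"16:0": .32, "16:1": .13, "18:0": .06,
                       "18:1": .22, "18:2": .20, "18:3": .07},
        ),
        "PE": ClassPlan(
            abundance_pct=29.1,
            core_pool={"16:0": .22, "16:1": .10, "18:0": .08,
                       "18:1": .25, "18:2": .22, "18:3": .13},
        ),
        "PG": ClassPlan(
            abundance_pct=3.5,
            core_pool={"16:0": .40, "18:1": .40, "10:2": .10, "24:2": .10},
        ),
        "PI": ClassPlan(
            abundance_pct=7.2,
            core_pool={"16:0": .32, "18:1": .27, "18:2": .27, "18:3": .14},
        ),
        "PS": ClassPlan(
            abundance_pct=3.4,
            core_pool={"18:0": .28, "18:1": .34, "18:2": .26, "20:4": .12},
        ),
        "LPC": ClassPlan(
            abundance_pct=1.3,
            core_pool={"16:0": .30, "16:1": .12, "18:0": .08,
                       "18:1": .25, "18:2": .17, "18:3": .08},
            rare_pool=_rare(0.10),
            n_species=14,
        ),
        "DGe": ClassPlan(
            abundance_pct=1.3,
            core_pool={"16:0": .35, "16:1": .25, "18:1": .40},
            ether_pool={"14:0": .3, "16:0": .4, "18:0": .3},
            n_species=6,
            unresolved_fraction=1.0,
        ),
        "TGe": ClassPlan(
            abundance_pct=0.3,
            core_pool={"16:1": .25, "18:1": .45, "18:2": .30},
            ether_pool={"16:0": .2, "18:0": .3, "20:0": .4, "22:0": .1},
            n_species=9,
            unresolved_fraction=0.23,
        ),
        "PCe": ClassPlan(
            abundance_pct=0.01,
            fixed_species=["PCe(20:0e_14:1)"],
        ),
        "PEe": ClassPlan(
            abundance_pct=1.7,
            core_pool={"18:2": .20, "20:4": .30, "22:6": .30, "24:2": .20},
            ether_pool={"12:0": .30, "14:0": .30, "16:0": .30, "18:0": .10},
            n_species=13,
            unresolved_fraction=0.38,
        ),
        "PEp": ClassPlan(
            abundance_pct=2.4,
            core_pool={"18:1": .25, "22:6": .30, "24:0": .20, "24:2": .25},
            ether_pool={"10:0": .40, "12:0": .40, "14:0": .20},
            n_species=7,
        ),
        "PSe": ClassPlan(
            abundance_pct=0.1,
            fixed_species=["PSe(38:5e)"],
        ),
    }
    return SyntheticConfig(seed=seed, class_plans=plans)


# -- multiset machinery --------------------------------------------------------


def _multiset_law(
    pool: Mapping[str, float], k: int, theta: float
) -> dict[tuple[str, ...], float]:
    """Theta-tilted law over unordered chain-identity multisets."""
    chains = sorted(pool)
    p = np.array([pool[c] for c in chains], dtype=float)
    p = p / p.sum()
    base: dict[tuple[str, ...], float] = {}
    for combo in combinations_with_replacement(range(len(chains)), k):
        counts: dict[int, int] = {}
        for i in combo:
            counts[i] = counts.get(i, 0) + 1
        coef = factorial(k)
        prob = 1.0
        for i, n in counts.items():
            coef //= factorial(n)
            prob *= p[i] ** n
        base[tuple(chains[i] for i in combo)] = coef * prob
    if theta == 0:
        return base
    homog_mass = sum(v for m, v in base.items() if len(set(m)) == 1)
    if theta > 0:
        homog = {tuple([c] * k): w for c, w in zip(chains, p)}
        return {
            m: (1 - theta) * v + theta * homog.get(m, 0.0)
            for m, v in base.items()
        }
    if homog_mass >= 1.0:
        raise ValueError(
            "theta < 0 is infeasible: every multiset of this pool is "
            "homogeneous (single-chain-type pool)"
        )
    t = -theta
    return {
        m: (1 - t) * v + (t * v / (1 - homog_mass) if len(set(m)) > 1 else 0.0)
        for m, v in base.items()
    }


def _ester_class_species(
    plan: ClassPlan, class_code: str, rng: np.random.Generator
) -> tuple[list[LipidSpecies], np.ndarray, list[tuple[str, ...]]]:
    """Species, mass-action abundance shares and chain multisets for a
    multi-chain ester class."""
    k = CLASS_CHAIN_COUNT[class_code]
    pool = {**plan.core_pool, **plan.rare_pool}
    law = _multiset_law(pool, k, plan.theta)
    core = set(plan.core_pool)
    core_multisets = [m for m in law if set(m) <= core]
    rare_multisets = [m for m in law if not set(m) <= core]
    chosen = list(core_multisets)
    if plan.n_rare:
        weights = np.array([law[m] for m in rare_multisets])
        if plan.n_rare > len(rare_multisets):
            raise ValueError(
                f"{class_code}: n_rare={plan.n_rare} exceeds the "
                f"{len(rare_multisets)} available rare multisets"
            )
        idx = rng.choice(
            len(rare_multisets),
            size=plan.n_rare,
            replace=False,
            p=weights / weights.sum(),
        )
        chosen += [rare_multisets[i] for i in sorted(idx)]
    shares = np.array([law[m] for m in chosen], dtype=float)
    if shares.sum() <= 0:
        raise ValueError(f"{class_code}: realized multisets carry no mass")
    shares /= shares.sum()
    species = [
        LipidSpecies(
            class_code,
            tuple(_chain(c) for c in m),
            sum(_chain(c).carbons for c in m),
            sum(_chain(c).double_bonds for c in m),
        )
        for m in chosen
    ]
    return species, shares, chosen


def _single_chain_species(
    plan: ClassPlan, class_code: str, rng: np.random.Generator
) -> tuple[list[LipidSpecies], np.ndarray, list[tuple[str, ...]]]:
    pool = {**plan.core_pool, **plan.rare_pool}
    chains = sorted(pool)
    p = np.array([pool[c] for c in chains], dtype=float)
    p /= p.sum()
    n = min(plan.n_species, len(chains))
    idx = rng.choice(len(chains), size=n, replace=False, p=p)
    chosen = [(chains[i],) for i in sorted(idx)]
    shares = np.array([pool[m[0]] for m in chosen])
    shares /= shares.sum()
    species = [
        LipidSpecies(class_code, (_chain(m[0]),),
                     _chain(m[0]).carbons, _chain(m[0]).double_bonds)
        for m in chosen
    ]
    return species, shares, chosen


def _ether_class_species(
    plan: ClassPlan, class_code: str, rng: np.random.Generator
) -> tuple[list[LipidSpecies], np.ndarray, list[tuple[str, ...]]]:
    """Ether-class species: one ether-linked chain from the ether pool plus
    k-1 acyl chains; a fraction reported as sum composition only."""
    k = CLASS_CHAIN_COUNT[class_code]
    linkage = ETHER_CLASSES[class_code]
    acyl_pool = {**plan.core_pool, **plan.rare_pool}
    acyl_chains = sorted(acyl_pool)
    pa = np.array([acyl_pool[c] for c in acyl_chains], float)
    pa /= pa.sum()
    eth_chains = sorted(plan.ether_pool)
    pe = np.array([plan.ether_pool[c] for c in eth_chains], float)
    pe /= pe.sum()

    species: list[LipidSpecies] = []
    multisets: list[tuple[str, ...]] = []
    seen: set[str] = set()
    n_unresolved = int(round(plan.unresolved_fraction * plan.n_species))
    attempts = 0
    while len(species) < plan.n_species:
        attempts += 1
        if attempts > 200 * max(plan.n_species, 1):
            raise ValueError(f"{class_code}: cannot realise distinct species")
        eth = _chain(eth_chains[rng.choice(len(eth_chains), p=pe)], linkage)
        acyl = [
            _chain(acyl_chains[rng.choice(len(acyl_chains), p=pa)])
            for _ in range(k - 1)
        ]
        chains = (eth, *acyl)
        unresolved = len(species) < n_unresolved
        sc = sum(c.carbons for c in chains)
        sd = sum(c.double_bonds for c in chains)
        sp = LipidSpecies(class_code, () if unresolved else chains, sc, sd)
        if sp.canonical_name in seen:
            continue
        seen.add(sp.canonical_name)
        species.append(sp)
        multisets.append(tuple(str(c) for c in chains))
    shares = rng.lognormal(mean=0.0, sigma=plan.abundance_sigma,
                           size=len(species))
    shares /= shares.sum()
    return species, shares, multisets


def generate(
    config: SyntheticConfig,
) -> tuple[ConcentrationTable, pd.DataFrame]:
    """Generate a replicate-level concentration table plus ground truth.

    Returns the :class:`ConcentrationTable` and a DataFrame with one row per
    species recording class, theta, the drawn chain identities (underscore
    joined, ether chain first) and their joint category labels — sufficient
    to recompute every species' category multiset without the parser.
    """
    rng = np.random.default_rng(config.seed)
    all_species: list[LipidSpecies] = []
    base_shares: list[float] = []
    truth_rows: list[dict] = []

    plan_items = sorted(config.class_plans.items())
    total_pct = sum(p.abundance_pct for _, p in plan_items)
    if total_pct <= 0:
        raise ValueError("class plan abundances sum to zero")

    for class_code, plan in plan_items:
        if class_code not in CLASS_CHAIN_COUNT:
            raise ValueError(f"unknown class {class_code!r} in plan")
        if plan.fixed_species:
            species = [parse_lipid_name(n) for n in plan.fixed_species]
            shares = np.full(len(species), 1.0 / len(species))
            multisets = [
                tuple(str(c) for c in sp.chains) if sp.chain_specified else ()
                for sp in species
            ]
        elif class_code in ETHER_CLASSES:
            species, shares, multisets = _ether_class_species(plan, class_code, rng)
        elif CLASS_CHAIN_COUNT[class_code] == 1:
            species, shares, multisets = _single_chain_species(plan, class_code, rng)
        else:
            species, shares, multisets = _ester_class_species(plan, class_code, rng)
        class_share = plan.abundance_pct / total_pct
        for sp, share, m in zip(species, shares, multisets):
            all_species.append(sp)
            base_shares.append(share * class_share)
            truth_rows.append(
                {
                    "species": sp.canonical_name,
                    "class": class_code,
                    "theta": plan.theta,
                    "chains": "_".join(m),
                    "categories": "_".join(
                        categorize_chain(_chain(t.rstrip("ep"))).label for t in m
                    ),
                    "chain_specified": sp.chain_specified,
                    "base_share": share * class_share,
                }
            )

    names = [sp.canonical_name for sp in all_species]
    if len(set(names)) != len(names):
        dup = pd.Series(names).value_counts()
        raise ValueError(f"duplicate species generated: {dup[dup > 1].index[:3]}")

    samples: list[SampleInfo] = []
    for group, n_rep in config.groups.items():
        for i in range(1, n_rep + 1):
            samples.append(SampleInfo(f"{group}_r{i:02d}", group, i))

    base = np.array(base_shares) * config.total_concentration
    sigma = config.replicate_sigma
    noise = rng.lognormal(
        mean=-0.5 * sigma**2, sigma=sigma, size=(len(samples), len(names))
    )
    values = pd.DataFrame(
        base[None, :] * noise,
        index=[s.sample_id for s in samples],
        columns=names,
    )
    table = ConcentrationTable(
        values, samples, {sp.canonical_name: sp for sp in all_species}
    )
    truth = pd.DataFrame(truth_rows)
    return table, truth
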