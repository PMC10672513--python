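"""Shorthand lipid nomenclature: parsing, validation and chain categorisation.

Lipid species exported by annotation software such as LipidSearch are named in
the common ``CLASS(C:D_C:D_...)`` shorthand, where each ``C:D`` term gives the
carbon and double-bond count of one hydrocarbon chain.  A species whose
individual chains could not be resolved carries a single *sum composition*
term (total carbons and double bonds across all chains), e.g. ``TGe(32:1e)``.
Ether lipids carry one ether-linked chain: an ``e`` suffix marks a plasmanyl
(alkyl, ether-bonded) chain and a ``p`` suffix a plasmenyl (alkenyl,
vinyl-ether-bonded) chain.

Chains are additionally binned into a 3x3 grid of length x saturation
categories: short/medium/long (S/M/L for <C16, C16-C18, >C18) crossed with
saturated/monounsaturated/polyunsaturated (0/1/X for zero, one, more than one
double bond).  These nine joint categories (e.g. ``M1``) are the alphabet of
the chain-combination analysis in :mod:`lipidchains.combination_test`.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable

__all__ = [
    "ChainSpec",
    "ChainCategory",
    "LipidSpecies",
    "LipidNameError",
    "CLASS_CHAIN_COUNT",
    "ETHER_CLASSES",
    "ESTER_MULTI_CHAIN_CLASSES",
    "LENGTH_ORDER",
    "BOND_ORDER",
    "CATEGORY_ORDER",
    "parse_lipid_name",
    "canonicalize",
    "categorize_chain",
]

#: Number of hydrocarbon chains per class.
CLASS_CHAIN_COUNT: dict[str, int] = {
    "DG": 2, "TG": 3, "CL": 4,
    "PC": 2, "PE": 2, "PG": 2, "PI": 2, "PS": 2, "LPC": 1,
    "DGe": 2, "TGe": 3, "PCe": 2, "PEe": 2, "PEp": 2, "PSe": 2,
}

#: Classes carrying one ether-linked chain; the value is that chain's linkage.
ETHER_CLASSES: dict[str, str] = {
    "DGe": "alkyl", "TGe": "alkyl", "PCe": "alkyl",
    "PEe": "alkyl", "PEp": "alkenyl", "PSe": "alkyl",
}

#: Ester classes with more than one chain (the combination test's domain).
ESTER_MULTI_CHAIN_CLASSES: tuple[str, ...] = (
    "DG", "TG", "CL", "PC", "PE", "PG", "PI", "PS",
)

LENGTH_ORDER = ("S", "M", "L")
BOND_ORDER = ("0", "1", "X")
#: The nine joint categories in canonical order (length-major).
CATEGORY_ORDER = tuple(f"{l}{b}" for l in LENGTH_ORDER for b in BOND_ORDER)

_LINKAGE_SUFFIX = {"acyl": "", "alkyl": "e", "alkenyl": "p"}


class LipidNameError(ValueError):
    """Raised for malformed or chemically invalid shorthand names."""


@dataclass(frozen=True, order=True)
class ChainSpec:
    """One hydrocarbon chain: carbon count, double bonds and linkage."""

    carbons: int
    double_bonds: int
    linkage: str = "acyl"  # acyl | alkyl | alkenyl

    def __post_init__(self) -> None:
        if self.linkage not in _LINKAGE_SUFFIX:
            raise LipidNameError(f"unknown linkage {self.linkage!r}")
        if self.carbons < 1:
            raise LipidNameError(f"chain needs >=1 carbon, got {self.carbons}")
        if self.double_bonds < 0:
            raise LipidNameError("negative double-bond count")
        if self.double_bonds >= self.carbons:
            raise LipidNameError(
                f"{self.carbons}:{self.double_bonds} has at least as many "
                "double bonds as carbons"
            )

    def __str__(self) -> str:
        return f"{self.carbons}:{self.double_bonds}{_LINKAGE_SUFFIX[self.linkage]}"


@dataclass(frozen=True)
class ChainCategory:
    """Joint length x saturation category of a chain (one of nine)."""

    length_class: str  # S | M | L
    bond_class: str    # 0 | 1 | X

    @property
    def label(self) -> str:
        return self.length_class + self.bond_class


def categorize_chain(chain: ChainSpec) -> ChainCategory:
    """Assign the S/M/L x 0/1/X category of a chain.

    Length: S below C16, M for C16-C18 inclusive, L above C18.
    Saturation: 0, 1 or X for zero, one, or more than one double bond.
    """
    if chain.carbons < 16:
        length = "S"
    elif chain.carbons <= 18:
        length = "M"
    else:
        length = "L"
    if chain.double_bonds == 0:
        bond = "0"
    elif chain.double_bonds == 1:
        bond = "1"
    else:
        bond = "X"
    return ChainCategory(length, bond)


@dataclass(frozen=True)
class LipidSpecies:
    """A parsed lipid species.

    ``chains`` is empty when the species is only resolved to a sum
    composition; ``sum_carbons``/``sum_double_bonds`` are always populated and
    equal the chain totals whenever the species is chain-specified.
    """

    class_code: str
    chains: tuple[ChainSpec, ...]
    sum_carbons: int
    sum_double_bonds: int
    canonical_name: str = field(compare=False, default="")

    def __post_init__(self) -> None:
        _validate_species(self)
        if not self.canonical_name:
            object.__setattr__(self, "canonical_name", _serialize(self))

    @property
    def chain_specified(self) -> bool:
        return len(self.chains) > 0

    @property
    def ether(self) -> bool:
        return self.class_code in ETHER_CLASSES

    @property
    def n_chains(self) -> int:
        return CLASS_CHAIN_COUNT[self.class_code]

    def chains_by_linkage(self, linkage_group: str) -> tuple[ChainSpec, ...]:
        """Chains in ``linkage_group`` ('acyl' or 'alkyl_or_alkenyl')."""
        if linkage_group == "acyl":
            return tuple(c for c in self.chains if c.linkage == "acyl")
        if linkage_group == "alkyl_or_alkenyl":
            return tuple(c for c in self.chains if c.linkage != "acyl")
        raise ValueError(f"unknown linkage group {linkage_group!r}")

    def category_labels(self) -> tuple[str, ...]:
        """Joint category label of every chain (chain-specified species only)."""
        if not self.chain_specified:
            raise ValueError(f"{self.canonical_name} is not chain-specified")
        return tuple(categorize_chain(c).label for c in self.chains)


def _validate_species(sp: LipidSpecies) -> None:
    k = CLASS_CHAIN_COUNT.get(sp.class_code)
    if k is None:
        raise LipidNameError(f"unknown lipid class {sp.class_code!r}")
    if sp.chains:
        if len(sp.chains) != k:
            raise LipidNameError(
                f"{sp.class_code} requires {k} chains, got {len(sp.chains)}"
            )
        ether_linkage = ETHER_CLASSES.get(sp.class_code)
        non_acyl = [c for c in sp.chains if c.linkage != "acyl"]
        if ether_linkage is None:
            if non_acyl:
                raise LipidNameError(
                    f"ester class {sp.class_code} cannot carry ether chains"
                )
        else:
            if len(non_acyl) != 1 or non_acyl[0].linkage != ether_linkage:
                raise LipidNameError(
                    f"{sp.class_code} requires exactly one {ether_linkage} chain"
                )
        if sp.sum_carbons != sum(c.carbons for c in sp.chains):
            raise LipidNameError("sum_carbons inconsistent with chains")
        if sp.sum_double_bonds != sum(c.double_bonds for c in sp.chains):
            raise LipidNameError("sum_double_bonds inconsistent with chains")
    if sp.sum_carbons < k:
        raise LipidNameError(
            f"sum composition {sp.sum_carbons} carbons is impossible for "
            f"{k}-chain class {sp.class_code}"
        )
    if sp.sum_double_bonds < 0 or sp.sum_double_bonds >= sp.sum_carbons:
        raise LipidNameError("invalid sum double-bond count")


_NAME_RE = re.compile(
    r"^\s*(?P<cls>[A-Za-z]+)\s*(?:\(\s*(?P<paren>[^()]+?)\s*\)|\s?(?P<bare>[0-9][^()\s]*))\s*$"
)
_CHAIN_RE = re.compile(r"^(?P<c>\d+):(?P<d>\d+)(?P<suffix>[ep])?$")


def parse_lipid_name(name: str) -> LipidSpecies:
    """Parse a shorthand species name into a validated :class:`LipidSpecies`.

    Both the parenthesised dialect ``PC(16:0_18:1)`` and the bare dialect
    ``PC 16:0_18:1`` are accepted, with ``_`` or ``/`` chain separators.  A
    single composition term on a multi-chain class is read as an unresolved
    sum composition.  On ether classes, a chain-level ``e``/``p`` suffix marks
    that chain as alkyl/alkenyl; when no chain carries a suffix the class
    designator is assigned to the first listed chain (``p`` classes meaning
    alkenyl, ``e`` classes alkyl).
    """
    m = _NAME_RE.match(name)
    if not m:
        raise LipidNameError(f"cannot parse lipid name {name!r}")
    class_code = m.group("cls")
    comp = m.group("paren") or m.group("bare")
    if class_code not in CLASS_CHAIN_COUNT:
        raise LipidNameError(f"unknown lipid class {class_code!r} in {name!r}")
    k = CLASS_CHAIN_COUNT[class_code]
    ether_linkage = ETHER_CLASSES.get(class_code)

    terms = re.split(r"[/_]", comp)
    parsed = []
    for term in terms:
        tm = _CHAIN_RE.match(term.strip())
        if not tm:
            raise LipidNameError(f"malformed chain term {term!r} in {name!r}")
        parsed.append(
            (int(tm.group("c")), int(tm.group("d")), tm.group("suffix"))
        )

    if len(terms) == 1 and k > 1:
        # Sum composition (unresolved species).
        c, d, suffix = parsed[0]
        if suffix and ether_linkage is None:
            raise LipidNameError(
                f"ether suffix {suffix!r} on ester class in {name!r}"
            )
        return LipidSpecies(class_code, (), c, d)

    if len(parsed) != k:
        raise LipidNameError(
            f"{class_code} requires {k} chains, got {len(parsed)} in {name!r}"
        )

    suffixes = [s for _, _, s in parsed if s]
    if ether_linkage is None:
        if suffixes:
            raise LipidNameError(
                f"ether chain suffix on ester class in {name!r}"
            )
        chains = tuple(ChainSpec(c, d) for c, d, _ in parsed)
    else:
        if len(suffixes) > 1:
            raise LipidNameError(f"multiple ether chains in {name!r}")
        chains_list: list[ChainSpec] = []
        # With no chain-level suffix, the class designator applies to the
        # first listed chain; a chain-level "p" overrides a class-level "e".
        for i, (c, d, suffix) in enumerate(parsed):
            if suffix == "p":
                linkage = "alkenyl"
            elif suffix == "e":
                linkage = "alkyl"
            elif not suffixes and i == 0:
                linkage = ether_linkage
            else:
                linkage = "acyl"
            chains_list.append(ChainSpec(c, d, linkage))
        chains = tuple(chains_list)

    return LipidSpecies(
        class_code,
        chains,
        sum(c.carbons for c in chains),
        sum(c.double_bonds for c in chains),
    )


def _serialize(sp: LipidSpecies) -> str:
    if not sp.chain_specified:
        suffix = "p" if ETHER_CLASSES.get(sp.class_code) == "alkenyl" else (
            "e" if sp.ether else ""
        )
        return f"{sp.class_code}({sp.sum_carbons}:{sp.sum_double_bonds}{suffix})"
    ether = [c for c in sp.chains if c.linkage != "acyl"]
    acyl = sorted(
        (c for c in sp.chains if c.linkage == "acyl"),
        key=lambda c: (c.carbons, c.double_bonds),
    )
    parts = [str(c) for c in ether + acyl]
    return f"{sp.class_code}({'_'.join(parts)})"


def canonicalize(species: LipidSpecies) -> str:
    """Deterministic canonical name: ether chain first, acyl chains sorted by
    (carbons, double bonds), ``CLASS(..._...)`` dialect.  Round-trips through
    :func:`parse_lipid_name` up to chain order."""
    return _serialize(species)


def parse_corpus(lines: Iterable[str]) -> list[LipidSpecies]:
    """Parse a plain-text corpus, one species name per line; '#' comments and
    blank lines are ignored."""
    out = []
    for line in lines:
        line = line.strip()
        if line and not line.startswith("#"):
            out.append(parse_lipid_name(line))
    return out
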