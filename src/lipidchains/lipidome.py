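"""Replicate-level concentration tables and class-level summaries.

The central container is :class:`ConcentrationTable`: a samples x species
matrix of concentrations (ng/uL) plus sample metadata (group label such as
"Day1"/"Day19", replicate index) and the parsed :class:`~lipidchains.nomenclature.LipidSpecies`
for every column.  On top of it sit the class-level accounting operations:
per-sample relative abundances, diversity (species detected) and mean %
abundance +/- SE per class and group, detection overlap between groups, the
PE/PC abundance ratio, and the across-class diversity-abundance correlation.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .nomenclature import LipidSpecies, parse_lipid_name

__all__ = [
    "SampleInfo",
    "ConcentrationTable",
    "ClassSummary",
    "OverlapCounts",
    "CLASS_CATEGORY",
    "read_table",
    "relative_abundance",
    "class_summary",
    "aggregate_categories",
    "detection_overlap",
    "pe_pc_ratio",
    "diversity_abundance_correlation",
]

#: Lipid category of each class (bold rows of class-summary reports).
CLASS_CATEGORY: dict[str, str] = {
    "DG": "Neutral lipids", "TG": "Neutral lipids",
    "CL": "Phospholipids", "PC": "Phospholipids", "PE": "Phospholipids",
    "PG": "Phospholipids", "PI": "Phospholipids", "PS": "Phospholipids",
    "LPC": "Phospholipids",
    "DGe": "Ether neutral lipids", "TGe": "Ether neutral lipids",
    "PCe": "Ether phospholipids", "PEe": "Ether phospholipids",
    "PEp": "Ether phospholipids", "PSe": "Ether phospholipids",
}


@dataclass(frozen=True)
class SampleInfo:
    sample_id: str
    group: str
    replicate_index: int


class ConcentrationTable:
    """Samples x species concentration matrix with metadata.

    Parameters
    ----------
    values
        DataFrame indexed by sample_id with one column per canonical species
        name; non-negative concentrations, 0 meaning not detected.
    samples
        One :class:`SampleInfo` per row of ``values`` (same order).
    species
        Mapping canonical name -> parsed species for every column.
    """

    def __init__(
        self,
        values: pd.DataFrame,
        samples: Sequence[SampleInfo],
        species: Mapping[str, LipidSpecies],
    ) -> None:
        if len(samples) != len(values):
            raise ValueError("sample metadata does not match value rows")
        ids = [s.sample_id for s in samples]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate sample ids")
        if list(values.index) != ids:
            raise ValueError("values index must equal sample ids, in order")
        missing = [c for c in values.columns if c not in species]
        if missing:
            raise ValueError(f"species metadata missing for {missing[:5]}")
        arr = values.to_numpy(dtype=float)
        if not np.isfinite(arr).all() or (arr < 0).any():
            raise ValueError("concentrations must be finite and non-negative")
        self.values = values
        self.samples = list(samples)
        self.species = dict(species)

    # -- convenience accessors -------------------------------------------------

    @property
    def groups(self) -> list[str]:
        seen: dict[str, None] = {}
        for s in self.samples:
            seen.setdefault(s.group, None)
        return list(seen)

    def group_sample_ids(self, group: str) -> list[str]:
        ids = [s.sample_id for s in self.samples if s.group == group]
        if not ids:
            raise ValueError(f"unknown group {group!r}")
        return ids

    def class_of(self, name: str) -> str:
        return self.species[name].class_code

    def species_of_class(self, class_code: str) -> list[str]:
        return [n for n, sp in self.species.items() if sp.class_code == class_code]

    def detected_in_group(self, group: str, min_replicates: int = 1) -> list[str]:
        """Species with concentration > 0 in at least ``min_replicates`` of the
        group's replicates."""
        sub = self.values.loc[self.group_sample_ids(group)]
        n_pos = (sub.to_numpy() > 0).sum(axis=0)
        return [c for c, n in zip(sub.columns, n_pos) if n >= min_replicates]


def read_table(path: str, layout: str = "long") -> ConcentrationTable:
    """Read a concentration CSV in ``long`` layout (columns sample_id, group,
    lipid_name, concentration) or ``wide`` layout (sample_id, group, one
    column per species).  Every name is parsed and validated; duplicate
    (sample, species) cells and negative concentrations are rejected."""
    df = pd.read_csv(path)
    if layout == "long":
        required = {"sample_id", "group", "lipid_name", "concentration"}
        if not required.issubset(df.columns):
            raise ValueError(f"long layout requires columns {sorted(required)}")
        return _from_long(df)
    if layout == "wide":
        if not {"sample_id", "group"}.issubset(df.columns):
            raise ValueError("wide layout requires sample_id and group columns")
        return _from_wide(df)
    raise ValueError(f"unknown layout {layout!r}")


def _parse_names(names: Sequence[str]) -> dict[str, LipidSpecies]:
    species: dict[str, LipidSpecies] = {}
    canonical: dict[str, str] = {}
    for name in names:
        sp = parse_lipid_name(name)
        if sp.canonical_name in species and canonical.get(name) != sp.canonical_name:
            # Two distinct input names mapping to the same species.
            prior = [k for k, v in canonical.items() if v == sp.canonical_name]
            raise ValueError(
                f"names {prior[0]!r} and {name!r} are the same species "
                f"{sp.canonical_name}"
            )
        species[sp.canonical_name] = sp
        canonical[name] = sp.canonical_name
    return species


def _from_long(df: pd.DataFrame) -> ConcentrationTable:
    bad = df[~np.isfinite(df["concentration"]) | (df["concentration"] < 0)]
    if len(bad):
        raise ValueError(
            f"negative or non-finite concentration at rows {list(bad.index[:5])}"
        )
    species = _parse_names(pd.unique(df["lipid_name"]))
    name_map = {n: parse_lipid_name(n).canonical_name for n in pd.unique(df["lipid_name"])}
    df = df.assign(_canon=df["lipid_name"].map(name_map))
    dup = df.duplicated(subset=["sample_id", "_canon"])
    if dup.any():
        raise ValueError(
            f"duplicate (sample, species) cells at rows {list(df.index[dup][:5])}"
        )
    groups = df.drop_duplicates("sample_id")[["sample_id", "group"]]
    if df.groupby("sample_id")["group"].nunique().gt(1).any():
        raise ValueError("a sample is assigned to more than one group")
    wide = (
        df.pivot(index="sample_id", columns="_canon", values="concentration")
        .fillna(0.0)
        .rename_axis(index=None, columns=None)
    )
    wide = wide.loc[groups["sample_id"]]
    samples = _make_samples(groups)
    return ConcentrationTable(wide, samples, species)


def _from_wide(df: pd.DataFrame) -> ConcentrationTable:
    lipid_cols = [c for c in df.columns if c not in ("sample_id", "group")]
    species = _parse_names(lipid_cols)
    name_map = {n: parse_lipid_name(n).canonical_name for n in lipid_cols}
    values = (
        df.set_index("sample_id")[lipid_cols]
        .rename(columns=name_map)
        .rename_axis(index=None)
    )
    if values.columns.duplicated().any():
        raise ValueError("duplicate species columns")
    values = values.fillna(0.0)
    samples = _make_samples(df[["sample_id", "group"]])
    return ConcentrationTable(values, samples, species)


def _make_samples(meta: pd.DataFrame) -> list[SampleInfo]:
    counters: dict[str, int] = {}
    samples = []
    for sid, group in zip(meta["sample_id"], meta["group"]):
        counters[group] = counters.get(group, 0) + 1
        samples.append(SampleInfo(str(sid), str(group), counters[group]))
    return samples


def to_long_csv(table: ConcentrationTable, path: str) -> None:
    """Write the long-layout CSV consumed by :func:`read_table` (zero cells
    are kept explicit)."""
    group_of = {s.sample_id: s.group for s in table.samples}
    long = table.values.stack().rename("concentration").reset_index()
    long.columns = ["sample_id", "lipid_name", "concentration"]
    long.insert(1, "group", long["sample_id"].map(group_of))
    long.to_csv(path, index=False)


# -- summaries -----------------------------------------------------------------


@dataclass(frozen=True)
class ClassSummary:
    """Diversity and % abundance (+/- SE over replicates) of one class in one
    group.  ``abundance_se`` is None when the summary was built from published
    rounded rows rather than replicate data."""

    class_code: str
    group: str
    diversity: int
    abundance_pct: float
    abundance_se: float | None = None

    @property
    def category(self) -> str:
        return CLASS_CATEGORY[self.class_code]


def relative_abundance(table: ConcentrationTable) -> pd.DataFrame:
    """Per-sample relative abundances: each species' concentration as a
    percentage of the sample's total lipid concentration (rows sum to 100)."""
    totals = table.values.sum(axis=1)
    zero = totals[totals <= 0]
    if len(zero):
        raise ValueError(f"sample(s) with zero total concentration: {list(zero.index)}")
    return table.values.div(totals, axis=0) * 100.0


def class_summary(
    table: ConcentrationTable,
    min_replicates: int = 1,
) -> list[ClassSummary]:
    """Per class and group: number of species detected (concentration > 0 in
    at least ``min_replicates`` replicates of the group) and mean per-sample
    summed relative abundance of the class +/- SE (SD/sqrt(n) over the group's
    replicates).  Classes absent from the table are reported with zeros."""
    rel = relative_abundance(table)
    class_of = {n: sp.class_code for n, sp in table.species.items()}
    by_class = rel.T.groupby(rel.columns.map(class_of)).sum().T  # samples x class
    out = []
    all_classes = sorted(CLASS_CATEGORY, key=list(CLASS_CATEGORY).index)
    for group in table.groups:
        ids = table.group_sample_ids(group)
        detected = table.detected_in_group(group, min_replicates)
        div_by_class: dict[str, int] = {}
        for name in detected:
            div_by_class[class_of[name]] = div_by_class.get(class_of[name], 0) + 1
        for cls in all_classes:
            if cls in by_class.columns:
                vals = by_class.loc[ids, cls].to_numpy()
                mean = float(vals.mean())
                se = float(vals.std(ddof=1) / np.sqrt(len(vals))) if len(vals) > 1 else 0.0
            else:
                mean, se = 0.0, 0.0
            out.append(ClassSummary(cls, group, div_by_class.get(cls, 0), mean, se))
    return out


@dataclass(frozen=True)
class CategorySummary:
    category: str
    group: str
    diversity: int
    abundance_pct: float


def aggregate_categories(summaries: Sequence[ClassSummary]) -> list[CategorySummary]:
    """Category-level rows (Neutral lipids, Phospholipids, ...) as sums of the
    member-class diversities and abundances, per group.  SEs are not summable
    from class rows and are omitted."""
    agg: dict[tuple[str, str], list[ClassSummary]] = {}
    for s in summaries:
        agg.setdefault((s.category, s.group), []).append(s)
    return [
        CategorySummary(
            category=cat,
            group=group,
            diversity=sum(r.diversity for r in rows),
            abundance_pct=sum(r.abundance_pct for r in rows),
        )
        for (cat, group), rows in agg.items()
    ]


@dataclass(frozen=True)
class OverlapCounts:
    """Detection overlap between two groups."""

    shared: int
    only_a: int
    only_b: int

    @property
    def union(self) -> int:
        return self.shared + self.only_a + self.only_b


def detection_overlap(
    table: ConcentrationTable,
    group_a: str,
    group_b: str,
    min_replicates: int = 1,
) -> OverlapCounts:
    """Counts of species detected in both groups / only in one, on canonical
    species names under the detection rule."""
    a = set(table.detected_in_group(group_a, min_replicates))
    b = set(table.detected_in_group(group_b, min_replicates))
    return OverlapCounts(len(a & b), len(a - b), len(b - a))


def _group_rows(
    summaries: Sequence[ClassSummary], group: str
) -> dict[str, ClassSummary]:
    rows = {s.class_code: s for s in summaries if s.group == group}
    if not rows:
        raise ValueError(f"no summaries for group {group!r}")
    return rows


def pe_pc_ratio(summaries: Sequence[ClassSummary], group: str) -> float:
    """Ratio of PE to PC % abundance for one group (a standard membrane
    lipid-packing index)."""
    rows = _group_rows(summaries, group)
    if "PE" not in rows or "PC" not in rows:
        raise ValueError("PE and PC summaries required")
    pc = rows["PC"].abundance_pct
    if pc <= 0:
        raise ValueError("PC abundance is zero")
    return rows["PE"].abundance_pct / pc


def diversity_abundance_correlation(
    summaries: Sequence[ClassSummary],
    group: str,
    transform: str = "log",
) -> float:
    """Squared Pearson correlation between class diversity and class %
    abundance across the group's classes, after ``log`` (default) or
    ``identity`` transform.  Classes with zero diversity or abundance are
    excluded; at least three must remain."""
    rows = [
        s for s in _group_rows(summaries, group).values()
        if s.diversity > 0 and s.abundance_pct > 0
    ]
    if len(rows) < 3:
        raise ValueError("need >=3 classes with positive diversity and abundance")
    div = np.array([s.diversity for s in rows], dtype=float)
    ab = np.array([s.abundance_pct for s in rows], dtype=float)
    if transform == "log":
        div, ab = np.log(div), np.log(ab)
    elif transform != "identity":
        raise ValueError(f"unknown transform {transform!r}")
    if np.ptp(div) == 0 or np.ptp(ab) == 0:
        raise ValueError("zero variance in diversity or abundance")
    r, _ = stats.pearsonr(div, ab)
    return float(r * r)
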