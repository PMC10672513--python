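"""Published reference summary of the adult male Queensland fruit fly lipidome.

Class-level diversity (number of lipid species detected) and % abundance
(+/- SE, percent by weight of all lipids detected) at 1 and 19 days
post-eclosion, together with the between-day detection overlap and the single
chain-specified plasmanyl PC species.  These published, rounded values serve
as worked-example inputs for the aggregation, ratio and correlation
operations in :mod:`lipidchains.lipidome` and the per-species chain
statistics in :mod:`lipidchains.chain_profiles`; they are not replicate-level
data.
"""

from __future__ import annotations

from .lipidome import ClassSummary, OverlapCounts

__all__ = [
    "REFERENCE_CLASS_ROWS",
    "REFERENCE_OVERLAP",
    "REFERENCE_PCE_NAME",
    "reference_class_summaries",
]

#: class -> (diversity Day1, diversity Day19, abundance% Day1, SE Day1,
#:           abundance% Day19, SE Day19)
REFERENCE_CLASS_ROWS: dict[str, tuple[int, int, float, float, float, float]] = {
    "DG":  (11, 16, 0.4, 0.05, 0.4, 0.04),
    "TG":  (202, 180, 36.1, 2.7, 29.7, 2.1),
    "CL":  (36, 34, 4.1, 0.2, 5.1, 0.2),
    "PC":  (26, 27, 9.0, 0.4, 8.6, 0.2),
    "PE":  (19, 27, 29.1, 1.4, 36.0, 1.1),
    "PG":  (9, 9, 3.5, 0.2, 4.7, 0.1),
    "PI":  (12, 15, 7.2, 0.3, 5.4, 0.2),
    "PS":  (9, 21, 3.4, 0.2, 4.1, 0.4),
    "LPC": (14, 15, 1.3, 0.1, 2.0, 0.2),
    "DGe": (6, 6, 1.3, 0.1, 0.5, 0.1),
    "TGe": (9, 9, 0.3, 0.03, 0.2, 0.02),
    "PCe": (1, 1, 0.01, 0.0, 0.03, 0.0),
    "PEe": (13, 11, 1.7, 0.1, 1.2, 0.1),
    "PEp": (7, 6, 2.4, 0.1, 2.2, 0.1),
    "PSe": (1, 1, 0.1, 0.01, 0.04, 0.01),
}

#: Species detected at both days / only at Day 1 / only at Day 19.
REFERENCE_OVERLAP = OverlapCounts(shared=332, only_a=43, only_b=46)

#: The single plasmanyl PC detected (alkyl 20:0, acyl 14:1).
REFERENCE_PCE_NAME = "PCe(20:0e_14:1)"


def reference_class_summaries() -> list[ClassSummary]:
    """The published class rows as :class:`ClassSummary` records for the
    groups ``Day1`` and ``Day19``."""
    out = []
    for cls, (d1, d19, a1, se1, a19, se19) in REFERENCE_CLASS_ROWS.items():
        out.append(ClassSummary(cls, "Day1", d1, a1, se1))
        out.append(ClassSummary(cls, "Day19", d19, a19, se19))
    return out
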