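from importlib import resources

import pandas as pd
import pytest

from lipidchains.lipidome import ConcentrationTable, SampleInfo
from lipidchains.nomenclature import parse_lipid_name
from lipidchains.synthetic import default_config, generate


def make_table(groups: dict[str, str], conc: dict[str, list[float]]) -> ConcentrationTable:
    """Build a small table by hand: groups maps sample_id -> group label,
    conc maps shorthand name -> concentrations (one per sample, in order)."""
    species = {}
    cols = {}
    for name, values in conc.items():
        sp = parse_lipid_name(name)
        species[sp.canonical_name] = sp
        cols[sp.canonical_name] = values
    values = pd.DataFrame(cols, index=list(groups))
    counters: dict[str, int] = {}
    samples = []
    for sid, grp in groups.items():
        counters[grp] = counters.get(grp, 0) + 1
        samples.append(SampleInfo(sid, grp, counters[grp]))
    return ConcentrationTable(values, samples, species)


@pytest.fixture(scope="session")
def corpus_names() -> list[str]:
    text = resources.files("lipidchains.data").joinpath("species_corpus.txt").read_text()
    return [
        line.strip()
        for line in text.splitlines()
        if line.strip() and not line.startswith("#")
    ]


@pytest.fixture(scope="session")
def synthetic_table():
    """Default two-group, 16-replicate synthetic lipidome (seed 11)."""
    table, truth = generate(default_config(seed=11))
    return table, truth
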