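"""Simulation experiments for the combination test's operating characteristics.

Two standard experiments, both built on the synthetic generator's default
two-group, 16-replicate study design:

* **Null calibration** — with random chain association (theta = 0) in every
  ester class, the fraction of Bonferroni-significant combination tests
  should not exceed the nominal level, and raw p-values should be
  approximately uniform.
* **Deficit recovery** — with theta < 0 in one two-chain phospholipid-like
  class (the documented test setting is theta = -0.5 on PC), homogeneous
  chain-type pairs are suppressed, and the test should flag at least one
  homogeneous-pair combination as a significant deficit in both groups.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .combination_test import run_combination_test
from .nomenclature import ESTER_MULTI_CHAIN_CLASSES
from .synthetic import default_config, generate

__all__ = ["NullCalibration", "null_calibration", "deficit_recovery"]

#: Documented association strength for power/recovery experiments.
RECOVERY_THETA = -0.5


@dataclass(frozen=True)
class NullCalibration:
    n_repeats: int
    n_tests: int
    significant_fraction: float
    ks_distance: float  # sup distance of raw p-values from U(0,1)


def null_calibration(
    n_repeats: int = 100,
    seed: int = 0,
    alpha: float = 0.05,
) -> NullCalibration:
    """Generate ``n_repeats`` independent theta=0 datasets and run the
    combination test on every multi-chain ester class and group."""
    rng = np.random.default_rng(seed)
    pvals: list[float] = []
    n_sig = 0
    for _ in range(n_repeats):
        cfg = default_config(seed=int(rng.integers(2**31)))
        table, _ = generate(cfg)
        for cls in ESTER_MULTI_CHAIN_CLASSES:
            for res in run_combination_test(table, cls, alpha=alpha):
                for g in res.groups.values():
                    pvals.append(g.p_raw)
                    n_sig += g.significant
    p = np.sort(pvals)
    n = len(p)
    grid = np.arange(1, n + 1) / n
    ks = float(np.max(np.maximum(grid - p, p - (grid - 1 / n))))
    return NullCalibration(n_repeats, n, n_sig / n, ks)


def deficit_recovery(
    n_repeats: int = 50,
    seed: int = 0,
    theta: float = RECOVERY_THETA,
    class_code: str = "PC",
) -> float:
    """Fraction of repeats in which suppression of homogeneous pairs
    (``theta`` < 0 on ``class_code``) is recovered: at least one homogeneous
    joint-category combination significant with a negative observed-expected
    difference in both groups."""
    if theta >= 0:
        raise ValueError("recovery experiment requires theta < 0")
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_repeats):
        cfg = default_config(seed=int(rng.integers(2**31)))
        cfg.class_plans[class_code].theta = theta
        table, _ = generate(cfg)
        found = False
        for res in run_combination_test(table, class_code):
            labels = res.combination.split("_")
            if len(set(labels)) != 1:
                continue
            gs = list(res.groups.values())
            if len(gs) == 2 and all(g.significant and g.diff_pp < 0 for g in gs):
                found = True
        hits += found
    return hits / n_repeats
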