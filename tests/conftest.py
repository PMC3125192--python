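"""Shared fixtures and independent brute-force oracles.

The oracles deliberately use plain Python loops over individual patients,
probes and conditions so they share no code path with the vectorized
implementations they check.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from afas_screen.io_model import (
    ExpressionMatrix,
    ProbeAnnotation,
    SampleKey,
    ScreenParams,
)
from afas_screen.screens import PairProfile
from afas_screen.synthetic_data import SimulationConfig, simulate_dataset


@pytest.fixture(scope="session")
def params():
    return ScreenParams()


@pytest.fixture(scope="session")
def small_dataset():
    cfg = SimulationConfig(n_genes=30, planted_reversal_fraction=0.1, seed=7)
    return simulate_dataset(cfg)


def make_matrix(values: dict[str, list[float]], keys: list[SampleKey]) -> ExpressionMatrix:
    """values: probe_id -> row (one intensity per key)."""
    frame = pd.DataFrame.from_dict(
        values, orient="index", columns=[k.sample_id for k in keys]
    )
    frame.index.name = "probe_id"
    return ExpressionMatrix(frame.astype(float), keys)


def full_design(n_patients: int) -> list[SampleKey]:
    return [
        SampleKey(p, t, pr)
        for p in range(1, n_patients + 1)
        for t in ("normal", "cancer")
        for pr in ("oligo_dT", "random")
    ]


def random_pairs(rng: np.random.Generator, n_pairs: int, n_patients: int = 6,
                 scale: float = 100.0) -> list[PairProfile]:
    pairs = []
    for i in range(n_pairs):
        pairs.append(
            PairProfile(
                gene_id=f"G{i:03d}",
                sense_probe_id=f"G{i:03d}-S",
                afas_probe_id=f"G{i:03d}-01",
                patients=list(range(1, n_patients + 1)),
                sense_cancer=scale * rng.lognormal(0, 1, n_patients),
                sense_normal=scale * rng.lognormal(0, 1, n_patients),
                afas_cancer=scale * rng.lognormal(0, 1, n_patients),
                afas_normal=scale * rng.lognormal(0, 1, n_patients),
            )
        )
    return pairs


# ---------------------------------------------------------------------------
# Brute-force oracles
# ---------------------------------------------------------------------------


def bf_patient_supports(pair: PairProfile, p: int, margin: float, direction: str,
                        require_dominance: bool) -> bool:
    # same inclusive-boundary tolerance as the operational definition
    f = (1.0 + margin) * (1.0 - 1e-9)
    sc, sn = pair.sense_cancer[p], pair.sense_normal[p]
    ac, an = pair.afas_cancer[p], pair.afas_normal[p]
    if direction == "sense_down_afas_up":
        sc, sn, ac, an = ac, an, sc, sn
    ok = sc >= f * sn and an >= f * ac
    if require_dominance:
        ok = ok and sc >= f * ac and an >= f * sn
    return ok


def bf_balance_screen(pairs, params: ScreenParams, direction: str,
                      require_dominance: bool = True) -> set[str]:
    hits = set()
    for pair in pairs:
        support = sum(
            bf_patient_supports(pair, p, params.margin, direction, require_dominance)
            for p in range(len(pair.patients))
        )
        if support >= params.min_support:
            hits.add(pair.afas_probe_id)
    return hits


def bf_median(values) -> float:
    ordered = sorted(values)
    n = len(ordered)
    if n % 2 == 1:
        return ordered[n // 2]
    return (ordered[n // 2 - 1] + ordered[n // 2]) / 2.0


def bf_ratio(cancer, normal, floor: float) -> float:
    return max(bf_median(cancer), floor) / max(bf_median(normal), floor)


def bf_fold_screen(pairs, params: ScreenParams) -> tuple[set[str], set[str]]:
    up, down = set(), set()
    for pair in pairs:
        r = bf_ratio(pair.afas_cancer, pair.afas_normal, params.intensity_floor)
        if r > params.fold_change:
            up.add(pair.afas_probe_id)
        if r < 1.0 / params.fold_change:
            down.add(pair.afas_probe_id)
    return up, down


def bf_dominant(pairs, params: ScreenParams) -> set[str]:
    hits = set()
    for pair in pairs:
        if (
            bf_median(pair.afas_cancer) >= params.dominance_fold * bf_median(pair.sense_cancer)
            and bf_median(pair.afas_normal) >= params.dominance_fold * bf_median(pair.sense_normal)
        ):
            hits.add(pair.afas_probe_id)
    return hits


def bf_concerted(pairs, params: ScreenParams) -> tuple[int, float]:
    dirs = []
    for pair in pairs:
        rs = bf_ratio(pair.sense_cancer, pair.sense_normal, params.intensity_floor)
        ra = bf_ratio(pair.afas_cancer, pair.afas_normal, params.intensity_floor)
        if rs == 1.0 or ra == 1.0:
            continue
        dirs.append((rs > 1.0, ra > 1.0))
    n = len(dirs)
    if n == 0:
        return 0, 0.0
    observed = sum(s == a for s, a in dirs)
    p_up_s = sum(s for s, _ in dirs) / n
    p_up_a = sum(a for _, a in dirs) / n
    expected = n * (p_up_s * p_up_a + (1 - p_up_s) * (1 - p_up_a))
    return observed, expected


def bf_pearson(x, y) -> float:
    n = len(x)
    mx = sum(x) / n
    my = sum(y) / n
    num = sum((a - mx) * (b - my) for a, b in zip(x, y))
    den = (sum((a - mx) ** 2 for a in x) * sum((b - my) ** 2 for b in y)) ** 0.5
    return num / den
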