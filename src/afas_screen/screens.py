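"""Screening statistics for paired cancer/normal probe intensities.

Everything here works on per-patient intensity profiles of sense-antisense
probe pairs or on per-probe medians across patients:

* twofold up/down screens on the cancer:normal ratio of medians,
* the balance-reversal screen (strand dominance flips between tissues),
* a relaxed preset requiring only opposite >=10% changes,
* antisense-dominance counting, concerted-change counting,
* per-probe correlation between priming methods,
* direction concordance against an external reference list.

Ratios always apply ``intensity_floor`` to both numerator and denominator,
so they are finite for non-negative data.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .io_model import (
    DataError,
    ExpressionMatrix,
    ProbeAnnotation,
    ScreenParams,
)

logger = logging.getLogger("afas_screen")

MODES = ("dt", "random", "mixed")
DIRECTIONS = ("sense_up_afas_down", "sense_down_afas_up")


def _primings_for_mode(mode: str) -> tuple[str, str]:
    """(sense priming, afas priming) for an analysis mode."""
    if mode == "dt":
        return "oligo_dT", "oligo_dT"
    if mode == "random":
        return "random", "random"
    if mode == "mixed":
        return "oligo_dT", "random"
    raise DataError(f"mode must be one of {MODES}, got {mode!r}")


# ---------------------------------------------------------------------------
# Pair profiles
# ---------------------------------------------------------------------------


@dataclass
class PairProfile:
    """Per-patient intensities of one sense probe and one antisense probe."""

    gene_id: str
    sense_probe_id: str
    afas_probe_id: str
    patients: list[int]
    sense_cancer: np.ndarray
    sense_normal: np.ndarray
    afas_cancer: np.ndarray
    afas_normal: np.ndarray


@dataclass
class BalanceScreenResult:
    """A pair that passed the balance-reversal (or preset) screen."""

    afas_probe_id: str
    gene_id: str
    direction: str
    support: int
    margin: float
    mode: str = "random"
    conflict: bool = False


def build_pair_profiles(
    matrix: ExpressionMatrix,
    annotation: ProbeAnnotation,
    params: ScreenParams,
    mode: str = "random",
) -> list[PairProfile]:
    """One profile per (gene's sense probe, antisense probe) pair.

    Pairs with any missing intensity in a required sample are skipped with a
    log entry; genes without a sense probe contribute no pairs.
    """
    sense_pr, afas_pr = _primings_for_mode(mode)
    sense_cancer = matrix.select("cancer", sense_pr)
    sense_normal = matrix.select("normal", sense_pr)
    afas_cancer = matrix.select("cancer", afas_pr)
    afas_normal = matrix.select("normal", afas_pr)
    patients = list(sense_cancer.columns)
    for frame in (sense_normal, afas_cancer, afas_normal):
        if list(frame.columns) != patients:
            raise DataError("dataset is incomplete: tissue/priming patient sets differ")

    sense_of = annotation.sense_probe_of()
    profiles: list[PairProfile] = []
    for row in annotation.afas.itertuples(index=False):
        sense_id = sense_of.get(row.gene_id)
        if sense_id is None:
            logger.info("gene %s has no sense probe; pair for %s skipped", row.gene_id, row.probe_id)
            continue
        if sense_id not in matrix.probe_ids or row.probe_id not in matrix.probe_ids:
            logger.info("pair (%s, %s) absent from matrix; skipped", sense_id, row.probe_id)
            continue
        arrays = (
            sense_cancer.loc[sense_id].to_numpy(dtype=float),
            sense_normal.loc[sense_id].to_numpy(dtype=float),
            afas_cancer.loc[row.probe_id].to_numpy(dtype=float),
            afas_normal.loc[row.probe_id].to_numpy(dtype=float),
        )
        if any(np.isnan(a).any() for a in arrays):
            logger.info("pair (%s, %s) has missing values; skipped", sense_id, row.probe_id)
            continue
        profiles.append(
            PairProfile(row.gene_id, sense_id, row.probe_id, patients, *arrays)
        )
    return profiles


def _stack(pairs: Sequence[PairProfile]) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    sc = np.stack([p.sense_cancer for p in pairs])
    sn = np.stack([p.sense_normal for p in pairs])
    ac = np.stack([p.afas_cancer for p in pairs])
    an = np.stack([p.afas_normal for p in pairs])
    return sc, sn, ac, an


# ---------------------------------------------------------------------------
# Ratio screens (per-probe medians)
# ---------------------------------------------------------------------------


def cancer_normal_ratio(
    probe_id: str,
    matrix: ExpressionMatrix,
    params: ScreenParams,
    priming: str = "random",
) -> float:
    """Floored ratio of per-tissue medians (across patients) for one probe."""
    cancer = matrix.select("cancer", priming)
    normal = matrix.select("normal", priming)
    if probe_id not in cancer.index:
        raise DataError(f"probe {probe_id!r} absent from matrix")
    med_c = float(np.median(cancer.loc[probe_id].to_numpy(dtype=float)))
    med_n = float(np.median(normal.loc[probe_id].to_numpy(dtype=float)))
    floor = params.intensity_floor
    return max(med_c, floor) / max(med_n, floor)


def _median_ratios(
    cancer: np.ndarray, normal: np.ndarray, floor: float
) -> np.ndarray:
    """Row-wise floored cancer:normal ratio of medians; arrays (..., n, P)."""
    med_c = np.median(cancer, axis=-1)
    med_n = np.median(normal, axis=-1)
    return np.maximum(med_c, floor) / np.maximum(med_n, floor)


def fold_change_screen(
    matrix: ExpressionMatrix,
    annotation: ProbeAnnotation,
    params: ScreenParams,
    priming: str = "random",
    probe_class: str = "afas",
) -> tuple[list[str], list[str]]:
    """Probes changed MORE than ``fold_change`` up or down in cancer.

    Strict inequalities on both sides, so the two lists are disjoint and a
    probe at exactly the fold boundary is reported in neither.
    """
    ids = [
        pid
        for pid in annotation.table.loc[
            annotation.table["probe_class"] == probe_class, "probe_id"
        ]
        if pid in matrix.probe_ids
    ]
    cancer = matrix.select("cancer", priming).loc[ids].to_numpy(dtype=float)
    normal = matrix.select("normal", priming).loc[ids].to_numpy(dtype=float)
    keep = ~(np.isnan(cancer).any(axis=1) | np.isnan(normal).any(axis=1))
    if (~keep).any():
        logger.info("fold_change_screen: %d probe(s) with missing values excluded", int((~keep).sum()))
    ids = [pid for pid, k in zip(ids, keep) if k]
    ratios = _median_ratios(cancer[keep], normal[keep], params.intensity_floor)
    up = [pid for pid, r in zip(ids, ratios) if r > params.fold_change]
    down = [pid for pid, r in zip(ids, ratios) if r < 1.0 / params.fold_change]
    return up, down


# ---------------------------------------------------------------------------
# Balance-reversal screens
# ---------------------------------------------------------------------------


def _support_counts(
    sc: np.ndarray,
    sn: np.ndarray,
    ac: np.ndarray,
    an: np.ndarray,
    margin: float,
    direction: str,
    require_dominance: bool = True,
) -> np.ndarray:
    """Per-pair number of patients meeting all per-patient conditions.

    For ``sense_up_afas_down`` a patient supports a pair when
      (1) sense_cancer >= (1+m) * afas_cancer      [dominance in cancer]
      (2) afas_normal  >= (1+m) * sense_normal     [reversed in normal]
      (3) sense_cancer >= (1+m) * sense_normal     [sense up in cancer]
      (4) afas_normal  >= (1+m) * afas_cancer      [afas down in cancer]
    (1) and (2) are dropped when ``require_dominance`` is False (relaxed
    preset).  The opposite direction swaps the sense and afas roles.
    """
    if direction not in DIRECTIONS:
        raise DataError(f"direction must be one of {DIRECTIONS}, got {direction!r}")
    if direction == "sense_down_afas_up":
        sc, sn, ac, an = ac, an, sc, sn
    # tiny relative tolerance keeps "exactly (1+m)x" inclusive despite binary FP
    f = (1.0 + margin) * (1.0 - 1e-9)
    cond = (sc >= f * sn) & (an >= f * ac)
    if require_dominance:
        cond &= (sc >= f * ac) & (an >= f * sn)
    return cond.sum(axis=-1)


def balance_reversal_screen(
    pairs: Sequence[PairProfile],
    params: ScreenParams,
    direction: str = "sense_up_afas_down",
    mode: str = "random",
    require_dominance: bool = True,
) -> list[BalanceScreenResult]:
    """Pairs whose strand dominance flips between tissues in enough patients.

    ``direction='both'`` runs both directions; a pair passing in both is
    reported twice with ``conflict=True`` on each record.
    """
    if not pairs:
        return []
    if direction == "both":
        up = balance_reversal_screen(pairs, params, "sense_up_afas_down", mode, require_dominance)
        down = balance_reversal_screen(pairs, params, "sense_down_afas_up", mode, require_dominance)
        both = {r.afas_probe_id for r in up} & {r.afas_probe_id for r in down}
        for r in up + down:
            if r.afas_probe_id in both:
                r.conflict = True
                logger.warning("pair %s passes in both directions", r.afas_probe_id)
        return up + down
    sc, sn, ac, an = _stack(pairs)
    support = _support_counts(sc, sn, ac, an, params.margin, direction, require_dominance)
    return [
        BalanceScreenResult(
            afas_probe_id=p.afas_probe_id,
            gene_id=p.gene_id,
            direction=direction,
            support=int(s),
            margin=params.margin,
            mode=mode,
        )
        for p, s in zip(pairs, support)
        if s >= params.min_support
    ]


def cdna_pair_screen(
    pairs: Sequence[PairProfile],
    params: ScreenParams,
    mode: str = "random",
) -> list[BalanceScreenResult]:
    """Relaxed preset: opposite >=margin changes only, both directions.

    No dominance-reversal requirement; the union over the two directions is
    deduplicated per pair (a pair can satisfy only one direction for a given
    patient, but support sets may differ between directions — the direction
    with the larger support wins; ties keep ``sense_up_afas_down``).
    """
    if not pairs:
        return []
    sc, sn, ac, an = _stack(pairs)
    out: list[BalanceScreenResult] = []
    sup_up = _support_counts(sc, sn, ac, an, params.margin, "sense_up_afas_down", False)
    sup_dn = _support_counts(sc, sn, ac, an, params.margin, "sense_down_afas_up", False)
    for p, u, d in zip(pairs, sup_up, sup_dn):
        best_dir, best = ("sense_up_afas_down", u) if u >= d else ("sense_down_afas_up", d)
        if best >= params.min_support:
            out.append(
                BalanceScreenResult(
                    afas_probe_id=p.afas_probe_id,
                    gene_id=p.gene_id,
                    direction=best_dir,
                    support=int(best),
                    margin=params.margin,
                    mode=mode,
                )
            )
    return out


# ---------------------------------------------------------------------------
# Dominance and concerted change
# ---------------------------------------------------------------------------


def afas_dominant_pairs(
    pairs: Sequence[PairProfile], params: ScreenParams
) -> list[PairProfile]:
    """Pairs where the antisense median is >= dominance_fold x the sense
    median in BOTH tissues (inclusive)."""
    if not pairs:
        return []
    sc, sn, ac, an = _stack(pairs)
    med_sc, med_sn = np.median(sc, axis=-1), np.median(sn, axis=-1)
    med_ac, med_an = np.median(ac, axis=-1), np.median(an, axis=-1)
    fold = params.dominance_fold
    hit = (med_ac >= fold * med_sc) & (med_an >= fold * med_sn)
    return [p for p, h in zip(pairs, hit) if h]


def concerted_change_count(
    pairs: Sequence[PairProfile], params: ScreenParams
) -> tuple[int, float]:
    """Observed vs expected number of pairs moving the same direction.

    Direction = sign of the floored cancer:normal ratio of medians; pairs
    where either member is exactly tied (ratio 1) are excluded and logged.
    The expectation assumes independence of the two marginal direction
    frequencies: N * (p_up^S * p_up^A + p_down^S * p_down^A).
    """
    if not pairs:
        return 0, 0.0
    sc, sn, ac, an = _stack(pairs)
    floor = params.intensity_floor
    r_sense = _median_ratios(sc, sn, floor)
    r_afas = _median_ratios(ac, an, floor)
    keep = (r_sense != 1.0) & (r_afas != 1.0)
    n_tied = int((~keep).sum())
    if n_tied:
        logger.info("concerted_change_count: %d tied pair(s) excluded", n_tied)
    r_sense, r_afas = r_sense[keep], r_afas[keep]
    n = r_sense.size
    if n == 0:
        return 0, 0.0
    up_s, up_a = r_sense > 1.0, r_afas > 1.0
    observed = int(np.sum(up_s == up_a))
    p_up_s, p_up_a = up_s.mean(), up_a.mean()
    expected = float(n * (p_up_s * p_up_a + (1 - p_up_s) * (1 - p_up_a)))
    return observed, expected


# ---------------------------------------------------------------------------
# Priming correlation and direction concordance
# ---------------------------------------------------------------------------


def priming_correlation(
    matrix: ExpressionMatrix,
    annotation: ProbeAnnotation,
    probe_class: str,
) -> tuple[pd.Series, float]:
    """Per-probe Pearson r between oligo-dT and random intensities.

    Vectors run over all (patient, tissue) samples in a fixed order.
    Probes with zero variance in either vector are skipped with a log
    entry.  Returns the per-probe series plus its arithmetic mean.
    """
    frames = {}
    for priming in ("oligo_dT", "random"):
        per_tissue = [matrix.select(t, priming) for t in ("normal", "cancer")]
        frames[priming] = pd.concat(per_tissue, axis=1)
    if frames["oligo_dT"].shape[1] < 3:
        raise DataError("fewer than 3 paired samples; correlation undefined")
    ids = [
        pid
        for pid in annotation.table.loc[
            annotation.table["probe_class"] == probe_class, "probe_id"
        ]
        if pid in matrix.probe_ids
    ]
    out: dict[str, float] = {}
    for pid in ids:
        a = frames["oligo_dT"].loc[pid].to_numpy(dtype=float)
        b = frames["random"].loc[pid].to_numpy(dtype=float)
        if np.isnan(a).any() or np.isnan(b).any():
            logger.info("priming_correlation: probe %s has missing values; skipped", pid)
            continue
        if np.std(a) == 0 or np.std(b) == 0:
            logger.info("priming_correlation: probe %s has zero variance; skipped", pid)
            continue
        out[pid] = float(np.corrcoef(a, b)[0, 1])
    series = pd.Series(out, name="pearson_r")
    if series.empty:
        raise DataError(f"no {probe_class} probe with computable correlation")
    return series, float(series.mean())


@dataclass
class ConcordanceResult:
    n_agree_up: int
    n_total_up: int
    n_agree_down: int
    n_total_down: int
    unmatched: list[str]


def direction_concordance(
    reference: Mapping[str, str], observed: Mapping[str, str]
) -> ConcordanceResult:
    """Agreement of observed up/down calls with a reference gene list."""
    for name, table in (("reference", reference), ("observed", observed)):
        bad = {d for d in table.values() if d not in ("up", "down")}
        if bad:
            raise DataError(f"{name} directions must be 'up' or 'down', got {sorted(bad)}")
    agree_up = total_up = agree_down = total_down = 0
    unmatched: list[str] = []
    for gene, ref_dir in reference.items():
        if gene not in observed:
            unmatched.append(gene)
            continue
        if ref_dir == "up":
            total_up += 1
            agree_up += observed[gene] == "up"
        else:
            total_down += 1
            agree_down += observed[gene] == "down"
    return ConcordanceResult(agree_up, total_up, agree_down, total_down, unmatched)


# ---------------------------------------------------------------------------
# Vectorized counting kernels (shared with the permutation null)
# ---------------------------------------------------------------------------


def count_balance_reversal(
    sc, sn, ac, an, params: ScreenParams, direction: str = "sense_up_afas_down"
) -> np.ndarray | int:
    """Count of pairs passing the reversal screen; broadcasts leading axes."""
    support = _support_counts(sc, sn, ac, an, params.margin, direction, True)
    return (support >= params.min_support).sum(axis=-1)


def count_cdna_pairs(sc, sn, ac, an, params: ScreenParams) -> np.ndarray | int:
    sup_up = _support_counts(sc, sn, ac, an, params.margin, "sense_up_afas_down", False)
    sup_dn = _support_counts(sc, sn, ac, an, params.margin, "sense_down_afas_up", False)
    hit = (sup_up >= params.min_support) | (sup_dn >= params.min_support)
    return hit.sum(axis=-1)


def count_fold(
    cancer: np.ndarray, normal: np.ndarray, params: ScreenParams, side: str
) -> np.ndarray | int:
    ratios = _median_ratios(cancer, normal, params.intensity_floor)
    if side == "up":
        return (ratios > params.fold_change).sum(axis=-1)
    if side == "down":
        return (ratios < 1.0 / params.fold_change).sum(axis=-1)
    raise DataError(f"side must be 'up' or 'down', got {side!r}")


def count_afas_dominant(sc, sn, ac, an, params: ScreenParams) -> np.ndarray | int:
    med_sc, med_sn = np.median(sc, axis=-1), np.median(sn, axis=-1)
    med_ac, med_an = np.median(ac, axis=-1), np.median(an, axis=-1)
    fold = params.dominance_fold
    return ((med_ac >= fold * med_sc) & (med_an >= fold * med_sn)).sum(axis=-1)


def count_concerted(sc, sn, ac, an, params: ScreenParams) -> np.ndarray | int:
    floor = params.intensity_floor
    r_s = _median_ratios(sc, sn, floor)
    r_a = _median_ratios(ac, an, floor)
    keep = (r_s != 1.0) & (r_a != 1.0)
    same = (r_s > 1.0) == (r_a > 1.0)
    return (same & keep).sum(axis=-1)
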