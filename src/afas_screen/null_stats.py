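"""Permutation null for screen counts plus small statistical kernels.

The random-shuffling null re-assigns, independently for every probe row and
patient, which of the patient's two arrays counts as "cancer" and which as
"normal".  This preserves each probe's value multiset and the patient
pairing while destroying exactly the tissue association the screens
measure.  An alternative scheme permutes the sense<->antisense partner
assignment instead.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .io_model import DataError, ExpressionMatrix, ProbeAnnotation, ScreenParams
from .screens import (
    PairProfile,
    _primings_for_mode,
    build_pair_profiles,
    count_afas_dominant,
    count_balance_reversal,
    count_cdna_pairs,
    count_concerted,
    count_fold,
)

logger = logging.getLogger("afas_screen")

SCREEN_NAMES = (
    "balance_reversal",
    "balance_reversal_down",
    "cdna_pairs",
    "fold_up",
    "fold_down",
    "afas_dominant",
    "concerted",
)

NULL_SCHEMES = ("tissue-labels", "pair-partners")


@dataclass
class PermutationResult:
    """Observed count with its shuffle-null summary."""

    observed: int
    null_mean: float
    null_sd: float
    n_shuffles: int
    seed: int
    empirical_p: float
    null_counts: np.ndarray = field(repr=False, default=None)

    def __post_init__(self) -> None:
        if self.null_sd < 0:
            raise DataError("null_sd must be >= 0")
        if not (0.0 < self.empirical_p <= 1.0):
            raise DataError("empirical_p must lie in (0, 1]")


def _pair_arrays(
    matrix: ExpressionMatrix,
    annotation: ProbeAnnotation,
    params: ScreenParams,
    mode: str,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray, list[PairProfile]]:
    """Probe-level cancer/normal arrays plus pair index vectors.

    Returns (cancer, normal, sense_idx, afas_idx, pairs) where cancer and
    normal have one row per distinct probe row (a sense probe shared by
    several antisense probes occupies ONE row, so it receives one shuffle).
    In mixed mode sense rows come from the oligo-dT arrays and antisense
    rows from the random-priming arrays; they are distinct rows.
    """
    pairs = build_pair_profiles(matrix, annotation, params, mode)
    if not pairs:
        raise DataError("no usable sense-antisense pairs in matrix")
    sense_pr, afas_pr = _primings_for_mode(mode)
    row_of: dict[tuple[str, str], int] = {}
    cancer_rows: list[np.ndarray] = []
    normal_rows: list[np.ndarray] = []

    def row_index(key, cancer_vals, normal_vals):
        if key not in row_of:
            row_of[key] = len(cancer_rows)
            cancer_rows.append(cancer_vals)
            normal_rows.append(normal_vals)
        return row_of[key]

    sense_idx = np.array(
        [
            row_index((p.sense_probe_id, sense_pr), p.sense_cancer, p.sense_normal)
            for p in pairs
        ]
    )
    afas_idx = np.array(
        [
            row_index((p.afas_probe_id, afas_pr), p.afas_cancer, p.afas_normal)
            for p in pairs
        ]
    )
    return np.stack(cancer_rows), np.stack(normal_rows), sense_idx, afas_idx, pairs


def _screen_count(screen: str, sc, sn, ac, an, params: ScreenParams):
    if screen == "balance_reversal":
        return count_balance_reversal(sc, sn, ac, an, params, "sense_up_afas_down")
    if screen == "balance_reversal_down":
        return count_balance_reversal(sc, sn, ac, an, params, "sense_down_afas_up")
    if screen == "cdna_pairs":
        return count_cdna_pairs(sc, sn, ac, an, params)
    if screen == "fold_up":
        return count_fold(ac, an, params, "up")
    if screen == "fold_down":
        return count_fold(ac, an, params, "down")
    if screen == "afas_dominant":
        return count_afas_dominant(sc, sn, ac, an, params)
    if screen == "concerted":
        return count_concerted(sc, sn, ac, an, params)
    raise DataError(f"unknown screen {screen!r}; choose from {SCREEN_NAMES}")


def shuffle_expected_count(
    matrix: ExpressionMatrix,
    annotation: ProbeAnnotation,
    screen: str,
    params: ScreenParams,
    n_shuffles: int | None = None,
    seed: int | None = None,
    mode: str = "random",
    scheme: str = "tissue-labels",
    batch: int = 250,
) -> PermutationResult:
    """Expected screen count (mean +/- SD) under random shuffling.

    ``scheme='tissue-labels'`` independently swaps each probe row's
    cancer/normal values per patient; ``scheme='pair-partners'`` keeps the
    data fixed but permutes which antisense probe is paired with which
    sense probe.  empirical_p is the +1-smoothed upper-tail fraction.
    """
    n_shuffles = params.n_shuffles if n_shuffles is None else n_shuffles
    seed = params.seed if seed is None else seed
    if n_shuffles < 100:
        raise DataError(f"n_shuffles must be >= 100, got {n_shuffles}")
    if scheme not in NULL_SCHEMES:
        raise DataError(f"scheme must be one of {NULL_SCHEMES}, got {scheme!r}")
    cancer, normal, si, ai, _ = _pair_arrays(matrix, annotation, params, mode)
    observed = int(
        _screen_count(screen, cancer[si], normal[si], cancer[ai], normal[ai], params)
    )
    rng = np.random.default_rng(seed)
    counts = np.empty(n_shuffles, dtype=np.int64)
    done = 0
    n_rows, n_pat = cancer.shape
    while done < n_shuffles:
        b = min(batch, n_shuffles - done)
        if scheme == "tissue-labels":
            mask = rng.random((b, n_rows, n_pat)) < 0.5
            c = np.where(mask, normal, cancer)
            n = np.where(mask, cancer, normal)
            counts[done : done + b] = _screen_count(
                screen, c[:, si, :], n[:, si, :], c[:, ai, :], n[:, ai, :], params
            )
        else:
            for k in range(b):
                perm = rng.permutation(len(ai))
                pai = ai[perm]
                counts[done + k] = _screen_count(
                    screen, cancer[si], normal[si], cancer[pai], normal[pai], params
                )
        done += b
    null_mean = float(counts.mean())
    null_sd = float(counts.std())  # population SD
    empirical_p = float((1 + np.sum(counts >= observed)) / (n_shuffles + 1))
    return PermutationResult(
        observed=observed,
        null_mean=null_mean,
        null_sd=null_sd,
        n_shuffles=n_shuffles,
        seed=seed,
        empirical_p=empirical_p,
        null_counts=counts,
    )


# ---------------------------------------------------------------------------
# Chi-square goodness of fit
# ---------------------------------------------------------------------------


def chisq_goodness_of_fit(observed, expected) -> tuple[float, int, float]:
    """Pearson chi-square of observed counts against expected counts.

    statistic = sum (O-E)^2 / E, df = k - 1, upper-tail p.
    """
    obs = np.asarray(observed, dtype=float)
    exp = np.asarray(expected, dtype=float)
    if obs.shape != exp.shape or obs.ndim != 1:
        raise DataError("observed and expected must be 1-D of equal length")
    if obs.size < 2:
        raise DataError("need at least 2 categories")
    if np.any(exp <= 0):
        raise DataError("expected counts must all be > 0")
    statistic = float(np.sum((obs - exp) ** 2 / exp))
    df = obs.size - 1
    p = float(stats.chi2.sf(statistic, df))
    return statistic, df, p


# ---------------------------------------------------------------------------
# Mann-Whitney rank-sum test
# ---------------------------------------------------------------------------


def _u_statistic(a: np.ndarray, b: np.ndarray) -> float:
    """U for sample a: #{a_i > b_j} + 0.5 * #{a_i == b_j}."""
    diff = a[:, None] - b[None, :]
    return float(np.sum(diff > 0) + 0.5 * np.sum(diff == 0))


def rank_sum_test(
    values_a, values_b, exact_limit: int = 10
) -> tuple[float, float]:
    """Two-sided Mann-Whitney U test.

    Exact p by full enumeration of group assignments when both samples have
    at most ``exact_limit`` observations (ties handled via midranks);
    otherwise the normal approximation with tie correction.  The two-sided
    exact p is the probability of a U at least as far from n1*n2/2 as
    observed.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise DataError("both samples must be non-empty")
    u_obs = _u_statistic(a, b)
    if np.all(a == a[0]) and np.all(b == b[0]) and a[0] == b[0]:
        logger.warning("rank_sum_test: all values tied across both samples; p = 1")
        return u_obs, 1.0
    n1, n2 = a.size, b.size
    if max(n1, n2) <= exact_limit and n1 + n2 <= 2 * exact_limit:
        pool = np.concatenate([a, b])
        center = n1 * n2 / 2.0
        dev = abs(u_obs - center) - 1e-12
        total = hits = 0
        for combo in itertools.combinations(range(n1 + n2), n1):
            sel = np.zeros(n1 + n2, dtype=bool)
            sel[list(combo)] = True
            u = _u_statistic(pool[sel], pool[~sel])
            hits += abs(u - center) >= dev
            total += 1
        return u_obs, hits / total
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic")
    return u_obs, float(res.pvalue)
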