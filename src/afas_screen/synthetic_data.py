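"""Synthetic expression matrices mirroring the paired two-tissue,
two-priming-method microarray design, with ground truth.

Each gene carries one sense probe and 1-12 antisense probes.  Sense
transcripts are polyadenylated, so their mean intensity is the same under
both priming methods.  Most expressed antisense transcripts lack a poly(A)
tail: under oligo-dT priming they show only a small leak fraction of their
random-priming signal.  Unexpressed probes sit at a low background level.
Noise is multiplicative log-normal per cell; an optional shared per-patient
scale factor gives normalization something to remove.

Balance-reversal pairs can be planted at a configurable effect size: for a
planted pair with sense mean S the antisense normal-tissue mean is set to
fold*S and the cancer means to (fold*S, S) for the sense and antisense
probes respectively (mirrored for the opposite direction), so the pair
satisfies the reversal screen in expectation at the configured fold.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, fields

import numpy as np
import pandas as pd

from .io_model import (
    DataError,
    ExpressionMatrix,
    ProbeAnnotation,
    SampleKey,
    ANNOTATION_COLUMNS,
)

logger = logging.getLogger("afas_screen")

DIRECTIONS = ("sense_up_afas_down", "sense_down_afas_up")


@dataclass(frozen=True)
class SimulationConfig:
    n_patients: int = 6
    n_genes: int = 60
    afas_probes_min: int = 1
    afas_probes_max: int = 12
    baseline_log_mean: float = math.log(1000.0)
    baseline_log_sd: float = 1.0
    afas_log_mean: float = math.log(150.0)
    afas_log_sd: float = 0.8
    afas_expressed_fraction: float = 0.45
    truncated_fraction: float = 0.1
    noise_cv: float = 0.2
    polyA_minus_fraction: float = 0.9
    dt_leak: float = 0.05
    planted_reversal_fraction: float = 0.1
    planted_fold: float = 3.0
    planted_direction_mix: float = 0.5
    background_log_mean: float = math.log(30.0)
    background_log_sd: float = 0.3
    patient_effect_sd: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "afas_expressed_fraction",
            "truncated_fraction",
            "polyA_minus_fraction",
            "dt_leak",
            "planted_reversal_fraction",
            "planted_direction_mix",
        ):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise DataError(f"{name} must lie in [0, 1], got {v}")
        if self.n_genes <= 0:
            raise DataError("n_genes must be positive")
        if self.n_patients <= 0:
            raise DataError("n_patients must be positive")
        if self.planted_fold <= 1.0:
            raise DataError("planted_fold must exceed 1")
        if not (1 <= self.afas_probes_min <= self.afas_probes_max):
            raise DataError("need 1 <= afas_probes_min <= afas_probes_max")
        if self.noise_cv < 0 or self.patient_effect_sd < 0:
            raise DataError("noise_cv and patient_effect_sd must be >= 0")


@dataclass
class GroundTruth:
    """Per-probe generative state plus the planted reversal pairs."""

    probes: pd.DataFrame  # probe_id, gene_id, probe_class, expressed, polyA_minus, planted
    planted_pairs: pd.DataFrame  # gene_id, sense_probe_id, afas_probe_id, direction


def _lognormal_sigma(cv: float) -> float:
    return math.sqrt(math.log(1.0 + cv * cv))


def simulate_dataset(
    cfg: SimulationConfig,
) -> tuple[ExpressionMatrix, ProbeAnnotation, GroundTruth]:
    """Generate a complete dataset; identical cfg + seed => identical output."""
    rng = np.random.default_rng(cfg.seed)
    noise_sigma = _lognormal_sigma(cfg.noise_cv)

    gene_ids = [f"G{i + 1:04d}" for i in range(cfg.n_genes)]
    n_afas_per_gene = rng.integers(
        cfg.afas_probes_min, cfg.afas_probes_max + 1, size=cfg.n_genes
    )

    probe_rows: list[dict] = []
    truth_rows: list[dict] = []
    # mean[probe][tissue][priming]
    means: list[dict[str, dict[str, float]]] = []

    sense_gene_mean = np.exp(
        rng.normal(cfg.baseline_log_mean, cfg.baseline_log_sd, size=cfg.n_genes)
    )

    afas_meta: dict[str, list[str]] = {}
    for g, gid in enumerate(gene_ids):
        probe_rows.append(
            {
                "probe_id": f"{gid}-S",
                "gene_id": gid,
                "probe_class": "sense",
                "afas_index": pd.NA,
                "truncated": False,
            }
        )
        s = sense_gene_mean[g]
        means.append({"normal": {"oligo_dT": s, "random": s}, "cancer": {"oligo_dT": s, "random": s}})
        truth_rows.append(
            {
                "probe_id": f"{gid}-S",
                "gene_id": gid,
                "probe_class": "sense",
                "expressed": True,
                "polyA_minus": False,
                "planted": False,
                "direction": "",
            }
        )
        afas_meta[gid] = []
        for i in range(int(n_afas_per_gene[g])):
            pid = f"{gid}-{i + 1:02d}"
            afas_meta[gid].append(pid)
            expressed = bool(rng.random() < cfg.afas_expressed_fraction)
            polya_minus = bool(rng.random() < cfg.polyA_minus_fraction)
            truncated = bool(rng.random() < cfg.truncated_fraction)
            background = float(
                np.exp(rng.normal(cfg.background_log_mean, cfg.background_log_sd))
            )
            if expressed:
                random_mean = float(
                    np.exp(rng.normal(cfg.afas_log_mean, cfg.afas_log_sd))
                )
                dt_mean = cfg.dt_leak * random_mean if polya_minus else random_mean
                dt_mean = max(dt_mean, background)
            else:
                random_mean = background
                dt_mean = background
            probe_rows.append(
                {
                    "probe_id": pid,
                    "gene_id": gid,
                    "probe_class": "afas",
                    "afas_index": i + 1,
                    "truncated": truncated,
                }
            )
            means.append(
                {
                    "normal": {"oligo_dT": dt_mean, "random": random_mean},
                    "cancer": {"oligo_dT": dt_mean, "random": random_mean},
                }
            )
            truth_rows.append(
                {
                    "probe_id": pid,
                    "gene_id": gid,
                    "probe_class": "afas",
                    "expressed": expressed,
                    "polyA_minus": polya_minus,
                    "planted": False,
                    "direction": "",
                }
            )

    probe_ids = [r["probe_id"] for r in probe_rows]
    row_of = {pid: i for i, pid in enumerate(probe_ids)}

    # plant balance reversals
    n_planted = int(round(cfg.planted_reversal_fraction * cfg.n_genes))
    planted_rows: list[dict] = []
    if n_planted:
        chosen = rng.choice(cfg.n_genes, size=n_planted, replace=False)
        for g in sorted(chosen):
            gid = gene_ids[g]
            afas_pid = afas_meta[gid][int(rng.integers(len(afas_meta[gid])))]
            direction = (
                "sense_up_afas_down"
                if rng.random() < cfg.planted_direction_mix
                else "sense_down_afas_up"
            )
            s = sense_gene_mean[g]
            f = cfg.planted_fold
            si, ai = row_of[f"{gid}-S"], row_of[afas_pid]
            for priming in ("random", "oligo_dT"):
                if priming == "oligo_dT":
                    # antisense still obeys its poly(A) status under oligo-dT
                    leak = (
                        cfg.dt_leak
                        if truth_rows[ai]["polyA_minus"]
                        else 1.0
                    )
                else:
                    leak = 1.0
                if direction == "sense_up_afas_down":
                    means[si]["cancer"][priming] = f * s
                    means[si]["normal"][priming] = s
                    means[ai]["normal"][priming] = leak * f * s
                    means[ai]["cancer"][priming] = leak * s
                else:
                    means[si]["normal"][priming] = f * s
                    means[si]["cancer"][priming] = s
                    means[ai]["cancer"][priming] = leak * f * s
                    means[ai]["normal"][priming] = leak * s
            truth_rows[ai].update(
                {"planted": True, "direction": direction, "expressed": True}
            )
            truth_rows[si].update({"planted": True, "direction": direction})
            planted_rows.append(
                {
                    "gene_id": gid,
                    "sense_probe_id": f"{gid}-S",
                    "afas_probe_id": afas_pid,
                    "direction": direction,
                }
            )

    # sample grid: patients ascending, normal before cancer, oligo_dT before random
    keys = [
        SampleKey(p, tissue, priming)
        for p in range(1, cfg.n_patients + 1)
        for tissue in ("normal", "cancer")
        for priming in ("oligo_dT", "random")
    ]
    patient_factor = np.exp(
        rng.normal(0.0, cfg.patient_effect_sd, size=cfg.n_patients)
    )
    mean_grid = np.array(
        [[means[i][k.tissue][k.priming] for k in keys] for i in range(len(probe_ids))]
    )
    factors = np.array([patient_factor[k.patient_id - 1] for k in keys])
    noise = np.exp(rng.normal(0.0, noise_sigma, size=mean_grid.shape)) if noise_sigma else 1.0
    values = mean_grid * factors[None, :] * noise

    matrix = ExpressionMatrix(
        pd.DataFrame(values, index=pd.Index(probe_ids, name="probe_id"),
                     columns=[k.sample_id for k in keys]),
        keys,
    )
    annotation = ProbeAnnotation(pd.DataFrame(probe_rows, columns=ANNOTATION_COLUMNS))
    truth = GroundTruth(
        probes=pd.DataFrame(truth_rows),
        planted_pairs=pd.DataFrame(
            planted_rows,
            columns=["gene_id", "sense_probe_id", "afas_probe_id", "direction"],
        ),
    )
    logger.info(
        "simulated %d probes x %d samples, %d planted pair(s)",
        len(probe_ids),
        len(keys),
        len(planted_rows),
    )
    return matrix, annotation, truth


def truth_table(gt: GroundTruth) -> pd.DataFrame:
    """Tidy planted-pair table joinable to screen output on
    (gene_id, afas_probe_id)."""
    return gt.planted_pairs.copy()


def evaluate_recovery(gt: GroundTruth, results) -> dict[str, float]:
    """Confusion counts of a balance-screen result list against ground truth.

    Raises on result records whose keys do not exist in the ground truth
    probe table (e.g. shuffled join keys).
    """
    known_afas = set(gt.probes.loc[gt.probes["probe_class"] == "afas", "probe_id"])
    known_genes = set(gt.probes["gene_id"])
    found = set()
    for r in results:
        if r.afas_probe_id not in known_afas:
            raise DataError(f"screen result references unknown probe {r.afas_probe_id!r}")
        if r.gene_id not in known_genes:
            raise DataError(f"screen result references unknown gene {r.gene_id!r}")
        found.add(r.afas_probe_id)
    planted = set(gt.planted_pairs["afas_probe_id"])
    tp = len(found & planted)
    fp = len(found - planted)
    fn = len(planted - found)
    recall = tp / len(planted) if planted else float("nan")
    fdr = fp / len(found) if found else 0.0
    return {"tp": tp, "fp": fp, "fn": fn, "recall": recall, "fdr": fdr}


def config_from_toml(text: str) -> SimulationConfig:
    """Parse key = value (TOML) overrides into a SimulationConfig."""
    import tomllib

    data = tomllib.loads(text)
    allowed = {f.name for f in fields(SimulationConfig)}
    unknown = sorted(set(data) - allowed)
    if unknown:
        raise DataError(f"unknown simulation config key(s): {unknown}")
    return SimulationConfig(**data)
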