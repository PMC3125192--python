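"""Normalization and detection-call summaries.

Arrays are brought onto a common scale by global mean scaling against a
reference array; detection calls then use a single conservative intensity
threshold (inclusive), summarised per probe class / tissue / priming either
on per-probe medians across patients (default) or per sample.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io_model import (
    DataError,
    ExpressionMatrix,
    ProbeAnnotation,
    ScreenParams,
    TISSUES,
    PRIMINGS,
)

logger = logging.getLogger("afas_screen")


@dataclass
class DetectionSummary:
    probe_class: str
    tissue: str
    priming: str
    n_probes_evaluated: int
    n_positive: int

    @property
    def percent_positive(self) -> float:
        return 100.0 * self.n_positive / self.n_probes_evaluated


def global_mean_scale(
    matrix: ExpressionMatrix, reference: str
) -> tuple[ExpressionMatrix, dict[str, float]]:
    """Scale every array so its mean intensity equals the reference array's.

    Each sample's intensities are multiplied by mean(reference)/mean(sample);
    the reference itself is unchanged (factor exactly 1).  Means ignore
    missing cells.  Returns the scaled matrix and the per-sample factors.
    """
    if reference not in matrix.sample_ids:
        raise DataError(f"reference sample {reference!r} absent from matrix")
    ref_mean = float(np.nanmean(matrix.values[reference].to_numpy(dtype=float)))
    if not np.isfinite(ref_mean) or ref_mean == 0:
        raise DataError(f"reference sample {reference!r} has zero or undefined mean")
    factors: dict[str, float] = {}
    scaled = matrix.values.copy()
    for sid in matrix.sample_ids:
        if sid == reference:
            factors[sid] = 1.0
            continue
        mean = float(np.nanmean(scaled[sid].to_numpy(dtype=float)))
        if not np.isfinite(mean) or mean == 0:
            raise DataError(f"sample {sid!r} has zero or undefined mean")
        factors[sid] = ref_mean / mean
        scaled[sid] = scaled[sid] * factors[sid]
    for sid, f in factors.items():
        logger.info("global_mean_scale: %s factor %.6g", sid, f)
    return ExpressionMatrix(scaled, list(matrix.samples)), factors


def detection_call(intensity, params: ScreenParams):
    """Inclusive threshold call: positive iff intensity >= detection_threshold."""
    arr = np.asarray(intensity, dtype=float)
    if np.any(arr[np.isfinite(arr)] < 0):
        raise DataError("negative intensity in detection_call")
    result = arr >= params.detection_threshold
    if np.isscalar(intensity) or arr.ndim == 0:
        return bool(result)
    return result


def _evaluated_probe_ids(
    matrix: ExpressionMatrix, annotation: ProbeAnnotation, probe_class: str
) -> list[str]:
    """Probes of the class present in the matrix, truncated ones excluded."""
    t = annotation.table
    sel = (t["probe_class"] == probe_class) & (~t["truncated"])
    ids = [pid for pid in t.loc[sel, "probe_id"] if pid in matrix.probe_ids]
    return ids


def positive_fraction(
    matrix: ExpressionMatrix,
    annotation: ProbeAnnotation,
    probe_class: str,
    tissue: str,
    priming: str,
    params: ScreenParams,
    per_sample: bool = False,
) -> DetectionSummary:
    """Fraction of (non-truncated) probes called positive.

    Default: a probe is positive when its MEDIAN intensity across patients
    (for the chosen tissue/priming) meets the threshold.  ``per_sample``
    counts positive probe-sample calls over all probe-sample cells instead.
    """
    ids = _evaluated_probe_ids(matrix, annotation, probe_class)
    if not ids:
        raise DataError(f"no probes evaluated for class {probe_class!r}")
    sub = matrix.select(tissue, priming).loc[ids]
    vals = sub.to_numpy(dtype=float)
    if per_sample:
        finite = np.isfinite(vals)
        calls = vals >= params.detection_threshold
        n_eval = int(finite.sum())
        n_pos = int((calls & finite).sum())
        if n_eval == 0:
            raise DataError("no probes evaluated (all cells missing)")
        return DetectionSummary(probe_class, tissue, priming, n_eval, n_pos)
    keep = ~np.isnan(vals).any(axis=1)
    if (~keep).any():
        logger.info("positive_fraction: %d probe(s) with missing values excluded", int((~keep).sum()))
    vals = vals[keep]
    if vals.shape[0] == 0:
        raise DataError("no probes evaluated")
    medians = np.median(vals, axis=1)
    n_pos = int(np.sum(medians >= params.detection_threshold))
    return DetectionSummary(probe_class, tissue, priming, vals.shape[0], n_pos)


def gene_positive(
    gene_id: str,
    matrix: ExpressionMatrix,
    annotation: ProbeAnnotation,
    tissue: str,
    priming: str,
    params: ScreenParams,
) -> bool:
    """True iff ANY non-truncated antisense probe of the gene has a median
    intensity (across patients) at or above the threshold."""
    t = annotation.table
    sel = (t["gene_id"] == gene_id) & (t["probe_class"] == "afas") & (~t["truncated"])
    ids = [pid for pid in t.loc[sel, "probe_id"] if pid in matrix.probe_ids]
    if not ids:
        raise DataError(f"gene {gene_id!r} has no evaluable antisense probes")
    sub = matrix.select(tissue, priming).loc[ids].to_numpy(dtype=float)
    keep = ~np.isnan(sub).any(axis=1)
    sub = sub[keep]
    if sub.shape[0] == 0:
        raise DataError(f"gene {gene_id!r}: all antisense probes have missing values")
    return bool(np.any(np.median(sub, axis=1) >= params.detection_threshold))


def gene_positive_fraction(
    matrix: ExpressionMatrix,
    annotation: ProbeAnnotation,
    tissue: str,
    priming: str,
    params: ScreenParams,
) -> tuple[int, int, float]:
    """(n_positive genes, n_evaluated genes, percent) over all genes with
    at least one evaluable antisense probe."""
    t = annotation.table
    genes = sorted(
        t.loc[(t["probe_class"] == "afas") & (~t["truncated"]), "gene_id"].unique()
    )
    n_pos = n_eval = 0
    for gid in genes:
        try:
            pos = gene_positive(gid, matrix, annotation, tissue, priming, params)
        except DataError:
            continue
        n_eval += 1
        n_pos += pos
    if n_eval == 0:
        raise DataError("no genes evaluated")
    return n_pos, n_eval, 100.0 * n_pos / n_eval


def detection_summary_table(
    matrix: ExpressionMatrix,
    annotation: ProbeAnnotation,
    params: ScreenParams,
    per_sample: bool = False,
) -> pd.DataFrame:
    """Detection summaries for every (probe class, tissue, priming) combination."""
    rows = []
    for probe_class in ("sense", "afas"):
        for tissue in TISSUES:
            for priming in PRIMINGS:
                try:
                    s = positive_fraction(
                        matrix, annotation, probe_class, tissue, priming, params, per_sample
                    )
                except DataError:
                    continue
                rows.append(
                    {
                        "probe_class": s.probe_class,
                        "tissue": s.tissue,
                        "priming": s.priming,
                        "n_probes_evaluated": s.n_probes_evaluated,
                        "n_positive": s.n_positive,
                        "percent_positive": s.percent_positive,
                    }
                )
    return pd.DataFrame(
        rows,
        columns=[
            "probe_class",
            "tissue",
            "priming",
            "n_probes_evaluated",
            "n_positive",
            "percent_positive",
        ],
    )
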