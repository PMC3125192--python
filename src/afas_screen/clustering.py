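"""Hierarchical clustering of log2 sense/antisense ratios and displays.

The ratio matrix holds log2(sense/antisense) per pair and sample, with the
intensity floor applied to both strands so every entry is finite.  Rows are
clustered agglomeratively (correlation or euclidean distance; average,
complete or single linkage) with a deterministic smallest-index tie break.
The heat map saturates at +/- log2(3): full green at threefold-or-more
sense dominance, full red at threefold-or-more antisense dominance.
Clipping affects the display and its TSV copy only.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .io_model import DataError, ScreenParams
from .screens import PairProfile

logger = logging.getLogger("afas_screen")

CLIP_LOG2 = float(np.log2(3.0))
DISTANCES = ("correlation", "euclidean")
LINKAGES = ("average", "complete", "single")


@dataclass
class RatioMatrix:
    """Rows = pairs, columns = (patient, tissue) samples, values = log2 ratios."""

    values: pd.DataFrame

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.values.to_numpy(dtype=float))):
            raise DataError("ratio matrix must be finite everywhere")
        if self.values.index.has_duplicates:
            raise DataError("duplicate pair ids in ratio matrix")


def build_ratio_matrix(
    pairs: Sequence[PairProfile], params: ScreenParams, mode: str = "random"
) -> RatioMatrix:
    """log2(max(sense, floor) / max(afas, floor)) per pair and sample.

    Columns are all normal samples then all cancer samples, patients
    ascending; rows are keyed by antisense probe id.
    """
    if not pairs:
        raise DataError("no pairs to build a ratio matrix from")
    floor = params.intensity_floor
    patients = pairs[0].patients
    columns = [f"P{p:02d}_normal" for p in patients] + [f"P{p:02d}_cancer" for p in patients]
    rows = {}
    for p in pairs:
        normal = np.log2(np.maximum(p.sense_normal, floor) / np.maximum(p.afas_normal, floor))
        cancer = np.log2(np.maximum(p.sense_cancer, floor) / np.maximum(p.afas_cancer, floor))
        rows[p.afas_probe_id] = np.concatenate([normal, cancer])
    return RatioMatrix(pd.DataFrame.from_dict(rows, orient="index", columns=columns))


# ---------------------------------------------------------------------------
# Agglomerative clustering (deterministic tie-break by smallest row index)
# ---------------------------------------------------------------------------


def _pairwise_distance(x: np.ndarray, distance: str) -> np.ndarray:
    n = x.shape[0]
    if distance == "euclidean":
        diff = x[:, None, :] - x[None, :, :]
        return np.sqrt((diff**2).sum(axis=-1))
    if distance == "correlation":
        sd = x.std(axis=1)
        constant = sd == 0
        if constant.any():
            logger.warning(
                "%d constant row(s); correlation distance set to 1 for them",
                int(constant.sum()),
            )
        centered = x - x.mean(axis=1, keepdims=True)
        norms = np.linalg.norm(centered, axis=1)
        safe = np.where(constant, 1.0, norms)
        r = (centered @ centered.T) / np.outer(safe, safe)
        d = 1.0 - r
        d[constant, :] = 1.0
        d[:, constant] = 1.0
        np.fill_diagonal(d, 0.0)
        return np.clip(d, 0.0, None)
    raise DataError(f"distance must be one of {DISTANCES}, got {distance!r}")


def hierarchical_cluster(
    ratio: RatioMatrix | pd.DataFrame,
    distance: str = "correlation",
    linkage: str = "average",
) -> tuple[np.ndarray, list[str]]:
    """Agglomerate rows; returns (merge table, leaf order as row ids).

    The merge table has scipy-linkage layout: each row is
    (cluster_a, cluster_b, height, size) with original rows numbered
    0..n-1 and merged clusters n, n+1, ...  Ties in minimum distance are
    broken by the smaller (then smaller second) cluster id, so the result
    is deterministic and independent of dictionary iteration order.
    """
    if linkage not in LINKAGES:
        raise DataError(f"linkage must be one of {LINKAGES}, got {linkage!r}")
    frame = ratio.values if isinstance(ratio, RatioMatrix) else ratio
    ids = list(frame.index)
    n = len(ids)
    if n < 2:
        raise DataError("need at least 2 rows to cluster")
    d = _pairwise_distance(frame.to_numpy(dtype=float), distance)

    active: dict[int, int] = {i: 1 for i in range(n)}  # cluster id -> size
    dist: dict[tuple[int, int], float] = {
        (i, j): float(d[i, j]) for i in range(n) for j in range(i + 1, n)
    }
    members: dict[int, list[int]] = {i: [i] for i in range(n)}
    merges = np.zeros((n - 1, 4))
    next_id = n
    for step in range(n - 1):
        (a, b), height = min(dist.items(), key=lambda kv: (kv[1], kv[0]))
        sa, sb = active[a], active[b]
        new = next_id
        next_id += 1
        for other in list(active):
            if other in (a, b):
                continue
            da = dist.pop(tuple(sorted((a, other))))
            db = dist.pop(tuple(sorted((b, other))))
            if linkage == "average":
                dn = (sa * da + sb * db) / (sa + sb)
            elif linkage == "complete":
                dn = max(da, db)
            else:
                dn = min(da, db)
            dist[(min(other, new), max(other, new))] = dn
        dist.pop((a, b))
        del active[a], active[b]
        active[new] = sa + sb
        if min(members[a]) <= min(members[b]):
            members[new] = members[a] + members[b]
        else:
            members[new] = members[b] + members[a]
        merges[step] = (a, b, height, sa + sb)
    leaf_order = [ids[i] for i in members[next_id - 1]]
    return merges, leaf_order


def align_to_order(other: RatioMatrix, leaf_order: Sequence[str]) -> RatioMatrix:
    """Reorder rows of another ratio matrix to a given leaf order."""
    missing = [r for r in leaf_order if r not in other.values.index]
    if missing:
        raise DataError(f"row id(s) missing from matrix: {missing}")
    return RatioMatrix(other.values.loc[list(leaf_order)].copy())


# ---------------------------------------------------------------------------
# Exports
# ---------------------------------------------------------------------------


def to_newick(merges: np.ndarray, ids: Sequence[str]) -> str:
    """Merge table -> Newick with branch lengths = height differences."""
    n = len(ids)
    height = {i: 0.0 for i in range(n)}
    text = {i: str(ids[i]) for i in range(n)}
    for step, (a, b, h, _) in enumerate(merges):
        a, b = int(a), int(b)
        node = n + step
        height[node] = float(h)
        la = float(h) - height[a]
        lb = float(h) - height[b]
        text[node] = f"({text[a]}:{la:.17g},{text[b]}:{lb:.17g})"
    return text[n + len(merges) - 1] + ";"


def clip_ratios(values: np.ndarray, clip: float = CLIP_LOG2) -> np.ndarray:
    return np.clip(values, -clip, clip)


def heatmap_export(
    ratio: RatioMatrix,
    leaf_order: Sequence[str],
    merges: np.ndarray,
    out_dir: str | Path,
    name: str = "heatmap",
) -> dict[str, Path]:
    """Write the clipped heat map (PNG), the clipped TSV and the Newick tree.

    Colors saturate at |log2 ratio| = log2(3): green = sense-dominant,
    red = antisense-dominant, neutral at ratio 1.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    ordered = align_to_order(ratio, leaf_order)
    clipped = clip_ratios(ordered.values.to_numpy(dtype=float))

    fig, ax = plt.subplots(
        figsize=(max(4, 0.25 * clipped.shape[1]), max(3, 0.12 * clipped.shape[0]))
    )
    im = ax.imshow(
        clipped, aspect="auto", cmap="RdYlGn", vmin=-CLIP_LOG2, vmax=CLIP_LOG2,
        interpolation="nearest",
    )
    ax.set_xticks(range(clipped.shape[1]))
    ax.set_xticklabels(ordered.values.columns, rotation=90, fontsize=6)
    ax.set_yticks(range(clipped.shape[0]))
    ax.set_yticklabels(ordered.values.index, fontsize=5)
    fig.colorbar(im, ax=ax, label="log2(sense/antisense), clipped at +/-log2 3")
    fig.tight_layout()
    png = out / f"{name}.png"
    fig.savefig(png, dpi=150)
    plt.close(fig)

    tsv = out / f"{name}_clipped.tsv"
    clipped_frame = pd.DataFrame(
        clipped, index=ordered.values.index, columns=ordered.values.columns
    )
    clipped_frame.insert(0, "pair_id", clipped_frame.index)
    clipped_frame.to_csv(tsv, sep="\t", index=False, float_format="%.6g", lineterminator="\n")

    nwk = out / f"{name}.nwk"
    nwk.write_text(to_newick(merges, list(ratio.values.index)) + "\n", encoding="utf-8")
    return {"png": png, "tsv": tsv, "newick": nwk}
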