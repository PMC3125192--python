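"""Shared data model, TSV input/output, configuration and logging.

The pipeline exchanges three plain-text tables:

* an expression matrix (rows = probes, columns = samples),
* a sample-metadata table mapping each sample id to (patient, tissue,
  priming method),
* a probe-annotation table linking each probe to its gene and class.

All tables are tab-separated UTF-8 with LF line endings.  Missing
intensities are encoded as empty cells and surface as NaN; they are never
silently treated as zero.
"""

from __future__ import annotations

import hashlib
import logging
import tomllib
from dataclasses import dataclass, field, fields
from pathlib import Path
from typing import IO, Iterable, Mapping

import numpy as np
import pandas as pd

logger = logging.getLogger("afas_screen")

TISSUES = ("normal", "cancer")
PRIMINGS = ("oligo_dT", "random")

ANNOTATION_COLUMNS = ["probe_id", "gene_id", "probe_class", "afas_index", "truncated"]
METADATA_COLUMNS = ["sample_id", "patient_id", "tissue", "priming"]
BALANCE_RESULT_COLUMNS = ["afas_id", "gene_id", "direction", "support", "margin"]


class AfasError(Exception):
    """Base class for all package errors."""


class ConfigError(AfasError):
    """Invalid configuration value or key."""


class DataError(AfasError):
    """Malformed or inconsistent input data."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True, order=True)
class SampleKey:
    """Identity of one array: which patient, tissue and priming method."""

    patient_id: int
    tissue: str
    priming: str

    def __post_init__(self) -> None:
        if not (isinstance(self.patient_id, (int, np.integer)) and self.patient_id >= 1):
            raise DataError(f"patient_id must be an integer >= 1, got {self.patient_id!r}")
        if self.tissue not in TISSUES:
            raise DataError(f"tissue must be one of {TISSUES}, got {self.tissue!r}")
        if self.priming not in PRIMINGS:
            raise DataError(f"priming must be one of {PRIMINGS}, got {self.priming!r}")

    @property
    def sample_id(self) -> str:
        """Default human-readable id; the metadata table remains authoritative."""
        return f"P{self.patient_id:02d}_{self.tissue}_{self.priming}"


@dataclass
class ExpressionMatrix:
    """Probe x sample intensity table with attached sample keys.

    ``values`` is indexed by probe id with one column per sample id;
    ``samples`` is parallel to the columns.
    """

    values: pd.DataFrame
    samples: list[SampleKey]

    def __post_init__(self) -> None:
        if len(self.samples) != self.values.shape[1]:
            raise DataError(
                f"{self.values.shape[1]} matrix columns but {len(self.samples)} sample keys"
            )
        if self.values.index.has_duplicates:
            dups = self.values.index[self.values.index.duplicated()].unique().tolist()
            raise DataError(f"duplicate probe id(s): {dups}")
        if len(set(self.samples)) != len(self.samples):
            raise DataError("duplicate sample keys")
        vals = self.values.to_numpy(dtype=float)
        if np.any(vals[np.isfinite(vals)] < 0):
            bad = np.argwhere((vals < 0) & np.isfinite(vals))[0]
            raise DataError(
                f"negative intensity at probe {self.values.index[bad[0]]!r}, "
                f"sample {self.values.columns[bad[1]]!r}"
            )

    # -- convenience accessors ---------------------------------------------

    @property
    def probe_ids(self) -> pd.Index:
        return self.values.index

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def patients(self) -> list[int]:
        return sorted({k.patient_id for k in self.samples})

    def is_complete(self) -> bool:
        """True when every patient has all four (tissue, priming) arrays."""
        have = {(k.patient_id, k.tissue, k.priming) for k in self.samples}
        return all(
            (p, t, pr) in have for p in self.patients for t in TISSUES for pr in PRIMINGS
        )

    def columns_for(self, tissue: str, priming: str) -> list[str]:
        """Sample ids of the (tissue, priming) arrays, patients ascending."""
        picked = [
            (k.patient_id, sid)
            for k, sid in zip(self.samples, self.values.columns)
            if k.tissue == tissue and k.priming == priming
        ]
        return [sid for _, sid in sorted(picked)]

    def select(self, tissue: str, priming: str) -> pd.DataFrame:
        """Sub-matrix for one (tissue, priming), columns renamed to patient ids."""
        cols = self.columns_for(tissue, priming)
        sub = self.values[cols].copy()
        patient_of = {sid: k.patient_id for k, sid in zip(self.samples, self.values.columns)}
        sub.columns = [patient_of[c] for c in cols]
        return sub

    def copy(self) -> "ExpressionMatrix":
        return ExpressionMatrix(self.values.copy(), list(self.samples))


@dataclass
class ProbeAnnotation:
    """Probe -> gene mapping with probe class and truncation flags."""

    table: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in ANNOTATION_COLUMNS if c not in self.table.columns]
        if missing:
            raise DataError(f"annotation table missing column(s) {missing}")
        t = self.table
        if t["probe_id"].duplicated().any():
            dups = t.loc[t["probe_id"].duplicated(), "probe_id"].tolist()
            raise DataError(f"duplicate probe id(s) in annotation: {dups}")
        bad_class = set(t["probe_class"]) - {"sense", "afas"}
        if bad_class:
            raise DataError(f"unknown probe_class value(s): {sorted(bad_class)}")
        sense = t[t["probe_class"] == "sense"]
        if sense["truncated"].any():
            raise DataError("sense probes must have truncated = False")
        if sense["afas_index"].notna().any():
            raise DataError("sense probes must have afas_index absent")
        if sense["gene_id"].duplicated().any():
            dups = sense.loc[sense["gene_id"].duplicated(), "gene_id"].tolist()
            raise DataError(f"gene(s) with more than one sense probe: {dups}")
        afas = t[t["probe_class"] == "afas"]
        if afas["afas_index"].isna().any():
            bad = afas.loc[afas["afas_index"].isna(), "probe_id"].tolist()
            raise DataError(f"afas probe(s) without afas_index: {bad}")
        if afas.duplicated(subset=["gene_id", "afas_index"]).any():
            raise DataError("afas_index values must be unique within a gene")

    @property
    def afas(self) -> pd.DataFrame:
        return self.table[self.table["probe_class"] == "afas"]

    @property
    def sense(self) -> pd.DataFrame:
        return self.table[self.table["probe_class"] == "sense"]

    def sense_probe_of(self) -> dict[str, str]:
        """gene_id -> its single sense probe id."""
        return dict(zip(self.sense["gene_id"], self.sense["probe_id"]))

    def genes(self) -> list[str]:
        return sorted(self.table["gene_id"].unique())


@dataclass(frozen=True)
class ScreenParams:
    """Every numeric constant used by the screens, in one place."""

    detection_threshold: float = 100.0
    fold_change: float = 2.0
    dominance_fold: float = 3.0
    margin: float = 0.10
    min_support: int = 3
    n_patients: int = 6
    tile_step: int = 500
    probe_length: int = 60
    intensity_floor: float = 1.0
    n_shuffles: int = 1000
    seed: int = 0

    def __post_init__(self) -> None:
        positive = (
            "detection_threshold",
            "fold_change",
            "dominance_fold",
            "min_support",
            "n_patients",
            "tile_step",
            "probe_length",
            "intensity_floor",
            "n_shuffles",
        )
        for name in positive:
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be strictly positive, got {getattr(self, name)}")
        if not (0.0 < self.margin < 1.0):
            raise ConfigError(f"margin must lie in (0, 1), got {self.margin}")
        if self.min_support > self.n_patients:
            raise ConfigError(
                f"min_support ({self.min_support}) exceeds n_patients ({self.n_patients})"
            )
        if self.probe_length > self.tile_step:
            raise ConfigError(
                f"probe_length ({self.probe_length}) exceeds tile_step ({self.tile_step})"
            )


# ---------------------------------------------------------------------------
# Readers
# ---------------------------------------------------------------------------


def _as_text(source: str | Path | IO[str]) -> IO[str] | Path:
    if isinstance(source, (str, Path)):
        return Path(source)
    return source


def read_sample_metadata(source: str | Path | IO[str]) -> pd.DataFrame:
    meta = pd.read_csv(_as_text(source), sep="\t", dtype=str)
    missing = [c for c in METADATA_COLUMNS if c not in meta.columns]
    if missing:
        raise DataError(f"metadata table missing column(s) {missing}")
    if meta["sample_id"].duplicated().any():
        dups = meta.loc[meta["sample_id"].duplicated(), "sample_id"].tolist()
        raise DataError(f"duplicate sample id(s) in metadata: {dups}")
    try:
        meta["patient_id"] = meta["patient_id"].astype(int)
    except ValueError as exc:
        raise DataError(f"non-integer patient_id in metadata: {exc}") from exc
    return meta


def read_expression_table(
    matrix_source: str | Path | IO[str],
    metadata_source: str | Path | IO[str],
) -> ExpressionMatrix:
    """Read a probe x sample TSV plus its sample-metadata TSV.

    The matrix header row is ``probe_id`` followed by sample ids; every
    header sample id must appear in the metadata, and the returned column
    order follows the metadata row order.
    """
    meta = read_sample_metadata(metadata_source)
    raw = pd.read_csv(_as_text(matrix_source), sep="\t", dtype=str)
    if raw.columns[0] != "probe_id":
        raise DataError(
            f"expression matrix must start with a 'probe_id' column, got {raw.columns[0]!r}"
        )
    raw = raw.set_index("probe_id")
    if raw.index.has_duplicates:
        dups = raw.index[raw.index.duplicated()].unique().tolist()
        raise DataError(f"duplicate probe id(s) in matrix: {dups}")

    known = set(meta["sample_id"])
    unknown = [c for c in raw.columns if c not in known]
    if unknown:
        raise DataError(f"sample id(s) in matrix header absent from metadata: {unknown}")
    absent = [s for s in meta["sample_id"] if s not in raw.columns]
    if absent:
        raise DataError(f"metadata sample id(s) absent from matrix: {absent}")

    values = pd.DataFrame(index=raw.index)
    for col in meta["sample_id"]:
        text = raw[col]
        num = pd.to_numeric(text, errors="coerce")
        bad = num.isna() & text.notna() & (text.str.strip() != "")
        if bad.any():
            probe = raw.index[bad][0]
            raise DataError(
                f"non-numeric cell {text[bad].iloc[0]!r} at probe {probe!r}, sample {col!r}"
            )
        neg = num < 0
        if neg.any():
            probe = raw.index[neg][0]
            raise DataError(f"negative intensity at probe {probe!r}, sample {col!r}")
        values[col] = num.astype(float)

    keys = [
        SampleKey(int(r.patient_id), r.tissue, r.priming)
        for r in meta.itertuples(index=False)
    ]
    if len(set(keys)) != len(keys):
        raise DataError("metadata contains duplicate (patient, tissue, priming) keys")
    n_missing = int(values.isna().to_numpy().sum())
    if n_missing:
        logger.info("expression matrix contains %d missing cells", n_missing)
    return ExpressionMatrix(values, keys)


def read_probe_annotation(source: str | Path | IO[str]) -> ProbeAnnotation:
    t = pd.read_csv(
        _as_text(source),
        sep="\t",
        dtype={"probe_id": str, "gene_id": str, "probe_class": str},
    )
    missing = [c for c in ANNOTATION_COLUMNS if c not in t.columns]
    if missing:
        raise DataError(f"annotation table missing column(s) {missing}")
    t["afas_index"] = pd.to_numeric(t["afas_index"], errors="coerce").astype("Int64")
    if t["truncated"].dtype != bool:
        t["truncated"] = (
            t["truncated"].astype(str).str.strip().str.lower().map(
                {"true": True, "false": False, "1": True, "0": False}
            )
        )
        if t["truncated"].isna().any():
            raise DataError("truncated column must contain only true/false values")
        t["truncated"] = t["truncated"].astype(bool)
    return ProbeAnnotation(t[ANNOTATION_COLUMNS].copy())


def parse_config(config_text: str) -> ScreenParams:
    """Parse ``key = value`` (TOML) text into a validated ScreenParams.

    Absent keys take their defaults; unknown keys are rejected.
    """
    try:
        data = tomllib.loads(config_text)
    except tomllib.TOMLDecodeError as exc:
        raise ConfigError(f"malformed config: {exc}") from exc
    allowed = {f.name: f.type for f in fields(ScreenParams)}
    unknown = sorted(set(data) - set(allowed))
    if unknown:
        raise ConfigError(f"unknown config key(s): {unknown}")
    ints = {"min_support", "n_patients", "tile_step", "probe_length", "n_shuffles", "seed"}
    kwargs: dict[str, float | int] = {}
    for key, value in data.items():
        if isinstance(value, bool) or not isinstance(value, (int, float)):
            raise ConfigError(f"config key {key!r} must be numeric, got {value!r}")
        if key in ints:
            if int(value) != value:
                raise ConfigError(f"config key {key!r} must be an integer, got {value!r}")
            kwargs[key] = int(value)
        else:
            kwargs[key] = float(value)
    return ScreenParams(**kwargs)


# ---------------------------------------------------------------------------
# Writers
# ---------------------------------------------------------------------------


def _format_cell(x: object) -> str:
    if isinstance(x, (float, np.floating)):
        if np.isnan(x):
            return ""
        return f"{x:.6g}"
    if isinstance(x, (bool, np.bool_)):
        return "True" if x else "False"
    if x is None or (isinstance(x, float) and np.isnan(x)):
        return ""
    if x is pd.NA:
        return ""
    return str(x)


def write_results(tables: Mapping[str, pd.DataFrame], out_dir: str | Path) -> dict[str, Path]:
    """Write named result tables as deterministic TSV files.

    Floats are rendered at 6 significant digits, line endings are LF and
    encoding UTF-8, so identical inputs produce byte-identical files.
    Returns a manifest mapping table name to the written path.
    """
    out = Path(out_dir)
    try:
        out.mkdir(parents=True, exist_ok=True)
    except OSError as exc:
        raise DataError(f"cannot create output directory {out}: {exc}") from exc
    manifest: dict[str, Path] = {}
    for name, table in tables.items():
        path = out / f"{name}.tsv"
        lines = ["\t".join(map(str, table.columns))]
        for row in table.itertuples(index=False):
            lines.append("\t".join(_format_cell(v) for v in row))
        try:
            path.write_text("\n".join(lines) + "\n", encoding="utf-8", newline="\n")
        except OSError as exc:
            raise DataError(f"cannot write {path}: {exc}") from exc
        manifest[name] = path
    return manifest


def write_expression_table(
    matrix: ExpressionMatrix, matrix_path: str | Path, metadata_path: str | Path
) -> None:
    """Write matrix + metadata TSVs at full float precision (lossless round trip)."""
    values = matrix.values.copy()
    values.insert(0, "probe_id", values.index)
    values.to_csv(
        matrix_path, sep="\t", index=False, lineterminator="\n", float_format="%.17g"
    )
    meta = pd.DataFrame(
        {
            "sample_id": matrix.sample_ids,
            "patient_id": [k.patient_id for k in matrix.samples],
            "tissue": [k.tissue for k in matrix.samples],
            "priming": [k.priming for k in matrix.samples],
        }
    )
    meta.to_csv(metadata_path, sep="\t", index=False, lineterminator="\n")


def write_probe_annotation(annotation: ProbeAnnotation, path: str | Path) -> None:
    write_results({"_annotation": annotation.table}, Path(path).parent)
    (Path(path).parent / "_annotation.tsv").rename(path)


def file_checksum(path: str | Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def balance_results_table(results: Iterable) -> pd.DataFrame:
    """Tabulate BalanceScreenResult records with the canonical column order."""
    rows = [
        {
            "afas_id": r.afas_probe_id,
            "gene_id": r.gene_id,
            "direction": r.direction,
            "support": r.support,
            "margin": r.margin,
        }
        for r in results
    ]
    return pd.DataFrame(rows, columns=BALANCE_RESULT_COLUMNS)
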