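"""Tiling of antisense 60-mer probes along spliced transcripts.

Probes are placed every ``tile_step`` bases of the spliced (sense) mRNA and
emitted as the antisense-strand sequence (reverse complement of the sense
window).  A probe whose transcript window spans an exon-exon junction maps
to more than one genomic block and is flagged ``truncated``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import IO, Iterable

from Bio import SeqIO
from Bio.Seq import Seq

from .io_model import DataError, ScreenParams

logger = logging.getLogger("afas_screen")

_ALPHABET = set("ACGTN")


@dataclass
class GeneModel:
    """One gene: exon structure plus the spliced sense mRNA (5'->3')."""

    gene_id: str
    chrom: str
    strand: str
    exons: list[tuple[int, int]]  # genomic, 0-based half-open, ascending
    spliced_sequence: str

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise DataError(f"gene {self.gene_id}: strand must be '+' or '-'")
        prev_end = -1
        for start, end in self.exons:
            if not (0 <= start < end):
                raise DataError(f"gene {self.gene_id}: bad exon interval [{start},{end})")
            if start < prev_end:
                raise DataError(f"gene {self.gene_id}: overlapping or unsorted exons")
            prev_end = end
        total = sum(e - s for s, e in self.exons)
        if total != len(self.spliced_sequence):
            raise DataError(
                f"gene {self.gene_id}: exon lengths sum to {total} but spliced "
                f"sequence has {len(self.spliced_sequence)} bases"
            )
        bad = set(self.spliced_sequence.upper()) - _ALPHABET
        if bad:
            raise DataError(f"gene {self.gene_id}: invalid base(s) {sorted(bad)}")

    @property
    def length(self) -> int:
        return len(self.spliced_sequence)

    def exons_in_transcript_order(self) -> list[tuple[int, int]]:
        """Exons ordered 5'->3' along the transcript (reversed on - strand)."""
        return self.exons if self.strand == "+" else list(reversed(self.exons))

    def transcript_to_genomic(self, start: int, end: int) -> list[tuple[int, int]]:
        """Project a transcript interval [start, end) onto genomic blocks.

        Blocks are returned in transcript order; on the minus strand each
        block is still a genomic (ascending) interval.
        """
        if not (0 <= start < end <= self.length):
            raise DataError(
                f"gene {self.gene_id}: transcript window [{start},{end}) outside [0,{self.length})"
            )
        blocks: list[tuple[int, int]] = []
        offset = 0
        for gstart, gend in self.exons_in_transcript_order():
            elen = gend - gstart
            lo = max(start - offset, 0)
            hi = min(end - offset, elen)
            if lo < hi:
                if self.strand == "+":
                    blocks.append((gstart + lo, gstart + hi))
                else:
                    blocks.append((gend - hi, gend - lo))
            offset += elen
        return blocks


@dataclass
class ProbeRecord:
    """A fixed-length antisense probe at one transcript window."""

    probe_id: str
    gene_id: str
    window_start: int  # tile start (multiple of tile_step)
    length: int
    sequence: str
    truncated: bool
    genomic_blocks: list[tuple[int, int]] = field(default_factory=list)
    has_ambiguity: bool = False
    probe_start: int | None = None  # transcript start of the probe itself

    def __post_init__(self) -> None:
        if self.probe_start is None:
            self.probe_start = self.window_start


# ---------------------------------------------------------------------------
# GFF3 + FASTA loading
# ---------------------------------------------------------------------------

_ID_KEYS = ("gene_id", "transcript_id", "Parent", "ID")


def _gff_attributes(text: str) -> dict[str, str]:
    out: dict[str, str] = {}
    for item in text.strip().split(";"):
        if not item:
            continue
        if "=" in item:
            key, _, value = item.partition("=")
            out[key.strip()] = value.strip()
    return out


def load_gene_models(
    gff_source: str | Path | IO[str],
    fasta_source: str | Path | IO[str],
    gene_ids: Iterable[str] | None = None,
) -> list[GeneModel]:
    """Build GeneModels from GFF3 exon features plus a genome FASTA.

    GFF3 coordinates (1-based inclusive) are converted to 0-based half-open.
    Minus-strand spliced sequences are reverse complemented so that
    ``spliced_sequence`` is always the sense mRNA 5'->3'.
    """
    seqs = {
        rec.id: str(rec.seq).upper() for rec in SeqIO.parse(_handle(fasta_source), "fasta")
    }
    exons: dict[str, dict] = {}
    for line in _lines(gff_source):
        if not line.strip() or line.startswith("#"):
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 9:
            raise DataError(f"malformed GFF3 line: {line!r}")
        chrom, _, feat_type, start, end, _, strand, _, attrs = parts[:9]
        if feat_type.lower() != "exon":
            continue
        attributes = _gff_attributes(attrs)
        gid = next((attributes[k] for k in _ID_KEYS if k in attributes), None)
        if gid is None:
            raise DataError(f"exon feature without a gene identifier: {line!r}")
        if gene_ids is not None and gid not in set(gene_ids):
            continue
        entry = exons.setdefault(gid, {"chrom": chrom, "strand": strand, "ivals": []})
        if entry["chrom"] != chrom:
            raise DataError(f"gene {gid}: exons on multiple chromosomes")
        if entry["strand"] != strand:
            raise DataError(f"gene {gid}: mixed strands among exons")
        entry["ivals"].append((int(start) - 1, int(end)))

    models: list[GeneModel] = []
    for gid in sorted(exons):
        entry = exons[gid]
        chrom = entry["chrom"]
        if chrom not in seqs:
            raise DataError(f"gene {gid}: sequence {chrom!r} absent from FASTA")
        genome = seqs[chrom]
        ivals = sorted(entry["ivals"])
        for s, e in ivals:
            if e > len(genome):
                raise DataError(
                    f"gene {gid}: exon end {e} beyond sequence {chrom!r} length {len(genome)}"
                )
        spliced = "".join(genome[s:e] for s, e in ivals)
        if entry["strand"] == "-":
            spliced = str(Seq(spliced).reverse_complement())
        models.append(GeneModel(gid, chrom, entry["strand"], ivals, spliced))
    return models


def _handle(source):
    if isinstance(source, (str, Path)):
        return str(source)
    return source


def _lines(source) -> Iterable[str]:
    if isinstance(source, (str, Path)):
        with open(source, encoding="utf-8") as fh:
            yield from fh
    else:
        yield from source


# ---------------------------------------------------------------------------
# Tiling
# ---------------------------------------------------------------------------


def tile_afas_probes(
    gene: GeneModel, params: ScreenParams, placement: str = "start"
) -> list[ProbeRecord]:
    """Place one antisense probe per tile_step window of the spliced mRNA.

    Window starts run 0, tile_step, 2*tile_step, ... while at least
    ``probe_length`` bases remain.  Genes shorter than one probe yield an
    empty list (the gene is excluded, with a warning).  ``placement``
    chooses where inside each window the probe sits (``start`` or
    ``center``); with ``start`` the probe begins exactly at the window
    start.
    """
    if placement not in ("start", "center"):
        raise DataError(f"placement must be 'start' or 'center', got {placement!r}")
    L = gene.length
    plen = params.probe_length
    step = params.tile_step
    if L < plen:
        logger.warning("gene %s excluded: length %d < probe length %d", gene.gene_id, L, plen)
        return []
    probes: list[ProbeRecord] = []
    index = 0
    for w in range(0, L, step):
        if L - w < plen:
            break
        index += 1
        if placement == "start":
            pstart = w
        else:
            window_len = min(step, L - w)
            pstart = w + (window_len - plen) // 2
        probes.append(_make_probe(gene, pstart, w, index, plen))
    return probes


def _make_probe(gene: GeneModel, pstart: int, window_start: int, index: int, plen: int) -> ProbeRecord:
    sense_window = gene.spliced_sequence[pstart : pstart + plen].upper()
    sequence = str(Seq(sense_window).reverse_complement())
    blocks = gene.transcript_to_genomic(pstart, pstart + plen)
    has_n = "N" in sense_window
    if has_n:
        logger.warning(
            "probe %s-%02d contains ambiguous bases in its window", gene.gene_id, index
        )
    return ProbeRecord(
        probe_id=f"{gene.gene_id}-{index:02d}",
        gene_id=gene.gene_id,
        window_start=window_start,
        length=plen,
        sequence=sequence,
        truncated=len(blocks) > 1,
        genomic_blocks=blocks,
        has_ambiguity=has_n,
        probe_start=pstart,
    )


def flag_truncated(probe: ProbeRecord, gene: GeneModel) -> bool:
    """Re-derive the truncated flag: does the window span an exon junction?"""
    start = probe.probe_start if probe.probe_start is not None else probe.window_start
    blocks = gene.transcript_to_genomic(start, start + probe.length)
    return len(blocks) > 1


def probes_table(probes: Iterable[ProbeRecord]):
    """ProbeRecord list -> tidy table (for TSV export)."""
    import pandas as pd

    rows = [
        {
            "probe_id": p.probe_id,
            "gene_id": p.gene_id,
            "window_start": p.window_start,
            "length": p.length,
            "sequence": p.sequence,
            "truncated": p.truncated,
            "n_blocks": len(p.genomic_blocks),
            "has_ambiguity": p.has_ambiguity,
        }
        for p in probes
    ]
    return pd.DataFrame(
        rows,
        columns=[
            "probe_id",
            "gene_id",
            "window_start",
            "length",
            "sequence",
            "truncated",
            "n_blocks",
            "has_ambiguity",
        ],
    )
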