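"""Genome parsing, TIR/CDS extraction and gene-level quality filters.

Coordinate conventions
----------------------
External formats (GenBank, GFF3) are 1-based inclusive; all internal slicing
is 0-based half-open.  The translation initiation region (TIR) spans -25..+30
relative to the start codon with +1 being the *first base of the start codon*
and no position 0, i.e. 25 nt of upstream sequence followed by the first
30 nt of the CDS — 55 nt in total.  On the minus strand every coordinate is
interpreted on the reverse complement.  On circular contigs the upstream
window may wrap across the origin.
"""

from __future__ import annotations

import logging

from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

logger = logging.getLogger(__name__)

TIR_UPSTREAM = 25
TIR_DOWNSTREAM = 30  # counted from the first base of the start codon
TIR_LENGTH = TIR_UPSTREAM + TIR_DOWNSTREAM

DEFAULT_ALLOWED_STARTS = frozenset({"ATG", "GTG", "TTG"})
STOP_CODONS = frozenset({"TAA", "TAG", "TGA"})

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


class FormatError(ValueError):
    """Input file does not parse under the declared standard."""


class CoordinateError(ValueError):
    """Annotation coordinates fall outside the contig on a linear topology."""


class ExtractionError(ValueError):
    """Gene region extraction failed; carries a machine-readable reason."""

    def __init__(self, reason: str, message: str):
        super().__init__(message)
        self.reason = reason


@dataclass(frozen=True)
class GeneAnnotation:
    """One protein-coding gene on a contig, 1-based inclusive coordinates."""

    gene_id: str
    start: int
    end: int
    strand: str
    contig_id: str

    def __post_init__(self):
        if self.start > self.end:
            raise ValueError(f"{self.gene_id}: start {self.start} > end {self.end}")
        if self.strand not in {"+", "-"}:
            raise ValueError(f"{self.gene_id}: strand must be '+' or '-'")


@dataclass(frozen=True)
class GeneRegions:
    """TIR and CDS nucleotide strings for one gene (mRNA-sense strand)."""

    gene_id: str
    tir_seq: str
    cds_seq: str

    @property
    def start_codon(self) -> str:
        return self.cds_seq[:3]

    @property
    def stop_codon(self) -> str:
        return self.cds_seq[-3:]


@dataclass(frozen=True)
class ExpressionRecord:
    """Per-gene mean expression: mRNA abundance and protein mean/variance."""

    gene_id: str
    mrna_level: float
    protein_mean: float
    protein_variance: float = 0.0


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def _normalize(seq: str) -> str:
    return seq.upper().replace("U", "T")


# ---------------------------------------------------------------------------
# Parsing
# ---------------------------------------------------------------------------

def load_annotated_genome(
    path: str | Path,
    format: str = "genbank",
    annotation_path: str | Path | None = None,
) -> tuple[dict[str, str], list[GeneAnnotation]]:
    """Read a genome plus CDS annotations.

    Parameters
    ----------
    path:
        GenBank flat file, or the FASTA file when ``format="fasta+gff3"``.
    annotation_path:
        GFF3 companion file, required for ``format="fasta+gff3"``.

    Returns
    -------
    (contigs, annotations):
        contig_id -> uppercased, U->T-normalized nucleotide string, and a
        list of :class:`GeneAnnotation` (one per CDS feature).
    """
    path = Path(path)
    if format == "genbank":
        return _load_genbank(path)
    if format == "fasta+gff3":
        if annotation_path is None:
            raise FormatError(
                f"format 'fasta+gff3' requires a GFF3 companion for {path}"
            )
        return _load_fasta_gff3(path, Path(annotation_path))
    raise FormatError(f"unknown format {format!r}")


def _load_genbank(path: Path):
    from Bio import SeqIO

    contigs: dict[str, str] = {}
    annotations: list[GeneAnnotation] = []
    try:
        records = list(SeqIO.parse(str(path), "genbank"))
    except Exception as exc:  # biopython raises bare ValueError subclasses
        raise FormatError(f"cannot parse GenBank file {path}: {exc}") from exc
    if not records:
        raise FormatError(f"no GenBank records found in {path}")
    for rec in records:
        contigs[rec.id] = _normalize(str(rec.seq))
        for feat in rec.features:
            if feat.type != "CDS":
                continue
            quals = feat.qualifiers
            gene_id = (
                quals.get("locus_tag", [None])[0]
                or quals.get("gene", [None])[0]
                or quals.get("protein_id", [f"{rec.id}_{int(feat.location.start)}"])[0]
            )
            annotations.append(
                GeneAnnotation(
                    gene_id=gene_id,
                    start=int(feat.location.start) + 1,
                    end=int(feat.location.end),
                    strand="+" if feat.location.strand != -1 else "-",
                    contig_id=rec.id,
                )
            )
    _check_coordinates(contigs, annotations)
    return contigs, annotations


def _load_fasta_gff3(fasta_path: Path, gff3_path: Path):
    from Bio import SeqIO

    import gffutils

    try:
        records = list(SeqIO.parse(str(fasta_path), "fasta"))
    except Exception as exc:
        raise FormatError(f"cannot parse FASTA file {fasta_path}: {exc}") from exc
    if not records:
        raise FormatError(f"no FASTA records found in {fasta_path}")
    contigs = {rec.id: _normalize(str(rec.seq)) for rec in records}

    if not gff3_path.exists():
        raise FormatError(f"GFF3 companion {gff3_path} does not exist")
    try:
        db = gffutils.create_db(
            str(gff3_path),
            dbfn=":memory:",
            force=True,
            keep_order=True,
            merge_strategy="create_unique",
        )
    except Exception as exc:
        raise FormatError(f"cannot parse GFF3 file {gff3_path}: {exc}") from exc

    annotations = []
    for feat in db.features_of_type("CDS"):
        gene_id = feat.attributes.get("ID", [None])[0] or feat.attributes.get(
            "locus_tag", [f"{feat.seqid}_{feat.start}"]
        )[0]
        if feat.strand not in {"+", "-"}:
            raise FormatError(f"CDS {gene_id}: strand {feat.strand!r} in {gff3_path}")
        annotations.append(
            GeneAnnotation(
                gene_id=gene_id,
                start=feat.start,
                end=feat.end,
                strand=feat.strand,
                contig_id=feat.seqid,
            )
        )
    _check_coordinates(contigs, annotations)
    return contigs, annotations


def _check_coordinates(contigs, annotations):
    for ann in annotations:
        if ann.contig_id not in contigs:
            raise CoordinateError(f"{ann.gene_id}: unknown contig {ann.contig_id}")
        length = len(contigs[ann.contig_id])
        if ann.start < 1 or ann.end > length:
            raise CoordinateError(
                f"{ann.gene_id}: {ann.start}..{ann.end} outside contig "
                f"{ann.contig_id} (length {length})"
            )


# ---------------------------------------------------------------------------
# Region extraction
# ---------------------------------------------------------------------------

def _circular_slice(seq: str, start0: int, stop0: int) -> str:
    """0-based half-open slice on a circular sequence; indices may be out of range."""
    n = len(seq)
    return "".join(seq[i % n] for i in range(start0, stop0))


def extract_gene_regions(
    contigs: Mapping[str, str],
    annotation: GeneAnnotation,
    topology: str = "linear",
    tir_upstream: int = TIR_UPSTREAM,
    tir_downstream: int = TIR_DOWNSTREAM,
) -> GeneRegions:
    """Extract the TIR (default 55 nt) and the CDS for one gene.

    Raises :class:`ExtractionError` with ``reason`` of ``insufficient_upstream``
    (linear contig with fewer than ``tir_upstream`` nt before the start codon)
    or ``short_cds`` (CDS shorter than ``tir_downstream`` nt).
    """
    seq = contigs[annotation.contig_id]
    n = len(seq)
    a0, b0 = annotation.start - 1, annotation.end  # 0-based half-open CDS span
    cds_len = b0 - a0
    if cds_len < tir_downstream:
        raise ExtractionError(
            "short_cds",
            f"{annotation.gene_id}: CDS of {cds_len} nt is shorter than the "
            f"{tir_downstream} nt TIR window inside the CDS",
        )

    if annotation.strand == "+":
        up_start = a0 - tir_upstream
        if up_start < 0 and topology == "linear":
            raise ExtractionError(
                "insufficient_upstream",
                f"{annotation.gene_id}: only {a0} nt upstream on linear contig",
            )
        if topology == "circular":
            tir = _circular_slice(seq, up_start, a0 + tir_downstream)
        else:
            tir = seq[up_start : a0 + tir_downstream]
        cds = seq[a0:b0] if topology == "linear" else _circular_slice(seq, a0, b0)
    else:
        # start codon's first base sits at genomic position `end`
        up_stop = b0 + tir_upstream
        if up_stop > n and topology == "linear":
            raise ExtractionError(
                "insufficient_upstream",
                f"{annotation.gene_id}: only {n - b0} nt upstream on linear contig",
            )
        if topology == "circular":
            window = _circular_slice(seq, b0 - tir_downstream, up_stop)
            cds = reverse_complement(_circular_slice(seq, a0, b0))
        else:
            window = seq[b0 - tir_downstream : up_stop]
            cds = reverse_complement(seq[a0:b0])
        tir = reverse_complement(window)

    return GeneRegions(gene_id=annotation.gene_id, tir_seq=tir, cds_seq=cds)


def extract_all_regions(
    contigs: Mapping[str, str],
    annotations: Iterable[GeneAnnotation],
    topology: str = "linear",
) -> tuple[list[GeneRegions], list[tuple[str, str]]]:
    """Extract regions for every gene, skipping failures with a logged warning.

    Returns (regions, skipped) where skipped holds (gene_id, reason) pairs.
    """
    regions, skipped = [], []
    for ann in annotations:
        try:
            regions.append(extract_gene_regions(contigs, ann, topology=topology))
        except ExtractionError as exc:
            logger.warning("skipping %s: %s", ann.gene_id, exc)
            skipped.append((ann.gene_id, exc.reason))
    return regions, skipped


# ---------------------------------------------------------------------------
# Filters
# ---------------------------------------------------------------------------

def screen_aberrant_genes(
    regions: Sequence[GeneRegions],
    allowed_starts: frozenset[str] | set[str] = DEFAULT_ALLOWED_STARTS,
) -> tuple[list[GeneRegions], list[tuple[GeneRegions, str]]]:
    """Partition genes into valid and aberrant (frameshift / bad start / internal stop)."""
    valid: list[GeneRegions] = []
    aberrant: list[tuple[GeneRegions, str]] = []
    for reg in regions:
        cds = reg.cds_seq
        if len(cds) < 6 or len(cds) % 3 != 0:
            aberrant.append((reg, "frameshift"))
            continue
        if reg.start_codon not in allowed_starts:
            aberrant.append((reg, "nonsense_start_codon"))
            continue
        codons = [cds[i : i + 3] for i in range(0, len(cds) - 3, 3)]
        if any(c in STOP_CODONS for c in codons[1:]):
            aberrant.append((reg, "internal_stop"))
            continue
        valid.append(reg)
    return valid, aberrant


def flag_expression_outliers(
    records: Sequence[ExpressionRecord],
    sd_threshold: float = 3.0,
) -> tuple[list[ExpressionRecord], list[ExpressionRecord]]:
    """Remove genes deviating from the genome-wide mRNA/protein linear trend.

    Fits OLS of z(log10 protein mean) on z(log10 mRNA) and removes records
    whose absolute residual exceeds ``sd_threshold`` residual standard
    deviations.  Operates in log10 space because abundances span orders of
    magnitude.
    """
    if len(records) < 10:
        raise ValueError("need at least 10 records to fit the outlier filter")
    for r in records:
        if r.mrna_level <= 0 or r.protein_mean <= 0:
            raise ValueError(f"{r.gene_id}: nonpositive abundance")
    x = np.log10([r.mrna_level for r in records])
    y = np.log10([r.protein_mean for r in records])
    xz = (x - x.mean()) / x.std()
    yz = (y - y.mean()) / y.std()
    slope = float(xz @ yz) / float(xz @ xz)
    resid = yz - slope * xz
    sd = resid.std()
    if sd < 1e-12:  # numerically collinear: no outliers
        return list(records), []
    mask = np.abs(resid) > sd_threshold * sd
    kept = [r for r, m in zip(records, mask) if not m]
    removed = [r for r, m in zip(records, mask) if m]
    return kept, removed


# ---------------------------------------------------------------------------
# Tabular I/O
# ---------------------------------------------------------------------------

def write_regions_tsv(regions: Sequence[GeneRegions], path: str | Path) -> None:
    import pandas as pd

    pd.DataFrame(
        {
            "gene_id": [r.gene_id for r in regions],
            "tir_seq": [r.tir_seq for r in regions],
            "cds_seq": [r.cds_seq for r in regions],
            "start_codon": [r.start_codon for r in regions],
            "stop_codon": [r.stop_codon for r in regions],
        }
    ).to_csv(path, sep="\t", index=False)


def write_filter_report(
    entries: Sequence[tuple[str, str]], path: str | Path
) -> None:
    """Write (gene_id, reason_code) pairs from extraction/screening filters."""
    import pandas as pd

    pd.DataFrame(entries, columns=["gene_id", "reason"]).to_csv(
        path, sep="\t", index=False
    )


def read_expression_tsv(path: str | Path) -> list[ExpressionRecord]:
    """Read gene_id / mrna_level / protein_mean / protein_variance (or cov)."""
    import pandas as pd

    df = pd.read_csv(path, sep="\t")
    records = []
    for _, row in df.iterrows():
        if "protein_variance" in df.columns:
            var = float(row["protein_variance"])
        elif "protein_cov" in df.columns:
            var = (float(row["protein_cov"]) * float(row["protein_mean"])) ** 2
        else:
            var = 0.0
        records.append(
            ExpressionRecord(
                gene_id=str(row["gene_id"]),
                mrna_level=float(row["mrna_level"]),
                protein_mean=float(row["protein_mean"]),
                protein_variance=var,
            )
        )
    return records


def write_expression_tsv(records: Sequence[ExpressionRecord], path: str | Path) -> None:
    import pandas as pd

    pd.DataFrame(
        {
            "gene_id": [r.gene_id for r in records],
            "mrna_level": [r.mrna_level for r in records],
            "protein_mean": [r.protein_mean for r in records],
            "protein_variance": [r.protein_variance for r in records],
        }
    ).to_csv(path, sep="\t", index=False)
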