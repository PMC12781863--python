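"""Transcript models and transcript<->genome coordinate projection.

A :class:`TranscriptModel` stores exons in transcription order (for minus
strand transcripts that is descending genomic coordinates) and provides the
coordinate lifting used by the realignment map-back stage and by
pseudoexon annotation.  Exactly one transcript per gene is flagged
*representative* in any loaded annotation set: the MANE-tagged transcript
when the GTF carries one, otherwise the longest-CDS transcript (ties broken
by transcript ID) — a deterministic fallback.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import gffutils

from splicedx.intervals import GenomeInterval


class AnnotationError(ValueError):
    """Raised for malformed annotation input."""


@dataclass
class TranscriptModel:
    """Exon structure, strand and CDS of one transcript isoform.

    ``exons`` are in transcription order; ``cds_start_tx``/``cds_end_tx``
    are 1-based transcript coordinates (None for noncoding transcripts).
    """

    tx_id: str
    gene_id: str
    gene_symbol: str
    exons: list[GenomeInterval]
    cds_start_tx: int | None = None
    cds_end_tx: int | None = None
    is_mane: bool = False
    is_representative: bool = False
    biotype: str = "coding"

    def __post_init__(self) -> None:
        if not self.exons:
            raise AnnotationError(f"{self.tx_id}: transcript without exons")
        chroms = {e.chrom for e in self.exons}
        strands = {e.strand for e in self.exons}
        if len(chroms) != 1 or len(strands) != 1:
            raise AnnotationError(f"{self.tx_id}: exons on mixed chrom/strand")
        ordered = sorted(self.exons, key=lambda e: e.start)
        for a, b in zip(ordered, ordered[1:]):
            if a.end > b.start:
                raise AnnotationError(f"{self.tx_id}: overlapping exons")
        # normalize to transcription order
        self.exons = ordered if self.strand == "+" else ordered[::-1]
        if self.cds_start_tx is not None and self.cds_end_tx is not None:
            if not (1 <= self.cds_start_tx <= self.cds_end_tx <= self.length):
                raise AnnotationError(f"{self.tx_id}: CDS outside transcript")
        self.biotype = "coding" if self.cds_start_tx is not None else "noncoding"

    @property
    def chrom(self) -> str:
        return self.exons[0].chrom

    @property
    def strand(self) -> str:
        return self.exons[0].strand

    @property
    def length(self) -> int:
        return sum(len(e) for e in self.exons)

    @property
    def cds_length(self) -> int:
        if self.cds_start_tx is None:
            return 0
        return self.cds_end_tx - self.cds_start_tx + 1

    def introns(self) -> list[GenomeInterval]:
        """Introns in transcription order, genomic coordinates."""
        out = []
        for a, b in zip(self.exons, self.exons[1:]):
            if self.strand == "+":
                out.append(GenomeInterval(self.chrom, a.end, b.start, "+"))
            else:
                out.append(GenomeInterval(self.chrom, b.end, a.start, "-"))
        return out

    # -- coordinate projection -------------------------------------------

    def project_tx_to_genome(self, pos_tx: int) -> int:
        """Genome coordinate (0-based) of 1-based transcript position."""
        if not 1 <= pos_tx <= self.length:
            raise IndexError(
                f"{self.tx_id}: transcript position {pos_tx} outside [1, {self.length}]"
            )
        off = pos_tx - 1
        for exon in self.exons:
            if off < len(exon):
                if self.strand == "+":
                    return exon.start + off
                return exon.end - 1 - off
            off -= len(exon)
        raise AssertionError("unreachable")

    def project_genome_to_tx(self, pos_genome: int) -> int:
        """1-based transcript coordinate of an exonic genome position."""
        consumed = 0
        for exon in self.exons:
            if exon.start <= pos_genome < exon.end:
                if self.strand == "+":
                    return consumed + (pos_genome - exon.start) + 1
                return consumed + (exon.end - 1 - pos_genome) + 1
            consumed += len(exon)
        raise IndexError(f"{self.tx_id}: genome position {pos_genome} not exonic")

    def exon_tx_bounds(self) -> list[tuple[int, int]]:
        """Per exon (transcription order): 1-based inclusive transcript span."""
        bounds, pos = [], 1
        for exon in self.exons:
            bounds.append((pos, pos + len(exon) - 1))
            pos += len(exon)
        return bounds

    def splice(self, genome: dict[str, str]) -> str:
        """Spliced transcript sequence from a genome sequence dict."""
        comp = str.maketrans("ACGTacgt", "TGCAtgca")
        parts = []
        for exon in self.exons:
            seq = genome[self.chrom][exon.start : exon.end]
            if self.strand == "-":
                seq = seq.translate(comp)[::-1]
            parts.append(seq)
        return "".join(parts)


def _validate_gtf_lines(text: str) -> None:
    for i, line in enumerate(text.splitlines(), start=1):
        if not line.strip() or line.startswith("#"):
            continue
        fields = line.split("\t")
        if len(fields) != 9:
            raise AnnotationError(f"malformed GTF line {i}: expected 9 fields, got {len(fields)}")
        try:
            int(fields[3]), int(fields[4])
        except ValueError:
            raise AnnotationError(f"malformed GTF line {i}: non-integer coordinates") from None


def load_annotation(gtf_source: str) -> dict[str, TranscriptModel]:
    """Load transcript models from a GTF file path or GTF text.

    Honours the Ensembl-dialect attributes ``gene_id``, ``transcript_id``,
    ``gene_name`` and ``tag "MANE_Select"``.  Genes without a MANE tag get
    the longest-CDS transcript as representative (ties: lexicographically
    smallest transcript ID).  Returns ``{tx_id: TranscriptModel}``.
    """
    if "\t" in gtf_source or "\n" in gtf_source:
        text = gtf_source
    else:
        with open(gtf_source) as fh:
            text = fh.read()
    _validate_gtf_lines(text)
    db = gffutils.create_db(
        text,
        dbfn=":memory:",
        from_string=True,
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
        disable_infer_genes=True,
        disable_infer_transcripts=True,
    )

    exons_by_tx: dict[str, list[GenomeInterval]] = {}
    cds_by_tx: dict[str, list[tuple[int, int]]] = {}
    meta: dict[str, dict] = {}
    for feat in db.all_features():
        if feat.featuretype not in ("exon", "CDS"):
            continue
        tx_id = feat.attributes.get("transcript_id", [None])[0]
        if tx_id is None:
            continue
        if tx_id not in meta:
            meta[tx_id] = {
                "gene_id": feat.attributes.get("gene_id", ["."])[0],
                "gene_symbol": feat.attributes.get(
                    "gene_name", feat.attributes.get("gene_id", ["."])
                )[0],
                "mane": False,
            }
        if "MANE_Select" in feat.attributes.get("tag", []):
            meta[tx_id]["mane"] = True
        iv = GenomeInterval(feat.seqid, feat.start - 1, feat.end, feat.strand)
        if feat.featuretype == "exon":
            exons_by_tx.setdefault(tx_id, []).append(iv)
        else:
            cds_by_tx.setdefault(tx_id, []).append((iv.start, iv.end))

    models: dict[str, TranscriptModel] = {}
    for tx_id, m in meta.items():
        exons = exons_by_tx.get(tx_id)
        if not exons:
            warnings.warn(f"transcript {tx_id} has no exon features; skipped")
            continue
        tx = TranscriptModel(
            tx_id=tx_id,
            gene_id=m["gene_id"],
            gene_symbol=m["gene_symbol"],
            exons=exons,
            is_mane=m["mane"],
        )
        cds = cds_by_tx.get(tx_id)
        if cds:
            gpos = [p for s, e in cds for p in (s, e - 1)]
            tpos = [tx.project_genome_to_tx(g) for g in gpos]
            tx.cds_start_tx, tx.cds_end_tx = min(tpos), max(tpos)
            tx.biotype = "coding"
        models[tx_id] = tx

    # representative flags: one per gene
    by_gene: dict[str, list[TranscriptModel]] = {}
    for tx in models.values():
        by_gene.setdefault(tx.gene_id, []).append(tx)
    for gene_txs in by_gene.values():
        mane = [t for t in gene_txs if t.is_mane]
        if mane:
            rep = sorted(mane, key=lambda t: t.tx_id)[0]
        else:
            rep = sorted(gene_txs, key=lambda t: (-t.cds_length, t.tx_id))[0]
        for t in gene_txs:
            t.is_representative = t is rep
    return models


def representative_of(models: dict[str, TranscriptModel], gene_symbol: str) -> TranscriptModel:
    """The representative transcript of a gene (by symbol)."""
    for tx in models.values():
        if tx.gene_symbol == gene_symbol and tx.is_representative:
            return tx
    raise KeyError(f"no representative transcript for gene {gene_symbol!r}")
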