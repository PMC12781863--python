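"""Realignment of reads against representative transcript sequences.

Small indels hugging exon boundaries are routinely missed by genome
spliced aligners: the few junction-spanning bases are absorbed into
soft-clips or misassigned to introns, so no novel junction ever appears
in the splice-junction tables.  Aligning the same reads against the
contiguous *transcript* sequence turns the event into an ordinary gapped
alignment.  This module provides

* a k-mer-anchored, windowed affine-gap aligner for reads against a
  small transcript set (desk scale; external aligner output can be
  substituted),
* a pileup indel caller with VCF-style left-normalization,
* case-unique retention (indels seen in any case sample and no control),
* genome map-back that discards calls reproducing the exon structure of
  a naturally occurring annotated isoform.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
from numba import njit

from splicedx.annotation import TranscriptModel
from splicedx.intervals import GenomeInterval

_COMP = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


@dataclass
class GapOp:
    """One indel operation from a read alignment, transcript coordinates."""

    op: str  # "ins" (bases present in read only) or "del" (transcript only)
    tx_pos: int  # 1-based position of the first event base (del) / first base after anchor (ins)
    seq: str  # inserted or deleted sequence


@dataclass
class ReadAlignment:
    read_id: str
    tx_id: str
    score: int
    tx_start: int  # 1-based first aligned transcript base
    tx_end: int  # 1-based last aligned transcript base
    strand: str
    gap_ops: list[GapOp] = field(default_factory=list)
    n_mismatch: int = 0


@dataclass
class TranscriptIndelCall:
    tx_id: str
    pos_tx: int  # 1-based last matching base before the event
    ref_allele: str
    alt_allele: str
    length: int  # signed; negative = deletion from transcript
    supporting_reads: int
    samples_observed: set[str] = field(default_factory=set)

    @property
    def key(self) -> tuple:
        return (self.tx_id, self.pos_tx, self.ref_allele, self.alt_allele)


@dataclass
class GenomeInterpretation:
    interval: GenomeInterval
    classification: str  # matches_annotated_isoform | novel_event
    matching_isoform_id: str | None = None


# ---------------------------------------------------------------------------
# aligner


@njit(cache=False)
def _fit_align(read, target, match, mismatch, gap_open, gap_extend):
    """Affine-gap (Gotoh) fit alignment: read global, target-end gaps free.

    Returns (score, end_j, P, PE, PF).  P codes the H-state choice
    (1 diagonal, 2 gap-in-target/up, 3 gap-in-read/left); PE/PF record
    whether the gap states opened (1) or extended (0), which the
    traceback needs to keep long gaps contiguous.
    """
    m, n = read.shape[0], target.shape[0]
    NEG = -10_000
    H = np.full((m + 1, n + 1), NEG, dtype=np.int32)
    E = np.full((m + 1, n + 1), NEG, dtype=np.int32)  # gap in target (up)
    F = np.full((m + 1, n + 1), NEG, dtype=np.int32)  # gap in read (left)
    P = np.zeros((m + 1, n + 1), dtype=np.uint8)
    PE = np.zeros((m + 1, n + 1), dtype=np.uint8)
    PF = np.zeros((m + 1, n + 1), dtype=np.uint8)
    for j in range(n + 1):
        H[0, j] = 0  # free leading target bases
    for i in range(1, m + 1):
        E[i, 0] = gap_open + (i - 1) * gap_extend
        H[i, 0] = E[i, 0]
        P[i, 0] = 2
        PE[i, 0] = 1 if i == 1 else 0
    for i in range(1, m + 1):
        for j in range(1, n + 1):
            s = match if read[i - 1] == target[j - 1] else mismatch
            diag = H[i - 1, j - 1] + s
            e_open = H[i - 1, j] + gap_open
            e_ext = E[i - 1, j] + gap_extend
            if e_open >= e_ext:
                E[i, j] = e_open
                PE[i, j] = 1
            else:
                E[i, j] = e_ext
                PE[i, j] = 0
            f_open = H[i, j - 1] + gap_open
            f_ext = F[i, j - 1] + gap_extend
            if f_open >= f_ext:
                F[i, j] = f_open
                PF[i, j] = 1
            else:
                F[i, j] = f_ext
                PF[i, j] = 0
            best = diag
            ptr = 1
            if E[i, j] > best:
                best = E[i, j]
                ptr = 2
            if F[i, j] > best:
                best = F[i, j]
                ptr = 3
            H[i, j] = best
            P[i, j] = ptr
    best_j = 0
    best_score = NEG
    for j in range(n + 1):
        if H[m, j] > best_score:
            best_score = H[m, j]
            best_j = j
    return best_score, best_j, P, PE, PF


def _traceback(P, PE, PF, m: int, end_j: int) -> list[tuple[str, int, int]]:
    """State-aware Gotoh traceback: (op, read_pos0, target_pos0), op in M/I/D."""
    ops = []
    i, j = m, end_j
    state = 0  # 0 = H, 1 = E (up), 2 = F (left)
    while i > 0:
        if state == 0:
            ptr = P[i, j]
            if ptr == 1:
                ops.append(("M", i - 1, j - 1))
                i, j = i - 1, j - 1
            elif ptr == 2:
                state = 1
            else:
                state = 2
        elif state == 1:
            ops.append(("I", i - 1, j))  # read base not in target
            opened = PE[i, j]
            i -= 1
            state = 0 if opened else 1
        else:
            ops.append(("D", i, j - 1))  # target base not in read
            opened = PF[i, j]
            j -= 1
            state = 0 if opened else 2
    ops.reverse()
    return ops


class TranscriptAligner:
    """K-mer-anchored windowed affine-gap aligner over a transcript set."""

    def __init__(
        self,
        sequences: Mapping[str, str],
        k: int = 15,
        band: int = 60,
        match: int = 1,
        mismatch: int = -2,
        gap_open: int = -4,
        gap_extend: int = -1,
        min_score_frac: float = 0.25,
    ):
        if not sequences:
            raise ValueError("empty transcript set")
        if len(set(sequences)) != len(sequences):
            raise ValueError("duplicate transcript IDs")
        self.params = dict(
            k=k, band=band, match=match, mismatch=mismatch,
            gap_open=gap_open, gap_extend=gap_extend,
        )
        self.k = k
        self.band = band
        self.match, self.mismatch = match, mismatch
        self.gap_open, self.gap_extend = gap_open, gap_extend
        self.min_score_frac = min_score_frac
        self.tx_ids = list(sequences)
        self.seqs = {t: s.upper() for t, s in sequences.items()}
        self.arrs = {
            t: np.frombuffer(s.encode(), dtype=np.uint8) for t, s in self.seqs.items()
        }
        self.index: dict[str, list[tuple[str, int]]] = {}
        for tx, seq in self.seqs.items():
            for pos in range(0, len(seq) - k + 1):
                self.index.setdefault(seq[pos : pos + k], []).append((tx, pos))

    @classmethod
    def from_fasta(cls, path: str, **kwargs) -> "TranscriptAligner":
        from Bio import SeqIO

        seqs: dict[str, str] = {}
        for rec in SeqIO.parse(path, "fasta"):
            if rec.id in seqs:
                raise ValueError(f"duplicate transcript ID {rec.id!r} in {path}")
            seqs[rec.id] = str(rec.seq)
        return cls(seqs, **kwargs)

    def _candidates(self, read: str) -> list[tuple[str, int]]:
        """Candidate (tx_id, approximate target start) anchors for a read."""
        votes: dict[tuple[str, int], int] = {}
        step = max(1, (len(read) - self.k) // 8) if len(read) > self.k else 1
        for off in range(0, max(1, len(read) - self.k + 1), step):
            kmer = read[off : off + self.k]
            for tx, pos in self.index.get(kmer, ()):
                diag = (pos - off) // self.band  # coarse diagonal bucket
                votes[(tx, diag)] = votes.get((tx, diag), 0) + 1
        ranked = sorted(votes.items(), key=lambda kv: -kv[1])[:4]
        return [(tx, diag * self.band) for (tx, diag), _ in ranked]

    def _align_oriented(self, read: str) -> ReadAlignment | None:
        best: ReadAlignment | None = None
        arr_read = np.frombuffer(read.encode(), dtype=np.uint8)
        for tx, approx in self._candidates(read):
            target = self.arrs[tx]
            lo = max(0, approx - self.band)
            hi = min(len(target), approx + len(read) + self.band)
            window = target[lo:hi]
            score, end_j, P, PE, PF = _fit_align(
                arr_read, window, self.match, self.mismatch, self.gap_open, self.gap_extend
            )
            if best is not None and score <= best.score:
                continue
            aln = self._ops_to_alignment(
                read, tx, lo, int(score), _traceback(P, PE, PF, len(read), int(end_j))
            )
            if best is None or aln.score > best.score:
                best = aln
        return best

    def _ops_to_alignment(
        self, read: str, tx: str, window_lo: int, score: int, walk
    ) -> ReadAlignment:
        seq = self.seqs[tx]
        gap_ops: list[GapOp] = []
        n_mm = 0
        tx_positions = [window_lo + t for op, r, t in walk if op in ("M", "D")]
        tx_start = (min(tx_positions) + 1) if tx_positions else 1
        tx_end = (max(tx_positions) + 1) if tx_positions else 1
        i = 0
        while i < len(walk):
            op, r, t = walk[i]
            if op == "M":
                if read[r] != seq[window_lo + t]:
                    n_mm += 1
                i += 1
            elif op == "D":
                j = i
                while j < len(walk) and walk[j][0] == "D":
                    j += 1
                start_t = window_lo + walk[i][2]
                length = j - i
                # leading/trailing free target gaps are not events
                if i > 0 and j < len(walk):
                    gap_ops.append(
                        GapOp(op="del", tx_pos=start_t + 1, seq=seq[start_t : start_t + length])
                    )
                i = j
            else:  # I
                j = i
                while j < len(walk) and walk[j][0] == "I":
                    j += 1
                ins_seq = read[walk[i][1] : walk[j - 1][1] + 1]
                anchor_t = window_lo + walk[i][2]  # target pos after which insertion sits
                if i > 0 and j < len(walk):
                    gap_ops.append(GapOp(op="ins", tx_pos=anchor_t + 1, seq=ins_seq))
                i = j
        return ReadAlignment(
            read_id="", tx_id=tx, score=score, tx_start=tx_start, tx_end=tx_end,
            strand="+", gap_ops=gap_ops, n_mismatch=n_mm,
        )

    def align_read(self, read_id: str, read: str) -> ReadAlignment | None:
        """Best-scoring alignment over both strands; None below min score."""
        read = read.upper()
        fwd = self._align_oriented(read)
        rev = self._align_oriented(revcomp(read))
        best, strand = fwd, "+"
        if rev is not None and (best is None or rev.score > best.score):
            best, strand = rev, "-"
        if best is None or best.score < self.min_score_frac * len(read) * self.match:
            return None
        best.read_id = read_id
        best.strand = strand
        return best

    def align_reads(self, reads: Iterable[tuple[str, str]]) -> list[ReadAlignment]:
        out = []
        for read_id, seq in reads:
            aln = self.align_read(read_id, seq)
            if aln is not None:
                out.append(aln)
        return out


def read_fastq(path: str) -> list[tuple[str, str]]:
    from Bio import SeqIO

    return [(rec.id, str(rec.seq)) for rec in SeqIO.parse(path, "fastq")]


# ---------------------------------------------------------------------------
# indel calling


def _left_normalize(seq: str, kind: str, start: int, allele: str) -> tuple[int, str]:
    """Shift an indel to its leftmost equivalent position on ``seq``.

    For a deletion, ``start`` is the 1-based position of the first
    deleted base; for an insertion, the 1-based position of the base
    *before which* the payload is inserted.  Both shift left one base at
    a time while the resulting modified sequence is unchanged.
    """
    s, a, L = start, allele, len(allele)
    if kind == "del":
        # deleting s..s+L-1 == deleting s-1..s+L-2 iff seq[s-1] == seq[s+L-1] (1-based)
        while s > 1 and s + L - 2 < len(seq) and seq[s - 2] == seq[s + L - 2]:
            s -= 1
        a = seq[s - 1 : s - 1 + L]
    else:
        # inserting A before s == inserting A' before s-1 iff seq[s-1] == A[-1]
        while s > 1 and seq[s - 2] == a[-1]:
            s -= 1
            a = seq[s - 1] + a[:-1]
    return s, a


def _consolidate(calls: list[TranscriptIndelCall], window: int = 60) -> list[TranscriptIndelCall]:
    """Suppress weaker calls near a stronger one on the same transcript.

    Reads with short flanks across a large indel admit mosaic gap
    decompositions that pile up as low-support satellite calls around
    the true event; keeping only the best-supported call per locus
    removes them (two genuinely distinct indels closer than ``window``
    nt would be merged — accepted for a targeted diagnostic caller).
    """
    kept: list[TranscriptIndelCall] = []
    for call in sorted(calls, key=lambda c: (-c.supporting_reads, -abs(c.length), c.pos_tx)):
        if any(
            k.tx_id == call.tx_id and abs(k.pos_tx - call.pos_tx) <= window
            for k in kept
        ):
            continue
        kept.append(call)
    return sorted(kept, key=lambda c: c.key)


def call_indels(
    alignments_by_sample: Mapping[str, Iterable[ReadAlignment]],
    sequences: Mapping[str, str],
    min_support: int = 3,
    min_len: int = 3,
    consolidation_window: int = 60,
) -> dict[str, list[TranscriptIndelCall]]:
    """Pileup gap operations into left-normalized indel calls per sample."""
    out: dict[str, list[TranscriptIndelCall]] = {}
    for sample, alns in alignments_by_sample.items():
        piles: dict[tuple, int] = {}
        for aln in alns:
            seq = sequences[aln.tx_id].upper()
            for gap in aln.gap_ops:
                if gap.op == "del":
                    start, allele = _left_normalize(seq, "del", gap.tx_pos, gap.seq)
                    key = (aln.tx_id, start, "del", allele)
                else:
                    start, allele = _left_normalize(seq, "ins", gap.tx_pos, gap.seq)
                    key = (aln.tx_id, start, "ins", allele)
                piles[key] = piles.get(key, 0) + 1
        calls = []
        for (tx_id, start, kind, allele), support in sorted(piles.items()):
            if support < min_support or len(allele) < min_len:
                continue
            seq = sequences[tx_id].upper()
            anchor = seq[start - 2] if start >= 2 else ""
            if kind == "del":
                call = TranscriptIndelCall(
                    tx_id=tx_id,
                    pos_tx=start - 1,
                    ref_allele=anchor + allele,
                    alt_allele=anchor or "-",
                    length=-len(allele),
                    supporting_reads=support,
                    samples_observed={sample},
                )
            else:
                call = TranscriptIndelCall(
                    tx_id=tx_id,
                    pos_tx=start - 1,
                    ref_allele=anchor or "-",
                    alt_allele=anchor + allele,
                    length=len(allele),
                    supporting_reads=support,
                    samples_observed={sample},
                )
            calls.append(call)
        out[sample] = _consolidate(calls, consolidation_window) if consolidation_window else calls
    return out


def retain_case_unique(
    case_calls: Mapping[str, Iterable[TranscriptIndelCall]],
    control_calls: Mapping[str, Iterable[TranscriptIndelCall]],
) -> list[TranscriptIndelCall]:
    """Indels observed in >= 1 case sample and in no control sample."""
    overlap = set(case_calls) & set(control_calls)
    if overlap:
        raise ValueError(f"samples present in both case and control sets: {sorted(overlap)}")
    control_keys = {c.key for calls in control_calls.values() for c in calls}
    merged: dict[tuple, TranscriptIndelCall] = {}
    for sample, calls in case_calls.items():
        for c in calls:
            if c.key in control_keys:
                continue
            if c.key in merged:
                merged[c.key].supporting_reads += c.supporting_reads
                merged[c.key].samples_observed |= c.samples_observed
            else:
                merged[c.key] = TranscriptIndelCall(
                    tx_id=c.tx_id, pos_tx=c.pos_tx, ref_allele=c.ref_allele,
                    alt_allele=c.alt_allele, length=c.length,
                    supporting_reads=c.supporting_reads,
                    samples_observed=set(c.samples_observed),
                )
    return sorted(merged.values(), key=lambda c: c.key)


# ---------------------------------------------------------------------------
# genome map-back


def _exon_intervals_from_positions(positions: list[int], chrom: str, strand: str):
    """Group transcribed genome positions (transcription order) into exons."""
    gsorted = sorted(positions)
    exons = []
    run_start = prev = gsorted[0]
    for g in gsorted[1:]:
        if g == prev + 1:
            prev = g
            continue
        exons.append((run_start, prev + 1))
        run_start = prev = g
    exons.append((run_start, prev + 1))
    return [GenomeInterval(chrom, s, e, strand) for s, e in exons]


def map_back_to_genome(
    call: TranscriptIndelCall,
    tx_models: Mapping[str, TranscriptModel],
    genome: Mapping[str, str] | None = None,
) -> GenomeInterpretation:
    """Project a transcript-space indel to the genome and classify it.

    A deletion whose removal reproduces the exon structure of another
    annotated isoform of the same gene (e.g. exactly excising a cassette
    exon that a documented isoform lacks) is a naturally occurring
    isoform, not a novel event, and is classified for exclusion.
    Insertions are searched against the flanking intron sequence (when a
    genome is supplied) so pseudoexon payloads are localized.
    """
    tx = tx_models.get(call.tx_id)
    if tx is None:
        raise KeyError(f"transcript {call.tx_id!r} not in models")
    siblings = [
        t for t in tx_models.values()
        if t.gene_id == tx.gene_id and t.tx_id != tx.tx_id
    ]
    if call.length < 0:
        del_lo, del_hi = call.pos_tx + 1, call.pos_tx - call.length  # 1-based inclusive
        if del_hi > tx.length:
            raise IndexError(
                f"{call.tx_id}: deletion spans {del_hi} > transcript length {tx.length}"
            )
        g_del = [tx.project_tx_to_genome(p) for p in range(del_lo, del_hi + 1)]
        interval = GenomeInterval(tx.chrom, min(g_del), max(g_del) + 1, tx.strand)
        remaining = [
            tx.project_tx_to_genome(p)
            for p in range(1, tx.length + 1)
            if not (del_lo <= p <= del_hi)
        ]
        new_exons = _exon_intervals_from_positions(remaining, tx.chrom, tx.strand)
        new_set = sorted((e.start, e.end) for e in new_exons)
        for iso in siblings:
            if sorted((e.start, e.end) for e in iso.exons) == new_set:
                return GenomeInterpretation(
                    interval=interval,
                    classification="matches_annotated_isoform",
                    matching_isoform_id=iso.tx_id,
                )
        return GenomeInterpretation(interval=interval, classification="novel_event")

    # insertion: locate payload in the flanking introns when possible
    if not 1 <= call.pos_tx <= tx.length:
        raise IndexError(f"{call.tx_id}: position {call.pos_tx} outside transcript")
    g_anchor = tx.project_tx_to_genome(call.pos_tx)
    if call.ref_allele == "-":
        payload = call.alt_allele
    else:
        payload = call.alt_allele[len(call.ref_allele):]
    if genome is not None and payload:
        comp = str.maketrans("ACGT", "TGCA")
        for intron in tx.introns():
            intron_seq = genome[tx.chrom][intron.start : intron.end].upper()
            probe = payload if tx.strand == "+" else payload.translate(comp)[::-1]
            hit = intron_seq.find(probe)
            if hit >= 0:
                return GenomeInterpretation(
                    interval=GenomeInterval(
                        tx.chrom, intron.start + hit, intron.start + hit + len(probe), tx.strand
                    ),
                    classification="novel_event",
                )
    return GenomeInterpretation(
        interval=GenomeInterval(tx.chrom, g_anchor, g_anchor + 1, tx.strand),
        classification="novel_event",
    )
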