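"""Parsing and annotation of HGVS-style RNA change strings.

Supports the dialects that appear in diagnostic reports of aberrant
splicing events:

* deletions          ``r.2416_2436del21``, ``r.287_335del49``, ``r.100_102del``,
                     ``r.100_102delACG``, ``r.-13_13del26`` (UTR-anchored)
* duplications       ``r.10_15dup6``
* insertions with intronic-offset payloads (pseudoexon retention)
                     ``r.1489_1490ins[1490-453_1490-489]``,
                     ``r.2981_2982ins2982-197_2982-281`` (unbracketed),
                     payloads may carry an inner ``r.`` prefix
* sequence insertions ``r.55_56insAUG``
* exon-skip shorthand ``Exon 9 skipping``, ``Exon 3-4 skipping``

Coordinates are 1-based inclusive transcript positions; negative positions
denote bases upstream of position +1 with no position zero (so
``-13_13`` spans 26 nt).  Unicode hyphen/dash/minus variants are
normalized on parse.
"""

from __future__ import annotations

import enum
import re
from dataclasses import dataclass

from splicedx.annotation import TranscriptModel
from splicedx.intervals import GenomeInterval

_DASHES = dict.fromkeys(map(ord, "‐‑‒–—−"), "-")


class HgvsParseError(ValueError):
    """Raised when an RNA change string cannot be parsed or is inconsistent."""

    def __init__(self, message: str, token: str = ""):
        super().__init__(message + (f" (offending token: {token!r})" if token else ""))
        self.token = token


class FrameEffect(enum.Enum):
    IN_FRAME = "in_frame"
    FRAMESHIFT = "frameshift"
    NONCODING_OR_UTR = "noncoding_or_utr"


def _span(a: int, b: int) -> int:
    # inclusive span skipping the nonexistent position 0
    if a > b:
        raise HgvsParseError(f"start {a} after end {b}")
    return b - a + 1 - (1 if a < 0 < b else 0)


@dataclass
class RnaChange:
    """A parsed RNA-level change on one transcript."""

    kind: str  # deletion | insertion | duplication | exon_skip
    tx_start: int | None = None
    tx_end: int | None = None
    intronic_offset_start: int | None = None
    intronic_offset_end: int | None = None
    anchor_start: int | None = None  # payload anchor tx coords (insertions)
    anchor_end: int | None = None
    length_nt: int | None = None
    sequence: str | None = None
    exon_first: int | None = None  # exon-skip shorthand
    exon_last: int | None = None

    def __post_init__(self) -> None:
        if self.kind not in ("deletion", "insertion", "duplication", "exon_skip"):
            raise ValueError(f"unknown change kind {self.kind!r}")
        if self.length_nt is not None and self.length_nt < 1:
            raise ValueError(f"length_nt must be >= 1, got {self.length_nt}")

    def to_string(self) -> str:
        """Canonical serialization (idempotent under re-parsing)."""
        if self.kind == "exon_skip":
            if self.exon_first == self.exon_last:
                return f"exon {self.exon_first} skipping"
            return f"exon {self.exon_first}-{self.exon_last} skipping"
        coords = f"r.{self.tx_start}_{self.tx_end}"
        if self.kind in ("deletion", "duplication"):
            op = "del" if self.kind == "deletion" else "dup"
            return f"{coords}{op}{self.sequence or self.length_nt}"
        if self.intronic_offset_start is not None:
            o1 = f"{self.anchor_start}{self.intronic_offset_start:+d}"
            o2 = f"{self.anchor_end}{self.intronic_offset_end:+d}"
            return f"{coords}ins[{o1}_{o2}]"
        return f"{coords}ins{self.sequence}"


_EXON_SKIP_RE = re.compile(
    r"^exon\s*(\d+)\s*(?:-\s*(\d+)\s*)?skipping$", re.IGNORECASE
)
_COORD = r"(-?\d+)"
_BODY_RE = re.compile(rf"^{_COORD}(?:_{_COORD})?(del|dup|ins)(.*)$")
_OFFSET_PAYLOAD_RE = re.compile(
    rf"^{_COORD}([+-]\d+)_{_COORD}([+-]\d+)$"
)


def parse_rna_change(hgvs_r: str) -> RnaChange:
    """Parse an RNA change string into an :class:`RnaChange`.

    ``length_nt`` is always computed from the coordinates/offsets; an
    explicit length suffix that disagrees raises :class:`HgvsParseError`.
    """
    s = str(hgvs_r).translate(_DASHES).strip()
    m = _EXON_SKIP_RE.match(s)
    if m:
        first = int(m.group(1))
        last = int(m.group(2)) if m.group(2) else first
        return RnaChange(kind="exon_skip", exon_first=first, exon_last=last)

    body = s
    if body.lower().startswith("r."):
        body = body[2:]
    m = _BODY_RE.match(body)
    if not m:
        raise HgvsParseError("unparseable RNA change", s)
    a = int(m.group(1))
    b = int(m.group(2)) if m.group(2) is not None else a
    op, payload = m.group(3), m.group(4).strip()

    if op in ("del", "dup"):
        kind = "deletion" if op == "del" else "duplication"
        length = _span(a, b)
        seq = None
        if payload:
            if payload.isdigit():
                if int(payload) != length:
                    raise HgvsParseError(
                        f"explicit length {payload} disagrees with coordinate span {length}",
                        s,
                    )
            elif re.fullmatch(r"[ACGUTacgut]+", payload):
                seq = payload.upper()
                if len(seq) != length:
                    raise HgvsParseError(
                        f"sequence length {len(seq)} disagrees with coordinate span {length}",
                        s,
                    )
            else:
                raise HgvsParseError("bad deletion/duplication payload", payload)
        return RnaChange(kind=kind, tx_start=a, tx_end=b, length_nt=length, sequence=seq)

    # insertion
    if b != a + 1:
        raise HgvsParseError("insertion flanks must be adjacent positions", s)
    inner = payload
    if inner.startswith("[") and inner.endswith("]"):
        inner = inner[1:-1].strip()
    if inner.lower().startswith("r."):
        inner = inner[2:]
    om = _OFFSET_PAYLOAD_RE.match(inner)
    if om:
        c1, o1, c2, o2 = (int(om.group(i)) for i in range(1, 5))
        length = abs(o2 - o1) + 1
        return RnaChange(
            kind="insertion",
            tx_start=a,
            tx_end=b,
            intronic_offset_start=o1,
            intronic_offset_end=o2,
            anchor_start=c1,
            anchor_end=c2,
            length_nt=length,
        )
    if re.fullmatch(r"[ACGUTacgut]+", inner or ""):
        seq = inner.upper()
        return RnaChange(kind="insertion", tx_start=a, tx_end=b, length_nt=len(seq), sequence=seq)
    raise HgvsParseError("bad insertion payload", payload)


def frame_effect(change: RnaChange, tx: TranscriptModel) -> FrameEffect:
    """Classify a change as in-frame, frameshift or UTR/noncoding.

    In-frame iff the length is a multiple of 3 and the change overlaps the
    CDS by at least one base; frameshift iff the length is not a multiple
    of 3 and the change overlaps the CDS; otherwise noncoding/UTR.
    """
    if tx.biotype != "coding" or tx.cds_start_tx is None:
        return FrameEffect.NONCODING_OR_UTR
    if change.kind == "exon_skip":
        if change.exon_first is None:
            return FrameEffect.NONCODING_OR_UTR
        bounds = tx.exon_tx_bounds()
        lo = bounds[change.exon_first - 1][0]
        hi = bounds[change.exon_last - 1][1]
        length = hi - lo + 1
    else:
        lo, hi, length = change.tx_start, change.tx_end, change.length_nt
    overlaps_cds = max(lo, tx.cds_start_tx) <= min(hi, tx.cds_end_tx)
    if not overlaps_cds:
        return FrameEffect.NONCODING_OR_UTR
    return FrameEffect.IN_FRAME if length % 3 == 0 else FrameEffect.FRAMESHIFT


def pseudoexon_span(change: RnaChange, tx: TranscriptModel) -> tuple[GenomeInterval, int]:
    """Genome interval of a retained intronic segment described by offsets.

    The insertion payload must be anchored (via intronic offsets) to an
    exon-boundary transcript position with an adjacent intron; the
    returned interval lies strictly within that intron.
    """
    if change.kind != "insertion" or change.intronic_offset_start is None:
        raise ValueError("pseudoexon_span requires an offset-described insertion")
    if change.anchor_start != change.anchor_end:
        raise ValueError("offsets must be anchored to the same transcript position")
    anchor = change.anchor_start
    o1, o2 = change.intronic_offset_start, change.intronic_offset_end
    if (o1 < 0) != (o2 < 0):
        raise ValueError("mixed-sign intronic offsets are not supported")

    bounds = tx.exon_tx_bounds()
    introns = tx.introns()
    if o1 < 0:
        # upstream of an exon's first base (acceptor side)
        starts = [lo for lo, _ in bounds]
        if anchor not in starts or starts.index(anchor) == 0:
            raise ValueError(
                f"position {anchor} has no adjacent upstream intron on {tx.tx_id}"
            )
        intron = introns[starts.index(anchor) - 1]
    else:
        ends = [hi for _, hi in bounds]
        if anchor not in ends or ends.index(anchor) == len(bounds) - 1:
            raise ValueError(
                f"position {anchor} has no adjacent downstream intron on {tx.tx_id}"
            )
        intron = introns[ends.index(anchor)]

    g_anchor = tx.project_tx_to_genome(anchor)
    sign = 1 if tx.strand == "+" else -1
    g1 = g_anchor + sign * o1
    g2 = g_anchor + sign * o2
    lo, hi = min(g1, g2), max(g1, g2)
    interval = GenomeInterval(tx.chrom, lo, hi + 1, tx.strand)
    if not (intron.start <= interval.start and interval.end <= intron.end):
        raise ValueError(
            f"offset span {interval} falls outside intron {intron} of {tx.tx_id}"
        )
    length = abs(o2 - o1) + 1
    return interval, length
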