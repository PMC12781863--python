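"""Splice-junction outlier calling with local normalization.

The caller works on a junction x sample matrix of uniquely-mapped split
reads.  Each candidate (non-annotated) junction is normalized *locally*:
its read count is divided by the maximum count, in the same sample, over
annotated junctions sharing a donor or acceptor with it.  This corrects
for gene expression level and library size without any global scaling.

A call is emitted for (junction, sample) only when all four filters pass:

a. the junction shares at least one end with a known annotated junction
   (splicing into an existing transcript);
b. supporting reads >= 5;
c. normalized value >= 0.05;
d. the sample's normalized value is the cohort maximum for that junction
   and at least twice the second-highest sample's value.

The procedure is a deterministic filter; no multiple-testing correction
is applied.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, NamedTuple

import pandas as pd

from splicedx.annotation import TranscriptModel


class JunctionKey(NamedTuple):
    """A splice junction identified by its intron, 1-based inclusive."""

    chrom: str
    intron_start: int  # first intronic base
    intron_end: int  # last intronic base
    strand: str = "?"  # '+', '-' or '?' (unknown)


@dataclass
class JunctionCountMatrix:
    """Junction x sample split-read counts with annotation flags."""

    counts: pd.DataFrame  # index: JunctionKey tuples, columns: sample IDs
    annotated: pd.Series = None  # bool per junction
    shares_annotated_end: pd.Series = None
    gene_symbol: pd.Series = None

    def __post_init__(self) -> None:
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("junction counts must be non-negative")
        if not isinstance(self.counts.index, pd.MultiIndex):
            self.counts.index = pd.MultiIndex.from_tuples(
                self.counts.index, names=["chrom", "intron_start", "intron_end", "strand"]
            )
        for flags in ("annotated", "shares_annotated_end", "gene_symbol"):
            s = getattr(self, flags)
            if s is not None and not isinstance(s.index, pd.MultiIndex):
                s.index = self.counts.index
        if self.annotated is None:
            self.annotated = pd.Series(False, index=self.counts.index)
        if self.shares_annotated_end is None:
            self.shares_annotated_end = pd.Series(False, index=self.counts.index)
        if self.gene_symbol is None:
            self.gene_symbol = pd.Series(".", index=self.counts.index)

    @property
    def junctions(self) -> list[JunctionKey]:
        return [JunctionKey(*k) for k in self.counts.index]

    @property
    def samples(self) -> list[str]:
        return list(self.counts.columns)


@dataclass
class AberrantSplicingCall:
    sample: str
    junction: JunctionKey
    gene_symbol: str
    raw_reads: int
    normalized_value: float
    second_highest_normalized: float
    passed_filters: frozenset = frozenset("abcd")


_STAR_STRAND = {0: "?", 1: "+", 2: "-"}


def _read_star_sj(path: str) -> pd.DataFrame:
    df = pd.read_csv(
        path,
        sep="\t",
        header=None,
        names=[
            "chrom", "intron_start", "intron_end", "strand_code",
            "motif", "annotated", "unique_reads", "multi_reads", "overhang",
        ],
        dtype={"chrom": str},
    )
    for col in ("intron_start", "intron_end", "unique_reads"):
        if not pd.api.types.is_integer_dtype(df[col]):
            raise ValueError(f"{path}: non-integer values in column {col}")
    df["strand"] = df["strand_code"].map(_STAR_STRAND)
    return df[["chrom", "intron_start", "intron_end", "strand", "unique_reads"]]


def _read_bed_sj(path: str) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", header=None, dtype={0: str})
    if df.shape[1] < 5:
        raise ValueError(f"{path}: BED junction table needs >= 5 columns")
    out = pd.DataFrame(
        {
            "chrom": df[0],
            # BED is 0-based half-open on the intron; convert to 1-based inclusive
            "intron_start": df[1].astype(int) + 1,
            "intron_end": df[2].astype(int),
            "strand": df[5] if df.shape[1] >= 6 else "?",
            "unique_reads": df[4].astype(int),
        }
    )
    out["strand"] = out["strand"].where(out["strand"].isin(["+", "-"]), "?")
    return out


def read_junction_tables(
    tables: Mapping[str, str], dialect: str = "star"
) -> JunctionCountMatrix:
    """Read per-sample junction tables and merge them on junction keys.

    ``tables`` maps sample ID -> file path.  ``dialect`` is ``"star"``
    (SJ.out.tab, 1-based intron coordinates) or ``"bed"`` (0-based
    half-open, converted on read).  A junction missing from a sample gets
    count 0; duplicate junction rows within one sample are an error.
    """
    reader = {"star": _read_star_sj, "bed": _read_bed_sj}.get(dialect)
    if reader is None:
        raise ValueError(f"unknown junction table dialect {dialect!r}")
    per_sample = {}
    for sample, path in tables.items():
        df = reader(path)
        keys = list(
            zip(df["chrom"], df["intron_start"], df["intron_end"], df["strand"])
        )
        if len(keys) != len(set(keys)):
            raise ValueError(
                f"{path}: duplicate junction rows; counts must be pre-aggregated"
            )
        per_sample[sample] = pd.Series(df["unique_reads"].values, index=pd.Index(keys))
    counts = pd.DataFrame(per_sample).fillna(0).astype(int)
    counts = counts[list(tables.keys())]
    return JunctionCountMatrix(counts=counts)


def annotate_matrix(
    matrix: JunctionCountMatrix, transcripts: Mapping[str, TranscriptModel]
) -> JunctionCountMatrix:
    """Set ``annotated`` / ``shares_annotated_end`` flags and gene symbols.

    A junction is *annotated* when both ends match an intron of some
    transcript of the same gene; it *shares an annotated end* when at
    least one end coincides with an annotated junction end.  Junctions
    with unknown strand are compared against annotation on both strands.
    """
    intron_gene: dict[tuple, str] = {}
    end_gene: dict[tuple, str] = {}
    for tx in transcripts.values():
        for intron in tx.introns():
            s, e = intron.start + 1, intron.end  # 1-based inclusive intron
            intron_gene[(intron.chrom, s, e, intron.strand)] = tx.gene_symbol
            end_gene[(intron.chrom, "s", s, intron.strand)] = tx.gene_symbol
            end_gene[(intron.chrom, "e", e, intron.strand)] = tx.gene_symbol

    ann, share, genes = [], [], []
    for key in matrix.counts.index:
        chrom, s, e, strand = key
        strands = [strand] if strand in ("+", "-") else ["+", "-"]
        is_ann = any((chrom, s, e, st) in intron_gene for st in strands)
        hit_genes = [
            end_gene[k]
            for st in strands
            for k in ((chrom, "s", s, st), (chrom, "e", e, st))
            if k in end_gene
        ]
        ann.append(is_ann)
        share.append(bool(hit_genes))
        genes.append(hit_genes[0] if hit_genes else ".")
    matrix.annotated = pd.Series(ann, index=matrix.counts.index)
    matrix.shares_annotated_end = pd.Series(share, index=matrix.counts.index)
    matrix.gene_symbol = pd.Series(genes, index=matrix.counts.index)
    return matrix


def _denominator_counts(
    matrix: JunctionCountMatrix, key: tuple
) -> pd.DataFrame:
    """Per-sample counts of annotated junctions sharing an end with ``key``."""
    chrom, s, e, strand = key
    rows = []
    for other in matrix.counts.index:
        if other == key or not matrix.annotated.at[other]:
            continue
        ochrom, os_, oe, ostrand = other
        if ochrom != chrom:
            continue
        if strand in ("+", "-") and ostrand in ("+", "-") and strand != ostrand:
            continue
        if os_ == s or oe == e or os_ == e or oe == s:
            rows.append(other)
    if not rows:
        return matrix.counts.iloc[0:0]
    return matrix.counts.loc[rows]


def normalize_junction(
    matrix: JunctionCountMatrix, junction: JunctionKey | tuple, sample: str
) -> float:
    """Locally-normalized value of (junction, sample); NaN when undefined.

    The denominator is the maximum read count, in the same sample, over
    annotated junctions sharing a donor or acceptor with the candidate
    (for a junction spanning two canonical exon-intron boundaries this is
    the max of the two canonical junction counts).  Zero denominator ->
    NaN (fails the normalized-value filter downstream).
    """
    key = tuple(junction)
    if key not in matrix.counts.index:
        raise KeyError(f"junction {key} not in matrix")
    denom_rows = _denominator_counts(matrix, key)
    if denom_rows.empty:
        return math.nan
    denom = denom_rows[sample].max()
    if denom <= 0:
        return math.nan
    return float(matrix.counts.at[key, sample]) / float(denom)


def call_aberrant_splicing(
    matrix: JunctionCountMatrix,
    transcripts: Mapping[str, TranscriptModel] | None = None,
    min_reads: int = 5,
    min_norm: float = 0.05,
    fold_vs_second: float = 2.0,
) -> list[AberrantSplicingCall]:
    """Apply the four-filter aberrant-splicing rule to every candidate.

    Filter (d) reads "maximal" strictly: when two samples tie at the
    exact maximum neither is called; when the second-highest value is 0
    the fold condition passes (the event is absent elsewhere).
    """
    if transcripts is not None:
        matrix = annotate_matrix(matrix, transcripts)
    if len(matrix.samples) < 2:
        raise ValueError("filter (d) needs at least 2 samples")

    calls: list[AberrantSplicingCall] = []
    for key in matrix.counts.index:
        if matrix.annotated.at[key]:
            continue
        if not matrix.shares_annotated_end.at[key]:
            continue  # filter (a)
        denom_rows = _denominator_counts(matrix, key)
        norms: dict[str, float] = {}
        for sample in matrix.samples:
            denom = denom_rows[sample].max() if not denom_rows.empty else 0
            raw = matrix.counts.at[key, sample]
            norms[sample] = raw / denom if denom > 0 else math.nan
        defined = {s: v for s, v in norms.items() if not math.isnan(v)}
        for sample in matrix.samples:
            raw = int(matrix.counts.at[key, sample])
            norm = norms[sample]
            if raw < min_reads:  # filter (b)
                continue
            if math.isnan(norm) or norm < min_norm:  # filter (c)
                continue
            others = [v for s, v in defined.items() if s != sample]
            second = max(others) if others else 0.0
            if any(v >= norm for v in others):  # strict maximum (d)
                continue
            if second > 0 and norm < fold_vs_second * second:
                continue
            calls.append(
                AberrantSplicingCall(
                    sample=sample,
                    junction=JunctionKey(*key),
                    gene_symbol=str(matrix.gene_symbol.at[key]),
                    raw_reads=raw,
                    normalized_value=float(norm),
                    second_highest_normalized=float(second),
                )
            )
    calls.sort(key=lambda c: (c.sample, -c.normalized_value))
    return calls


def restrict_to_panel(
    calls: Iterable[AberrantSplicingCall], gene_set: Iterable[str]
) -> list[AberrantSplicingCall]:
    """Subset calls to a gene panel (e.g. OMIM genes), preserving order."""
    gene_set = set(gene_set)
    if not gene_set:
        warnings.warn("empty gene panel: no calls retained")
        return []
    return [c for c in calls if c.gene_symbol in gene_set]


def calls_to_frame(calls: Iterable[AberrantSplicingCall]) -> pd.DataFrame:
    """Tabular view of calls (one row per call)."""
    return pd.DataFrame(
        [
            {
                "sample": c.sample,
                "gene": c.gene_symbol,
                "chrom": c.junction.chrom,
                "intron_start": c.junction.intron_start,
                "intron_end": c.junction.intron_end,
                "strand": c.junction.strand,
                "raw_reads": c.raw_reads,
                "normalized": c.normalized_value,
                "second_highest": c.second_highest_normalized,
                "filters_passed": "".join(sorted(c.passed_filters)),
            }
            for c in calls
        ],
        columns=[
            "sample", "gene", "chrom", "intron_start", "intron_end", "strand",
            "raw_reads", "normalized", "second_highest", "filters_passed",
        ],
    )
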