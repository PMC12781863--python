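"""Transcript isoform distribution (TID) analysis.

Aberrant splicing that shifts usage between *annotated* isoforms is
invisible to novel-junction outlier callers.  The TID statistic makes it
visible: for each alternative isoform of a candidate gene, TID is the
TPM ratio of that isoform to the gene's representative transcript.  A
pathological isoform redistribution elevates the ratio in the affected
sample(s) even when total gene expression is unchanged.

The module also carries a lightweight inclusion-level (psi) layer:
splicing events are enumerated from annotation isoform pairs, psi is
estimated from junction counts, and case-vs-control differential events
are screened (|delta psi| >= 0.15, BH-FDR <= 0.05; Fisher exact test on
case vs pooled-control counts) before isoform ratios are computed.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from splicedx.annotation import TranscriptModel
from splicedx.intervals import GenomeInterval
from splicedx.junctions import JunctionCountMatrix, JunctionKey


@dataclass
class SplicingEvent:
    """An inclusion-level alternative splicing event.

    ``inclusion_counts[sample]`` / ``skipping_counts[sample]`` hold the
    *effective* counts: the mean split-read count over the event's
    inclusion (resp. skipping) junctions in that sample.
    """

    event_id: str
    gene_symbol: str
    event_type: str  # SE | A5SS | A3SS | RI | MXE
    inclusion_junctions: list[JunctionKey]
    skipping_junctions: list[JunctionKey]
    inclusion_counts: dict[str, float] = field(default_factory=dict)
    skipping_counts: dict[str, float] = field(default_factory=dict)
    included_segment: GenomeInterval | None = None
    psi: dict[str, float] = field(default_factory=dict)
    delta_psi: float | None = None
    p_value: float | None = None
    fdr: float | None = None


@dataclass
class TIDRecord:
    """Per-sample isoform / representative TPM ratios for one isoform."""

    gene_symbol: str
    isoform_id: str
    representative_id: str
    tpm_isoform: dict[str, float]
    tpm_representative: dict[str, float]
    tid: dict[str, float] = field(default_factory=dict)
    outlier_samples: set[str] = field(default_factory=set)


# ---------------------------------------------------------------------------
# psi layer


def attach_junction_counts(event: SplicingEvent, matrix: JunctionCountMatrix) -> SplicingEvent:
    """Fill effective inclusion/skipping counts from a junction matrix.

    Junctions absent from the matrix contribute count 0.
    """
    if not event.inclusion_junctions or not event.skipping_junctions:
        raise ValueError(f"{event.event_id}: event with empty junction lists")

    def mean_for(juncs: list[JunctionKey], sample: str) -> float:
        vals = []
        for j in juncs:
            key = tuple(j)
            vals.append(float(matrix.counts.at[key, sample]) if key in matrix.counts.index else 0.0)
        return float(np.mean(vals))

    for sample in matrix.samples:
        event.inclusion_counts[sample] = mean_for(event.inclusion_junctions, sample)
        event.skipping_counts[sample] = mean_for(event.skipping_junctions, sample)
    return event


def compute_psi(event: SplicingEvent, sample: str, min_informative: int = 10) -> float:
    """psi = I_eff / (I_eff + S); NaN below ``min_informative`` reads."""
    if not event.inclusion_junctions or not event.skipping_junctions:
        raise ValueError(f"{event.event_id}: event with empty junction lists")
    i_eff = event.inclusion_counts.get(sample, 0.0)
    s = event.skipping_counts.get(sample, 0.0)
    if i_eff + s < min_informative:
        return math.nan
    return i_eff / (i_eff + s)


def differential_events(
    events: Iterable[SplicingEvent],
    case_sample: str,
    control_samples: list[str],
    min_delta: float = 0.15,
    max_fdr: float = 0.05,
    min_informative: int = 10,
) -> list[SplicingEvent]:
    """Case-vs-control differential splicing screen.

    For each event: delta psi = psi(case) - mean psi(controls); p-value
    from a two-sided Fisher exact test of the case (I_eff, S) counts
    against the pooled control counts (rounded to integers); BH
    correction across all tested events; retain events with
    ``|delta psi| >= min_delta`` and ``fdr <= max_fdr``.
    """
    if len(control_samples) < 3:
        raise ValueError("differential_events needs >= 3 control samples")
    tested: list[SplicingEvent] = []
    pvals: list[float] = []
    for event in events:
        psi_case = compute_psi(event, case_sample, min_informative)
        psi_ctrl = [compute_psi(event, s, min_informative) for s in control_samples]
        psi_ctrl = [p for p in psi_ctrl if not math.isnan(p)]
        if math.isnan(psi_case) or not psi_ctrl:
            continue
        event.psi[case_sample] = psi_case
        event.delta_psi = psi_case - float(np.mean(psi_ctrl))
        ci = round(event.inclusion_counts[case_sample])
        cs = round(event.skipping_counts[case_sample])
        ki = round(sum(event.inclusion_counts[s] for s in control_samples))
        ks = round(sum(event.skipping_counts[s] for s in control_samples))
        _, p = stats.fisher_exact([[ci, cs], [ki, ks]], alternative="two-sided")
        event.p_value = float(p)
        tested.append(event)
        pvals.append(float(p))
    if not tested:
        warnings.warn("no events testable for differential splicing")
        return []
    _, fdrs, _, _ = multipletests(pvals, method="fdr_bh")
    retained = []
    for event, fdr in zip(tested, fdrs):
        event.fdr = float(fdr)
        if abs(event.delta_psi) >= min_delta and event.fdr <= max_fdr:
            retained.append(event)
    return retained


# ---------------------------------------------------------------------------
# event <-> isoform structural matching


def _exon_set(tx: TranscriptModel) -> list[tuple[int, int]]:
    return sorted((e.start, e.end) for e in tx.exons)


def match_event_to_isoforms(
    event: SplicingEvent, transcripts: Mapping[str, TranscriptModel]
) -> list[tuple[TranscriptModel, TranscriptModel]]:
    """Isoform pairs whose structures differ exactly by the event's segment.

    For an SE event with included segment ``seg``: returns pairs
    (inclusion_isoform, exclusion_isoform) where the inclusion isoform's
    exon set equals the exclusion isoform's plus one exon identical to
    ``seg``, everything else equal.  Empty list when no annotated pair
    realizes the event.
    """
    if event.included_segment is None:
        return []
    seg = (event.included_segment.start, event.included_segment.end)
    gene_txs = [t for t in transcripts.values() if t.gene_symbol == event.gene_symbol]
    pairs = []
    for inc in gene_txs:
        for exc in gene_txs:
            if inc.tx_id == exc.tx_id:
                continue
            inc_set, exc_set = _exon_set(inc), _exon_set(exc)
            if seg in inc_set and sorted(set(inc_set) - {seg}) == exc_set:
                pairs.append((inc, exc))
    return pairs


def enumerate_events(transcripts: Mapping[str, TranscriptModel]) -> list[SplicingEvent]:
    """Enumerate SE events between each isoform and its gene's representative.

    For every gene, every exon present in exactly one member of an
    (isoform, representative) pair — with both flanking exons shared —
    yields one skipped-exon event.  The inclusion junctions are the two
    introns flanking the cassette; the skipping junction joins the
    flanks directly.
    """
    by_gene: dict[str, list[TranscriptModel]] = {}
    for tx in transcripts.values():
        by_gene.setdefault(tx.gene_symbol, []).append(tx)
    events: list[SplicingEvent] = []
    for gene, txs in sorted(by_gene.items()):
        rep = next((t for t in txs if t.is_representative), None)
        if rep is None:
            continue
        for other in sorted(txs, key=lambda t: t.tx_id):
            if other.tx_id == rep.tx_id:
                continue
            for long_tx, short_tx in ((rep, other), (other, rep)):
                long_set, short_set = _exon_set(long_tx), _exon_set(short_tx)
                extra = sorted(set(long_set) - set(short_set))
                if len(extra) != 1 or sorted(set(long_set) - set(extra)) != short_set:
                    continue
                seg = extra[0]
                idx = long_set.index(seg)
                if idx == 0 or idx == len(long_set) - 1:
                    continue  # cassette must be internal
                left, right = long_set[idx - 1], long_set[idx + 1]
                chrom, strand = long_tx.chrom, long_tx.strand
                inc = [
                    JunctionKey(chrom, left[1] + 1, seg[0], strand),
                    JunctionKey(chrom, seg[1] + 1, right[0], strand),
                ]
                skip = [JunctionKey(chrom, left[1] + 1, right[0], strand)]
                events.append(
                    SplicingEvent(
                        event_id=f"SE:{gene}:{chrom}:{seg[0]}-{seg[1]}",
                        gene_symbol=gene,
                        event_type="SE",
                        inclusion_junctions=inc,
                        skipping_junctions=skip,
                        included_segment=GenomeInterval(chrom, seg[0], seg[1], strand),
                    )
                )
    # de-duplicate events discovered via multiple isoform pairs
    seen: dict[str, SplicingEvent] = {}
    for e in events:
        seen.setdefault(e.event_id, e)
    return list(seen.values())


# ---------------------------------------------------------------------------
# TID ratios and outliers


def compute_tid(
    quant: pd.DataFrame,
    isoform_id: str,
    representative_id: str,
    rep_floor: float = 1.0,
) -> TIDRecord:
    """TID(sample) = TPM_isoform / TPM_representative.

    ``quant`` is a tidy table with columns tx_id, gene_id, sample, TPM.
    The ratio is undefined (NaN) in samples where the representative is
    below ``rep_floor`` TPM (the expressed-transcript convention).
    """
    for tx in (isoform_id, representative_id):
        if tx not in set(quant["tx_id"]):
            raise KeyError(f"transcript {tx!r} not in quantification table")
    iso = quant[quant["tx_id"] == isoform_id].set_index("sample")["TPM"]
    rep = quant[quant["tx_id"] == representative_id].set_index("sample")["TPM"]
    gene = quant.loc[quant["tx_id"] == isoform_id, "gene_id"].iloc[0]
    tid = {}
    for sample in rep.index:
        r = float(rep.get(sample, 0.0))
        i = float(iso.get(sample, 0.0))
        tid[sample] = i / r if r >= rep_floor else math.nan
    return TIDRecord(
        gene_symbol=str(gene),
        isoform_id=isoform_id,
        representative_id=representative_id,
        tpm_isoform={s: float(v) for s, v in iso.items()},
        tpm_representative={s: float(v) for s, v in rep.items()},
        tid=tid,
    )


def tid_outliers(
    record: TIDRecord,
    fold_vs_second: float = 2.0,
    min_tid: float = 0.05,
    co_affected: Mapping[str, set] | None = None,
) -> set[str]:
    """Flag samples whose TID is the cohort maximum by a >= 2x margin.

    A sample is flagged iff its TID is defined, >= ``min_tid``, strictly
    above every comparison sample, and >= ``fold_vs_second`` times the
    highest comparison value (vacuously when no comparison value is
    positive).  ``co_affected`` maps a sample to the set of relatives
    expected to share the event (family mode): those relatives are
    excluded from the sample's comparison set, so two affected family
    members can both be flagged.
    """
    defined = {s: v for s, v in record.tid.items() if not math.isnan(v)}
    if len(defined) < 3:
        warnings.warn(
            f"{record.isoform_id}: fewer than 3 samples with defined TID; no outliers"
        )
        record.outlier_samples = set()
        return set()
    co_affected = co_affected or {}
    flagged = set()
    for sample, value in defined.items():
        if value < min_tid:
            continue
        excluded = {sample} | set(co_affected.get(sample, set()))
        others = [v for s, v in defined.items() if s not in excluded]
        if not others:
            flagged.add(sample)
            continue
        second = max(others)
        if value <= second:
            continue
        if second > 0 and value < fold_vs_second * second:
            continue
        flagged.add(sample)
    record.outlier_samples = flagged
    return flagged


def tid_records_to_frame(records: Iterable[TIDRecord]) -> pd.DataFrame:
    rows = []
    for r in records:
        for sample, value in sorted(r.tid.items()):
            rows.append(
                {
                    "gene": r.gene_symbol,
                    "isoform": r.isoform_id,
                    "representative": r.representative_id,
                    "sample": sample,
                    "tid": value,
                    "outlier": sample in r.outlier_samples,
                }
            )
    return pd.DataFrame(rows, columns=["gene", "isoform", "representative", "sample", "tid", "outlier"])
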