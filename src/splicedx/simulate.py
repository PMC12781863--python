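"""Synthetic fixtures for every pipeline stage.

The generator builds a toy annotation whose gene structures mirror the
diagnostic scenarios the pipeline exists for:

* ``PKD2L`` — coding representative plus a *noncoding* annotated isoform
  lacking an internal cassette exon (exon 9): the isoform-redistribution
  scenario that junction outlier callers cannot see;
* ``CLN6L`` — minus-strand gene with an exon-3-skipping annotated isoform;
* ``GALCL`` — long intron 13 hosting a pseudoexon (acceptor offsets
  -489..-453 from the first base of exon 14);
* ``FANCAL`` — intron 30 pseudoexon (offsets -281..-197 from exon 31);
* ``KAT6AL`` / ``GATAD2BL`` — exon-boundary deletion scenarios (21 nt at
  an exon 3' boundary; 49 nt after a cryptic acceptor inside an exon);
* two background genes.

Junction cohorts use negative-binomial split-read counts; injected
events add novel junctions at a stated fraction of flanking coverage,
attenuated by an NMD mask unless simulated cycloheximide (CHX) is on —
CHX also multiplies the background noise rate, emulating the genome-wide
increase in aberrant junctions under translation inhibition.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Iterable

import numpy as np
import pandas as pd

from splicedx.annotation import TranscriptModel, load_annotation
from splicedx.cohort import FamilyRecord, Finding
from splicedx.intervals import GenomeInterval
from splicedx.junctions import JunctionCountMatrix


# ---------------------------------------------------------------------------
# configuration


@dataclass
class EventSpec:
    """One injected aberration."""

    type: str  # exon_skip | pseudoexon | cryptic_acceptor | boundary_indel | isoform_shift | knockdown
    gene: str
    sample: str = "case"
    magnitude: float = 0.3  # junction support as fraction of flanking coverage,
    # target isoform fraction (isoform_shift), or expression scale (knockdown)
    nmd_masked: bool = False
    exon: int | None = None  # 1-based cassette exon (exon_skip)
    intron: int | None = None  # 1-based host intron (pseudoexon)
    pe_offsets: tuple[int, int] | None = None  # acceptor-relative offsets
    tx_del: tuple[int, int] | None = None  # 1-based deleted tx span (boundary_indel)
    fraction: float = 0.5  # mutant haplotype fraction (boundary_indel reads)

    _ALLOWED = (
        "exon_skip", "pseudoexon", "cryptic_acceptor",
        "boundary_indel", "isoform_shift", "knockdown",
    )

    def __post_init__(self) -> None:
        if self.type not in self._ALLOWED:
            raise ValueError(f"unknown event type {self.type!r}")
        if self.magnitude < 0:
            raise ValueError("event magnitude must be >= 0")


@dataclass
class SimulationConfig:
    seed: int
    n_controls: int = 7
    depth_mean: float = 100.0
    depth_dispersion: float = 0.1  # NB: var = mu + disp * mu^2
    noise_rate: float = 0.01  # expected novel-junction support / depth
    noise_junctions_per_sample: float = 3.0
    events: list[EventSpec] = field(default_factory=list)
    chx: bool = False  # simulated cycloheximide treatment
    nmd_mask_factor: float = 0.1
    chx_unmask_factor: float = 10.0
    chx_noise_factor: float = 5.0
    read_length: int = 100
    reads_per_sample: int = 60
    error_rate: float = 0.01

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("seed is mandatory (no silent entropy)")
        for name in ("depth_mean", "depth_dispersion", "noise_rate", "error_rate"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")

    @property
    def samples(self) -> list[str]:
        return ["case"] + [f"control{i + 1}" for i in range(self.n_controls)]


@dataclass
class GroundTruthEvent:
    type: str
    gene: str
    sample: str
    detail: dict


# ---------------------------------------------------------------------------
# toy annotation


def _random_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(np.array(list("ACGT"))[rng.integers(0, 4, n)])


def _exons_from_lengths(
    start: int, exon_lens: list[int], intron_lens: list[int], chrom: str, strand: str
) -> list[GenomeInterval]:
    exons, pos = [], start
    for i, el in enumerate(exon_lens):
        exons.append(GenomeInterval(chrom, pos, pos + el, strand))
        pos += el
        if i < len(intron_lens):
            pos += intron_lens[i]
    return exons  # genomic order; loader reorders for minus strand


def _gtf_lines(
    gene: str, tx: str, exons: list[GenomeInterval], cds_tx: tuple[int, int] | None,
    mane: bool,
) -> list[str]:
    attrs = f'gene_id "{gene}"; transcript_id "{tx}"; gene_name "{gene}";'
    if mane:
        attrs += ' tag "MANE_Select";'
    lines = []
    order = exons if exons[0].strand == "+" else exons[::-1]  # transcription order
    model = TranscriptModel(tx_id=tx, gene_id=gene, gene_symbol=gene, exons=list(exons))
    for e in exons:
        lines.append(
            "\t".join(
                [e.chrom, "toy", "exon", str(e.start + 1), str(e.end), ".", e.strand, ".", attrs]
            )
        )
    if cds_tx is not None:
        lo, hi = cds_tx
        # per-exon CDS pieces in genome space
        for (b_lo, b_hi), exon in zip(model.exon_tx_bounds(), model.exons):
            s, e = max(lo, b_lo), min(hi, b_hi)
            if s > e:
                continue
            g1 = model.project_tx_to_genome(s)
            g2 = model.project_tx_to_genome(e)
            glo, ghi = min(g1, g2), max(g1, g2)
            lines.append(
                "\t".join(
                    [exon.chrom, "toy", "CDS", str(glo + 1), str(ghi + 1), ".", exon.strand, "0", attrs]
                )
            )
    return lines


@dataclass
class ToyAnnotation:
    gtf: str
    genome: dict[str, str]
    models: dict[str, TranscriptModel]

    def transcript_sequences(self) -> dict[str, str]:
        return {tx_id: m.splice(self.genome) for tx_id, m in self.models.items()}

    def write(self, outdir: str) -> dict[str, str]:
        os.makedirs(outdir, exist_ok=True)
        paths = {
            "gtf": os.path.join(outdir, "toy.gtf"),
            "genome": os.path.join(outdir, "genome.fa"),
            "transcripts": os.path.join(outdir, "transcripts.fa"),
        }
        with open(paths["gtf"], "w") as fh:
            fh.write(self.gtf)
        with open(paths["genome"], "w") as fh:
            for chrom, seq in self.genome.items():
                fh.write(f">{chrom}\n")
                for i in range(0, len(seq), 80):
                    fh.write(seq[i : i + 80] + "\n")
        with open(paths["transcripts"], "w") as fh:
            for tx_id, seq in sorted(self.transcript_sequences().items()):
                fh.write(f">{tx_id}\n")
                for i in range(0, len(seq), 80):
                    fh.write(seq[i : i + 80] + "\n")
        return paths


def make_toy_annotation(seed: int = 0) -> ToyAnnotation:
    """Deterministic toy annotation covering all fixture gene scenarios."""
    rng = np.random.default_rng(seed)
    chrom = "chrT"
    lines: list[str] = []
    cursor = 1000

    def place(exon_lens, intron_lens, strand):
        nonlocal cursor
        exons = _exons_from_lengths(cursor, exon_lens, intron_lens, chrom, strand)
        cursor = max(e.end for e in exons) + 2000
        return exons

    # PKD2L: 10 exons of 100; cassette = exon 9; noncoding isoform lacks it
    ex = place([100] * 10, [200] * 9, "+")
    lines += _gtf_lines("PKD2L", "PKD2L-201", ex, (50, 950), mane=True)
    lines += _gtf_lines("PKD2L", "PKD2L-202", ex[:8] + ex[9:], None, mane=False)

    # CLN6L: minus strand, 7 exons of 90; isoform lacks exon 3 (transcription order)
    ex = place([90] * 7, [180] * 6, "-")
    tx_order = ex[::-1]  # transcription order for '-'
    lines += _gtf_lines("CLN6L", "CLN6L-201", ex, (40, 600), mane=True)
    skip3 = [e for e in ex if e != tx_order[2]]
    lines += _gtf_lines("CLN6L", "CLN6L-202", skip3, (40, 510), mane=False)

    # GALCL: exon 14 starts at tx 1490; intron 13 long enough for offsets -489..-453
    exon_lens = [110] * 12 + [169] + [100] * 4  # cumulative through exon 13 = 1489
    intron_lens = [150] * 12 + [600] + [150] * 3
    ex = place(exon_lens, intron_lens, "+")
    lines += _gtf_lines("GALCL", "GALCL-201", ex, (60, 1800), mane=True)

    # FANCAL: exon 31 starts at tx 2982; intron 30 hosts offsets -281..-197
    exon_lens = [100] * 29 + [81] + [100, 100]  # cumulative through exon 30 = 2981
    intron_lens = [120] * 29 + [400] + [120]
    ex = place(exon_lens, intron_lens, "+")
    lines += _gtf_lines("FANCAL", "FANCAL-201", ex, (90, 3000), mane=True)

    # KAT6AL: exon 5 ends at tx 2436 (21 nt boundary deletion scenario)
    ex = place([500, 500, 500, 500, 436, 400], [150] * 5, "+")
    lines += _gtf_lines("KAT6AL", "KAT6AL-201", ex, (100, 2700), mane=True)

    # GATAD2BL: positions 287..335 inside exon 2 (cryptic-acceptor deletion)
    ex = place([150, 250, 300], [200, 200], "+")
    lines += _gtf_lines("GATAD2BL", "GATAD2BL-201", ex, (61, 650), mane=True)

    # background genes
    ex = place([120] * 5, [160] * 4, "+")
    lines += _gtf_lines("BGA", "BGA-201", ex, (30, 500), mane=True)
    ex = place([120] * 4, [160] * 3, "-")
    lines += _gtf_lines("BGB", "BGB-201", ex, (30, 420), mane=True)

    genome = {chrom: _random_seq(rng, cursor + 1000)}
    gtf = "\n".join(lines) + "\n"
    models = load_annotation(gtf)
    return ToyAnnotation(gtf=gtf, genome=genome, models=models)


# ---------------------------------------------------------------------------
# junction cohort


def _nb_draw(rng: np.random.Generator, mean: float, dispersion: float, size=None):
    if dispersion <= 0:
        return rng.poisson(mean, size)
    n = 1.0 / dispersion
    p = n / (n + mean)
    return rng.negative_binomial(n, p, size)


def _annotated_junction_keys(models) -> list[tuple]:
    keys = []
    for tx in models.values():
        for intron in tx.introns():
            keys.append((intron.chrom, intron.start + 1, intron.end, intron.strand))
    return sorted(set(keys))


def simulate_junction_cohort(
    config: SimulationConfig, annotation: ToyAnnotation
) -> tuple[JunctionCountMatrix, list[GroundTruthEvent]]:
    """Simulate per-sample junction counts with injected splice events.

    Annotated junction counts are NB(depth_mean, dispersion) scaled by a
    per-sample library factor.  Injected events add novel junctions at
    ``magnitude x flanking coverage``; NMD-masked events are attenuated
    by ``nmd_mask_factor`` unless simulated CHX is on, in which case the
    support is re-amplified by ``chx_unmask_factor`` and the background
    noise rate is multiplied by ``chx_noise_factor``.
    """
    rng = np.random.default_rng(config.seed)
    models = annotation.models
    samples = config.samples
    ann_keys = _annotated_junction_keys(models)
    lib = {s: float(np.exp(rng.normal(0.0, 0.15))) for s in samples}
    counts: dict[tuple, dict[str, int]] = {
        k: {s: int(_nb_draw(rng, config.depth_mean * lib[s], config.depth_dispersion))
            for s in samples}
        for k in ann_keys
    }
    truth: list[GroundTruthEvent] = []

    def flank_max(tx: TranscriptModel, intron_indices: Iterable[int], sample: str) -> float:
        vals = []
        introns = tx.introns()
        for i in intron_indices:
            if 0 <= i < len(introns):
                intron = introns[i]
                k = (intron.chrom, intron.start + 1, intron.end, intron.strand)
                vals.append(counts.get(k, {}).get(sample, 0))
        return float(max(vals)) if vals else 0.0

    for ev in config.events:
        if ev.type in ("isoform_shift", "knockdown"):
            continue  # quantification-table events
        reps = [
            m for m in models.values()
            if m.gene_symbol == ev.gene and m.is_representative
        ]
        if not reps:
            raise ValueError(f"event gene {ev.gene!r} absent from annotation")
        tx = reps[0]
        introns = tx.introns()
        support_scale = 1.0
        if ev.nmd_masked:
            support_scale *= config.nmd_mask_factor
            if config.chx:
                support_scale *= config.chx_unmask_factor

        if ev.type == "exon_skip":
            n_ex = len(tx.exons)
            e = (ev.exon - 1) if ev.exon else n_ex // 2  # 0-based cassette index
            if not 1 <= e <= n_ex - 2:
                raise ValueError(f"cassette exon must be internal (gene {ev.gene})")
            left, right = tx.exons[e - 1], tx.exons[e + 1]
            if tx.strand == "+":
                key = (tx.chrom, left.end + 1, right.start, "+")
            else:
                key = (tx.chrom, right.end + 1, left.start, "-")
            flank = flank_max(tx, [e - 1, e], ev.sample)
            cnt = int(round(ev.magnitude * flank * support_scale))
            counts.setdefault(key, {s: 0 for s in samples})[ev.sample] += cnt
            truth.append(GroundTruthEvent(
                type=ev.type, gene=ev.gene, sample=ev.sample,
                detail={"junction": key, "count": cnt, "magnitude": ev.magnitude},
            ))
        elif ev.type in ("pseudoexon", "cryptic_acceptor"):
            i = (ev.intron - 1) if ev.intron else len(introns) // 2
            intron = introns[i]
            if ev.type == "pseudoexon":
                offsets = ev.pe_offsets or (-120, -80)
                # acceptor-anchored offsets: pseudoexon start inside the intron
                acc_exon = tx.exons[i + 1]
                anchor = acc_exon.start if tx.strand == "+" else acc_exon.end - 1
                sign = 1 if tx.strand == "+" else -1
                pe_lo = anchor + sign * min(offsets)
                pe_hi = anchor + sign * max(offsets)
                pe_start, pe_end = min(pe_lo, pe_hi), max(pe_lo, pe_hi)
                if tx.strand == "+":
                    don = tx.exons[i]
                    key = (tx.chrom, don.end + 1, pe_start, "+")
                else:
                    don = tx.exons[i]
                    key = (tx.chrom, pe_end + 1, don.start, "-")
            else:
                # cryptic acceptor: annotated donor, acceptor shifted into the intron
                shift = 30
                if tx.strand == "+":
                    key = (tx.chrom, intron.start + 1, intron.end - shift, "+")
                else:
                    key = (tx.chrom, intron.start + 1 + shift, intron.end, "-")
            flank = flank_max(tx, [i], ev.sample)
            cnt = int(round(ev.magnitude * flank * support_scale))
            counts.setdefault(key, {s: 0 for s in samples})[ev.sample] += cnt
            truth.append(GroundTruthEvent(
                type=ev.type, gene=ev.gene, sample=ev.sample,
                detail={"junction": key, "count": cnt, "magnitude": ev.magnitude,
                        "nmd_masked": ev.nmd_masked, "chx": config.chx},
            ))
        elif ev.type == "boundary_indel":
            # invisible in genome-space junction tables: reads carrying the
            # indel fail to produce a novel junction (the motivating blind
            # spot of genome alignment); ground truth only
            truth.append(GroundTruthEvent(
                type=ev.type, gene=ev.gene, sample=ev.sample,
                detail={"tx_del": ev.tx_del},
            ))

    # background noise: sporadic novel junctions sharing one annotated end
    noise_rate = config.noise_rate * (config.chx_noise_factor if config.chx else 1.0)
    ann_set = set(ann_keys)
    for sample in samples:
        n_noise = rng.poisson(config.noise_junctions_per_sample)
        for _ in range(n_noise):
            base = ann_keys[rng.integers(0, len(ann_keys))]
            chrom, s0, e0, strand = base
            if rng.random() < 0.5:
                key = (chrom, s0, e0 + int(rng.integers(20, 120)), strand)
            else:
                key = (chrom, max(1, s0 - int(rng.integers(20, 120))), e0, strand)
            if key in ann_set:
                continue
            cnt = int(rng.poisson(noise_rate * config.depth_mean * lib[sample]))
            if cnt <= 0:
                continue
            counts.setdefault(key, {s: 0 for s in samples})[sample] += cnt

    index = pd.MultiIndex.from_tuples(
        sorted(counts), names=["chrom", "intron_start", "intron_end", "strand"]
    )
    frame = pd.DataFrame(
        [[counts[k].get(s, 0) for s in samples] for k in sorted(counts)],
        index=index,
        columns=samples,
    )
    matrix = JunctionCountMatrix(counts=frame)
    return matrix, truth


def write_sj_dir(matrix: JunctionCountMatrix, outdir: str) -> dict[str, str]:
    """Write one STAR-dialect SJ.out.tab per sample (zero rows omitted)."""
    os.makedirs(outdir, exist_ok=True)
    strand_code = {"?": 0, "+": 1, "-": 2}
    paths = {}
    for sample in matrix.samples:
        path = os.path.join(outdir, f"{sample}.SJ.out.tab")
        with open(path, "w") as fh:
            for key in matrix.counts.index:
                cnt = int(matrix.counts.at[key, sample])
                if cnt == 0:
                    continue
                chrom, s, e, strand = key
                fh.write(
                    f"{chrom}\t{s}\t{e}\t{strand_code.get(strand, 0)}\t1\t"
                    f"{int(bool(matrix.annotated.at[key]))}\t{cnt}\t0\t30\n"
                )
        paths[sample] = path
    return paths


# ---------------------------------------------------------------------------
# quantification table


def simulate_quant_table(
    config: SimulationConfig, annotation: ToyAnnotation
) -> tuple[pd.DataFrame, list[GroundTruthEvent]]:
    """Tidy per-transcript TPM table with isoform-shift / knockdown events.

    Isoform shifts move TPM mass between isoforms holding the gene total
    constant (the redistribution signature); knockdowns scale the gene
    total in the target sample.
    """
    rng = np.random.default_rng(config.seed + 1)
    models = annotation.models
    samples = config.samples
    by_gene: dict[str, list[TranscriptModel]] = {}
    for tx in models.values():
        by_gene.setdefault(tx.gene_symbol, []).append(tx)

    base_totals = {g: float(rng.uniform(50, 200)) for g in sorted(by_gene)}
    shift = {(e.gene, e.sample): e.magnitude for e in config.events if e.type == "isoform_shift"}
    knock = {(e.gene, e.sample): e.magnitude for e in config.events if e.type == "knockdown"}
    truth = [
        GroundTruthEvent(type=e.type, gene=e.gene, sample=e.sample,
                         detail={"magnitude": e.magnitude})
        for e in config.events
        if e.type in ("isoform_shift", "knockdown")
    ]

    rows = []
    for gene, txs in sorted(by_gene.items()):
        txs = sorted(txs, key=lambda t: (not t.is_representative, t.tx_id))
        rep, alts = txs[0], txs[1:]
        base_alt_frac = 0.05
        for sample in samples:
            total = base_totals[gene] * float(np.exp(rng.normal(0.0, 0.05)))
            total *= knock.get((gene, sample), 1.0)
            alt_frac = shift.get((gene, sample), base_alt_frac) if alts else 0.0
            per_alt = alt_frac / len(alts) if alts else 0.0
            fracs = [1.0 - alt_frac] + [per_alt] * len(alts)
            for tx, frac in zip(txs, fracs):
                tpm = total * frac
                rows.append(
                    {"tx_id": tx.tx_id, "gene_id": gene, "sample": sample,
                     "TPM": tpm, "est_counts": tpm * 20.0}
                )
    return pd.DataFrame(rows), truth


# ---------------------------------------------------------------------------
# realignment reads


def _apply_deletion(seq: str, tx_del: tuple[int, int]) -> str:
    lo, hi = tx_del
    return seq[: lo - 1] + seq[hi:]


def simulate_realign_reads(
    config: SimulationConfig, annotation: ToyAnnotation
) -> tuple[dict[str, list[tuple[str, str]]], list[GroundTruthEvent]]:
    """Per-sample reads from target transcripts, cases carrying an indel.

    Reads are drawn uniformly from a targeted window around the event
    locus (candidate-gene-directed sequencing at desk scale); in case
    samples a ``fraction`` of reads comes from the event haplotype.  A
    per-base substitution error rate is applied; half the reads are
    emitted reverse-complemented.
    """
    rng = np.random.default_rng(config.seed + 2)
    tx_seqs = annotation.transcript_sequences()
    events = [e for e in config.events if e.type == "boundary_indel"]
    if not events:
        raise ValueError("simulate_realign_reads needs >= 1 boundary_indel event")
    comp = str.maketrans("ACGT", "TGCA")
    bases = np.array(list("ACGT"))

    reads: dict[str, list[tuple[str, str]]] = {s: [] for s in config.samples}
    truth: list[GroundTruthEvent] = []
    for ev in events:
        reps = [m for m in annotation.models.values()
                if m.gene_symbol == ev.gene and m.is_representative]
        if not reps:
            raise ValueError(f"event gene {ev.gene!r} absent from annotation")
        tx = reps[0]
        ref = tx_seqs[tx.tx_id]
        mut = _apply_deletion(ref, ev.tx_del)
        truth.append(GroundTruthEvent(
            type="boundary_indel", gene=ev.gene, sample=ev.sample,
            detail={"tx_id": tx.tx_id, "tx_del": ev.tx_del,
                    "length": ev.tx_del[1] - ev.tx_del[0] + 1},
        ))
        L = config.read_length
        # targeted window: every read overlaps the event anchor
        anchor = ev.tx_del[0] - 1
        for sample in config.samples:
            for i in range(config.reads_per_sample):
                use_mut = sample == ev.sample and rng.random() < ev.fraction
                template = mut if use_mut else ref
                flank = max(10, min(30, (L - 10) // 2))
                lo = max(0, anchor - L + flank)
                hi = min(max(1, len(template) - L), anchor - flank)
                start = int(rng.integers(lo, max(lo + 1, hi)))
                seq = list(template[start : start + L])
                errs = rng.random(len(seq)) < config.error_rate
                for j in np.flatnonzero(errs):
                    seq[j] = str(bases[(int(bases.searchsorted(seq[j])) + int(rng.integers(1, 4))) % 4])
                read = "".join(seq)
                if rng.random() < 0.5:
                    read = read.translate(comp)[::-1]
                reads[sample].append((f"{sample}:{tx.tx_id}:{i}", read))
    return reads, truth


def write_fastq(reads: dict[str, list[tuple[str, str]]], outdir: str) -> dict[str, str]:
    os.makedirs(outdir, exist_ok=True)
    paths = {}
    for sample, rs in reads.items():
        path = os.path.join(outdir, f"{sample}.fastq")
        with open(path, "w") as fh:
            for rid, seq in rs:
                fh.write(f"@{rid}\n{seq}\n+\n{'I' * len(seq)}\n")
        paths[sample] = path
    return paths


# ---------------------------------------------------------------------------
# the 55-family cohort fixture


_POSITIVE_FAMILIES = [
    # family, tier, gene, attributed stage, RNA effect, definitive diagnosis
    ("1", "suspected_gene_variant_negative", "FANCA", "pharmacological",
     "r.2981_2982ins2982-197_2982-281", True),
    ("11", "VUS", "C1QBP", "conventional_splicing", "exon 4 skipping", True),
    ("15", "suspected_gene_variant_negative", "GALC", "pharmacological",
     "r.1489_1490ins[1490-453_1490-489]", True),
    ("17", "VUS", "KAT6A", "MANE_realign", "r.2416_2436del21", False),
    ("20", "VUS", "PKD2", "TID", "exon 9 skipping", True),
    ("21", "suspected_gene_variant_negative", "ERCC8", "conventional_splicing",
     "exon 4 skipping", True),
    ("46", "unsolved_no_candidate", "NAA15", "conventional_splicing",
     "r.1014_1015ins[r.1014+1102_1014+1199]", True),
    ("47", "VUS", "CLN6", "TID", "exon 3 skipping", True),
    ("48", "suspected_gene_variant_negative", "HGSNAT", "conventional_splicing",
     "exon 3-4 skipping", True),
    ("54", "unsolved_no_candidate", "GLUL", "conventional_splicing", "r.-13_13del26", True),
    ("55", "VUS", "GATAD2B", "MANE_realign", "r.287_335del49", True),
]

_TIER_SIZES = {"VUS": 7, "suspected_gene_variant_negative": 10, "unsolved_no_candidate": 38}


def make_table1_cohort() -> tuple[list[FamilyRecord], dict[str, dict[str, list[Finding]]]]:
    """The 55-family cohort fixture with per-family stage findings.

    Returns (family records, stage_outputs) where ``stage_outputs`` maps
    family ID -> stage -> findings, ready for
    :func:`splicedx.cohort.classify_family`.  Tier totals are 7 / 10 / 38;
    the 11 positive families carry their reported stage, gene and RNA
    effect; the remaining 44 families are negative at every stage.
    """
    records: list[FamilyRecord] = []
    outputs: dict[str, dict[str, list[Finding]]] = {}
    used = set()
    for fam, tier, gene, stage, effect, definitive in _POSITIVE_FAMILIES:
        rec = FamilyRecord(
            family_id=fam, tier=tier, candidate_genes={gene},
            samples=[f"F{fam}-proband"],
        )
        rec.definitive = definitive
        records.append(rec)
        outputs[fam] = {stage: [Finding(stage=stage, gene=gene, description=effect)]}
        used.add(fam)
    # reported-negative VUS families
    for fam in ("18", "40"):
        records.append(FamilyRecord(family_id=fam, tier="VUS",
                                    candidate_genes={"GENEX"}, samples=[f"F{fam}-proband"]))
        outputs[fam] = {}
        used.add(fam)
    remaining = [str(i) for i in range(1, 56) if str(i) not in used]
    need = {
        tier: _TIER_SIZES[tier] - sum(1 for r in records if r.tier == tier)
        for tier in _TIER_SIZES
    }
    cursor = 0
    for tier in ("VUS", "suspected_gene_variant_negative", "unsolved_no_candidate"):
        for _ in range(need[tier]):
            fam = remaining[cursor]
            cursor += 1
            records.append(FamilyRecord(family_id=fam, tier=tier,
                                        candidate_genes={"GENEX"},
                                        samples=[f"F{fam}-proband"]))
            outputs[fam] = {}
    records.sort(key=lambda r: int(r.family_id))
    return records, outputs


def cohort_manifest_frame(records: list[FamilyRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "family_id": r.family_id,
                "tier": r.tier,
                "candidate_genes": ";".join(sorted(r.candidate_genes)),
                "samples": ";".join(r.samples),
            }
            for r in records
        ]
    )
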