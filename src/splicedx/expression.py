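"""Expression filters, outliers, allelic imbalance and signature concordance.

These are the deliberately transparent substitutes for the conventional
pipeline's expression stages: an expressed-gene filter (TPM and exonic
coverage floors), panel detection proportions, a robust-z expression
outlier rule (median/MAD on log2 TPM, leave-one-in — explicitly *not* an
autoencoder-based confounder-corrected caller), an exact binomial test
for allelic expression imbalance at heterozygous sites, and a Fisher
exact enrichment of a case DEG list against a pathway signature.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable

import numpy as np
import pandas as pd
from scipy import stats

from splicedx.intervals import GenomeInterval

METHOD_LABELS = {
    "expression_outliers": "robust-z (median/MAD of log2 TPM); not confounder-corrected",
    "allelic_imbalance": "exact binomial test vs 0.5",
}


@dataclass
class ExpressionMatrix:
    """Gene x sample TPM plus mean exonic coverage layers."""

    tpm: pd.DataFrame
    coverage: pd.DataFrame

    def __post_init__(self) -> None:
        if (self.tpm.to_numpy() < 0).any() or (self.coverage.to_numpy() < 0).any():
            raise ValueError("TPM and coverage must be non-negative")
        if not self.tpm.index.equals(self.coverage.index) or not self.tpm.columns.equals(
            self.coverage.columns
        ):
            raise ValueError("TPM and coverage layers must share genes and samples")


@dataclass
class AllelicCount:
    gene_symbol: str
    site: GenomeInterval  # 1 bp
    ref_count: int
    alt_count: int

    def __post_init__(self) -> None:
        if self.ref_count < 0 or self.alt_count < 0:
            raise ValueError("allele counts must be non-negative")


@dataclass
class AeiResult:
    evaluable: bool
    ratio: float | None = None
    p_value: float | None = None


def expressed_gene_filter(
    matrix: ExpressionMatrix,
    stat: str = "mean",
    tpm_floor: float = 1.0,
    cov_floor: float = 10.0,
) -> set[str]:
    """Genes with stat(TPM) > tpm_floor AND stat(coverage) > cov_floor.

    ``stat`` is "mean" (cohort-wide expressed-gene convention) or
    "median" (the panel-detection convention).
    """
    if stat not in ("mean", "median"):
        raise ValueError(f"unknown statistic {stat!r}; use 'mean' or 'median'")
    agg_tpm = getattr(matrix.tpm, stat)(axis=1)
    agg_cov = getattr(matrix.coverage, stat)(axis=1)
    keep = (agg_tpm > tpm_floor) & (agg_cov > cov_floor)
    return set(matrix.tpm.index[keep])


def panel_detection_rate(gene_set: Iterable[str], panel: Iterable[str]) -> float:
    """Fraction of a disease gene panel meeting the expression thresholds."""
    panel = set(panel)
    if not panel:
        raise ValueError("empty gene panel")
    return len(set(gene_set) & panel) / len(panel)


def expression_outliers(
    matrix: ExpressionMatrix,
    sample: str,
    panel: Iterable[str],
    z_threshold: float = 3.0,
) -> pd.DataFrame:
    """Panel genes whose log2 TPM robust z-score exceeds the threshold.

    z = (log2(TPM+1)_sample - cohort median) / (1.4826 * MAD); the sample
    itself stays in the cohort statistics (leave-one-in).  Genes with
    MAD 0 are skipped (flagged in the ``note`` column of the output).
    """
    if sample not in matrix.tpm.columns:
        raise KeyError(f"sample {sample!r} not in matrix")
    if matrix.tpm.shape[1] < 5:
        raise ValueError("expression outlier calling needs >= 5 samples")
    panel = set(panel)
    log_tpm = np.log2(matrix.tpm + 1.0)
    med = log_tpm.median(axis=1)
    mad = (log_tpm.sub(med, axis=0)).abs().median(axis=1)
    rows = []
    for gene in matrix.tpm.index:
        if gene not in panel:
            continue
        if mad[gene] == 0:
            rows.append({"gene": gene, "z": math.nan, "note": "MAD=0, skipped"})
            continue
        z = (log_tpm.at[gene, sample] - med[gene]) / (1.4826 * mad[gene])
        if abs(z) >= z_threshold:
            rows.append({"gene": gene, "z": float(z), "note": ""})
    return pd.DataFrame(rows, columns=["gene", "z", "note"])


def allelic_imbalance(ac: AllelicCount, min_depth: int = 20) -> AeiResult:
    """Alt-allele fraction and exact binomial two-sided p-value vs 0.5.

    Sites below ``min_depth`` total reads are not evaluable (distinct
    from balanced).
    """
    depth = ac.ref_count + ac.alt_count
    if depth < min_depth:
        return AeiResult(evaluable=False)
    ratio = ac.alt_count / depth
    p = stats.binomtest(ac.alt_count, depth, 0.5, alternative="two-sided").pvalue
    return AeiResult(evaluable=True, ratio=ratio, p_value=float(p))


def signature_concordance(
    case_deg: Iterable[str], background: Iterable[str], signature: Iterable[str]
) -> dict:
    """Fisher exact enrichment of a case DEG list in a pathway signature.

    The 2x2 table crosses membership in ``case_deg`` with membership in
    ``signature`` over the ``background`` gene universe (both sets are
    intersected with the background first).
    """
    background = set(background)
    if not background:
        raise ValueError("empty background gene universe")
    deg = set(case_deg) & background
    sig = set(signature) & background
    a = len(deg & sig)
    b = len(deg - sig)
    c = len(sig - deg)
    d = len(background - deg - sig)
    odds, p = stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")
    return {
        "overlap": a,
        "odds_ratio": float(odds) if not math.isinf(odds) else math.inf,
        "p_value": float(p),
        "table": ((a, b), (c, d)),
    }
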