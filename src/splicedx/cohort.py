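"""Cohort-level diagnostic-yield reporting.

Families enter the pipeline under a three-tier clinical stratification
based on their prior DNA findings:

* ``VUS`` — a variant of uncertain significance awaits functional
  support;
* ``suspected_gene_variant_negative`` — a gene is strongly suspected (or
  one pathogenic allele known) but DNA sequencing found no (second)
  variant;
* ``unsolved_no_candidate`` — open-ended cases with no genetic lead.

Stages run sequentially (conventional splicing/expression -> TID ->
transcriptome realignment -> pharmacological re-analysis); a family is
positive at the first stage producing a candidate-gene finding.  The
pharmacological stage is only evaluated for the two candidate-bearing
tiers, mirroring a hypothesis-driven re-culture of cryopreserved cells.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

TIERS = ("VUS", "suspected_gene_variant_negative", "unsolved_no_candidate")

STAGE_ORDER = (
    "conventional_splicing",
    "conventional_expression",
    "TID",
    "MANE_realign",
    "pharmacological",
)

CONVENTIONAL_STAGES = {"conventional_splicing", "conventional_expression"}

PHARMACOLOGICAL_TIERS = {"VUS", "suspected_gene_variant_negative"}


@dataclass
class Finding:
    stage: str
    gene: str
    description: str = ""

    def __post_init__(self) -> None:
        if self.stage not in STAGE_ORDER:
            raise ValueError(f"unknown stage {self.stage!r}")


@dataclass
class FamilyRecord:
    family_id: str
    tier: str
    candidate_genes: set[str] = field(default_factory=set)
    samples: list[str] = field(default_factory=list)
    findings: list[Finding] = field(default_factory=list)
    incidental: list[Finding] = field(default_factory=list)
    definitive: bool = False

    def __post_init__(self) -> None:
        if self.tier not in TIERS:
            raise ValueError(f"unknown tier {self.tier!r}")

    @property
    def status(self) -> str:
        return "positive" if self.findings else "negative"


def classify_family(
    record: FamilyRecord, stage_outputs: Mapping[str, Iterable[Finding]]
) -> FamilyRecord:
    """Apply stage outputs to a family in pipeline order.

    ``stage_outputs`` maps stage name -> findings for this family.  The
    first stage with a candidate-gene finding sets the family positive
    with that attribution; later stages are not consulted (sequential
    flow).  A finding in a gene outside the family's candidate set is
    recorded as incidental and does not flip status.  The
    pharmacological stage is skipped for the no-candidate tier.
    """
    record.findings = []
    record.incidental = []
    for stage in STAGE_ORDER:
        if stage == "pharmacological" and record.tier not in PHARMACOLOGICAL_TIERS:
            continue
        hits = list(stage_outputs.get(stage, ()))
        in_panel = [
            f for f in hits
            if not record.candidate_genes or f.gene in record.candidate_genes
        ]
        record.incidental.extend(f for f in hits if f not in in_panel)
        if in_panel and not record.findings:
            record.findings = in_panel
            # conventional splicing and expression form one stage wall:
            # stop at the first positive stage
            break
    return record


@dataclass
class YieldReport:
    n_total: int
    n_positive: int
    n_definitive: int
    overall_rate: float  # percent, printed precision
    conventional_rate: float
    fold_improvement: float | None
    per_tier: dict  # tier -> dict(n, positive, rate)
    per_stage_attribution: dict  # stage -> sorted family ids
    raw: dict  # unrounded fractions + alternate roundings


def diagnostic_yield(cohort: Iterable[FamilyRecord]) -> YieldReport:
    """Aggregate classified families into the yield report.

    Rates are reported as percentages at the conventional printed
    precision: integer percent overall, per the VUS and suspected tiers,
    and for the conventional comparator; one decimal for the large
    no-candidate tier.  The unsolved-tier rate is additionally emitted
    both floor-rounded and half-up-rounded in ``raw`` (2/38 sits between
    the two conventions).  A family counts as *conventional* positive
    when its attributed stage is conventional splicing or expression.
    """
    families = list(cohort)
    if not families:
        raise ValueError("empty cohort")
    ids = [f.family_id for f in families]
    if len(ids) != len(set(ids)):
        raise ValueError("duplicate family IDs in cohort")
    n = len(families)
    positives = [f for f in families if f.status == "positive"]
    conventional = [
        f for f in positives if f.findings[0].stage in CONVENTIONAL_STAGES
    ]
    per_tier = {}
    for tier in TIERS:
        fam = [f for f in families if f.tier == tier]
        pos = [f for f in fam if f.status == "positive"]
        if fam:
            frac = 100.0 * len(pos) / len(fam)
            rate = round(frac, 1) if tier == "unsolved_no_candidate" else float(round(frac))
        else:
            rate = 0.0
        per_tier[tier] = {"n": len(fam), "positive": len(pos), "rate": rate}
    attribution: dict[str, list[str]] = {}
    for f in positives:
        attribution.setdefault(f.findings[0].stage, []).append(f.family_id)
    for stage in attribution:
        attribution[stage].sort()
    overall = float(round(100.0 * len(positives) / n))
    conv = float(round(100.0 * len(conventional) / n))
    fold = round(len(positives) / len(conventional), 1) if conventional else None
    unsolved_frac = (
        100.0 * per_tier["unsolved_no_candidate"]["positive"] / per_tier["unsolved_no_candidate"]["n"]
        if per_tier["unsolved_no_candidate"]["n"]
        else 0.0
    )
    return YieldReport(
        n_total=n,
        n_positive=len(positives),
        n_definitive=sum(1 for f in positives if f.definitive),
        overall_rate=overall,
        conventional_rate=conv,
        fold_improvement=fold,
        per_tier=per_tier,
        per_stage_attribution=attribution,
        raw={
            "overall_fraction": len(positives) / n,
            "conventional_fraction": len(conventional) / n,
            # 2/38 = 5.263%: both one-decimal conventions, made visible
            "unsolved_rate_rounded": round(unsolved_frac, 1),
            "unsolved_rate_floored": int(unsolved_frac * 10) / 10.0,
        },
    )
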