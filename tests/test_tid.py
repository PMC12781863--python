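"""Inclusion levels, differential events and transcript isoform ratios."""

import math

import numpy as np
import pandas as pd
import pytest

from splicedx.junctions import JunctionKey
from splicedx.tid import (
    SplicingEvent,
    compute_psi,
    compute_tid,
    differential_events,
    enumerate_events,
    match_event_to_isoforms,
    tid_outliers,
)


def _se_event(inc, skip, samples=("case",)):
    """SE event with per-sample effective counts supplied directly."""
    e = SplicingEvent(
        event_id="e1",
        gene_symbol="G",
        event_type="SE",
        inclusion_junctions=[JunctionKey("c", 100, 200), JunctionKey("c", 301, 400)],
        skipping_junctions=[JunctionKey("c", 100, 400)],
    )
    for s in samples:
        e.inclusion_counts[s] = inc[s] if isinstance(inc, dict) else inc
        e.skipping_counts[s] = skip[s] if isinstance(skip, dict) else skip
    return e


class TestPsi:
    def test_mean_of_inclusion_junctions(self):
        e = _se_event(90.0, 10.0)
        assert compute_psi(e, "case") == pytest.approx(0.9)

    def test_uninformative_counts_are_missing(self):
        e = _se_event(0.0, 0.0)
        assert math.isnan(compute_psi(e, "case"))
        e = _se_event(4.0, 4.0)  # 8 < 10 informative reads
        assert math.isnan(compute_psi(e, "case"))

    def test_empty_junction_lists_rejected(self):
        e = SplicingEvent("e", "G", "SE", [], [JunctionKey("c", 1, 2)])
        with pytest.raises(ValueError, match="empty junction"):
            compute_psi(e, "case")

    def test_scale_free(self):
        a = compute_psi(_se_event(30.0, 10.0), "case")
        b = compute_psi(_se_event(300.0, 100.0), "case")
        assert a == pytest.approx(b)

    def test_simulation_recovers_true_inclusion_level(self):
        # binomial junction sampling at depth 200, true psi 0.5
        rng = np.random.default_rng(42)
        estimates = []
        for _ in range(100):
            inc = rng.binomial(200, 0.5)
            e = _se_event(float(inc), float(200 - inc))
            estimates.append(compute_psi(e, "case"))
        assert abs(np.mean(estimates) - 0.5) < 0.02
        assert np.std(estimates) < 2 * math.sqrt(0.25 / 200) * 1.5


class TestDifferentialEvents:
    def _events(self, case_psi, ctrl_psi, depth=400, n=1):
        events = []
        samples = ["case", "k1", "k2", "k3"]
        for i in range(n):
            e = _se_event(
                {"case": case_psi * depth, "k1": ctrl_psi * depth,
                 "k2": ctrl_psi * depth, "k3": ctrl_psi * depth},
                {"case": (1 - case_psi) * depth, "k1": (1 - ctrl_psi) * depth,
                 "k2": (1 - ctrl_psi) * depth, "k3": (1 - ctrl_psi) * depth},
                samples,
            )
            e.event_id = f"e{i}"
            events.append(e)
        return events

    def test_large_shift_retained(self):
        retained = differential_events(self._events(0.9, 0.5), "case", ["k1", "k2", "k3"])
        assert len(retained) == 1
        assert retained[0].delta_psi == pytest.approx(0.4)
        assert retained[0].fdr < 1e-6

    def test_small_delta_rejected_regardless_of_p(self):
        retained = differential_events(
            self._events(0.60, 0.50, depth=100_000), "case", ["k1", "k2", "k3"]
        )
        assert retained == []

    def test_requires_three_controls(self):
        with pytest.raises(ValueError, match="3 control"):
            differential_events(self._events(0.9, 0.5), "case", ["k1", "k2"])

    def test_bh_matches_step_up_oracle(self):
        from statsmodels.stats.multitest import multipletests

        rng = np.random.default_rng(3)
        p = rng.uniform(size=200)
        got = multipletests(p, method="fdr_bh")[1]
        # independent step-up oracle
        order = np.argsort(p)
        n = len(p)
        adj = np.empty(n)
        running = 1.0
        for rank in range(n, 0, -1):
            i = order[rank - 1]
            running = min(running, p[i] * n / rank)
            adj[i] = running
        assert np.allclose(got, adj)

    def test_null_false_positive_fraction_controlled(self):
        # shared binomial psi in case and controls: BH-significant fraction
        # should not exceed the nominal level by much
        rng = np.random.default_rng(7)
        events = []
        samples = ["case", "k1", "k2", "k3"]
        for i in range(300):
            psi = rng.uniform(0.2, 0.8)
            e = SplicingEvent(
                f"e{i}", "G", "SE",
                [JunctionKey("c", 1, 2)], [JunctionKey("c", 1, 9)],
            )
            for s in samples:
                inc = rng.binomial(200, psi)
                e.inclusion_counts[s] = float(inc)
                e.skipping_counts[s] = float(200 - inc)
            events.append(e)
        retained = differential_events(events, "case", ["k1", "k2", "k3"])
        assert len(retained) / 300 <= 0.05


class TestEventIsoformMatching:
    def test_cassette_exon_pair_found(self, models):
        events = enumerate_events(models)
        pkd_events = [e for e in events if e.gene_symbol == "PKD2L"]
        assert len(pkd_events) == 1
        pairs = match_event_to_isoforms(pkd_events[0], models)
        assert len(pairs) == 1
        inc, exc = pairs[0]
        assert inc.tx_id == "PKD2L-201" and inc.is_representative
        assert exc.tx_id == "PKD2L-202"

    def test_minus_strand_gene_pair(self, models):
        events = enumerate_events(models)
        cln = [e for e in events if e.gene_symbol == "CLN6L"]
        assert len(cln) == 1
        pairs = match_event_to_isoforms(cln[0], models)
        assert {p[0].tx_id for p in pairs} == {"CLN6L-201"}
        # the included segment is exon 3 in transcription order
        tx = models["CLN6L-201"]
        seg = cln[0].included_segment
        assert (seg.start, seg.end) == (tx.exons[2].start, tx.exons[2].end)

    def test_unrealized_event_yields_empty_list(self, models):
        from splicedx.intervals import GenomeInterval

        e = SplicingEvent(
            "x", "GALCL", "SE", [JunctionKey("chrT", 1, 2)], [JunctionKey("chrT", 1, 9)],
            included_segment=GenomeInterval("chrT", 5, 50),
        )
        assert match_event_to_isoforms(e, models) == []


class TestTid:
    def _quant(self, tids, rep_tpm=10.0):
        rows = []
        for sample, ratio in tids.items():
            rows.append({"tx_id": "REP", "gene_id": "G", "sample": sample, "TPM": rep_tpm})
            rows.append({"tx_id": "ALT", "gene_id": "G", "sample": sample, "TPM": ratio * rep_tpm})
        return pd.DataFrame(rows)

    def test_ratio(self):
        q = self._quant({"a": 0.5})
        rec = compute_tid(q, "ALT", "REP")
        assert rec.tid["a"] == pytest.approx(0.5)

    def test_representative_floor_guards_division(self):
        q = pd.DataFrame([
            {"tx_id": "REP", "gene_id": "G", "sample": "a", "TPM": 0.2},
            {"tx_id": "ALT", "gene_id": "G", "sample": "a", "TPM": 3.0},
        ])
        rec = compute_tid(q, "ALT", "REP", rep_floor=1.0)
        assert math.isnan(rec.tid["a"])

    def test_unknown_transcript_raises(self):
        with pytest.raises(KeyError):
            compute_tid(self._quant({"a": 0.5}), "NOPE", "REP")

    def test_scale_free(self):
        q1 = self._quant({"a": 0.5}, rep_tpm=10)
        q2 = self._quant({"a": 0.5}, rep_tpm=1000)
        assert compute_tid(q1, "ALT", "REP").tid["a"] == pytest.approx(
            compute_tid(q2, "ALT", "REP").tid["a"]
        )

    def test_outlier_rule(self):
        rec = compute_tid(self._quant({"a": 0.40, "b": 0.10, "c": 0.08, "d": 0.05}), "ALT", "REP")
        assert tid_outliers(rec) == {"a"}

    def test_no_flag_below_fold(self):
        rec = compute_tid(self._quant({"a": 0.40, "b": 0.30, "c": 0.05}), "ALT", "REP")
        assert tid_outliers(rec) == set()

    def test_too_few_defined_values_warns(self):
        rec = compute_tid(self._quant({"a": 0.4, "b": 0.1}), "ALT", "REP")
        with pytest.warns(UserWarning, match="fewer than 3"):
            assert tid_outliers(rec) == set()

    def test_family_mode_flags_co_affected_relatives(self):
        tids = {"proband": 0.40, "father": 0.35, "k1": 0.05, "k2": 0.06, "k3": 0.04}
        rec = compute_tid(self._quant(tids), "ALT", "REP")
        # cohort-wide: proband not 2x the father -> neither flagged
        assert tid_outliers(rec) == set()
        fam = {"proband": {"father"}, "father": {"proband"}}
        assert tid_outliers(rec, co_affected=fam) == {"proband", "father"}


class TestEndToEndRecovery:
    def test_isoform_shift_seen_by_tid_not_by_junctions(self, toy_annotation):
        from splicedx.junctions import annotate_matrix, call_aberrant_splicing
        from splicedx.simulate import (
            EventSpec, SimulationConfig, simulate_junction_cohort, simulate_quant_table,
        )

        for seed in range(3):
            cfg = SimulationConfig(
                seed=seed,
                events=[EventSpec(type="isoform_shift", gene="PKD2L", magnitude=0.40)],
            )
            quant, _ = simulate_quant_table(cfg, toy_annotation)
            rec = compute_tid(quant, "PKD2L-202", "PKD2L-201")
            assert tid_outliers(rec) == {"case"}
            totals = quant[quant.gene_id == "PKD2L"].groupby("sample").TPM.sum()
            assert totals.std() / totals.mean() < 0.2  # no expression-level signal
            matrix, _ = simulate_junction_cohort(cfg, toy_annotation)
            matrix = annotate_matrix(matrix, toy_annotation.models)
            calls = [c for c in call_aberrant_splicing(matrix) if c.gene_symbol == "PKD2L"]
            assert calls == []
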