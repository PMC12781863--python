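"""Junction matrix ingestion, local normalization and the four-filter caller."""

import math

import numpy as np
import pandas as pd
import pytest

from splicedx.junctions import (
    JunctionCountMatrix,
    JunctionKey,
    annotate_matrix,
    call_aberrant_splicing,
    normalize_junction,
    read_junction_tables,
    restrict_to_panel,
)


def _matrix(rows, samples, annotated, shares=None, genes=None):
    """rows: {key tuple: [counts per sample]}"""
    index = pd.MultiIndex.from_tuples(rows.keys())
    counts = pd.DataFrame(list(rows.values()), index=index, columns=samples)
    m = JunctionCountMatrix(counts=counts)
    m.annotated = pd.Series([k in annotated for k in rows], index=m.counts.index)
    shares = shares if shares is not None else set(rows) - set()
    m.shares_annotated_end = pd.Series(
        [k in annotated or k in shares for k in rows], index=m.counts.index
    )
    if genes:
        m.gene_symbol = pd.Series([genes.get(k, ".") for k in rows], index=m.counts.index)
    return m


class TestReaders:
    def test_star_tables_merge_with_zero_fill(self, tmp_path):
        a = tmp_path / "a.SJ.out.tab"
        b = tmp_path / "b.SJ.out.tab"
        a.write_text("chr1\t100\t200\t1\t1\t1\t50\t0\t30\nchr1\t300\t400\t1\t1\t0\t7\t0\t30\n")
        b.write_text("chr1\t100\t200\t1\t1\t1\t60\t0\t30\nchr1\t500\t600\t2\t1\t0\t4\t0\t30\n")
        m = read_junction_tables({"A": str(a), "B": str(b)})
        assert len(m.junctions) == 3
        key = ("chr1", 100, 200, "+")
        assert m.counts.at[key, "A"] == 50 and m.counts.at[key, "B"] == 60
        assert m.counts.at[("chr1", 300, 400, "+"), "B"] == 0

    def test_bed_dialect_coordinate_conversion(self, tmp_path):
        p = tmp_path / "x.tsv"
        p.write_text("chr1\t99\t200\tj1\t12\t+\n")
        m = read_junction_tables({"A": str(p)}, dialect="bed")
        assert m.junctions == [JunctionKey("chr1", 100, 200, "+")]
        assert m.counts.at[("chr1", 100, 200, "+"), "A"] == 12

    def test_duplicate_rows_rejected(self, tmp_path):
        p = tmp_path / "a.SJ.out.tab"
        p.write_text("chr1\t100\t200\t1\t1\t1\t50\t0\t30\nchr1\t100\t200\t1\t1\t1\t5\t0\t30\n")
        with pytest.raises(ValueError, match="duplicate"):
            read_junction_tables({"A": str(p)})

    def test_generator_round_trip(self, toy_annotation, tmp_path):
        from splicedx.simulate import (
            EventSpec, SimulationConfig, simulate_junction_cohort, write_sj_dir,
        )

        cfg = SimulationConfig(
            seed=7, n_controls=3,
            events=[EventSpec(type="exon_skip", gene="GALCL", magnitude=0.3)],
        )
        matrix, _ = simulate_junction_cohort(cfg, toy_annotation)
        annotate_matrix(matrix, toy_annotation.models)
        paths = write_sj_dir(matrix, str(tmp_path))
        loaded = read_junction_tables(paths)
        for key in loaded.counts.index:
            for s in loaded.samples:
                assert loaded.counts.at[key, s] == matrix.counts.at[key, s]


class TestAnnotate:
    def test_flags_against_fixture_annotation(self, toy_annotation):
        models = toy_annotation.models
        galc = models["GALCL-201"]
        introns = galc.introns()
        exact = introns[0]
        rows = {
            # exact annotated intron
            (exact.chrom, exact.start + 1, exact.end, "+"): [5],
            # exon-skip junction: both ends annotated, pairing in no transcript
            (exact.chrom, introns[0].start + 1, introns[1].end, "+"): [5],
            # pseudoexon junction: annotated donor, intronic acceptor
            (exact.chrom, introns[12].start + 1, introns[12].start + 120, "+"): [5],
            # junction outside any gene
            ("chrUn", 10, 20, "+"): [5],
        }
        index = pd.MultiIndex.from_tuples(rows.keys())
        m = JunctionCountMatrix(pd.DataFrame(list(rows.values()), index=index, columns=["A"]))
        m = annotate_matrix(m, models)
        flags = list(zip(m.annotated, m.shares_annotated_end, m.gene_symbol))
        assert flags[0] == (True, True, "GALCL")
        assert flags[1] == (False, True, "GALCL")
        assert flags[2] == (False, True, "GALCL")
        assert flags[3] == (False, False, ".")

    def test_unknown_strand_matches_both(self, toy_annotation):
        cln = toy_annotation.models["CLN6L-201"]  # minus strand
        intron = cln.introns()[0]
        key = (intron.chrom, intron.start + 1, intron.end, "?")
        index = pd.MultiIndex.from_tuples([key])
        m = JunctionCountMatrix(pd.DataFrame([[3]], index=index, columns=["A"]))
        m = annotate_matrix(m, toy_annotation.models)
        assert bool(m.annotated.iloc[0])


class TestNormalization:
    def test_direct_arithmetic(self):
        rows = {
            ("c", 100, 200, "+"): [100],
            ("c", 201, 300, "+"): [80],
            ("c", 100, 300, "+"): [10],  # novel, spans both canonical boundaries
        }
        m = _matrix(rows, ["A"], annotated={("c", 100, 200, "+"), ("c", 201, 300, "+")})
        assert normalize_junction(m, ("c", 100, 300, "+"), "A") == pytest.approx(0.10)

    def test_zero_denominator_is_missing(self):
        rows = {
            ("c", 100, 200, "+"): [0],
            ("c", 201, 300, "+"): [0],
            ("c", 100, 300, "+"): [5],
        }
        m = _matrix(rows, ["A"], annotated={("c", 100, 200, "+"), ("c", 201, 300, "+")})
        assert math.isnan(normalize_junction(m, ("c", 100, 300, "+"), "A"))

    def test_unknown_junction_raises(self):
        m = _matrix({("c", 100, 200, "+"): [1]}, ["A"], annotated=set())
        with pytest.raises(KeyError):
            normalize_junction(m, ("c", 1, 2, "+"), "A")

    def test_matches_bruteforce_on_fixture_cohort(self):
        rng = np.random.default_rng(11)
        samples = [f"s{i}" for i in range(5)]
        ann = {("c", 100, 200, "+"), ("c", 201, 300, "+"), ("c", 301, 400, "+")}
        novel = {("c", 100, 300, "+"), ("c", 201, 400, "+"), ("c", 100, 250, "+")}
        rows = {k: list(rng.integers(0, 120, len(samples))) for k in sorted(ann | novel)}
        m = _matrix(rows, samples, annotated=ann)
        for key in novel:
            for s in samples:
                # brute force: max annotated count sharing either end
                shared = [
                    rows[a][samples.index(s)]
                    for a in ann
                    if a[1] in (key[1], key[2]) or a[2] in (key[1], key[2])
                ]
                d = max(shared) if shared else 0
                expect = rows[key][samples.index(s)] / d if d > 0 else math.nan
                got = normalize_junction(m, key, s)
                assert (math.isnan(got) and math.isnan(expect)) or got == pytest.approx(expect)

    def test_invariant_under_per_sample_scaling(self):
        rows = {
            ("c", 100, 200, "+"): [100, 50],
            ("c", 201, 300, "+"): [80, 40],
            ("c", 100, 300, "+"): [10, 5],
        }
        ann = {("c", 100, 200, "+"), ("c", 201, 300, "+")}
        m1 = _matrix(rows, ["A", "B"], annotated=ann)
        scaled = {k: [v[0] * 7, v[1]] for k, v in rows.items()}
        m2 = _matrix(scaled, ["A", "B"], annotated=ann)
        key = ("c", 100, 300, "+")
        assert normalize_junction(m1, key, "A") == normalize_junction(m2, key, "A")


def _four_filter_oracle(m, min_reads=5, min_norm=0.05, fold=2.0):
    """Independent brute-force reimplementation of the filter cascade."""
    hits = set()
    keys = list(m.counts.index)
    for key in keys:
        if m.annotated.at[key] or not m.shares_annotated_end.at[key]:
            continue
        chrom, s, e, strand = key
        denom = [
            k for k in keys
            if k != key and m.annotated.at[k] and k[0] == chrom
            and not (strand in "+-" and k[3] in "+-" and strand != k[3])
            and (k[1] in (s, e) or k[2] in (s, e))
        ]
        norms = {}
        for smp in m.samples:
            d = max((m.counts.at[k, smp] for k in denom), default=0)
            norms[smp] = m.counts.at[key, smp] / d if d > 0 else None
        for smp in m.samples:
            v = norms[smp]
            if m.counts.at[key, smp] < min_reads or v is None or v < min_norm:
                continue
            others = [norms[o] for o in m.samples if o != smp and norms[o] is not None]
            if any(o >= v for o in others):
                continue
            second = max(others) if others else 0
            if second > 0 and v < fold * second:
                continue
            hits.add((smp, key))
    return hits


def _random_matrix(rng, n_junc=20, n_samples=5):
    samples = [f"s{i}" for i in range(n_samples)]
    keys = set()
    while len(keys) < n_junc:
        s = int(rng.integers(1, 40))
        e = s + int(rng.integers(5, 60))
        keys.add(("c", s, e, rng.choice(["+", "-", "?"])))
    keys = sorted(keys)
    ann = {k for k in keys if rng.random() < 0.45}
    rows = {k: list(rng.integers(0, 60, n_samples)) for k in keys}
    ends = {(k[1], k[3]) for k in ann} | {(k[2], k[3]) for k in ann}

    def shares(k):
        if k in ann:
            return True
        for pos in (k[1], k[2]):
            for st in (["+", "-"] if k[3] == "?" else [k[3], "?"]):
                if (pos, st) in ends or (pos, "?") in ends:
                    return True
        return False

    # conservative end-sharing flags: the caller re-derives denominators
    # itself, the flag only gates filter (a)
    m = _matrix(rows, samples, annotated=ann, shares={k for k in keys if shares(k)})
    return m


class TestCaller:
    def test_clear_outlier_called(self):
        rows = {
            ("c", 100, 200, "+"): [40, 40, 40, 40],
            ("c", 100, 300, "+"): [12, 4, 2, 0],
        }
        m = _matrix(rows, ["case", "c1", "c2", "c3"], annotated={("c", 100, 200, "+")})
        calls = call_aberrant_splicing(m)
        assert len(calls) == 1
        c = calls[0]
        assert c.sample == "case" and c.raw_reads == 12
        assert c.normalized_value == pytest.approx(0.30)

    def test_fold_filter_boundary(self):
        # second-highest at 0.20: 0.30 < 2 x 0.20 -> no call
        rows = {
            ("c", 100, 200, "+"): [40, 40],
            ("c", 100, 300, "+"): [12, 8],
        }
        m = _matrix(rows, ["case", "c1"], annotated={("c", 100, 200, "+")})
        assert call_aberrant_splicing(m) == []

    def test_tied_maximum_yields_no_call(self):
        rows = {
            ("c", 100, 200, "+"): [40, 40],
            ("c", 100, 300, "+"): [12, 12],
        }
        m = _matrix(rows, ["a", "b"], annotated={("c", 100, 200, "+")})
        assert call_aberrant_splicing(m) == []

    def test_fewer_than_two_samples_rejected(self):
        m = _matrix({("c", 100, 200, "+"): [4]}, ["A"], annotated=set())
        with pytest.raises(ValueError, match="2 samples"):
            call_aberrant_splicing(m)

    def test_oracle_equivalence_randomized(self):
        rng = np.random.default_rng(23)
        for _ in range(25):
            m = _random_matrix(rng)
            got = {(c.sample, tuple(c.junction)) for c in call_aberrant_splicing(m)}
            assert got == _four_filter_oracle(m)

    def test_filter_monotonicity(self):
        rng = np.random.default_rng(5)
        m = _random_matrix(rng, n_junc=30)
        base = {(c.sample, tuple(c.junction)) for c in call_aberrant_splicing(m)}
        for kwargs in ({"min_reads": 8}, {"min_norm": 0.2}, {"fold_vs_second": 4.0}):
            tighter = {(c.sample, tuple(c.junction)) for c in call_aberrant_splicing(m, **kwargs)}
            assert tighter <= base


class TestPanel:
    def test_subset_and_identity(self):
        rows = {
            ("c", 100, 200, "+"): [40, 40],
            ("c", 100, 300, "+"): [12, 0],
        }
        m = _matrix(
            rows, ["case", "c1"], annotated={("c", 100, 200, "+")},
            genes={("c", 100, 300, "+"): "G1", ("c", 100, 200, "+"): "G1"},
        )
        calls = call_aberrant_splicing(m)
        assert len(restrict_to_panel(calls, {"G1", "G2"})) == 1
        assert restrict_to_panel(calls, {"G2"}) == []
        assert restrict_to_panel(calls, {c.gene_symbol for c in calls}) == calls

    def test_empty_panel_warns(self):
        with pytest.warns(UserWarning, match="empty"):
            assert restrict_to_panel([], set()) == []
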