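"""Unit and oracle tests for the twelve pairwise distance measures."""

import numpy as np
import pytest

from ligomap.datatypes import (
    DistanceMatrix,
    DomainHit,
    LigomapError,
    OntologyGraph,
    ProteinRecord,
)
from ligomap.distances import (
    correlation_screen,
    duplication_distance,
    expression_distance,
    gamma_distance,
    gamma_from_p,
    gk_gamma_distance,
    global_alignment,
    jaccard_distance,
    lms_distance,
    localization_distance,
    scale_unit_interval,
    semantic_distance,
    structural_distance,
    term_similarity,
    tm_d0,
    tm_score,
)

from _reference import (
    duplication_brute,
    gk_gamma_brute,
    jaccard_brute,
    lms_distance_brute,
    semantic_distance_brute,
    wang_similarity_brute,
)
from conftest import AA, random_protein


def protein_with_domains(domains, pid="P", seq_len=None):
    seq_len = seq_len or max(len(domains), 1) * 10
    arch = tuple(
        DomainHit(d, 1 + 10 * i, 10 * (i + 1)) for i, d in enumerate(domains)
    )
    return ProteinRecord(id=pid, sequence="A" * seq_len, architecture=arch)


# ---------------------------------------------------------------------------
# sequence layer
# ---------------------------------------------------------------------------

class TestLms:
    def test_self_distance_zero(self, blosum):
        p = ProteinRecord(id="p", sequence="MKTAYIAKQR")
        assert lms_distance(p, p, blosum) == 0.0

    def test_matches_fragment_enumeration_oracle(self, blosum, blosum_dict):
        rng = np.random.default_rng(42)
        for _ in range(60):
            p = random_protein(rng, rng.integers(6, 18), "p")
            q = random_protein(rng, rng.integers(6, 18), "q")
            expected = lms_distance_brute(p.sequence, q.sequence, blosum_dict)
            assert lms_distance(p, q, blosum) == pytest.approx(expected, abs=1e-12)

    def test_single_substitution_example(self, blosum, blosum_dict):
        p = ProteinRecord(id="p", sequence="MKTAYIAKQR")
        q = ProteinRecord(id="q", sequence="MKTAYIAKQW")
        expected = lms_distance_brute(p.sequence, q.sequence, blosum_dict)
        assert lms_distance(p, q, blosum) == pytest.approx(expected, abs=1e-12)
        assert lms_distance(p, q, blosum) > 0

    def test_too_short_sequence_errors(self, blosum):
        p = ProteinRecord(id="p", sequence="MKTA")
        q = ProteinRecord(id="q", sequence="MKTAYIAKQR")
        with pytest.raises(LigomapError):
            lms_distance(p, q, blosum, k=5)


class TestGamma:
    def test_closed_form_at_half(self):
        assert gamma_from_p(0.5, a=2.0) == pytest.approx(0.8284271, abs=1e-6)

    def test_identical_sequences_zero(self, blosum):
        p = ProteinRecord(id="p", sequence="MKTAYIAKQRMKTAYIAKQR")
        assert gamma_distance(p, p, blosum) == 0.0

    def test_monotone_in_p(self):
        vals = [gamma_from_p(p) for p in (0.0, 0.2, 0.4, 0.6, 0.8)]
        assert vals == sorted(vals)
        assert all(b > a for a, b in zip(vals, vals[1:]))

    def test_saturated_alignment_is_infinite(self):
        assert gamma_from_p(1.0) == np.inf

    def test_alignment_degaps_to_inputs(self, blosum):
        p = ProteinRecord(id="p", sequence="MKTAYIAKQRLL")
        q = ProteinRecord(id="q", sequence="MKTAYIKQR")
        aln = global_alignment(p, q, blosum)
        assert aln.aligned_p.replace("-", "") == p.sequence
        assert aln.aligned_q.replace("-", "") == q.sequence
        assert 0.0 <= aln.p <= 1.0


# ---------------------------------------------------------------------------
# architecture layer
# ---------------------------------------------------------------------------

class TestArchitectureMeasures:
    def test_jaccard_examples(self):
        p = protein_with_domains(["A", "B", "C"])
        q = protein_with_domains(["B", "C", "D"])
        assert jaccard_distance(p, q) == pytest.approx(0.5)
        assert jaccard_distance(p, p) == 0.0
        r = protein_with_domains(["X", "Y"])
        assert jaccard_distance(p, r) == 1.0

    def test_gk_examples(self):
        abc = protein_with_domains(["A", "B", "C"])
        assert gk_gamma_distance(abc, abc) == 0.0
        ab = protein_with_domains(["A", "B"])
        ba = protein_with_domains(["B", "A"])
        assert gk_gamma_distance(ab, ba) == 1.0
        acb = protein_with_domains(["A", "C", "B"])
        assert gk_gamma_distance(abc, acb) == pytest.approx(1.0 / 3.0, abs=1e-12)

    def test_duplication_examples(self):
        p = protein_with_domains(["A", "A", "B"])
        q = protein_with_domains(["A", "B"])
        assert duplication_distance(p, q) == pytest.approx(1 - np.exp(-1 / 3), abs=1e-5)
        assert duplication_distance(p, p) == 0.0
        a3 = protein_with_domains(["A", "A", "A"])
        b3 = protein_with_domains(["B", "B", "B"])
        assert duplication_distance(a3, b3) == pytest.approx(1 - np.exp(-1), abs=1e-5)

    def test_match_set_oracles_on_random_architectures(self):
        rng = np.random.default_rng(7)
        vocab = list("ABCDEFGH")
        for _ in range(250):
            ap = list(rng.choice(vocab, size=rng.integers(1, 7)))
            aq = list(rng.choice(vocab, size=rng.integers(1, 7)))
            p, q = protein_with_domains(ap), protein_with_domains(aq)
            assert jaccard_distance(p, q) == pytest.approx(
                jaccard_brute(ap, aq), abs=1e-12
            )
            assert duplication_distance(p, q) == pytest.approx(
                duplication_brute(ap, aq), abs=1e-12
            )
            expected = gk_gamma_brute(ap, aq)
            got = gk_gamma_distance(p, q)
            if expected is None:
                assert np.isnan(got)
            else:
                assert got == pytest.approx(expected, abs=1e-12)

    def test_no_domains_is_undefined(self):
        p = ProteinRecord(id="p", sequence="AAAA")
        assert np.isnan(jaccard_distance(p, p))
        assert np.isnan(duplication_distance(p, p))


# ---------------------------------------------------------------------------
# structure layer
# ---------------------------------------------------------------------------

class TestStructure:
    def test_d0_closed_form(self):
        assert tm_d0(20) == 0.5  # short-segment floor
        assert 1.24 * 5 ** (1 / 3) - 1.8 == pytest.approx(0.32037, abs=1e-4)
        assert tm_d0(40) == pytest.approx(1.24 * 25 ** (1 / 3) - 1.8, abs=1e-12)

    def test_identical_structures_score_one(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=(30, 3)) * 5
        assert tm_score(x, x) == pytest.approx(1.0, abs=1e-12)

    def test_rigid_motion_invariance(self):
        rng = np.random.default_rng(3)
        for _ in range(10):
            x = np.cumsum(rng.normal(size=(40, 3)), axis=0) * 2
            theta = rng.uniform(0, np.pi)
            rot = np.array(
                [
                    [np.cos(theta), -np.sin(theta), 0],
                    [np.sin(theta), np.cos(theta), 0],
                    [0, 0, 1],
                ]
            )
            y = x @ rot.T + rng.normal(size=3) * 10
            assert tm_score(x, y) == pytest.approx(1.0, abs=1e-6)

    def test_score_bounded(self):
        rng = np.random.default_rng(5)
        for _ in range(20):
            x = np.cumsum(rng.normal(size=(25, 3)), axis=0)
            y = np.cumsum(rng.normal(size=(25, 3)), axis=0)
            s = tm_score(x, y)
            assert 0.0 < s <= 1.0

    def test_structural_distance_symmetric(self):
        rng = np.random.default_rng(11)
        for _ in range(50):
            p = ProteinRecord(id="p", sequence="A" * 30, structure=np.cumsum(rng.normal(size=(30, 3)), axis=0))
            q = ProteinRecord(id="q", sequence="A" * 30, structure=np.cumsum(rng.normal(size=(30, 3)), axis=0))
            assert structural_distance(p, q) == structural_distance(q, p)

    def test_external_table_mode(self):
        p = ProteinRecord(id="p", sequence="AAAA")
        q = ProteinRecord(id="q", sequence="CCCC")
        table = {("p", "q"): 0.8, ("q", "p"): 0.6}
        assert structural_distance(p, q, tm_table=table) == pytest.approx(0.3)

    def test_missing_structure_is_undefined(self):
        p = ProteinRecord(id="p", sequence="AAAA")
        q = ProteinRecord(id="q", sequence="CCCC", structure=np.zeros((4, 3)))
        assert np.isnan(structural_distance(p, q))

    def test_too_few_pairs_error(self):
        with pytest.raises(LigomapError):
            tm_score(np.zeros((2, 3)), np.zeros((2, 3)))


# ---------------------------------------------------------------------------
# function layer
# ---------------------------------------------------------------------------

def random_dag(rng, n_terms=10):
    """Random layered DAG; returns (OntologyGraph, parents dict for the oracle)."""
    terms = [f"t{i}" for i in range(n_terms)]
    weights = {"is_a": 0.8, "part_of": 0.6}
    edges = []
    for i in range(1, n_terms):
        n_parents = 1 + (rng.random() < 0.4)
        for p in rng.choice(i, size=min(n_parents, i), replace=False):
            rel = "is_a" if rng.random() < 0.7 else "part_of"
            edges.append((terms[i], terms[int(p)], rel))
    parents = {}
    for c, p, rel in edges:
        parents.setdefault(c, []).append((p, weights[rel]))
    return OntologyGraph(terms, edges, weights), parents


class TestSemantic:
    def test_identity_is_one(self):
        ont = OntologyGraph(["r", "c"], [("c", "r", "is_a")])
        assert term_similarity("c", "c", ont) == 1.0

    def test_two_term_chain(self):
        ont = OntologyGraph(["r", "c"], [("c", "r", "is_a")])
        assert term_similarity("c", "r", ont) == pytest.approx(1.8 / 2.8, abs=1e-6)

    def test_matches_all_paths_oracle(self):
        rng = np.random.default_rng(9)
        checked = 0
        while checked < 220:
            ont, parents = random_dag(rng, n_terms=int(rng.integers(5, 12)))
            terms = sorted(ont.terms)
            x, y = rng.choice(terms, size=2, replace=True)
            expected = wang_similarity_brute(str(x), str(y), parents)
            assert term_similarity(str(x), str(y), ont) == pytest.approx(
                expected, abs=1e-12
            )
            checked += 1

    def test_protein_distance_chain_example(self):
        ont = OntologyGraph(["r", "c"], [("c", "r", "is_a")])
        p = ProteinRecord(id="p", sequence="A", go_terms={"MF": {"c"}})
        q = ProteinRecord(id="q", sequence="A", go_terms={"MF": {"r"}})
        assert semantic_distance(p, q, "MF", ont) == pytest.approx(
            1 - 1.8 / 2.8, abs=1e-6
        )
        assert semantic_distance(p, p, "MF", ont) == 0.0

    def test_protein_distance_matches_best_match_oracle(self):
        rng = np.random.default_rng(13)
        for _ in range(50):
            ont, parents = random_dag(rng, n_terms=10)
            terms = sorted(ont.terms)
            tp = [str(t) for t in rng.choice(terms, size=int(rng.integers(1, 4)), replace=False)]
            tq = [str(t) for t in rng.choice(terms, size=int(rng.integers(1, 4)), replace=False)]
            p = ProteinRecord(id="p", sequence="A", go_terms={"BP": set(tp)})
            q = ProteinRecord(id="q", sequence="A", go_terms={"BP": set(tq)})
            expected = semantic_distance_brute(tp, tq, parents)
            assert semantic_distance(p, q, "BP", ont) == pytest.approx(
                expected, abs=1e-12
            )

    def test_empty_annotation_undefined(self):
        ont = OntologyGraph(["r"], [])
        p = ProteinRecord(id="p", sequence="A", go_terms={"MF": {"r"}})
        q = ProteinRecord(id="q", sequence="A")
        assert np.isnan(semantic_distance(p, q, "MF", ont))


# ---------------------------------------------------------------------------
# localization and expression
# ---------------------------------------------------------------------------

class TestLocalizationExpression:
    def test_localization_cases(self):
        p = ProteinRecord(id="p", sequence="A", localization_main={"nucleus"})
        q = ProteinRecord(id="q", sequence="A", localization_main={"nucleus"})
        assert localization_distance(p, q) == pytest.approx(0.0)
        r = ProteinRecord(id="r", sequence="A", localization_main={"cytosol"})
        assert localization_distance(p, r) == pytest.approx(1.0)
        # same compartment at different tiers: cosine is scale-invariant
        s = ProteinRecord(id="s", sequence="A", localization_aux={"nucleus"})
        assert localization_distance(p, s) == pytest.approx(0.0)

    def test_localization_undefined_without_annotation(self):
        p = ProteinRecord(id="p", sequence="A")
        q = ProteinRecord(id="q", sequence="A", localization_main={"x"})
        assert np.isnan(localization_distance(p, q))

    def test_expression_cases(self):
        mk = lambda pid, v: ProteinRecord(id=pid, sequence="A", expression_tissue=np.array(v, float))
        p = mk("p", [1, 2, 3, 4])
        assert expression_distance(p, mk("q", [1, 2, 3, 4])) == pytest.approx(0.0)
        assert expression_distance(p, mk("r", [4, 3, 2, 1])) == pytest.approx(1.0)
        assert expression_distance(p, mk("s", [1, 3, 2, 4])) == pytest.approx(0.1)

    def test_constant_profile_undefined(self):
        p = ProteinRecord(id="p", sequence="A", expression_tissue=np.array([1.0, 1.0, 1.0]))
        q = ProteinRecord(id="q", sequence="A", expression_tissue=np.array([1.0, 2.0, 3.0]))
        assert np.isnan(expression_distance(p, q))


# ---------------------------------------------------------------------------
# scaling and screening
# ---------------------------------------------------------------------------

def matrix_from_upper(vals, measure="m"):
    v = np.array(vals, float)
    return DistanceMatrix(tuple(f"p{i}" for i in range(len(v))), v, measure)


class TestScaling:
    def test_minmax_arithmetic(self):
        m = matrix_from_upper(
            [[0, 0, 2, 4], [0, 0, 4, 2], [2, 4, 0, 0], [4, 2, 0, 0]]
        )
        scaled = scale_unit_interval(m)
        off = scaled.values[~np.eye(4, dtype=bool)]
        assert set(np.round(off, 12)) == {0.0, 0.5, 1.0}

    def test_degenerate_scale_warns_and_zeros(self):
        m = matrix_from_upper([[0, 3], [3, 0]])
        with pytest.warns(UserWarning):
            scaled = scale_unit_interval(m)
        assert scaled.values.max() == 0.0

    def test_infinity_maps_to_one_and_nan_to_median(self):
        v = np.array(
            [
                [0, 1, 2, np.inf],
                [1, 0, np.nan, 3],
                [2, np.nan, 0, 1],
                [np.inf, 3, 1, 0],
            ]
        )
        meta = {}
        scaled = scale_unit_interval(DistanceMatrix(("a", "b", "c", "d"), v, "m"), meta=meta)
        assert scaled.scaled
        assert scaled.values[0, 3] == 1.0
        assert np.isfinite(scaled.values).all()
        assert meta["n_undefined_pairs"] == 1

    def test_correlation_screen_flags(self):
        rng = np.random.default_rng(21)
        a = rng.random((10, 10))
        a = np.triu(a, 1) + np.triu(a, 1).T
        m1 = DistanceMatrix(tuple(f"p{i}" for i in range(10)), a, "m1", scaled=True)
        inv = 1.0 - a
        np.fill_diagonal(inv, 0.0)
        m2 = DistanceMatrix(m1.labels, inv, "m2")
        df = correlation_screen([m1, m1, m2])
        self_row = df[(df.measure_a == "m1") & (df.measure_b == "m1")].iloc[0]
        assert self_row.pearson_r == pytest.approx(1.0)
        assert self_row.redundant
        anti = df[(df.measure_a == "m1") & (df.measure_b == "m2")].iloc[0]
        assert anti.pearson_r == pytest.approx(-1.0)
        assert anti.redundant

    def test_independent_random_matrices_uncorrelated(self):
        for seed in range(20):
            rng = np.random.default_rng(seed)
            mats = []
            for k in range(2):
                a = rng.random((40, 40))
                a = np.triu(a, 1) + np.triu(a, 1).T
                mats.append(
                    DistanceMatrix(tuple(f"p{i}" for i in range(40)), a, f"m{k}")
                )
            r = correlation_screen(mats).iloc[0].pearson_r
            assert abs(r) < 0.3


class TestAllMeasuresContract:
    def test_symmetry_zero_diagonal_range(self, all_matrices):
        for m, dm in all_matrices.items():
            v = dm.values
            assert np.array_equal(v, v.T), m
            assert not np.diagonal(v).any(), m
            assert np.isfinite(v).all(), m
            assert v.min() >= 0.0 and v.max() <= 1.0, m
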