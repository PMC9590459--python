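import numpy as np
import pytest
from Bio.Align import substitution_matrices
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from enzdesign.alphabet import AA20
from enzdesign.errors import InputError, ParameterError, ValidationError
from enzdesign.variants import (
    ClusterAssignment,
    Substitution,
    Variant,
    VariantSet,
    apply_variant,
    cluster_variants,
    combine_substitutions,
    diff_sequences,
    distance_matrix,
    enumerate_candidates,
    load_pam30,
    parse_variant_name,
    select_representatives,
    variant_distance,
)

V1_NAME = "L48F-S49A-I61F-L120T-T352K-L356P"


@pytest.fixture
def aliases(base_seq):
    v1 = parse_variant_name(V1_NAME, base_seq)
    v1.display_name = "V1"
    v2 = parse_variant_name("V1-K352I", base_seq, {"V1": v1})
    v2.display_name = "V2"
    v3 = parse_variant_name("L109F-F113L-E286A", base_seq)
    v3.display_name = "V3"
    return {"V1": v1, "V2": v2, "V3": v3}


class TestParse:
    def test_six_substitutions(self, base_seq):
        v = parse_variant_name(V1_NAME, base_seq)
        assert [s.position for s in v.substitutions] == [48, 49, 61, 120, 352, 356]
        assert v.name == V1_NAME

    def test_alias_composition_net_from_base(self, base_seq, aliases):
        v2 = parse_variant_name("V1-K352I", base_seq, aliases)
        by_pos = {s.position: s for s in v2.substitutions}
        assert len(v2.substitutions) == 6
        assert by_pos[352].from_residue == "T"
        assert by_pos[352].to_residue == "I"

    def test_from_equals_to_rejected(self, base_seq):
        with pytest.raises(ValidationError):
            parse_variant_name("A10A", base_seq)

    def test_from_residue_must_match_base(self, base_seq):
        with pytest.raises(ValidationError, match="48"):
            parse_variant_name("K48F", base_seq)

    def test_unknown_alias(self, base_seq):
        with pytest.raises(ValidationError):
            parse_variant_name("V9-K352I", base_seq)

    def test_restoring_base_residue_cancels(self, base_seq, aliases):
        # composing K352T on V1 undoes the T352K substitution
        v = parse_variant_name("V1-K352T", base_seq, aliases)
        assert 352 not in {s.position for s in v.substitutions}
        assert len(v.substitutions) == 5


class TestApply:
    def test_empty_variant_is_identity(self, base_seq):
        v = Variant(base_id="base", substitutions=())
        assert apply_variant(v, base_seq) == base_seq

    def test_single_substitution(self):
        v = Variant(base_id="base", substitutions=(Substitution(3, "A", "V"),))
        assert apply_variant(v, "MKAG") == "MKVG"

    def test_apply_then_diff_round_trip(self, base_seq):
        v = parse_variant_name(V1_NAME, base_seq)
        mutant = apply_variant(v, base_seq)
        assert diff_sequences(base_seq, mutant) == v.substitutions

    @given(st.data())
    @settings(max_examples=50, deadline=None)
    def test_round_trip_random(self, data):
        gen = np.random.default_rng(data.draw(st.integers(0, 2**31 - 1)))
        base = "".join(gen.choice(list(AA20), 40))
        n_subs = int(gen.integers(0, 8))
        positions = gen.choice(np.arange(1, 41), size=n_subs, replace=False)
        subs = []
        for pos in sorted(positions):
            to = gen.choice([a for a in AA20 if a != base[pos - 1]])
            subs.append(Substitution(int(pos), base[pos - 1], str(to)))
        v = Variant(base_id="base", substitutions=tuple(subs))
        mutant = apply_variant(v, base)
        assert diff_sequences(base, mutant) == v.substitutions
        if subs:
            reparsed = parse_variant_name(v.name, base)
            assert reparsed.substitutions == v.substitutions


class TestCombine:
    def test_paper_style_composition(self, base_seq, aliases):
        v2_46_49 = parse_variant_name("V2-I46L-A49L", base_seq, aliases)
        v2_46_49.display_name = "V2-I46L-A49L"
        out = combine_substitutions(v2_46_49, [Substitution(343, "C", "Y")], base_seq)
        assert out.display_name == "V2-I46L-A49L-C343Y"
        assert 343 in {s.position for s in out.substitutions}

    def test_two_branches_from_v3(self, base_seq, aliases):
        v3y = combine_substitutions(aliases["V3"], [Substitution(343, "C", "Y")], base_seq)
        v3y.display_name = "V3-C343Y"
        seq_after = apply_variant(v3y, base_seq)
        b1 = combine_substitutions(
            v3y, [Substitution(49, seq_after[48], "L")], base_seq
        )
        b2 = combine_substitutions(
            v3y, [Substitution(46, seq_after[45], "L")], base_seq
        )
        assert b1.display_name == "V3-C343Y-S49L"
        assert b2.display_name == "V3-C343Y-I46L"

    def test_empty_list_unchanged(self, base_seq, aliases):
        out = combine_substitutions(aliases["V2"], [], base_seq)
        assert out.substitutions == aliases["V2"].substitutions
        assert out.display_name == aliases["V2"].display_name


# ---------------------------------------------------------------------------
# enumeration


class FakePssmRec:
    def __init__(self, position, from_residue, to_residue, score):
        self.position, self.from_residue = position, from_residue
        self.to_residue, self.score = to_residue, score


class FakeCoevRec:
    def __init__(self, position, from_residue, to_residue, gain):
        self.position, self.from_residue = position, from_residue
        self.to_residue, self.coupling_gain = to_residue, gain


class FakeEnv:
    def __init__(self, burial_class, pocket=False):
        self.burial_class, self.pocket = burial_class, pocket


class TestEnumerate:
    def test_no_overlap_union(self, base_seq):
        pssm = [FakePssmRec(i, base_seq[i - 1], "G", 1.0) for i in range(1, 42)]
        coev = [FakeCoevRec(i, base_seq[i - 1], "H", 0.5) for i in range(100, 141)]
        vs = enumerate_candidates(base_seq, pssm, coev, {}, "all")
        assert len(vs.variants) == 82

    def test_overlap_merges_provenance(self, base_seq):
        pssm = [FakePssmRec(5, "A", "G", 1.0)]
        coev = [FakeCoevRec(5, "A", "G", 0.5)]
        vs = enumerate_candidates(base_seq, pssm, coev, {}, "all")
        assert len(vs.variants) == 1
        v = vs.variants[0]
        assert v.provenance == frozenset({"pssm", "coevolution"})
        assert v.score == pytest.approx(-1.5)

    def test_surface_filter(self, base_seq):
        env = {1: FakeEnv("surface"), 2: FakeEnv("surface"), 3: FakeEnv("surface"),
               4: FakeEnv("buried"), 5: FakeEnv("buried")}
        pssm = [FakePssmRec(i, base_seq[i - 1], "G", 1.0) for i in range(1, 6)]
        vs = enumerate_candidates(base_seq, pssm, [], env, "surface")
        assert len(vs.variants) == 3

    def test_missing_environment_is_unknown(self, base_seq):
        vs = enumerate_candidates(base_seq, [FakePssmRec(7, "A", "G", 1.0)], [], {}, "all")
        assert vs.variants[0].burial_class == "unknown"

    def test_bad_filter(self, base_seq):
        with pytest.raises(ParameterError):
            enumerate_candidates(base_seq, [], [], {}, "bogus")


# ---------------------------------------------------------------------------
# distances and clustering


class TestDistance:
    def test_identity(self, base_seq):
        v = parse_variant_name("I46L", base_seq)
        assert variant_distance(v, v, base_seq) == 0.0

    def test_single_position_table_lookup(self, base_seq):
        pam30 = substitution_matrices.load("PAM30")
        a = parse_variant_name("I46L", base_seq)
        b = Variant(base_id="base", substitutions=())
        expected = (pam30["L", "L"] + pam30["I", "I"] - 2 * pam30["I", "L"]) / 2
        assert variant_distance(a, b, base_seq) == pytest.approx(expected)

    def test_symmetry_random(self, base_seq, rng):
        sim = load_pam30()
        variants = []
        for _ in range(6):
            pos = int(rng.integers(1, 400))
            to = str(rng.choice([x for x in AA20 if x != base_seq[pos - 1]]))
            variants.append(
                Variant(base_id="base", substitutions=(Substitution(pos, base_seq[pos - 1], to),))
            )
        for a in variants:
            for b in variants:
                assert variant_distance(a, b, base_seq, sim) == pytest.approx(
                    variant_distance(b, a, base_seq, sim)
                )
                if a.name == b.name:
                    assert variant_distance(a, b, base_seq, sim) == 0.0

    def test_distances_non_negative(self, base_seq):
        sim = load_pam30()
        a = parse_variant_name("I46L", base_seq)
        b = parse_variant_name("I46H", base_seq)
        assert variant_distance(a, b, base_seq, sim) >= 0


def make_variant_set(base_seq, tokens, scores=None):
    variants = [parse_variant_name(t, base_seq) for t in tokens]
    if scores:
        for v, s in zip(variants, scores):
            v.score = s
    return VariantSet(base=base_seq, variants=variants)


class TestClustering:
    def test_two_separated_triplets(self, base_seq):
        # positions far apart: three variants share position 46, three share 352
        tokens = ["I46L", "I46V", "I46M", "T352K", "T352R", "T352S"]
        vs = make_variant_set(base_seq, tokens)
        ca = cluster_variants(vs, k=2)
        labels = ca.labels
        assert len(set(labels[:3])) == 1
        assert len(set(labels[3:])) == 1
        assert labels[0] != labels[3]

    def test_k_equals_n_singletons(self, base_seq):
        vs = make_variant_set(base_seq, ["I46L", "T352K", "L48F"])
        ca = cluster_variants(vs, k=3)
        assert sorted(ca.labels) == [1, 2, 3]

    def test_matches_scipy_average_linkage(self, base_seq, rng):
        # tie-free fixture: independent oracle via scipy hierarchical clustering
        tokens = ["I46L", "I46V", "T352K", "T352R", "L48F", "E463P"]
        vs = make_variant_set(base_seq, tokens)
        D = distance_matrix(vs)
        ca = cluster_variants(vs, k=2)
        Z = linkage(squareform(D), method="average")
        expected = fcluster(Z, t=2, criterion="maxclust")
        # compare partitions up to label renaming
        ours = {tuple(sorted(np.nonzero(ca.labels == lab)[0])) for lab in set(ca.labels)}
        theirs = {tuple(sorted(np.nonzero(expected == lab)[0])) for lab in set(expected)}
        assert ours == theirs

    def test_permutation_invariance(self, base_seq, rng):
        tokens = ["I46L", "I46V", "T352K", "T352R", "L48F", "E463P", "W399K", "R385Y"]
        vs = make_variant_set(base_seq, tokens)
        ca = cluster_variants(vs, k=3)
        parts = {frozenset(vs.variants[i].name for i in ca.members(lab)) for lab in range(1, 4)}
        perm = rng.permutation(len(tokens))
        vs2 = VariantSet(base=base_seq, variants=[vs.variants[i] for i in perm])
        ca2 = cluster_variants(vs2, k=3)
        parts2 = {
            frozenset(vs2.variants[i].name for i in ca2.members(lab)) for lab in range(1, 4)
        }
        assert parts == parts2

    def test_k_out_of_range(self, base_seq):
        vs = make_variant_set(base_seq, ["I46L"])
        with pytest.raises(ParameterError):
            cluster_variants(vs, k=2)
        with pytest.raises(ParameterError):
            cluster_variants(vs, k=0)


class TestRepresentatives:
    def test_minimum_score_wins(self, base_seq):
        vs = make_variant_set(base_seq, ["I46L", "I46V", "I46M"], scores=[-1.0, -3.0, 0.0])
        ca = cluster_variants(vs, k=1)
        reps = select_representatives(ca)
        assert len(reps) == 1 and reps[0].name == "I46V"

    def test_tie_breaks_by_name(self, base_seq):
        vs = make_variant_set(base_seq, ["T352K", "I46L"], scores=[-3.0, -3.0])
        ca = cluster_variants(vs, k=1)
        reps = select_representatives(ca)
        assert reps[0].name == "I46L"

    def test_reps_bound_cluster_scores(self, base_seq, rng):
        tokens = ["I46L", "I46V", "T352K", "T352R", "L48F", "E463P", "W399K", "R385Y"]
        scores = list(rng.normal(size=len(tokens)))
        vs = make_variant_set(base_seq, tokens, scores)
        ca = cluster_variants(vs, k=3)
        reps = {v.name: v for v in select_representatives(ca)}
        assert len(reps) == 3
        for lab in range(1, 4):
            members = [vs.variants[i] for i in ca.members(lab)]
            rep = min(members, key=lambda v: (v.score, v.name))
            assert rep.name in reps
            assert all(reps[rep.name].score <= m.score for m in members)
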