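"""Distance metrics against independent brute-force oracles."""

import itertools
from functools import lru_cache

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

import tcrsplit as t
from tcrsplit.dataset import AMINO_ACIDS
from tcrsplit.errors import AlphabetError, NoOverlapError
from tcrsplit.metrics import DEFAULT_PARAMS
from tcrsplit.synthetic import _ideal_backbone

# ---------------------------------------------------------------- oracles


@lru_cache(maxsize=None)
def edit_distance_oracle(a: str, b: str) -> int:
    """Plain recursive definition of unit-cost edit distance."""
    if not a:
        return len(b)
    if not b:
        return len(a)
    sub = edit_distance_oracle(a[1:], b[1:]) + (a[0] != b[0])
    return min(sub, 1 + edit_distance_oracle(a[1:], b),
               1 + edit_distance_oracle(a, b[1:]))


def enumerate_alignments(a: str, b: str):
    """Yield every global alignment as a list of columns (i or None, j or None)."""
    if not a and not b:
        yield []
        return
    if a:
        for rest in enumerate_alignments(a[1:], b):
            yield [(a[0], None)] + rest
    if b:
        for rest in enumerate_alignments(a, b[1:]):
            yield [(None, b[0])] + rest
    if a and b:
        for rest in enumerate_alignments(a[1:], b[1:]):
            yield [(a[0], b[0])] + rest


def alignment_score_oracle(a: str, b: str, params=DEFAULT_PARAMS) -> float:
    """Best score over exhaustive enumeration of all global alignments.

    Affine gap convention as documented: a gap run of length L costs
    gap_open + (L - 1) * gap_extend.
    """
    from Bio.Align import substitution_matrices
    mat = substitution_matrices.load(params.substitution_matrix_name)
    best = -np.inf
    for alignment in enumerate_alignments(a, b):
        score, gap_state = 0.0, None  # gap_state: which side is gapped
        for ca, cb in alignment:
            if ca is not None and cb is not None:
                score += mat[ca, cb]
                gap_state = None
            else:
                side = "a" if ca is None else "b"
                score += params.gap_extend if gap_state == side else params.gap_open
                gap_state = side
        best = max(best, score)
    return best


def kabsch_oracle(p: np.ndarray, q: np.ndarray) -> float:
    """Grid search over Euler angles plus local refinement of the RMSD."""
    from scipy.optimize import minimize

    p = p - p.mean(axis=0)
    q = q - q.mean(axis=0)

    def rmsd_of(rotvec):
        r = Rotation.from_rotvec(rotvec).as_matrix()
        return float(np.sqrt(((p @ r.T - q) ** 2).sum() / len(p)))

    candidates = []
    step = np.deg2rad(30)
    for ai in np.arange(0, 2 * np.pi, step):
        for bj in np.arange(0, np.pi + 1e-9, step):
            for ck in np.arange(0, 2 * np.pi, step):
                rv = Rotation.from_euler("zyz", [ai, bj, ck]).as_rotvec()
                candidates.append((rmsd_of(rv), tuple(rv)))
    candidates.sort()
    best = np.inf
    for _val, rv in candidates[:10]:  # multi-start: escape local basins
        res = minimize(rmsd_of, np.array(rv), method="Nelder-Mead",
                       options={"xatol": 1e-10, "fatol": 1e-12, "maxiter": 5000})
        best = min(best, float(res.fun))
    return best


def random_peptides(rng, n, lo=8, hi=11):
    return ["".join(AMINO_ACIDS[i]
                    for i in rng.integers(len(AMINO_ACIDS), size=rng.integers(lo, hi + 1)))
            for _ in range(n)]


# ----------------------------------------------------------------- tests


class TestLevenshtein:
    def test_identity_and_single_substitution(self):
        assert t.levenshtein_distance("GILGFVFTL", "GILGFVFTL") == 0
        assert t.levenshtein_distance("AAAA", "AAAC") == 1

    def test_matches_recursive_oracle_on_random_pairs(self, rng):
        for _ in range(200):
            a, b = random_peptides(rng, 2, lo=1, hi=8)
            assert t.levenshtein_distance(a, b) == edit_distance_oracle(a, b)

    def test_triangle_inequality_on_random_triples(self, rng):
        for _ in range(100):
            a, b, c = random_peptides(rng, 3, lo=4, hi=10)
            ab = t.levenshtein_distance(a, b)
            bc = t.levenshtein_distance(b, c)
            ac = t.levenshtein_distance(a, c)
            assert ac <= ab + bc

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            t.levenshtein_distance("", "AAA")


class TestGlobalAlignment:
    def test_all_match_score_is_diagonal_sum(self):
        # BLOSUM62 scores s(A,A)=4: three matches score 12
        assert t.global_alignment_score("AAA", "AAA") == pytest.approx(12.0)

    def test_symmetry_on_random_pairs(self, rng):
        for _ in range(50):
            a, b = random_peptides(rng, 2)
            assert (t.global_alignment_score(a, b)
                    == pytest.approx(t.global_alignment_score(b, a)))

    def test_matches_enumeration_oracle_on_short_pairs(self):
        alphabet = "ACDE"
        seqs = [''.join(s) for n in (1, 2, 3)
                for s in itertools.product(alphabet, repeat=n)]
        # sample systematically rather than all 7056 pairs: every 13th pair
        pairs = list(itertools.product(seqs, seqs))[::13]
        for a, b in pairs:
            assert (t.global_alignment_score(a, b)
                    == pytest.approx(alignment_score_oracle(a, b)))

    def test_nonstandard_residue_rejected(self):
        with pytest.raises(AlphabetError):
            t.global_alignment_score("AAJ", "AAA")


class TestBlosumDistance:
    def test_self_distance_zero(self):
        assert t.blosum_distance("GILGFVFTL", "GILGFVFTL") == 0.0

    def test_symmetric_and_nonnegative(self, rng):
        for _ in range(50):
            a, b = random_peptides(rng, 2)
            d = t.blosum_distance(a, b)
            assert d >= 0
            assert d == pytest.approx(t.blosum_distance(b, a))

    def test_formula_against_oracle_scores(self):
        a, b = "AAA", "ARA"
        expected = (alignment_score_oracle(a, a) + alignment_score_oracle(b, b)
                    - 2 * alignment_score_oracle(a, b))
        assert t.blosum_distance(a, b) == pytest.approx(max(0.0, expected))


class TestPairCaAtoms:
    def _structure(self, seq):
        return t.PeptideStructure(seq, _ideal_backbone(len(seq), "helix_jitter"))

    def test_identical_sequences_pair_positionally(self):
        x = self._structure("GILGFVFTL")
        pairs = t.pair_ca_atoms(x, x)
        assert pairs == [(i, i) for i in range(9)]

    def test_length_mismatch_pairs_are_monotone(self):
        pairs = t.pair_ca_atoms(self._structure("AAAA"), self._structure("AAA"))
        assert len(pairs) == 3
        assert all(i2 > i1 and j2 > j1
                   for (i1, j1), (i2, j2) in zip(pairs, pairs[1:]))

    def test_fully_gapped_alignment_is_no_overlap_error(self):
        # gap cost cheaper than any substitution forces an all-gap optimum
        params = t.AlignmentParams(gap_open=-0.01, gap_extend=-0.001)
        with pytest.raises(NoOverlapError):
            t.pair_ca_atoms(self._structure("WWWWW"), self._structure("GGGGG"),
                            params=params)


class TestKabsch:
    def test_pure_translation_gives_zero_rmsd(self, rng):
        p = rng.normal(size=(8, 3))
        _r, _t, rmsd = t.kabsch_superpose(p, p + np.array([5.0, -2.0, 7.0]))
        assert rmsd <= 1e-6

    def test_random_proper_rotation_gives_zero_rmsd(self, rng):
        p = rng.normal(size=(10, 3))
        rot = Rotation.random(random_state=7).as_matrix()
        _r, _t, rmsd = t.kabsch_superpose(p, p @ rot.T)
        assert rmsd <= 1e-6

    def test_rotation_is_proper(self, rng):
        p, q = rng.normal(size=(6, 3)), rng.normal(size=(6, 3))
        r, _t, _d = t.kabsch_superpose(p, q)
        assert np.linalg.det(r) == pytest.approx(1.0, abs=1e-9)
        np.testing.assert_allclose(r @ r.T, np.eye(3), atol=1e-9)

    def test_matches_scipy_align_vectors(self, rng):
        for _ in range(10):
            p, q = rng.normal(size=(7, 3)), rng.normal(size=(7, 3))
            _r, _t, rmsd = t.kabsch_superpose(p, q)
            rot, ssd = Rotation.align_vectors(
                q - q.mean(0), p - p.mean(0), return_sensitivity=False)
            dev = (p - p.mean(0)) @ rot.as_matrix().T - (q - q.mean(0))
            assert rmsd == pytest.approx(np.sqrt((dev ** 2).sum() / 7), abs=1e-9)

    def test_four_point_toys_match_grid_refinement_oracle(self, rng):
        for _ in range(3):
            p, q = rng.normal(size=(4, 3)), rng.normal(size=(4, 3))
            _r, _t, rmsd = t.kabsch_superpose(p, q)
            assert rmsd == pytest.approx(kabsch_oracle(p, q), abs=1e-4)

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            t.kabsch_superpose(np.zeros((2, 3)), np.zeros((2, 3)))


class TestCaRmsd:
    def _jittered(self, seq, seed, sd=0.5):
        spec = t.FixtureSpec(n_peptides=2, seed=seed, jitter_sd=sd)
        return t.generate_structures([seq], spec)[seq]

    def test_self_distance_zero(self):
        x = self._jittered("GILGFVFTL", 1)
        assert t.ca_rmsd(x, x) == pytest.approx(0.0, abs=1e-9)

    def test_symmetric(self):
        x = self._jittered("GILGFVFTL", 1)
        y = self._jittered("NLVPMVATV", 2)
        assert t.ca_rmsd(x, y) == pytest.approx(t.ca_rmsd(y, x), abs=1e-12)

    def test_zero_cycles_equals_plain_superposition(self):
        x = self._jittered("GILGFVFTL", 1)
        y = self._jittered("GILGFVMTL", 2)
        pairs = t.pair_ca_atoms(x, y)
        xi = [i for i, _ in pairs]
        yi = [j for _, j in pairs]
        _r, _t, plain = t.kabsch_superpose(x.ca_coords[xi], y.ca_coords[yi])
        assert t.ca_rmsd(x, y, refine_cycles=0) == pytest.approx(plain)

    def test_outlier_rejection_never_increases_rmsd(self):
        x = self._jittered("GILGFVFTL", 3)
        moved = x.ca_coords.copy()
        moved[4] += np.array([10.0, 0.0, 0.0])  # one displaced C-alpha
        y = t.PeptideStructure(x.sequence, moved)
        base = t.ca_rmsd(x, y, refine_cycles=0)
        refined = t.ca_rmsd(x, y, refine_cycles=5, outlier_cutoff=2.0)
        assert refined <= base
        assert refined < 0.5 * base  # the outlier dominates the plain RMSD

    def test_rigid_motion_invariance(self, rng):
        x = self._jittered("GILGFVFTL", 4)
        rot = Rotation.random(random_state=11).as_matrix()
        y = t.PeptideStructure(x.sequence, x.ca_coords @ rot.T + [1.0, 2.0, 3.0])
        assert t.ca_rmsd(x, y) <= 1e-6


class TestDistanceMatrix:
    def test_levenshtein_matrix_matches_pairwise_calls(self):
        peps = ["GILGFVFTL", "NLVPMVATV", "ELAGIGILTV"]
        m = t.build_distance_matrix(peps, "levenshtein")
        for i, j in itertools.combinations(range(3), 2):
            assert m.values[i, j] == t.levenshtein_distance(peps[i], peps[j])
            assert m.values[i, j] == m.values[j, i]
        assert np.all(np.diag(m.values) == 0)

    def test_blosum_matrix_matches_elementwise_recomputation(self, rng):
        peps = random_peptides(rng, 10)
        m = t.build_distance_matrix(peps, "blosum")
        for i, j in itertools.combinations(range(10), 2):
            assert m.values[i, j] == pytest.approx(
                t.blosum_distance(peps[i], peps[j]))

    def test_duplicate_peptides_rejected(self):
        with pytest.raises(ValueError):
            t.build_distance_matrix(["AAAA", "AAAA"], "levenshtein")

    def test_rmsd_requires_structures(self):
        with pytest.raises(Exception):
            t.build_distance_matrix(["AAAA", "CCCC"], "rmsd")

    def test_tsv_roundtrip(self, tmp_path, rng):
        peps = random_peptides(rng, 6)
        m = t.build_distance_matrix(peps, "blosum")
        path = t.write_distance_matrix(m, tmp_path / "m.tsv",
                                       params=DEFAULT_PARAMS)
        back = t.read_distance_matrix(path)
        assert back.metric == "blosum"
        assert back.peptides == m.peptides
        np.testing.assert_allclose(back.values, m.values, rtol=1e-9)


class TestAggregateRowwise:
    def _matrix_from(self, values):
        n = values.shape[0]
        peps = [f"{'ACDEFGHIKL'[i] * 5}" for i in range(n)]
        return t.DistanceMatrix(tuple(peps), values, "levenshtein")

    def test_textbook_median(self):
        v = np.array([[0, 2, 4, 6], [2, 0, 9, 9], [4, 9, 0, 9], [6, 9, 9, 0]],
                     dtype=float)
        agg = t.aggregate_rowwise(self._matrix_from(v), "median")
        assert agg.values[0] == 4.0

    @pytest.mark.parametrize("aggregator", ["median", "mean", "min"])
    def test_constant_off_diagonal(self, aggregator):
        v = np.full((4, 4), 7.0)
        np.fill_diagonal(v, 0.0)
        agg = t.aggregate_rowwise(self._matrix_from(v), aggregator)
        assert np.all(agg.values == 7.0)

    @pytest.mark.parametrize("aggregator", ["median", "mean", "min"])
    def test_matches_sort_based_recomputation(self, rng, aggregator):
        peps = random_peptides(rng, 20)
        m = t.build_distance_matrix(peps, "levenshtein")
        agg = t.aggregate_rowwise(m, aggregator)
        fn = {"median": np.median, "mean": np.mean, "min": np.min}[aggregator]
        for i in range(20):
            row = np.delete(m.values[i], i)
            assert agg.values[i] == pytest.approx(fn(np.sort(row)))

    def test_single_peptide_rejected(self):
        m = t.DistanceMatrix(("AAAAA",), np.zeros((1, 1)), "levenshtein")
        with pytest.raises(ValueError):
            t.aggregate_rowwise(m)
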