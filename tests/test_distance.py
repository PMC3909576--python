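import itertools

import numpy as np
import pytest

from ssrkit.distance import (
    DistanceError,
    cultivar_matrix,
    distance_matrix,
    ld_screen,
    pair_distance,
    pcoa,
    phipt,
    score_vector,
)
from ssrkit.model import GenotypeCall, GenotypeTable, Locus
from ssrkit.simulate import SimPopConfig, simulate_background, simulate_cultivars

from conftest import make_table


def brute_force_locus_distance(geno_x, geno_y, alleles):
    """Independent oracle: half the squared Euclidean gap between dosage vectors."""
    def dosage(geno):
        return [list(geno).count(a) for a in alleles]

    vx, vy = dosage(geno_x), dosage(geno_y)
    return 0.5 * sum((a - b) ** 2 for a, b in zip(vx, vy))


class TestScoreVector:
    def test_homozygote(self):
        locus = Locus("L1", (1, 2))
        assert list(score_vector(GenotypeCall(1, 1), locus)) == [2, 0]

    def test_heterozygote(self):
        locus = Locus("L1", (1, 2, 3))
        assert list(score_vector(GenotypeCall(1, 2), locus)) == [1, 1, 0]

    def test_missing_is_zero_vector(self):
        locus = Locus("L1", (1, 2))
        assert list(score_vector(GenotypeCall(), locus)) == [0, 0]

    def test_unregistered_allele_rejected(self):
        with pytest.raises(DistanceError):
            score_vector(GenotypeCall(9, 9), Locus("L1", (1, 2)))


SINGLE_LOCUS_CASES = [
    ((1, 2), (1, 2), 0),  # identical heterozygotes
    ((1, 1), (1, 1), 0),  # identical homozygotes
    ((1, 2), (1, 3), 1),  # heterozygotes sharing one allele
    ((1, 1), (1, 2), 1),  # homozygote vs sharing heterozygote
    ((1, 2), (3, 4), 2),  # disjoint heterozygotes
    ((1, 1), (2, 3), 3),  # homozygote vs disjoint heterozygote
    ((1, 1), (2, 2), 4),  # disjoint homozygotes
]


class TestPairDistance:
    @pytest.mark.parametrize("gx,gy,expected", SINGLE_LOCUS_CASES)
    def test_single_locus_values(self, gx, gy, expected):
        table = make_table([("x", "cv", {"L1": gx}), ("y", "cv", {"L1": gy})])
        x, y = table.samples
        d = pair_distance(x, y, table.loci)
        assert d == expected
        alleles = sorted(set(gx) | set(gy))
        assert d == brute_force_locus_distance(gx, gy, alleles)

    def test_exhaustive_against_brute_force(self):
        # every unordered genotype pair over a 4-allele ladder
        alleles = [1, 2, 3, 4]
        genotypes = list(itertools.combinations_with_replacement(alleles, 2))
        for gx, gy in itertools.product(genotypes, repeat=2):
            table = make_table([("x", "cv", {"L1": gx}), ("y", "cv", {"L1": gy})])
            d = pair_distance(*table.samples, table.loci)
            assert d == brute_force_locus_distance(gx, gy, alleles)
            assert d in {0, 1, 2, 3, 4}

    def test_multilocus_additivity(self):
        table = make_table(
            [("x", "cv", {"L1": (1, 1), "L2": (5, 6)}),
             ("y", "cv", {"L1": (2, 2), "L2": (5, 7)})]
        )
        assert pair_distance(*table.samples, table.loci) == 4 + 1

    def test_missing_locus_dropped(self):
        table = make_table(
            [("x", "cv", {"L1": (1, 1), "L2": None}),
             ("y", "cv", {"L1": (2, 2), "L2": (5, 7)})]
        )
        assert pair_distance(*table.samples, table.loci) == 4

    def test_rescaling_for_missing(self):
        table = make_table(
            [("x", "cv", {"L1": (1, 1), "L2": None}),
             ("y", "cv", {"L1": (2, 2), "L2": (5, 7)})]
        )
        assert pair_distance(*table.samples, table.loci, rescale_missing=True) == 8

    def test_no_shared_locus_errors(self):
        table = make_table(
            [("x", "cv", {"L1": (1, 1), "L2": None}),
             ("y", "cv", {"L1": None, "L2": (5, 7)})]
        )
        with pytest.raises(DistanceError):
            pair_distance(*table.samples, table.loci)


class TestDistanceMatrix:
    def test_matches_pairwise_function(self):
        cfg = SimPopConfig(n_loci=5, n_cultivars=3, clones_per_cultivar=3,
                           variant_clone_rate=0.5, rng_seed=4)
        bg = simulate_background(cfg)
        table, _ = simulate_cultivars(cfg, bg)
        dist = distance_matrix(table)
        for i, x in enumerate(table.samples):
            for j, y in enumerate(table.samples):
                assert dist.matrix[i, j] == pytest.approx(
                    0.0 if i == j else pair_distance(x, y, table.loci)
                )
        assert np.allclose(dist.matrix, dist.matrix.T)
        assert np.all(dist.matrix <= 4 * len(table.loci))

    def test_zero_iff_identical(self):
        table = make_table(
            [("a", "cv", {"L1": (1, 2), "L2": (5, 5)}),
             ("b", "cv", {"L1": (1, 2), "L2": (5, 5)}),
             ("c", "cv", {"L1": (1, 2), "L2": (5, 6)})]
        )
        m = distance_matrix(table).matrix
        assert m[0, 1] == 0.0
        assert m[0, 2] > 0.0


class TestCultivarMatrix:
    def test_identical_clones_zero_diagonal(self):
        table = make_table(
            [("a1", "A", {"L1": (1, 2)}), ("a2", "A", {"L1": (1, 2)}),
             ("b1", "B", {"L1": (3, 4)}), ("b2", "B", {"L1": (3, 4)})]
        )
        dist = distance_matrix(table)
        summary = cultivar_matrix(dist, [s.cultivar for s in table.samples])
        assert summary.matrix[0, 0] == 0.0 and summary.matrix[1, 1] == 0.0
        assert summary.matrix[0, 1] == 2.0  # AB-CD disjoint heterozygotes

    def test_singleton_cultivars(self):
        table = make_table(
            [("a", "A", {"L1": (1, 1)}), ("b", "B", {"L1": (2, 2)})]
        )
        dist = distance_matrix(table)
        summary = cultivar_matrix(dist, ["A", "B"])
        assert summary.matrix[0, 1] == 4.0
        assert summary.singletons == ["A", "B"]

    def test_means_equal_brute_force(self):
        table = make_table(
            [("a1", "A", {"L1": (1, 2)}), ("a2", "A", {"L1": (1, 1)}),
             ("b1", "B", {"L1": (3, 3)}), ("b2", "B", {"L1": (2, 3)})]
        )
        dist = distance_matrix(table)
        summary = cultivar_matrix(dist, [s.cultivar for s in table.samples])
        cross = [
            pair_distance(x, y, table.loci)
            for x in table.samples[:2]
            for y in table.samples[2:]
        ]
        assert summary.matrix[0, 1] == pytest.approx(sum(cross) / 4)
        assert summary.matrix[0, 0] == pytest.approx(
            pair_distance(table.samples[0], table.samples[1], table.loci)
        )


class TestPCoA:
    def test_three_equidistant_entities(self):
        D2 = np.array([[0, 2, 2], [2, 0, 2], [2, 2, 0]], dtype=float)
        res = pcoa(D2, ids=["a", "b", "c"])
        assert res.eigenvalues[0] == pytest.approx(res.eigenvalues[1])
        # equilateral triangle: all pairwise coordinate gaps equal
        gaps = [
            np.sum((res.coordinates[i] - res.coordinates[j]) ** 2)
            for i, j in itertools.combinations(range(3), 2)
        ]
        assert np.allclose(gaps, gaps[0])
        assert res.pct_variation.sum() == pytest.approx(100.0)

    def test_identical_entities_coincide(self):
        D2 = np.array(
            [[0, 0, 5], [0, 0, 5], [5, 5, 0]], dtype=float
        )
        res = pcoa(D2)
        assert np.allclose(res.coordinates[0], res.coordinates[1])

    def test_round_trip_on_euclidean_points(self):
        rng = np.random.default_rng(8)
        points = rng.normal(size=(7, 3))
        diff = points[:, None, :] - points[None, :, :]
        D2 = (diff**2).sum(axis=-1)
        res = pcoa(D2)
        C = res.coordinates
        dd = ((C[:, None, :] - C[None, :, :]) ** 2).sum(axis=-1)
        assert np.allclose(dd, D2, atol=1e-8)
        assert res.eigenvalues[res.eigenvalues > 1e-8].sum() == pytest.approx(
            np.trace(
                -0.5
                * (np.eye(7) - 1 / 7)
                @ D2
                @ (np.eye(7) - 1 / 7)
            )
        )

    def test_nan_rejected(self):
        D2 = np.zeros((3, 3))
        D2[0, 1] = D2[1, 0] = np.nan
        with pytest.raises(ValueError):
            pcoa(D2)


def amova_phipt_oracle(matrix, labels):
    """Independent spreadsheet-style AMOVA on a squared-distance matrix."""
    n = len(labels)
    groups = sorted(set(labels))
    ss_total = sum(matrix[i][j] for i in range(n) for j in range(i + 1, n)) / n
    ss_within = 0.0
    for g in groups:
        idx = [i for i, l in enumerate(labels) if l == g]
        ss_within += sum(
            matrix[i][j] for i in idx for j in idx if i < j
        ) / len(idx)
    ss_among = ss_total - ss_within
    ms_among = ss_among / (len(groups) - 1)
    ms_within = ss_within / (n - len(groups))
    n0 = (n - sum(labels.count(g) ** 2 for g in groups) / n) / (len(groups) - 1)
    var_among = (ms_among - ms_within) / n0
    return var_among / (var_among + ms_within)


@pytest.fixture
def six_sample_table():
    return make_table(
        [
            ("a1", "A", {"L1": (1, 2), "L2": (5, 5)}),
            ("a2", "A", {"L1": (1, 1), "L2": (5, 6)}),
            ("a3", "A", {"L1": (1, 2), "L2": (5, 6)}),
            ("b1", "B", {"L1": (3, 4), "L2": (7, 7)}),
            ("b2", "B", {"L1": (3, 3), "L2": (7, 8)}),
            ("b3", "B", {"L1": (2, 4), "L2": (7, 8)}),
        ]
    )


class TestPhiPT:
    def test_matches_independent_amova_oracle(self, six_sample_table):
        table = six_sample_table
        dist = distance_matrix(table)
        labels = [s.cultivar for s in table.samples]
        res = phipt(dist, labels, n_perm=9, seed=0)
        expected = amova_phipt_oracle(dist.matrix.tolist(), labels)
        assert res.phi_pt == pytest.approx(expected, abs=1e-10)

    def test_null_labels_not_significant(self):
        rng = np.random.default_rng(5)
        rows = []
        for k in range(24):
            rows.append(
                (f"s{k}", "X" if k % 2 else "Y",
                 {"L1": tuple(sorted(rng.integers(1, 5, 2))),
                  "L2": tuple(sorted(rng.integers(1, 5, 2)))})
            )
        table = make_table(rows)
        dist = distance_matrix(table)
        res = phipt(dist, [s.cultivar for s in table.samples], n_perm=999, seed=1)
        assert res.p_value > 0.05
        assert abs(res.phi_pt) < 0.15

    def test_disjoint_clone_groups_phi_one(self):
        table = make_table(
            [("a1", "A", {"L1": (1, 1)}), ("a2", "A", {"L1": (1, 1)}),
             ("b1", "B", {"L1": (2, 2)}), ("b2", "B", {"L1": (2, 2)})]
        )
        dist = distance_matrix(table)
        res = phipt(dist, ["A", "A", "B", "B"], n_perm=9, seed=0)
        assert res.phi_pt == pytest.approx(1.0)
        assert 0 < res.p_value <= 1

    def test_invariant_under_relabeling_and_order(self, six_sample_table):
        table = six_sample_table
        dist = distance_matrix(table)
        labels = [s.cultivar for s in table.samples]
        base = phipt(dist, labels, n_perm=9, seed=0).phi_pt
        renamed = phipt(dist, ["G1" if l == "A" else "G2" for l in labels],
                        n_perm=9, seed=0).phi_pt
        assert renamed == pytest.approx(base)
        order = [3, 1, 5, 0, 4, 2]
        samples = [table.samples[i] for i in order]
        t2 = GenotypeTable.from_samples(samples, table.locus_names)
        d2 = distance_matrix(t2)
        permuted = phipt(d2, [s.cultivar for s in samples], n_perm=9, seed=0).phi_pt
        assert permuted == pytest.approx(base)

    def test_single_group_rejected(self, six_sample_table):
        dist = distance_matrix(six_sample_table)
        with pytest.raises(ValueError):
            phipt(dist, ["A"] * 6, n_perm=9)


class TestLDScreen:
    def test_pair_count(self):
        cfg = SimPopConfig(n_loci=16, n_cultivars=3, clones_per_cultivar=4,
                           rng_seed=6)
        bg = simulate_background(cfg)
        table, _ = simulate_cultivars(cfg, bg)
        pvals = ld_screen(table, n_perm=19, seed=0)
        assert len(pvals) == 120

    def test_duplicated_locus_hits_permutation_floor(self):
        rng = np.random.default_rng(2)
        rows = []
        for k in range(30):
            g = tuple(sorted(rng.integers(1, 5, 2)))
            rows.append((f"s{k}", "cv", {"L1": g, "L2": tuple(a + 100 for a in g)}))
        table = make_table(rows)
        n_perm = 99
        pvals = ld_screen(table, n_perm=n_perm, seed=0)
        assert pvals[("L1", "L2")] == pytest.approx(1 / (n_perm + 1))

    def test_independent_loci_roughly_uniform(self):
        cfg = SimPopConfig(n_loci=10, n_cultivars=1, clones_per_cultivar=80,
                           seed_propagated=frozenset({0}), rng_seed=9)
        bg = simulate_background(cfg)
        table, _ = simulate_cultivars(cfg, bg)
        pvals = ld_screen(table, n_perm=199, seed=3)
        assert len(pvals) == 45
        frac_sig = sum(1 for p in pvals.values() if p < 0.05) / len(pvals)
        assert frac_sig <= 0.12
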