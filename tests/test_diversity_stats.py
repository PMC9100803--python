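"""Nucleotide diversity, rarefaction, QC SNP selection, LD, K2P, Ward, SFS."""

import math
from itertools import combinations

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from haplomine.io_formats import ALT, MISSING, REF, GeneRegion
from haplomine import diversity_stats as dv
from conftest import make_matrix, make_site

GENE = GeneRegion(gene_id="g1", chrom="chr1", start=1, end=1000)


def brute_pi(states, length):
    """Oracle: explicit pairwise Hamming loop."""
    states = np.asarray(states)
    n = states.shape[1]
    total = 0
    for i, j in combinations(range(n), 2):
        both = (states[:, i] != MISSING) & (states[:, j] != MISSING)
        total += np.count_nonzero(
            (states[both, i] == ALT) != (states[both, j] == ALT))
    return total / (n * (n - 1) / 2) / length


class TestNucleotideDiversity:
    def test_monomorphic_region_is_zero(self):
        assert dv.nucleotide_diversity(np.zeros((5, 4)), 100) == 0.0

    def test_one_difference_over_hundred_sites(self):
        states = np.array([[REF, ALT]])
        assert dv.nucleotide_diversity(states, 100) == pytest.approx(0.01)

    def test_two_pairs_example(self):
        """2 all-REF + 2 accessions ALT at the same 2 sites, L=10 -> (8/6)/10."""
        states = np.zeros((2, 4), dtype=np.int8)
        states[:, 2] = ALT
        states[:, 3] = ALT
        assert dv.nucleotide_diversity(states, 10) == pytest.approx(8 / 6 / 10)

    def test_fewer_than_two_accessions_errors(self):
        with pytest.raises(ValueError):
            dv.nucleotide_diversity(np.zeros((3, 1)), 10)

    def test_matches_pairwise_oracle_with_missing(self):
        rng = np.random.default_rng(0)
        for _ in range(10):
            states = rng.choice([REF, ALT, MISSING], size=(8, 7), p=[0.6, 0.3, 0.1])
            assert dv.nucleotide_diversity(states, 50) == \
                pytest.approx(brute_pi(states, 50))

    def test_frequency_form_identity_on_complete_data(self):
        """Sum 2p(1-p) n/(n-1) / L equals pairwise-Hamming pi, 20 random fixtures."""
        rng = np.random.default_rng(123)
        for _ in range(20):
            n = int(rng.integers(2, 12))
            s = int(rng.integers(1, 15))
            states = rng.choice([REF, ALT], size=(s, n)).astype(np.int8)
            length = int(rng.integers(s, 3 * s + 10))
            a = dv.nucleotide_diversity(states, length)
            b = dv.pi_from_frequencies(states, length)
            assert abs(a - b) < 1e-12


class TestRarefaction:
    def test_self_rarefaction_is_mostly_indistinct(self):
        """A focal panel that IS a pool subsample is indistinct >= 95/100 trials."""
        rng = np.random.default_rng(77)
        pool = rng.choice([REF, ALT], size=(40, 60), p=[0.8, 0.2]).astype(np.int8)
        indistinct = 0
        for trial in range(100):
            cols = rng.choice(60, size=30, replace=False)
            result = dv.rarefied_pi_comparison(
                pool[:, cols], pool, 100, reps=100, seed=trial)
            indistinct += result.verdict == "indistinct"
        assert indistinct >= 95

    def test_monomorphic_focal_vs_polymorphic_pool_is_reduced(self):
        rng = np.random.default_rng(5)
        pool = rng.choice([REF, ALT], size=(10, 40)).astype(np.int8)
        focal = np.zeros((10, 10), dtype=np.int8)
        result = dv.rarefied_pi_comparison(focal, pool, 100, reps=50, seed=0)
        assert result.verdict == "reduced"

    def test_single_rep_still_produces_verdict(self):
        pool = np.zeros((2, 5), dtype=np.int8)
        pool[0, 0] = ALT
        result = dv.rarefied_pi_comparison(pool[:, :3], pool, 10, reps=1, seed=1)
        assert result.verdict in ("reduced", "elevated", "indistinct")
        assert len(result.rarefied_pis) == 1

    def test_full_size_subsample_equals_pool_pi(self):
        rng = np.random.default_rng(3)
        pool = rng.choice([REF, ALT], size=(6, 12)).astype(np.int8)
        result = dv.rarefied_pi_comparison(pool, pool, 30, reps=5, seed=0)
        pool_pi = dv.nucleotide_diversity(pool, 30)
        assert all(v == pytest.approx(pool_pi) for v in result.rarefied_pis)
        assert result.verdict == "indistinct"

    def test_pool_smaller_than_focal_errors(self):
        with pytest.raises(ValueError, match="pool"):
            dv.rarefied_pi_comparison(np.zeros((2, 10)), np.zeros((2, 5)), 10)


class TestSelectQcSnp:
    def build(self, specs, n=20, seed=0):
        """specs: list of (pos, alt_fraction, filter, n_alts, missing_count)."""
        rng = np.random.default_rng(seed)
        sites, rows = [], []
        for pos, alt_frac, filt, n_alts, miss in specs:
            alts = tuple("GCT"[:n_alts])
            sites.append(make_site(pos, filt=filt, alts=alts))
            n_alt = int(round(alt_frac * n))
            row = np.array([ALT] * n_alt + [REF] * (n - n_alt), dtype=np.int8)
            row[rng.permutation(n)[:miss]] = MISSING
            rows.append(row)
        m = make_matrix(np.array(rows), positions=[s.pos for s in sites])
        return type(m)(sites, m.accessions, m.states)

    def test_rule_by_rule_elimination(self):
        m = self.build([
            (10, 0.2, "PASS", 1, 2),    # cov 0.9, MAF .2 biallelic -> survivor
            (20, 0.2, "LowQual", 1, 1),  # rejected: low quality
            (30, 0.2, "PASS", 2, 0),     # rejected: 3 alleles
            (40, 0.2, "PASS", 1, 5),     # rejected: coverage 0.75
            (50, 0.02, "PASS", 1, 0),    # rejected: MAF < 0.05
        ])
        pick = dv.select_qc_snp(GENE, range(5), m)
        assert m.sites[pick].pos == 10

    def test_all_rare_gives_none(self):
        m = self.build([(10, 0.02, "PASS", 1, 0), (20, 0.0, "PASS", 1, 0)])
        assert dv.select_qc_snp(GENE, range(2), m) is None

    def test_single_passing_candidate_selected(self):
        m = self.build([(10, 0.3, "PASS", 1, 0)])
        assert dv.select_qc_snp(GENE, [0], m) == 0

    def test_highest_coverage_wins_ties_to_lowest_pos(self):
        m = self.build([
            (10, 0.3, "PASS", 1, 1),
            (20, 0.3, "PASS", 1, 0),
            (30, 0.3, "PASS", 1, 0),
        ])
        assert m.sites[dv.select_qc_snp(GENE, range(3), m)].pos == 20


class TestLD:
    def test_identical_vectors_r2_one(self):
        pair = dv.ld_r2(np.array([REF, REF, ALT, ALT]), np.array([REF, REF, ALT, ALT]))
        assert pair.r2 == pytest.approx(1.0)

    def test_orthogonal_vectors_r2_zero(self):
        pair = dv.ld_r2(np.array([REF, REF, ALT, ALT]), np.array([REF, ALT, REF, ALT]))
        assert pair.r2 == pytest.approx(0.0)

    def test_agreement_with_textbook_d_squared_formula(self):
        """r2 from Pearson correlation equals D^2/(p1 q1 p2 q2) on haploid data."""
        rng = np.random.default_rng(11)
        checked = 0
        while checked < 10:
            a = rng.choice([REF, ALT], size=6)
            b = rng.choice([REF, ALT], size=6)
            if len(set(a)) < 2 or len(set(b)) < 2:
                continue
            pa = np.mean(a == ALT)
            pb = np.mean(b == ALT)
            pab = np.mean((a == ALT) & (b == ALT))
            d = pab - pa * pb
            expected = d * d / (pa * (1 - pa) * pb * (1 - pb))
            pair = dv.ld_r2(a, b)
            assert pair.r2 == pytest.approx(expected)
            checked += 1

    def test_constant_vector_skipped(self):
        assert dv.ld_r2(np.array([REF, REF, REF]), np.array([REF, ALT, REF])) is None

    def test_too_few_complete_pairs_errors(self):
        with pytest.raises(ValueError):
            dv.ld_r2(np.array([MISSING, MISSING, ALT]), np.array([ALT, REF, MISSING]))

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.lists(st.tuples(st.integers(0, 1), st.integers(0, 1)),
                    min_size=3, max_size=30))
    def test_r2_bounded_in_unit_interval(self, pairs):
        a = np.array([p[0] for p in pairs], dtype=np.int8)
        b = np.array([p[1] for p in pairs], dtype=np.int8)
        if len(set(a.tolist())) < 2 or len(set(b.tolist())) < 2:
            return
        pair = dv.ld_r2(a, b)
        assert 0.0 <= pair.r2 <= 1.0 + 1e-12


class TestK2P:
    def test_identical_sequences_zero(self):
        result = dv.k2p_distance("ACGTACGT", "ACGTACGT")
        assert result.p == result.q == 0 and result.d == 0

    def test_closed_form_example(self):
        # P=0.1, Q=0.05: d = -0.5 ln((1-0.25) sqrt(0.9)) = 0.1701812 (frozen
        # from the high-precision closed-form evaluation)
        expected = -0.5 * math.log(0.75 * math.sqrt(0.9))
        assert expected == pytest.approx(0.1701812, abs=1e-7)
        assert dv.k2p_from_proportions(0.1, 0.05) == pytest.approx(expected)
        # 20 sites: 2 transitions (A<->G), 1 transversion (A<->C)
        a = "AAGGCCTTACGTACGTACGT"
        b = "AGGACCTTCCGTACGTACGT"
        result = dv.k2p_distance(a, b)
        assert result.p == pytest.approx(0.1) and result.q == pytest.approx(0.05)
        assert result.d == pytest.approx(0.1701812, abs=1e-5)

    def test_saturation_error(self):
        with pytest.raises(dv.SaturationError):
            dv.k2p_from_proportions(0.5, 0.0)

    def test_symmetry_and_n_skipping(self):
        a, b = "ACGTN", "AAGTC"
        assert dv.k2p_distance(a, b).d == dv.k2p_distance(b, a).d
        # N position skipped: compared=4, one transition C->A? (C,A) is transversion
        result = dv.k2p_distance(a, b)
        assert result.q == pytest.approx(1 / 4) and result.p == 0.0

    def test_small_p_limit_approaches_p(self):
        p = 1e-4
        assert dv.k2p_from_proportions(p, 0.0) == pytest.approx(p, abs=1e-6)

    def test_matrix_agrees_with_per_pair_route(self):
        rng = np.random.default_rng(4)
        seqs = {}
        for i in range(6):
            seqs[f"s{i}"] = "".join(rng.choice(list("ACGTN"), size=30,
                                               p=[0.24, 0.24, 0.24, 0.24, 0.04]))
        frame, undefined = dv.k2p_matrix(seqs)
        for x, y in combinations(seqs, 2):
            if (x, y) in undefined or (y, x) in undefined:
                continue
            assert frame.loc[x, y] == pytest.approx(dv.k2p_distance(seqs[x], seqs[y]).d)


def naive_ward(dist):
    """Oracle: O(n^3) greedy agglomeration with the Lance-Williams Ward update."""
    n = dist.shape[0]
    active = {i: (1, i) for i in range(n)}  # cluster id -> (size, linkage index)
    d = {frozenset((i, j)): dist[i, j] for i in range(n) for j in range(i + 1, n)}
    merges = []
    next_id = n
    while len(active) > 1:
        pair = min(d, key=lambda k: (d[k], sorted(active[c][1] for c in k)))
        i, j = sorted(pair, key=lambda c: active[c][1])
        dij = d.pop(pair)
        ni, nj = active[i][0], active[j][0]
        merges.append((active[i][1], active[j][1], dij, ni + nj))
        for k in list(active):
            if k in (i, j):
                continue
            nk = active[k][0]
            dik = d.pop(frozenset((i, k)))
            djk = d.pop(frozenset((j, k)))
            new = math.sqrt(
                ((ni + nk) * dik ** 2 + (nj + nk) * djk ** 2 - nk * dij ** 2)
                / (ni + nj + nk)
            )
            d[frozenset((next_id, k))] = new
        del active[i], active[j]
        active[next_id] = (ni + nj, next_id)
        next_id += 1
    return merges


class TestWard:
    def test_two_separated_zero_distance_pairs_suggest_two(self):
        d = np.array([
            [0.0, 0.0, 5.0, 5.0],
            [0.0, 0.0, 5.0, 5.0],
            [5.0, 5.0, 0.0, 0.0],
            [5.0, 5.0, 0.0, 0.0],
        ])
        _, k = dv.ward_dendrogram(d)
        assert k == 2

    def test_all_zero_matrix_single_cluster(self):
        _, k = dv.ward_dendrogram(np.zeros((5, 5)))
        assert k == 1

    def test_merge_heights_non_decreasing(self):
        rng = np.random.default_rng(6)
        pts = rng.normal(size=(12, 3))
        d = np.sqrt(((pts[:, None] - pts[None]) ** 2).sum(-1))
        z, _ = dv.ward_dendrogram(d)
        assert np.all(np.diff(z[:, 2]) >= -1e-12)

    def test_matches_exhaustive_greedy_oracle_on_six_points(self):
        rng = np.random.default_rng(10)
        for _ in range(5):
            pts = rng.normal(size=(6, 2))
            d = np.sqrt(((pts[:, None] - pts[None]) ** 2).sum(-1))
            z, _ = dv.ward_dendrogram(d)
            expected = naive_ward(d)
            for row, (a, b, h, size) in zip(z, expected):
                assert sorted(row[:2]) == sorted((a, b))
                assert row[2] == pytest.approx(h)
                assert row[3] == size

    def test_undefined_entries_rejected(self):
        d = np.zeros((3, 3))
        d[0, 1] = d[1, 0] = np.nan
        with pytest.raises(ValueError, match="undefined"):
            dv.ward_dendrogram(d)


class TestSFS:
    def test_counts_example(self):
        states = np.zeros((3, 5), dtype=np.int8)
        states[0, 0] = ALT
        states[1, 1] = ALT
        states[2, :4] = ALT
        m = make_matrix(states)
        per_chrom, genome = dv.sfs(m)
        assert genome[1] == 2 and genome[4] == 1
        assert genome.sum() == 3

    def test_bin_sum_equals_sites_with_alt(self):
        rng = np.random.default_rng(9)
        states = rng.choice([REF, ALT], size=(50, 8), p=[0.6, 0.4]).astype(np.int8)
        m = make_matrix(states)
        _, genome = dv.sfs(m)
        expected = int(((states == ALT).sum(axis=1) >= 1).sum())
        assert genome.sum() == expected

    def test_genome_is_sum_of_chromosomes(self):
        rng = np.random.default_rng(14)
        states = rng.choice([REF, ALT], size=(20, 6)).astype(np.int8)
        m1 = make_matrix(states[:10], chrom="chr1")
        m2 = make_matrix(states[10:], chrom="chr2", positions=[500 + i for i in range(10)])
        from haplomine.io_formats import GenotypeMatrix
        m = GenotypeMatrix(m1.sites + m2.sites, m1.accessions,
                           np.vstack([m1.states, m2.states]))
        per_chrom, genome = dv.sfs(m)
        assert np.array_equal(per_chrom["chr1"] + per_chrom["chr2"], genome)

    def test_matches_exhaustive_tally(self):
        rng = np.random.default_rng(21)
        states = rng.choice([REF, ALT, MISSING], size=(50, 9),
                            p=[0.5, 0.4, 0.1]).astype(np.int8)
        m = make_matrix(states)
        _, genome = dv.sfs(m)
        tally = np.zeros(10, dtype=int)
        for row in states:
            k = int((row == ALT).sum())
            if k >= 1:
                tally[k] += 1
        assert np.array_equal(genome, tally)


class TestExport:
    def test_nexus_dimensions(self, tmp_path):
        rng = np.random.default_rng(2)
        m = make_matrix(rng.integers(0, 3, size=(10, 5)).astype(np.int8))
        path = dv.export_genotype_matrix(m, tmp_path / "g.nex")
        text = path.read_text()
        assert "DIMENSIONS NTAX=5 NCHAR=10" in text
        assert 'SYMBOLS="01"' in text

    def test_tsv_round_trip(self, tmp_path):
        rng = np.random.default_rng(7)
        m = make_matrix(rng.integers(0, 3, size=(6, 4)).astype(np.int8))
        path = dv.export_genotype_matrix(m, tmp_path / "g.tsv", fmt="plain_tsv")
        back = dv.import_genotype_tsv(path)
        assert back.accessions == m.accessions
        assert np.array_equal(back.states, m.states)
        assert [(s.chrom, s.pos) for s in back.sites] == \
               [(s.chrom, s.pos) for s in m.sites]

    def test_multiallelic_rejected_with_site_name(self, tmp_path):
        m = make_matrix(np.zeros((1, 2)), positions=[123], alts=("G", "T"))
        with pytest.raises(ValueError, match="chr1:123"):
            dv.export_genotype_matrix(m, tmp_path / "g.nex")
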