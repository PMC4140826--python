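"""Folding engine vs exhaustive enumeration, region search, empirical p-values."""

import numpy as np
import pytest

from lncsnp.core_io import GenomicInterval, ValidationError
from lncsnp.core_io import revcomp_rna
from lncsnp.structure_disruption import (
    BasePairMatrix,
    FoldWindow,
    NotScoreableError,
    ReferenceMismatchError,
    ScoreConfig,
    base_pair_probabilities,
    disruption_score,
    empirical_pvalue,
    enumerate_pair_probabilities,
    extract_window,
    score_variant,
    substitution_distance_table,
)
from lncsnp.synthetic_data import SimulationConfig, generate_structure_fixture
from lncsnp.variant_map import map_variants
from .conftest import make_lnc, make_variant


def random_rna(rng, n):
    return "".join(rng.choice(list("ACGU"), size=n))


class TestBasePairProbabilities:
    def test_unpairable_sequences_give_zero_matrix(self):
        for seq in ("AAAAAAA", "ACGU"):
            assert base_pair_probabilities(seq).P.sum() == 0.0

    def test_matches_enumeration_on_hairpin(self):
        P = base_pair_probabilities("GGGAAAACCC").P
        E = enumerate_pair_probabilities("GGGAAAACCC")
        assert np.abs(P - E).max() < 1e-9

    def test_matches_enumeration_on_random_sequences(self, rng):
        worst = 0.0
        for _ in range(25):
            seq = random_rna(rng, int(rng.integers(6, 26)))
            P = base_pair_probabilities(seq).P
            E = enumerate_pair_probabilities(seq)
            worst = max(worst, float(np.abs(P - E).max()))
        assert worst < 1e-9

    def test_row_sums_bounded_by_one(self, rng):
        for n in (40, 120, 300):
            P = base_pair_probabilities(random_rna(rng, n)).P
            assert P.sum(axis=1).max() <= 1.0 + 1e-9

    def test_min_hairpin_and_pair_rules_hold(self, rng):
        seq = random_rna(rng, 60)
        P = base_pair_probabilities(seq).P
        ok = {"AU", "UA", "GC", "CG", "GU", "UG"}
        for i in range(60):
            for j in range(i + 1, 60):
                if j - i < 4 or seq[i] + seq[j] not in ok:
                    assert P[i, j] == 0.0

    def test_complement_symmetry_without_wobble(self, rng):
        for _ in range(10):
            seq = random_rna(rng, 30)
            P = base_pair_probabilities(seq, wobble=False).P
            Q = base_pair_probabilities(revcomp_rna(seq), wobble=False).P
            assert np.abs(P - Q[::-1, ::-1].T).max() < 1e-9

    def test_complement_symmetry_with_wobble_on_watson_crick_alphabets(self, rng):
        # GU wobble breaks the mirror in general; AU-only and GC-only
        # sequences cannot form wobble pairs on either strand
        for letters in ("AU", "GC"):
            seq = "".join(rng.choice(list(letters), size=40))
            P = base_pair_probabilities(seq).P
            Q = base_pair_probabilities(revcomp_rna(seq)).P
            assert np.abs(P - Q[::-1, ::-1].T).max() < 1e-9

    def test_invalid_alphabet_rejected(self):
        with pytest.raises(ValueError):
            base_pair_probabilities("ACGT")  # DNA not allowed here

    def test_deterministic(self, rng):
        seq = random_rna(rng, 150)
        P1 = base_pair_probabilities(seq).P
        P2 = base_pair_probabilities(seq).P
        assert np.array_equal(P1, P2)


class TestDisruptionScore:
    def _brute_force(self, Pw, Pm, snp, min_region):
        n = Pw.shape[0]
        best = (-1.0, None)
        for i in range(0, snp + 1):
            for j in range(max(snp, i + min_region - 1), n):
                if j - i + 1 < min_region:
                    continue
                s = 0.0
                for u in range(i, j + 1):
                    for v in range(u + 1, j + 1):
                        s += (Pw[u, v] - Pm[u, v]) ** 2
                d = np.sqrt(s) / (j - i + 1)
                if d > best[0] + 1e-15:
                    best = (d, (i, j))
        return best[1], best[0]

    def test_identity_returns_first_admissible_region(self):
        P = BasePairMatrix(np.zeros((60, 60)))
        region, d = disruption_score(P, P, snp_offset=10, min_region=50)
        assert d == 0.0
        # smallest i then smallest j: the shortest admissible interval
        # containing the variant (snp_offset < min_region here)
        assert region == (0, 49)

    def test_matches_bruteforce_region_scan(self, rng):
        n, snp, min_region = 60, 25, 12
        seqw = random_rna(rng, n)
        seqm = seqw[:snp] + ("A" if seqw[snp] != "A" else "G") + seqw[snp + 1:]
        Pw = base_pair_probabilities(seqw)
        Pm = base_pair_probabilities(seqm)
        region, d = disruption_score(Pw, Pm, snp, min_region)
        exp_region, exp_d = self._brute_force(Pw.P, Pm.P, snp, min_region)
        assert region == exp_region
        assert d == pytest.approx(exp_d, abs=1e-12)

    def test_symmetric_in_arguments(self, rng):
        a = base_pair_probabilities(random_rna(rng, 70))
        b = base_pair_probabilities(random_rna(rng, 70))
        _, d1 = disruption_score(a, b, 30, 20)
        _, d2 = disruption_score(b, a, 30, 20)
        assert d1 == d2

    def test_region_contains_snp(self, rng):
        a = base_pair_probabilities(random_rna(rng, 80))
        b = base_pair_probabilities(random_rna(rng, 80))
        for snp in (0, 40, 79):
            (i, j), _ = disruption_score(a, b, snp, 30)
            assert i <= snp <= j

    def test_dimension_mismatch(self):
        with pytest.raises(ValidationError):
            disruption_score(BasePairMatrix(np.zeros((5, 5))),
                             BasePairMatrix(np.zeros((6, 6))), 0, 2)


class TestExtractWindow:
    def test_central_window_arithmetic(self):
        lnc = make_lnc(start=0, end=1000, seed=3)
        v = make_variant(pos=500, ref=lnc.transcript_seq[500].replace("U", "T"),
                         alt="G" if lnc.transcript_seq[500] != "G" else "C")
        (a,) = map_variants([v], [lnc])
        wt, mut = extract_window(lnc, a, v.ref, v.alt)
        assert len(wt.sequence) == 401 and wt.snp_offset == 200
        assert sum(x != y for x, y in zip(wt.sequence, mut.sequence)) == 1

    def test_clipped_window_near_start(self):
        lnc = make_lnc(start=0, end=1000, seed=3)
        base = lnc.transcript_seq[10]
        v = make_variant(pos=10, ref=base.replace("U", "T"),
                         alt="G" if base != "G" else "C")
        (a,) = map_variants([v], [lnc])
        wt, _ = extract_window(lnc, a, v.ref, v.alt)
        assert len(wt.sequence) == 211 and wt.snp_offset == 10

    def test_reference_mismatch_raises(self):
        lnc = make_lnc(start=0, end=100, seq="A" * 100)
        v = make_variant(pos=50, ref="G", alt="C")
        (a,) = map_variants([v], [lnc])
        with pytest.raises(ReferenceMismatchError):
            extract_window(lnc, a, v.ref, v.alt)

    def test_minus_strand_alleles_complemented(self):
        # minus-strand transcript: genomic + strand 'G' appears as 'C' in RNA
        seq = "C" * 100
        lnc = make_lnc(start=0, end=100, strand="-", seq=seq)
        v = make_variant(pos=50, ref="G", alt="T")
        (a,) = map_variants([v], [lnc])
        wt, mut = extract_window(lnc, a, v.ref, v.alt)
        assert wt.sequence[wt.snp_offset] == "C"
        assert mut.sequence[mut.snp_offset] == "A"  # complement of T

    def test_intronic_not_scoreable(self):
        exons = (GenomicInterval("chr1", 0, 50, "+"),
                 GenomicInterval("chr1", 100, 150, "+"))
        lnc = make_lnc(start=0, end=150, exons=exons)
        v = make_variant(pos=75, ref="A", alt="G")
        (a,) = map_variants([v], [lnc])
        with pytest.raises(NotScoreableError):
            extract_window(lnc, a, v.ref, v.alt)


class TestEmpiricalPvalue:
    def test_formula_bounds(self, rng):
        window = FoldWindow(random_rna(rng, 80), snp_offset=40)
        n = 49
        p_top = empirical_pvalue(np.inf, window, n_background=n, seed=1, min_region=20)
        assert p_top == pytest.approx(1 / (n + 1))
        p_zero = empirical_pvalue(0.0, window, n_background=n, seed=1, min_region=20)
        assert p_zero == 1.0

    def test_monotone_in_observed_distance(self, rng):
        window = FoldWindow(random_rna(rng, 80), snp_offset=40)
        table = substitution_distance_table(window, min_region=20)
        ds = np.quantile(table.ravel(), [0.1, 0.5, 0.9])
        ps = [empirical_pvalue(float(d), window, n_background=49, seed=7,
                               min_region=20) for d in ds]
        assert ps == sorted(ps, reverse=True)

    def test_deterministic_given_seed(self, rng):
        window = FoldWindow(random_rna(rng, 60), snp_offset=30)
        args = dict(n_background=29, seed=123, min_region=20)
        assert empirical_pvalue(0.01, window, **args) == \
               empirical_pvalue(0.01, window, **args)

    def test_requires_minimum_background(self, rng):
        window = FoldWindow(random_rna(rng, 60), snp_offset=30)
        with pytest.raises(ValidationError):
            empirical_pvalue(0.1, window, n_background=5)


class TestScoreVariant:
    CFG = ScoreConfig(n_background=49, seed=5, min_region=50)

    def test_polya_context_not_significant(self):
        lnc = make_lnc(start=0, end=200, seq="A" * 200)
        v = make_variant(pos=100, ref="A", alt="C")
        (a,) = map_variants([v], [lnc])
        res = score_variant(lnc, a, v.ref, v.alt, self.CFG)
        assert res.d == 0.0 and res.p_value == 1.0 and not res.significant

    def test_planted_stem_break_beats_neutral(self):
        fix = generate_structure_fixture(SimulationConfig(seed=42))
        (a_dis,) = map_variants([fix.disruptive], [fix.lnc])
        (a_neu,) = map_variants([fix.neutral], [fix.lnc])
        res_dis = score_variant(fix.lnc, a_dis, fix.disruptive.ref,
                                fix.disruptive.alt, self.CFG)
        res_neu = score_variant(fix.lnc, a_neu, fix.neutral.ref,
                                fix.neutral.alt, self.CFG)
        assert res_dis.d > res_neu.d
        assert res_dis.significant

    def test_planted_power_over_seeds(self):
        hits = 0
        for seed in range(12):
            fix = generate_structure_fixture(SimulationConfig(seed=seed))
            (a,) = map_variants([fix.disruptive], [fix.lnc])
            res = score_variant(fix.lnc, a, fix.disruptive.ref,
                                fix.disruptive.alt, self.CFG)
            hits += res.significant
        assert hits >= 10  # >= ~90 percent power at small n

    def test_dot_plot_frame_triangles(self, rng):
        from lncsnp.structure_disruption import dot_plot_frame

        seq = random_rna(rng, 40)
        mut = "A" + seq[1:] if seq[0] != "A" else "G" + seq[1:]
        Pw = base_pair_probabilities(seq)
        Pm = base_pair_probabilities(mut)
        frame = dot_plot_frame(Pw, Pm).to_numpy()
        assert np.array_equal(np.triu(frame, 1), np.triu(Pw.P, 1))
        assert np.array_equal(np.tril(frame, -1), np.tril(Pm.P, -1))

    def test_result_is_deterministic(self):
        fix = generate_structure_fixture(SimulationConfig(seed=3))
        (a,) = map_variants([fix.disruptive], [fix.lnc])
        r1 = score_variant(fix.lnc, a, fix.disruptive.ref, fix.disruptive.alt, self.CFG)
        r2 = score_variant(fix.lnc, a, fix.disruptive.ref, fix.disruptive.alt, self.CFG)
        assert r1 == r2
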