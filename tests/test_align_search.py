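import math

import numpy as np
import pytest

import _oracles as oracle
from dupmode import align_search as als
from dupmode.genome_io import SeqRecord

DNA_SIMPLE = als.AlignParams(mode="local", substitution_matrix=None,
                             match=1.0, mismatch=-1.0,
                             gap_open=-2.0, gap_extend=-1.0)


class TestPairwiseAlign:
    def test_identical_local(self):
        r = als.pairwise_align("ACGT", "ACGT", DNA_SIMPLE)
        assert r.score == 4 and r.identity_pct == 100.0

    def test_unrelated_local_empty(self):
        r = als.pairwise_align("AAAA", "CCCC", DNA_SIMPLE)
        assert r.score == 0 and r.aligned_cols == 0

    def test_global_one_gap_column(self):
        # match +1 / mismatch -1 / single gap column -1
        params = als.AlignParams(mode="global", substitution_matrix=None,
                                 match=1.0, mismatch=-1.0,
                                 gap_open=-1.0, gap_extend=0.0)
        r = als.pairwise_align("ACGT", "AGT", params)
        assert r.score == 2
        assert r.gap_cols == 1 and r.matches == 3
        # exhaustive enumeration of all global alignments agrees
        assert oracle.brute_global_score(
            "ACGT", "AGT", protein=False, match=1, mismatch=-1,
            gap_open=-1, gap_extend=0) == 2

    def test_empty_sequence_error(self):
        with pytest.raises(als.AlignmentError):
            als.pairwise_align("", "ACGT", DNA_SIMPLE)

    def test_non_dna_under_dna_scoring_error(self):
        with pytest.raises(als.AlignmentError):
            als.pairwise_align("MKV", "MKV", DNA_SIMPLE)

    @pytest.mark.parametrize("protein", [True, False])
    @pytest.mark.parametrize("mode", ["global", "local"])
    def test_matches_brute_force_battery(self, rng, protein, mode):
        """Optimal scores equal the exhaustive alignment enumerator on
        random short pairs (the full battery runs in the acceptance suite)."""
        alphabet = "ARNDCQEGHK" if protein else "ACGT"
        maxlen = 4 if mode == "local" else 6
        params = als.AlignParams(
            mode=mode,
            substitution_matrix="BLOSUM62" if protein else None,
            match=1.0, mismatch=-2.0, gap_open=-3.0, gap_extend=-1.0)
        brute = (oracle.brute_local_score if mode == "local"
                 else oracle.brute_global_score)
        for _ in range(10):
            a = "".join(rng.choice(list(alphabet), int(rng.integers(1, maxlen + 1))))
            b = "".join(rng.choice(list(alphabet), int(rng.integers(1, maxlen + 1))))
            expect = brute(a, b, protein=protein, match=1.0, mismatch=-2.0,
                           gap_open=-3.0, gap_extend=-1.0)
            got = als.pairwise_align(a, b, params).score
            assert got == pytest.approx(expect), (a, b)


class TestIdentityAndEvalue:
    def test_gapless_480_columns_24_mismatches_is_95pct(self):
        r = als.AlignmentResult("q", "s", 0.0, 480, 456, 24, 0, 0.0)
        assert als.percent_identity(r) == pytest.approx(95.0)

    def test_identical_is_100(self):
        r = als.pairwise_align("MDEKV", "MDEKV")
        assert als.percent_identity(r) == 100.0

    def test_half_matches(self):
        r = als.AlignmentResult("q", "s", 0.0, 10, 5, 5, 0, 0.0)
        assert als.percent_identity(r) == 50.0

    def test_empty_alignment_error(self):
        r = als.AlignmentResult("q", "s", 0.0, 0, 0, 0, 0, 0.0)
        with pytest.raises(als.AlignmentError):
            als.percent_identity(r)

    def test_evalue_closed_forms(self):
        kp = als.KarlinParams(1.33, 0.621)
        s_unit = math.log(0.621 * 1000 * 1000) / 1.33
        assert als.evalue(s_unit, 1000, 1000, kp) == pytest.approx(1.0)
        e = als.evalue(20, 1000, 1000, kp)
        # K*m*n*exp(-lambda*S) = 0.621e6 * exp(-26.6) = 1.7412e-6
        assert e == pytest.approx(0.621e6 * math.exp(-26.6), rel=1e-12)
        assert e == pytest.approx(1.7412e-6, rel=1e-4)

    def test_evalue_scales_linearly_and_decreases_in_score(self):
        kp = als.KarlinParams(0.3176, 0.134)
        assert als.evalue(30, 100, 400, kp) == pytest.approx(
            2 * als.evalue(30, 100, 200, kp))
        assert als.evalue(31, 100, 200, kp) < als.evalue(30, 100, 200, kp)

    def test_bad_karlin_params_error(self):
        with pytest.raises(als.AlignmentError):
            als.KarlinParams(-1.0, 0.1)


class TestDistances:
    def test_p_distance_examples(self):
        assert als.p_distance("MDEK", "MDEK") == 0.0
        assert als.p_distance("MDEK", "MDQK") == pytest.approx(0.25)

    def test_p_distance_symmetry(self, rng):
        aas = list("ARNDCQEGHILKMFPSTWYV")
        for _ in range(10):
            a = "".join(rng.choice(aas, 30))
            b = "".join(rng.choice(aas, 30))
            assert als.p_distance(a, b) == pytest.approx(als.p_distance(b, a))

    def test_poisson_closed_forms(self):
        assert als.poisson_correct(0.0) == 0.0
        assert als.poisson_correct(0.5) == pytest.approx(math.log(2), abs=1e-12)
        assert als.poisson_correct(0.95) == pytest.approx(-math.log(0.05),
                                                          abs=1e-12)

    def test_poisson_dominates_p_and_increases(self):
        grid = np.linspace(0.01, 0.9, 20)
        d = [als.poisson_correct(p) for p in grid]
        assert all(dv >= pv for dv, pv in zip(d, grid))
        assert all(d[i] < d[i + 1] for i in range(len(d) - 1))

    def test_poisson_undefined_at_saturation(self):
        with pytest.raises(als.AlignmentError):
            als.poisson_correct(1.0)

    def test_triangle_inequality_low_divergence(self, rng):
        """Poisson-corrected p-distance behaves as a metric on mildly
        diverged proteins."""
        aas = list("ARNDCQEGHILKMFPSTWYV")
        base = "".join(rng.choice(aas, 120))
        seqs = []
        for _ in range(4):
            s = list(base)
            for pos in rng.choice(120, size=10, replace=False):
                s[pos] = str(rng.choice(aas))
            seqs.append("".join(s))
        recs = [SeqRecord(f"p{i}", s) for i, s in enumerate(seqs)]
        _, d = als.poisson_distance_matrix(recs)
        n = len(recs)
        for i in range(n):
            for j in range(n):
                for k in range(n):
                    assert d[i, j] <= d[i, k] + d[k, j] + 1e-9


def _mutate_protein(seq, n_subs, rng):
    aas = list("ARNDCQEGHILKMFPSTWYV")
    s = list(seq)
    for pos in rng.choice(len(s), size=n_subs, replace=False):
        choices = [a for a in aas if a != s[pos]]
        s[pos] = str(rng.choice(choices))
    return "".join(s)


class TestFindFamily:
    def test_query_self_hit_is_top(self, rng):
        aas = list("ARNDCQEGHILKMFPSTWYV")
        query = SeqRecord("q", "".join(rng.choice(aas, 200)))
        decoy = SeqRecord("d", "".join(rng.choice(aas, 200)))
        hits = als.find_family(query, [decoy, query])
        assert hits[0][0].id == "q"
        assert hits[0][1].identity_pct == 100.0

    def test_planted_homologs_fully_recovered(self, rng):
        """20 homologs at <= 0.2 substitutions/site pass the default E
        threshold; 20 random proteins do not (perfect recall & precision)."""
        aas = list("ARNDCQEGHILKMFPSTWYV")
        query = SeqRecord("q", "".join(rng.choice(aas, 250)))
        homologs = [SeqRecord(f"h{i}", _mutate_protein(query.seq,
                                                       int(rng.integers(10, 51)),
                                                       rng))
                    for i in range(20)]
        decoys = [SeqRecord(f"d{i}", "".join(rng.choice(aas, 250)))
                  for i in range(20)]
        hits = als.find_family(query, homologs + decoys)
        assert {rec.id for rec, _ in hits} == {h.id for h in homologs}

    def test_empty_hit_list(self, rng):
        aas = list("ARNDCQEGHILKMFPSTWYV")
        query = SeqRecord("q", "".join(rng.choice(aas, 100)))
        decoys = [SeqRecord(f"d{i}", "".join(rng.choice(aas, 100)))
                  for i in range(5)]
        assert als.find_family(query, decoys) == []

    def test_empty_proteome_error(self):
        with pytest.raises(als.AlignmentError):
            als.find_family(SeqRecord("q", "MKV"), [])
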