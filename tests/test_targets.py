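import itertools

import numpy as np
import pytest

from saltmir.sequences import revcomp
from saltmir.targets import (
    predict_cleavage,
    scan_transcriptome,
    score_site,
    tally_clones,
)

MIRNA = "TTGAGTGCAGCGTTGATGAAC"  # 21 nt


def oracle_ungapped_score(mirna, window):
    """Independent direct scorer for equal-length, ungapped sites: miRNA
    position k (1-based from 5') faces window base len-k."""
    assert len(mirna) == len(window)
    wc = {("A", "T"), ("T", "A"), ("G", "C"), ("C", "G")}
    wobble = {("G", "T"), ("T", "G")}
    total = 0.0
    n = len(mirna)
    for k in range(1, n + 1):
        pair = (mirna[k - 1], window[n - k])
        if pair in wc:
            pen = 0.0
        elif pair in wobble:
            pen = 0.5
        else:
            pen = 1.0
        if 2 <= k <= 13:
            pen *= 2
        total += pen
    return total


class TestScoreSite:
    def test_perfect_complement_scores_zero(self):
        score, aln, _ = score_site(MIRNA, revcomp(MIRNA))
        assert score == 0.0
        assert set(aln[1]) == {"|"}

    def test_wobble_position_weighting(self):
        # G:U at miRNA position 15 (outside seed): 0.5
        site = list(revcomp(MIRNA))
        n = len(MIRNA)
        pos = 15  # miRNA position; pairs site index n - pos
        assert MIRNA[pos - 1] == "G"
        site[n - pos] = "T"  # G:T wobble
        score, _, _ = score_site(MIRNA, "".join(site))
        assert score == 0.5
        # same wobble inside the seed (position 5): doubled to 1.0
        site = list(revcomp(MIRNA))
        pos = 5
        assert MIRNA[pos - 1] == "G"
        site[n - pos] = "T"  # G:T wobble
        score, _, _ = score_site(MIRNA, "".join(site))
        assert score == 1.0

    def test_all_single_mismatch_positions_match_oracle(self):
        perfect = revcomp(MIRNA)
        n = len(MIRNA)
        for i in range(n):
            for b in "ACGT":
                if b == perfect[i]:
                    continue
                window = perfect[:i] + b + perfect[i + 1:]
                score, _, _ = score_site(MIRNA, window)
                assert score == oracle_ungapped_score(MIRNA, window), (i, b)

    def test_gap_penalty(self):
        # extra target base between non-seed pairings costs 2
        perfect = revcomp(MIRNA)
        window = perfect[:2] + "A" + perfect[2:]  # bulge opposite positions ~19
        score, aln, _ = score_site(MIRNA, window)
        assert score == 2.0
        assert "-" in aln[0]

    def test_incompatible_window_length(self):
        with pytest.raises(ValueError):
            score_site(MIRNA, "ACGT")

    def test_random_equal_length_windows_match_oracle(self):
        # equal-length sites admit only the ungapped registration, so the
        # scan scorer must agree exactly with the independent direct scorer
        rng = np.random.default_rng(0)
        for _ in range(60):
            m = "".join(rng.choice(list("ACGT"), 21))
            w = "".join(rng.choice(list("ACGT"), 21))
            score, _, _ = score_site(m, w)
            assert score == oracle_ungapped_score(m, w)


class TestScan:
    def test_exact_site_found_once(self):
        t = "G" * 60 + revcomp(MIRNA) + "A" * 60
        hits = scan_transcriptome("mir", MIRNA, [("TX1", t)], cutoff=3.0)
        exact = [h for h in hits if h.expectation == 0.0]
        assert len(exact) == 1
        assert exact[0].t_start == 60

    def test_non_seed_mismatch_scores_one(self):
        site = list(revcomp(MIRNA))
        site[1] = {"A": "C", "C": "A", "G": "G", "T": "C"}[site[1]]
        t = "G" * 50 + "".join(site) + "A" * 50
        hits = scan_transcriptome("mir", MIRNA, [("TX1", t)], cutoff=3.0)
        assert hits and hits[0].expectation == 1.0

    def test_cutoff_contract_and_subset(self):
        rng = np.random.default_rng(1)
        t = "".join(rng.choice(list("ACGT"), 300)) + revcomp(MIRNA)
        hi = scan_transcriptome("mir", MIRNA, [("TX1", t)], cutoff=3.0)
        lo = scan_transcriptome("mir", MIRNA, [("TX1", t)], cutoff=1.0)
        assert all(h.expectation <= 3.0 for h in hi)
        keys_hi = {(h.transcript_id, h.t_start, h.t_end) for h in hi}
        keys_lo = {(h.transcript_id, h.t_start, h.t_end) for h in lo}
        assert keys_lo <= keys_hi

    def test_scan_equals_exhaustive_enumeration_small(self):
        """For short miRNAs, the scan must equal brute-force enumeration of
        every window and registration."""
        mirna = "ACGGTTCAATCG"  # 12 nt
        rng = np.random.default_rng(7)
        t = "".join(rng.choice(list("ACGT"), 80))
        t = t[:30] + revcomp(mirna) + t[30:]
        cutoff = 4.0
        hits = scan_transcriptome("m", mirna, [("TX1", t)], cutoff=cutoff)
        # brute force: every start x window length, direct score_site
        brute = []
        for w_len in (len(mirna) - 1, len(mirna), len(mirna) + 1):
            for s in range(len(t) - w_len + 1):
                score, _, _ = score_site(mirna, t[s:s + w_len])
                if score <= cutoff:
                    brute.append((score, s, s + w_len))
        brute.sort()
        # greedy non-overlapping selection, same ordering rule as the scan
        chosen, spans = [], []
        for score, s, e in brute:
            if all(e <= a or s >= b for a, b in spans):
                chosen.append((score, s, e))
                spans.append((s, e))
        assert sorted((h.expectation, h.t_start, h.t_end) for h in hits) == sorted(chosen)

    def test_empty_transcriptome_error(self):
        with pytest.raises(ValueError):
            scan_transcriptome("m", MIRNA, [])


class TestCleavage:
    def test_perfect_site_cleaves_between_ten_and_eleven(self):
        t = "C" * 100 + revcomp(MIRNA) + "C" * 100
        hits = scan_transcriptome("mir", MIRNA, [("TX1", t)], cutoff=0.0)
        h = hits[0]
        assert (h.t_start, h.t_end) == (100, 121)
        # base paired with miRNA position 10; the cut falls 5' of it,
        # i.e. between transcript positions 110 and 111
        assert predict_cleavage(h) == 111

    def test_gap_opposite_cleavage_site_yields_interval(self):
        perfect = revcomp(MIRNA)
        n = len(MIRNA)
        # insert a target bulge between partners of miRNA positions 10/11
        window = perfect[:n - 10] + "A" + perfect[n - 10:]
        score, _, cols = score_site(MIRNA, window)
        from saltmir.targets import _cleavage_from_columns
        cleavage = _cleavage_from_columns(cols, n, 0)
        assert isinstance(cleavage, tuple)


class TestCloneTally:
    def test_fractions(self):
        frac, hist = tally_clones([5, 5, 5, 5, 5, 5, 5, 1, 2, 3], predicted=5)
        assert frac == 0.7
        assert hist[5] == 7
        assert tally_clones([9, 9], 9)[0] == 1.0

    def test_empty_error(self):
        with pytest.raises(ValueError):
            tally_clones([], 0)

    def test_uniform_background_rate(self):
        rng = np.random.default_rng(42)
        positions = rng.integers(0, 50, size=1000).tolist()
        frac, _ = tally_clones(positions, predicted=25)
        assert frac == pytest.approx(0.02, abs=0.01)
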