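import numpy as np
import pytest

from chromoevol.annotate import (annotate_genome, build_consensus,
                                 check_domain_order, check_itr,
                                 cluster_families, detect_tsd,
                                 find_ltr_pairs, find_orfs, find_pbs,
                                 find_ppt, global_identity,
                                 reconstruct_pseudo_orf)
from chromoevol.genetics import revcomp
from chromoevol.io import write_gff3
from chromoevol.simulate import (SyntheticElementSpec, default_genome,
                                 mutate_ltr_pair, random_dna)


def _genome_with_repeat(ltr, interior_len, seed, divergence=0.0):
    rng = np.random.default_rng(seed)
    a, b = mutate_ltr_pair(ltr, divergence, rng)
    return (random_dna(2000, rng) + a + random_dna(interior_len, rng)
            + b + random_dna(2000, rng)), a, b


class TestLtrPairs:
    def test_identical_pair_found_exactly(self, rng):
        ltr = "TG" + random_dna(496, rng) + "CA"
        seq, _a, _b = _genome_with_repeat(ltr, 3000, seed=1)
        cands = find_ltr_pairs(seq)
        assert len(cands) == 1
        c = cands[0]
        assert c.identity == pytest.approx(100.0)
        assert c.ltr5 == (2000, 2500)
        assert c.ltr3 == (2000 + 500 + 3000, 2000 + 1000 + 3000)

    def test_diverged_pair_identity_close_to_truth(self, rng):
        ltr = "TG" + random_dna(396, rng) + "CA"
        seq, a, b = _genome_with_repeat(ltr, 2500, seed=2, divergence=0.03)
        true_ident = 100.0 * sum(x == y for x, y in zip(a, b)) / len(a)
        cands = find_ltr_pairs(seq)
        assert len(cands) == 1
        assert abs(cands[0].identity - true_ident) <= 1.0

    def test_random_background_is_clean(self):
        hits = 0
        for seed in range(10):
            bg = random_dna(10000, np.random.default_rng(seed + 777))
            hits += bool(find_ltr_pairs(bg))
        assert hits == 0


class TestItr:
    @pytest.mark.parametrize("seq,expected", [
        ("TG" + "A" * 40 + "CA", True),
        ("TA" + "A" * 40 + "CA", False),
        ("TG" + "A" * 40 + "CC", False),
    ])
    def test_terminal_repeat_rule(self, seq, expected):
        assert check_itr(seq) is expected

    def test_too_short_rejected(self):
        with pytest.raises(ValueError):
            check_itr("TGC")


class TestTsd:
    @pytest.mark.parametrize("tsd", ["CCTAT", "GTTTCT", "ACGT"])
    def test_planted_tsd_detected(self, tsd, rng):
        elem = "TG" + random_dna(200, rng) + "CA"
        seq = random_dna(50, rng) + tsd + elem + tsd + random_dna(50, rng)
        start = 50 + len(tsd)
        assert detect_tsd(seq, (start, start + len(elem))) == tsd

    def test_unrelated_flanks_absent(self, rng):
        seq = "A" * 20 + "TGCA" * 30 + "C" * 20
        assert detect_tsd(seq, (20, 20 + 120)) is None

    def test_insufficient_flank_rejected(self):
        with pytest.raises(ValueError):
            detect_tsd("ACGTACGT", (2, 6))


class TestPbs:
    trna = "TCCATCGGGAGATGGACCA"

    def _seq_with_pbs(self, length, spacer, rng):
        pbs = revcomp(self.trna[-length:])
        return random_dna(300, rng) + random_dna(spacer, rng) + pbs \
            + "T" + random_dna(60, rng)

    def test_13bp_with_one_spacer(self, rng):
        seq = self._seq_with_pbs(13, 1, rng)
        hit = find_pbs(seq, 300, {"tRNA-Met": self.trna})
        assert hit is not None
        assert (hit.length, hit.spacer) == (13, 1)
        assert (hit.start, hit.end) == (301, 314)

    def test_12bp_with_two_spacers(self, rng):
        seq = self._seq_with_pbs(12, 2, rng)
        hit = find_pbs(seq, 300, {"tRNA-Met": self.trna})
        assert hit is not None
        assert (hit.length, hit.spacer) == (12, 2)

    def test_below_min_len_absent(self, rng):
        seq = self._seq_with_pbs(10, 0, rng)
        assert find_pbs(seq, 300, {"tRNA-Met": self.trna}) is None

    def test_empty_library_rejected(self):
        with pytest.raises(ValueError):
            find_pbs("ACGT" * 100, 10, {})


class TestPpt:
    def test_fourteen_purine_tract(self, rng):
        seq = random_dna(100, rng) + "C" + "AGAGAGAGAGAGAG" + "TG" \
            + random_dna(40, rng)
        hit = find_ppt(seq, 115)
        assert hit is not None
        assert hit.length == 14
        assert (hit.start, hit.end) == (101, 115)

    def test_boundary_run_of_twelve(self):
        seq = "C" * 50 + "A" * 12 + "TG" + "C" * 20
        hit = find_ppt(seq, 62)
        assert hit is not None and hit.length == 12

    def test_alternating_pyrimidines_absent(self):
        seq = "ACAC" * 40
        assert find_ppt(seq, 120) is None


class TestOrfs:
    def test_simple_orf_length(self):
        seq = "ATG" + "AAA" * 100 + "TAA"
        orfs = find_orfs(seq)
        assert len(orfs) == 1
        o = orfs[0]
        assert (o.start, o.end, o.frame) == (0, 306, 1)

    def test_no_start_codon(self):
        assert find_orfs("AAA" * 200) == []

    def test_reverse_strand_orf(self):
        fwd = "ATG" + "AAA" * 100 + "TAA"
        seq = revcomp(fwd)
        orfs = find_orfs(seq)
        assert any(o.frame < 0 and o.end - o.start == 306 for o in orfs)

    def test_pseudo_orf_stop_marking(self):
        pep = "ATG" + "AAA" * 30 + "TAA" + "AAA" * 30 + "TGA" \
            + "AAA" * 30 + "TAG" + "AAA" * 30 + "TAA"
        translation, stops = reconstruct_pseudo_orf(pep, 0)
        assert len(stops) == 3
        assert translation.count("*") == 4  # three internal + terminal

    def test_clean_orf_no_marks(self):
        _t, stops = reconstruct_pseudo_orf("ATG" + "AAA" * 10 + "TAA", 0)
        assert stops == []

    def test_out_of_frame_rejected(self):
        with pytest.raises(ValueError, match="frame"):
            reconstruct_pseudo_orf("ATGAAAT", 0)
        with pytest.raises(ValueError, match="frame"):
            reconstruct_pseudo_orf("ATGAAA", 5)


class TestDomainOrder:
    @pytest.mark.parametrize("order,ok", [
        (["CCHC", "PR", "RT", "RNH", "INT", "CHD"], True),
        (["PR", "RT", "INT"], True),
        (["RT", "PR"], False),
        (["CCHC", "CCHC"], False),
        (["PR", "XX"], False),
    ])
    def test_subsequence_rule(self, order, ok):
        assert check_domain_order(order)[0] is ok


class TestFamilies:
    def _copies(self, master, divergences, rng):
        out = {}
        for i, d in enumerate(divergences):
            _m, c = mutate_ltr_pair(master, d, rng)
            out[f"c{i}"] = c
        return out

    def test_close_copies_one_family(self, rng):
        master = "TG" + random_dna(400, rng) + "CA"
        fams = cluster_families(self._copies(master, [0.02, 0.03], rng))
        assert len(fams) == 1 and len(fams[0].members) == 2
        assert fams[0].mean_identity > 80

    def test_distant_copies_two_families(self, rng):
        master = "TG" + random_dna(400, rng) + "CA"
        elems = self._copies(master, [0.0, 0.30], rng)
        fams = cluster_families(elems)
        assert len(fams) == 2

    def test_radiation_recovers_truth(self, rng):
        # two families: within-family ~90 percent, between ~60 percent
        m1 = "TG" + random_dna(400, rng) + "CA"
        _x, m2 = mutate_ltr_pair(m1, 0.45, rng)
        elems = {}
        for name, master in (("a", m1), ("b", m2)):
            for i in range(3):
                _m, c = mutate_ltr_pair(master, 0.05, rng)
                elems[f"{name}{i}"] = c
        fams = cluster_families(elems)
        groups = sorted(tuple(sorted(f.members)) for f in fams)
        assert groups == [("a0", "a1", "a2"), ("b0", "b1", "b2")]


class TestConsensus:
    def test_majority_base(self):
        assert build_consensus(["ACGT", "ACGA", "ACGT"]) == "ACGT"

    def test_identity_on_identical(self):
        assert build_consensus(["ACGT"] * 3) == "ACGT"

    def test_tie_goes_to_first_copy(self):
        assert build_consensus(["AT", "GT"]) == "AT"

    def test_gap_majority(self):
        # gap wins only when gaps exceed half the column
        assert build_consensus(["A-", "--", "-A"]) == "--"
        assert build_consensus(["AA", "A-", "AA"]) == "AA"

    def test_master_recovery(self, rng):
        master = random_dna(500, rng)
        copies = [mutate_ltr_pair("TG" + master + "CA", 0.03, rng)[1][2:-2]
                  for _ in range(10)]
        cons = build_consensus(copies)
        ident = sum(a == b for a, b in zip(cons, master)) / len(master)
        assert ident >= 0.99


class TestIdentityAndDeterminism:
    def test_identity_symmetric_and_bounded(self, rng):
        a = random_dna(200, rng)
        _x, b = mutate_ltr_pair("TG" + a + "CA", 0.1, rng)
        b = b[2:-2]
        assert global_identity(a, b) == pytest.approx(
            global_identity(b, a))
        assert global_identity(a, a) == 100.0
        assert global_identity(a, b) < 100.0

    def test_annotation_deterministic_gff_bytes(self, tmp_path):
        genome = default_genome(seed=13)
        files = []
        for i in range(2):
            anns = annotate_genome(genome.seq, "toy")
            p = tmp_path / f"run{i}.gff3"
            write_gff3(anns, p)
            files.append(p.read_bytes())
        assert files[0] == files[1]
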