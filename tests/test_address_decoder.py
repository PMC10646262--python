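"""Address scanning, segmentation, consensus, full decode, random access."""

import numpy as np
import pytest

from splintstore import workflows
from splintstore.address_decoder import (
    AddressHit,
    classify_read,
    consensus,
    decode_pool,
    group_and_consensus,
    orient_read,
    random_access,
    scan_addresses,
    segment_payloads,
)
from splintstore.read_sim import ERROR_FREE, ErrorProfile, simulate_reads
from splintstore.seqcore import (
    AddressBook,
    AddressSequence,
    DnaString,
    hamming,
    random_address_book,
    revcomp,
)


def brute_force_scan(read, book, min_match=15, max_match=20):
    """Independent oracle: exhaustive sliding-window comparison at every
    offset for every address, then the same (longer, fewer-mismatch,
    leftmost) greedy overlap resolution the contract declares."""
    read = str(read)
    n = len(read)
    cands = []
    for addr in book:
        for i in range(n):
            allowed = i >= 20 or (addr.role == "forward" and i <= 5)
            if not allowed and not (i == 0):
                continue
            window = read[i : i + max_match]
            if len(window) == max_match and allowed:
                mm = sum(1 for x, y in zip(window, addr.seq) if x != y)
                if mm <= max_match - min_match:
                    cands.append((addr, i, i + max_match, max_match, mm))
            elif len(window) < max_match and allowed and len(window) >= min_match:
                # right-truncated exact prefix of the address
                if window == addr.seq[: len(window)]:
                    cands.append((addr, i, n, len(window), 0))
        # left-truncated exact suffix of the address at offset 0
        for k in range(max_match - 1, min_match - 1, -1):
            if n >= k and read[:k] == addr.seq[max_match - k :]:
                cands.append((addr, 0, k, k, 0))
                break
    chosen = []
    for cand in sorted(cands, key=lambda c: (-c[3], c[4], c[1])):
        if all(cand[2] <= c[1] or cand[1] >= c[2] for c in chosen):
            chosen.append(cand)
    return sorted(
        (
            AddressHit(a.id, a.role, s, e, ml, mm)
            for a, s, e, ml, mm in chosen
        ),
        key=lambda h: h.start,
    )


@pytest.fixture(scope="module")
def book():
    return random_address_book(
        ["forward", "internal", "reverse", "forward", "reverse"], seed=31
    )


def _payload(rng, n):
    return "".join(rng.choice(list("ACGT"), n))


class TestOrientRead:
    def test_flipped_read_is_restored(self, book):
        rng = np.random.default_rng(1)
        f, m, r = book.by_id("addrF1"), book.by_id("addrM1"), book.by_id("addrR1")
        frag = f.seq + _payload(rng, 30) + r.seq
        oriented, flag = orient_read(revcomp(frag), book)
        assert flag == "flipped" and oriented == frag

    def test_forward_read_untouched(self, book):
        rng = np.random.default_rng(2)
        frag = book.by_id("addrF1").seq + _payload(rng, 30) + book.by_id("addrR1").seq
        oriented, flag = orient_read(frag, book)
        assert flag == "forward" and oriented == frag

    def test_addressless_read_flagged_unknown(self, book):
        read = "ACGT" * 15
        oriented, flag = orient_read(read, book)
        assert flag == "unknown" and oriented == read


class TestScanAddresses:
    def test_three_hit_construction(self, book):
        rng = np.random.default_rng(3)
        f, m, r = book.by_id("addrF1"), book.by_id("addrM1"), book.by_id("addrR1")
        p1, p2 = _payload(rng, 25), _payload(rng, 35)
        read = f.seq + p1 + m.seq + p2 + r.seq
        hits = scan_addresses(read, book)
        assert [h.address_id for h in hits] == ["addrF1", "addrM1", "addrR1"]
        assert [(h.start, h.end) for h in hits] == [
            (0, 20),
            (45, 65),
            (100, 120),
        ]
        assert all(h.mismatches == 0 for h in hits)

    def test_partial_match_survives_substitutions(self, book):
        """Corrupt each position of an interior address in turn: with <= 5
        mismatches of its 20-mer window the address is still found."""
        rng = np.random.default_rng(4)
        f, m, r = book.by_id("addrF1"), book.by_id("addrM1"), book.by_id("addrR1")
        p1, p2 = _payload(rng, 25), _payload(rng, 35)
        for pos in range(20):
            maddr = list(str(m.seq))
            maddr[pos] = {"A": "C", "C": "G", "G": "T", "T": "A"}[maddr[pos]]
            read = f.seq + p1 + "".join(maddr) + p2 + r.seq
            hits = scan_addresses(read, book)
            ids = [h.address_id for h in hits]
            assert ids == ["addrF1", "addrM1", "addrR1"]
            assert hits[1].mismatches == 1

    def test_truncated_terminal_address_matches_at_least_15(self, book):
        rng = np.random.default_rng(5)
        f, r = book.by_id("addrF1"), book.by_id("addrR1")
        read = f.seq + _payload(rng, 30) + r.seq[:17]  # last 3 nt lost
        hits = scan_addresses(read, book)
        assert hits[-1].address_id == "addrR1"
        assert hits[-1].matched_length == 17 and hits[-1].mismatches == 0

    def test_matches_brute_force_oracle_on_500_seeded_instances(self, book):
        """Oracle equivalence on short synthetic reads, including reads made
        of address fragments, noise and partial overlaps."""
        rng = np.random.default_rng(6)
        entries = [e.seq for e in book]
        for _ in range(500):
            n = int(rng.integers(20, 61))
            kind = rng.integers(3)
            if kind == 0:
                read = _payload(rng, n)
            elif kind == 1:
                a = str(entries[rng.integers(len(entries))])
                start = int(rng.integers(0, 6))
                read = (a + _payload(rng, n))[: n + 10]
                read = _payload(rng, start) + read[: n - start]
            else:
                a = str(entries[rng.integers(len(entries))])
                b = str(entries[rng.integers(len(entries))])
                read = (a + _payload(rng, int(rng.integers(0, 8))) + b)[:n]
            assert scan_addresses(read, book) == brute_force_scan(read, book)


class TestSegmentPayloads:
    def test_three_hits_two_payloads(self, book):
        rng = np.random.default_rng(7)
        f, m, r = book.by_id("addrF1"), book.by_id("addrM1"), book.by_id("addrR1")
        p1, p2 = _payload(rng, 25), _payload(rng, 35)
        read = f.seq + p1 + m.seq + p2 + r.seq
        sr = segment_payloads(read, scan_addresses(read, book), "r1")
        assert sr.payloads == [(20, 45), (65, 100)]
        assert sr.payload_seq(0) == p1 and sr.payload_seq(1) == p2
        assert sr.terminal  # ends on a reverse-role address

    def test_adjacent_hits_give_flagged_empty_payload(self, book):
        f, r = book.by_id("addrF1"), book.by_id("addrR1")
        read = f.seq + r.seq
        sr = segment_payloads(read, scan_addresses(read, book), "r1")
        assert sr.payloads == [(20, 20)] and sr.payload_seq(0) == ""

    def test_fewer_than_two_hits_unalignable(self, book):
        read = book.by_id("addrF1").seq + "ACGT" * 5
        assert segment_payloads(read, scan_addresses(read, book), "r1") is None


class TestConsensus:
    def test_identical_members(self):
        assert consensus(["ACGT"] * 3) == "ACGT"

    def test_majority_vote(self):
        assert consensus(["ACGT", "ACGT", "ACTT"]) == "ACGT"

    def test_tie_breaks_lexicographically(self):
        assert consensus(["ACGT", "AAGT"]) == "AAGT"  # A < C at position 2

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            consensus(["ACGT", "ACG"])

    def test_modal_length_cohort_selected(self, book):
        rng = np.random.default_rng(8)
        f, r = book.by_id("addrF1"), book.by_id("addrR1")
        p = _payload(rng, 30)
        reads = []
        for i in range(5):
            payload = p if i < 3 else p[:-1]  # two 1-nt-deleted minority reads
            read = f.seq + payload + r.seq
            reads.append(segment_payloads(read, scan_addresses(read, book), f"r{i}"))
        groups = group_and_consensus(reads)
        assert groups[("addrF1", "addrR1")] == [p]


class TestClassifyRead:
    @pytest.mark.parametrize(
        "read_len,ref_len,identical,expected",
        [
            (200, 200, True, "perfect"),
            (200, 200, False, "substitution"),
            (199, 200, False, "deletion_1_2"),
            (198, 200, False, "deletion_1_2"),
            (197, 200, False, "other"),
            (201, 200, False, "insertion"),
        ],
    )
    def test_length_taxonomy(self, read_len, ref_len, identical, expected):
        assert classify_read(read_len, ref_len, identical) == expected


class TestDecodePool:
    def test_end_to_end_serial_sentence(self, sentence_build, sentence_products):
        rs = simulate_reads(sentence_products, depth=20, profile=ERROR_FREE)
        report = decode_pool(rs, sentence_build.book, codec="text")
        assert list(report.recovered_texts().values()) == ["DNAdata Stores Apple"]
        assert report.aligned_reads == report.perfect_reads == 20
        assert report.class_fractions["perfect"] == 1.0

    def test_parallel_pool_three_species(self):
        pb = workflows.build_parallel_pool(
            ["DNAdata", "Stores"], ["Apple", "Orange", "Grape"], seed=3
        )
        prod = workflows.products_only(pb.pool, min_length=180)
        rs = simulate_reads(prod, depth=15, profile=ERROR_FREE)
        report = decode_pool(rs, pb.book, codec="text")
        assert sorted(report.recovered_texts().values()) == [
            "DNAdata Stores Apple",
            "DNAdata Stores Grape",
            "DNAdata Stores Orange",
        ]

    def test_decoded_order_follows_programmed_order(self):
        """Permuting the assembly program permutes the decoded sentence."""
        words = ["DNAdata", "Stores", "Apple", "Orange"]
        for order, expect in [
            ([0, 1, 2, 3], "DNAdata Stores Apple Orange"),
            ([0, 3, 2, 1], "DNAdata Orange Apple Stores"),
        ]:
            sb = workflows.build_sentence_pool(words, seed=5, order=order)
            pool = workflows.products_only(sb.pool, min_length=250)
            rs = simulate_reads(pool, depth=10, profile=ERROR_FREE)
            report = decode_pool(rs, sb.book, codec="text")
            assert list(report.recovered_texts().values()) == [expect]

    def test_movie_pool_recovers_all_frames(self, movie_build, movie_products):
        rs = simulate_reads(movie_products, depth=10, profile=ERROR_FREE)
        report = decode_pool(
            rs, movie_build.book, codec="pixel", codon_table=movie_build.table
        )
        recovered = [s.frame for s in report.species if s.frame is not None]
        for frame in movie_build.frames:
            assert any(r.complete and r.frame == frame for r in recovered)

    def test_filter_monotonicity_on_noisy_reads(self, sentence_build, sentence_products):
        """aligned >= length-match >= perfect on every read set."""
        for seed in (1, 2, 3):
            rs = simulate_reads(
                sentence_products,
                depth=60,
                profile=ErrorProfile(0.005, 0.002, 0.002, seed=seed),
            )
            report = decode_pool(rs, sentence_build.book, codec="text", min_reads=3)
            assert (
                report.aligned_reads
                >= report.length_match_reads
                >= report.perfect_reads
            )
            assert report.aligned_reads <= report.total_reads

    def test_ecc_recovery_monotone_on_corrupted_reads(
        self, sentence_build, sentence_products
    ):
        rs = simulate_reads(
            sentence_products, depth=80, profile=ErrorProfile(0.01, 0, 0, seed=9)
        )
        report = decode_pool(rs, sentence_build.book, codec="text", min_reads=3)
        assert report.ecc_recovered_words >= report.no_ecc_recovered_words
        assert report.ecc_recovered_words > report.no_ecc_recovered_words

    def test_noisy_consensus_still_exact(self, sentence_build, sentence_products):
        """Depth-100 consensus at 1% substitution recovers the truth."""
        rs = simulate_reads(
            sentence_products, depth=100, profile=ErrorProfile(0.01, 0, 0, seed=10)
        )
        report = decode_pool(rs, sentence_build.book, codec="text", min_reads=5)
        assert list(report.recovered_texts().values()) == ["DNAdata Stores Apple"]
        product = sentence_products.species()[0]
        main = max(report.species, key=lambda s: s.n_reads)
        assert main.consensus_seq == product.seq

    def test_empty_readset_empty_report(self, sentence_build):
        from splintstore.read_sim import ReadSet
        import pandas as pd

        report = decode_pool(
            ReadSet([], pd.DataFrame(columns=["read_id"])), sentence_build.book
        )
        assert report.total_reads == 0 and report.species == []

    def test_decoder_classifier_agrees_with_truth_ledger_on_sparse_errors(
        self, sentence_build, sentence_products
    ):
        """Oracle equivalence: on reads with <= 1 edit the decoder's
        reference-based classes match the simulation ledger >= 99%."""
        rs = simulate_reads(
            sentence_products,
            depth=300,
            profile=ErrorProfile(0.002, 0.001, 0.001, seed=11),
        )
        report = decode_pool(rs, sentence_build.book, codec="text", min_reads=5)
        ref = sentence_products.species()[0].seq
        truth = rs.truth
        sparse = truth[(truth.n_sub + truth.n_del + truth.n_ins) <= 1]
        reads_by_id = {r.id: r for r in rs.reads}
        agree = total = 0
        for _, row in sparse.iterrows():
            read = reads_by_id[row.read_id]
            identical = row.n_sub == row.n_del == row.n_ins == 0
            ledger_cls = classify_read(len(read.seq), len(ref), identical)
            decoder_cls = classify_read(
                len(read.seq), len(ref), read.seq in (ref, revcomp(ref))
            )
            total += 1
            agree += ledger_cls == decoder_cls
        assert total > 0 and agree / total >= 0.99


@pytest.fixture(scope="module")
def parallel():
    pb = workflows.build_parallel_pool(
        ["DNAdata", "Stores"], ["Apple", "Orange", "Grape"], seed=3
    )
    return pb, workflows.products_only(pb.pool, min_length=180)


class TestRandomAccess:

    def test_primer_pair_selects_single_species(self, parallel):
        pb, prod = parallel
        sel = random_access(prod, pb.book.by_id("addrF1"), pb.book.by_id("addrR4"))
        assert [f.id for f in sel.species()] == ["word:DNAdata+word:Stores+word:Orange"]

    def test_shared_forward_unique_reverse_isolates_each(self, parallel):
        pb, prod = parallel
        fwd = pb.book.by_id("addrF1")
        for rev_id in ("addrR3", "addrR4", "addrR5"):
            sel = random_access(prod, fwd, pb.book.by_id(rev_id))
            assert len(sel) == 1

    def test_selected_subset_decodes_alone(self, parallel):
        pb, prod = parallel
        sel = random_access(prod, pb.book.by_id("addrF1"), pb.book.by_id("addrR5"))
        rs = simulate_reads(sel, depth=10, profile=ERROR_FREE)
        report = decode_pool(rs, pb.book, codec="text")
        assert list(report.recovered_texts().values()) == ["DNAdata Stores Grape"]

    def test_wrong_order_primers_select_nothing(self, parallel):
        pb, prod = parallel
        sel = random_access(prod, pb.book.by_id("addrF3"), pb.book.by_id("addrR1"))
        assert len(sel) == 0

    def test_readset_selection_keeps_both_orientations(self, parallel):
        pb, prod = parallel
        rs = simulate_reads(prod, depth=30, profile=ERROR_FREE)
        sel = random_access(rs, pb.book.by_id("addrF1"), pb.book.by_id("addrR4"))
        kept_species = set(sel.truth["species_id"])
        assert kept_species == {"word:DNAdata+word:Stores+word:Orange"}
        assert sel.truth["flipped"].nunique() == 2  # both strands retained
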