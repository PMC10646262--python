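"""Address-primer scanning decoder and in-silico PCR random access.

Payload sizes and positions in a read are unknown a priori; they are
recovered by scanning for the fixed 20-nt address sequences that flank and
separate payloads:

1. orient: a read from the opposite strand is recognised by its address
   content and flipped back, roughly doubling usable coverage;
2. scan: forward-role addresses are anchored within the first 20 bases;
   every address is additionally sought from base 21 onward.  A hit is a
   full 20-nt window with at most 5 mismatches, or an exact >= 15-nt
   contiguous match where the address is truncated at a read end;
3. segment: payloads are the spans strictly between consecutive hits;
4. group + consensus: reads with the same address path are grouped per
   payload ordinal; the modal-length cohort yields a per-position
   plurality consensus (minority-length reads are excluded from consensus
   but still counted in the error classes — this is the "payload length
   match" filter);
5. codec decode: Reed-Solomon-protected ASCII words, or indexed pixel
   codon payloads, reconstructed from the consensus.

Random access mimics PCR selection: a species is retained when it contains
the forward primer followed by the reverse complement of the reverse primer.
"""

from __future__ import annotations

import dataclasses
from collections import Counter, defaultdict

import numpy as np
import pandas as pd

from . import pixel_codec, text_codec
from .assembly_sim import Pool
from .read_sim import CLASSES, ReadSet, classify_by_length
from .seqcore import AddressBook, AddressSequence, DnaString, hamming, revcomp

FULL_MATCH = 20
MIN_MATCH = 15
MAX_FULL_MISMATCHES = FULL_MATCH - MIN_MATCH  # 5
FORWARD_ANCHOR_MAX_OFFSET = 5  # a 15-mer suffix still ends by base 20
INTERIOR_START = 20  # interior scan begins at the 21st base (0-based 20)


@dataclasses.dataclass(frozen=True)
class AddressHit:
    address_id: str
    role: str
    start: int  # 0-based half-open read coordinates
    end: int
    matched_length: int
    mismatches: int

    def __post_init__(self) -> None:
        assert self.end - self.start == self.matched_length


@dataclasses.dataclass
class SegmentedRead:
    read_id: str
    hits: list[AddressHit]
    payloads: list[tuple[int, int]]  # spans strictly between consecutive hits
    terminal: bool  # last hit has reverse role
    flipped: bool = False
    seq: str = ""

    @property
    def address_path(self) -> tuple[str, ...]:
        return tuple(h.address_id for h in self.hits)

    def payload_seq(self, k: int) -> str:
        s, e = self.payloads[k]
        return self.seq[s:e]


def orient_read(
    read: str, book: AddressBook
) -> tuple[DnaString, str]:
    """Return (oriented read, flag) with flag in {'forward','flipped','unknown'}.

    Both the read and its reverse complement are scanned; the orientation
    with more total matched address bases (fewer mismatches on ties) wins.
    """
    fwd = DnaString(read)
    rev = revcomp(fwd)
    hits_f = scan_addresses(fwd, book)
    hits_r = scan_addresses(rev, book)

    def score(hits: list[AddressHit]) -> tuple[int, int]:
        return (
            sum(h.matched_length for h in hits),
            -sum(h.mismatches for h in hits),
        )

    sf, sr = score(hits_f), score(hits_r)
    if sf == sr == (0, 0):
        return fwd, "unknown"
    if sr > sf:
        return rev, "flipped"
    return fwd, "forward"


def scan_addresses(
    read: str,
    book: AddressBook,
    min_match: int = MIN_MATCH,
    max_match: int = FULL_MATCH,
) -> list[AddressHit]:
    """Locate address sequences in an oriented read, left to right.

    Overlapping candidates are resolved greedily by (longer match, fewer
    mismatches, leftmost) priority.
    """
    if min_match > max_match or max_match != FULL_MATCH:
        raise ValueError("require min_match <= max_match == 20")
    read = str(read).upper()
    n = len(read)
    max_mm = max_match - min_match
    candidates: list[AddressHit] = []
    for addr in book:
        offsets = range(INTERIOR_START, max(n - 1, INTERIOR_START))
        if addr.role == "forward":
            offsets = list(range(0, FORWARD_ANCHOR_MAX_OFFSET + 1)) + list(offsets)
        for i in offsets:
            if i >= n:
                break
            window = read[i : i + FULL_MATCH]
            if len(window) == FULL_MATCH:
                mm = hamming(window, addr.seq)
                if mm <= max_mm:
                    candidates.append(
                        AddressHit(addr.id, addr.role, i, i + FULL_MATCH, FULL_MATCH, mm)
                    )
            else:
                # right-truncated: exact match of the address prefix
                k = len(window)
                if k >= min_match and window == addr.seq[:k]:
                    candidates.append(
                        AddressHit(addr.id, addr.role, i, i + k, k, 0)
                    )
        # left-truncated address at the very start of the read
        for k in range(max_match - 1, min_match - 1, -1):
            if n >= k and read[:k] == addr.seq[FULL_MATCH - k :]:
                candidates.append(AddressHit(addr.id, addr.role, 0, k, k, 0))
                break
    chosen: list[AddressHit] = []
    for hit in sorted(
        candidates, key=lambda h: (-h.matched_length, h.mismatches, h.start)
    ):
        if all(hit.end <= c.start or hit.start >= c.end for c in chosen):
            chosen.append(hit)
    return sorted(chosen, key=lambda h: h.start)


def segment_payloads(
    read: str, hits: list[AddressHit], read_id: str = "", flipped: bool = False
) -> SegmentedRead | None:
    """Payload spans strictly between consecutive hits; None if < 2 hits."""
    if len(hits) < 2:
        return None
    payloads = [
        (hits[k].end, hits[k + 1].start) for k in range(len(hits) - 1)
    ]
    return SegmentedRead(
        read_id=read_id,
        hits=hits,
        payloads=payloads,
        terminal=(hits[-1].role == "reverse"),
        flipped=flipped,
        seq=str(read),
    )


def consensus(seqs: list[str]) -> DnaString:
    """Per-position plurality base over same-length sequences.

    Ties break to the lexicographically smallest base, deterministically.
    """
    if not seqs:
        raise ValueError("empty consensus group")
    length = len(seqs[0])
    if any(len(s) != length for s in seqs):
        raise ValueError("consensus requires same-length members")
    out = []
    for i in range(length):
        counts = Counter(s[i] for s in seqs)
        best = max(sorted(counts), key=lambda b: counts[b])
        out.append(best)
    return DnaString("".join(out))


def group_and_consensus(
    segmented: list[SegmentedRead],
) -> dict[tuple[str, ...], list[DnaString]]:
    """Consensus payloads per address path.

    Reads sharing an address path form one cohort per payload ordinal; each
    cohort is restricted to its modal payload length (smallest length on
    ties) before the plurality vote.
    """
    by_path: dict[tuple[str, ...], list[SegmentedRead]] = defaultdict(list)
    for sr in segmented:
        by_path[sr.address_path].append(sr)
    out: dict[tuple[str, ...], list[DnaString]] = {}
    for path, cohort in by_path.items():
        n_payloads = len(path) - 1
        payloads = []
        for k in range(n_payloads):
            seqs = [sr.payload_seq(k) for sr in cohort]
            modal = _modal_length(seqs)
            payloads.append(consensus([s for s in seqs if len(s) == modal]))
        out[path] = payloads
    return out


def _modal_length(seqs: list[str]) -> int:
    counts = Counter(len(s) for s in seqs)
    return max(sorted(counts), key=lambda length: counts[length])


def classify_read(read_len: int, ref_len: int, identical: bool) -> str:
    return classify_by_length(read_len, ref_len, identical)


# ---------------------------------------------------------------------------
# Full pipeline
# ---------------------------------------------------------------------------


@dataclasses.dataclass
class SpeciesResult:
    address_path: tuple[str, ...]
    n_reads: int
    consensus_payloads: list[DnaString]
    consensus_seq: DnaString
    text: str | None = None
    words: list[text_codec.WordDecodeResult] = dataclasses.field(default_factory=list)
    frame: "pixel_codec.FrameDecodeResult | None" = None


@dataclasses.dataclass
class DecodeReport:
    """Per-pool decoding statistics and recovered data.

    Count monotonicity holds by construction:
    aligned >= length_match >= perfect.
    """

    total_reads: int = 0
    oriented_flipped: int = 0
    oriented_unknown: int = 0
    aligned_reads: int = 0
    length_match_reads: int = 0
    perfect_reads: int = 0
    ecc_recovered_words: int = 0
    no_ecc_recovered_words: int = 0
    class_fractions: dict = dataclasses.field(default_factory=dict)
    length_histogram: dict = dataclasses.field(default_factory=dict)
    species: list[SpeciesResult] = dataclasses.field(default_factory=list)
    warnings: list[str] = dataclasses.field(default_factory=list)

    def recovered_texts(self) -> dict[str, str]:
        return {
            "|".join(s.address_path): s.text
            for s in self.species
            if s.text is not None
        }

    def to_dict(self) -> dict:
        return {
            "total_reads": self.total_reads,
            "oriented_flipped": self.oriented_flipped,
            "oriented_unknown": self.oriented_unknown,
            "aligned_reads": self.aligned_reads,
            "length_match_reads": self.length_match_reads,
            "perfect_reads": self.perfect_reads,
            "ecc_recovered_words": self.ecc_recovered_words,
            "no_ecc_recovered_words": self.no_ecc_recovered_words,
            "class_fractions": self.class_fractions,
            "length_histogram": {int(k): int(v) for k, v in self.length_histogram.items()},
            "species": [
                {
                    "address_path": list(s.address_path),
                    "n_reads": s.n_reads,
                    "consensus": str(s.consensus_seq),
                    "text": s.text,
                    "frame": s.frame.frame.pixels.tolist() if s.frame else None,
                }
                for s in self.species
            ],
            "warnings": self.warnings,
        }


def _reconstruct_reference(
    path: tuple[str, ...], payloads: list[DnaString], book: AddressBook
) -> DnaString:
    parts = []
    for k, addr_id in enumerate(path):
        parts.append(book.by_id(addr_id).seq)
        if k < len(payloads):
            parts.append(payloads[k])
    return DnaString("".join(parts))


def decode_pool(
    readset: ReadSet,
    book: AddressBook,
    codec: str = "text",
    ecc_cfg: text_codec.EccConfig = text_codec.DEFAULT_ECC,
    codon_table: "pixel_codec.CodonTable | None" = None,
    min_reads: int = 1,
) -> DecodeReport:
    """Run the full decoding pipeline on a read set.

    Species assembled serially or in parallel are separated purely by their
    distinct address paths — no clustering.  For ``codec='pixel'`` the
    grouping key additionally includes the 2-nt oligo index at the start of
    each payload, and recovered frames are attached per forward/reverse
    address pair.

    ``min_reads`` is the minimum cohort size for a path to be called as a
    species: reads whose errors corrupt an address hit land on spurious
    low-support paths, which are excluded from consensus (their reads stay
    in the aligned count and are classified 'other').  Keep the default of
    1 for error-free or truth-checked runs; ~3 is a sensible floor for
    noisy read sets at real depths.
    """
    report = DecodeReport(total_reads=len(readset.reads))
    if not readset.reads:
        return report

    segmented: list[SegmentedRead] = []
    for read in readset.reads:
        oriented, flag = orient_read(read.seq, book)
        if flag == "flipped":
            report.oriented_flipped += 1
        elif flag == "unknown":
            report.oriented_unknown += 1
        hits = scan_addresses(oriented, book)
        sr = segment_payloads(oriented, hits, read.id, flipped=(flag == "flipped"))
        if sr is None:
            report.warnings.append(f"{read.id}: <2 address hits, unalignable")
            continue
        segmented.append(sr)
    report.aligned_reads = len(segmented)

    if codec == "pixel":
        return _decode_pixel(segmented, book, codon_table, report, min_reads)
    return _decode_text(segmented, book, ecc_cfg, report, min_reads)


def _tally_read_stats(
    segmented: list[SegmentedRead],
    ref_for,
    report: DecodeReport,
) -> None:
    counts = dict.fromkeys(CLASSES, 0)
    lengths: list[int] = []
    for sr in segmented:
        ref = ref_for(sr)
        lengths.append(len(sr.seq))
        if ref is None:  # read's path was below the species support floor
            cls = "other"
        else:
            cls = classify_by_length(len(sr.seq), len(ref), identical=(sr.seq == ref))
        counts[cls] += 1
        if cls == "perfect":
            report.perfect_reads += 1
            report.length_match_reads += 1
        elif cls == "substitution":
            report.length_match_reads += 1
    total = max(len(segmented), 1)
    report.class_fractions = {k: v / total for k, v in counts.items()}
    report.length_histogram = dict(Counter(lengths))


def _decode_text(
    segmented: list[SegmentedRead],
    book: AddressBook,
    ecc_cfg: text_codec.EccConfig,
    report: DecodeReport,
    min_reads: int = 1,
) -> DecodeReport:
    n_per_path = Counter(sr.address_path for sr in segmented)
    supported = [sr for sr in segmented if n_per_path[sr.address_path] >= min_reads]
    dropped = len(segmented) - len(supported)
    if dropped:
        report.warnings.append(
            f"{dropped} reads on address paths below the {min_reads}-read support floor"
        )
    groups = group_and_consensus(supported)
    references = {
        path: _reconstruct_reference(path, payloads, book)
        for path, payloads in groups.items()
    }
    _tally_read_stats(segmented, lambda sr: references.get(sr.address_path), report)

    for path, payloads in sorted(groups.items()):
        words = []
        texts = []
        for payload in payloads:
            if len(payload) == 0:
                continue  # junction between a reverse and the next forward address
            res = text_codec.decode_word(payload, ecc_cfg)
            words.append(res)
            texts.append(res.text if res.ok else "?")
        result = SpeciesResult(
            address_path=path,
            n_reads=n_per_path[path],
            consensus_payloads=payloads,
            consensus_seq=references[path],
            text=" ".join(texts) if texts else None,
            words=words,
        )
        report.species.append(result)

    # per-read word recovery, with and without ECC: a word counts as
    # recovered without ECC only when its payload decodes with 0 corrections
    for sr in segmented:
        for k in range(len(sr.payloads)):
            payload = sr.payload_seq(k)
            if len(payload) == 0:
                continue
            res = text_codec.decode_word(payload, ecc_cfg)
            if res.ok:
                report.ecc_recovered_words += 1
                if res.corrections == 0:
                    report.no_ecc_recovered_words += 1
    return report


def _decode_pixel(
    segmented: list[SegmentedRead],
    book: AddressBook,
    codon_table: "pixel_codec.CodonTable | None",
    report: DecodeReport,
    min_reads: int = 1,
) -> DecodeReport:
    table = codon_table or pixel_codec.build_codon_table()
    idx_len = pixel_codec.INDEX_LENGTH

    # Distinct indexed oligos (or their serial products) share the same
    # address path, so species are demultiplexed by the path PLUS the 2-nt
    # index prefix of every payload.
    def species_key(sr: SegmentedRead) -> tuple:
        return (
            sr.address_path,
            tuple(sr.payload_seq(k)[:idx_len] for k in range(len(sr.payloads))),
        )

    members: dict[tuple, list[SegmentedRead]] = defaultdict(list)
    for sr in segmented:
        members[species_key(sr)].append(sr)

    dropped = sum(len(c) for c in members.values() if len(c) < min_reads)
    if dropped:
        report.warnings.append(
            f"{dropped} reads on oligo species below the {min_reads}-read support floor"
        )

    references: dict[tuple, DnaString] = {}
    # frames are identified by (address path, payload ordinal): a serial
    # product of m frames has frame payloads at ordinals 0, 2, 4, ...
    # Two species can nominate the same (frame, index) slot when an index
    # base was misread; the better-supported consensus wins.
    frames: dict[tuple, dict[int, DnaString]] = defaultdict(dict)
    support: dict[tuple, dict[int, int]] = defaultdict(dict)
    frame_reads: dict[tuple, int] = defaultdict(int)
    for key, cohort in members.items():
        if len(cohort) < min_reads:
            continue
        path = key[0]
        payloads = []
        for k in range(len(path) - 1):
            seqs = [sr.payload_seq(k) for sr in cohort]
            modal = _modal_length(seqs)
            cons = consensus([s for s in seqs if len(s) == modal])
            payloads.append(cons)
            if len(cons) == idx_len + pixel_codec.PAYLOAD_LENGTH:
                ordinal = pixel_codec.bases_to_index(cons[:idx_len])
                slot = (path, k)
                if len(cohort) > support[slot].get(ordinal, 0):
                    frames[slot][ordinal] = DnaString(cons[idx_len:])
                    support[slot][ordinal] = len(cohort)
                frame_reads[slot] += len(cohort)
        references[key] = _reconstruct_reference(path, payloads, book)
    _tally_read_stats(segmented, lambda sr: references.get(species_key(sr)), report)

    for (path, k) in sorted(frames):
        by_index = frames[(path, k)]
        frame_res = pixel_codec.decode_frame(by_index, table)
        report.warnings.extend(
            f"{'|'.join(path)}[payload {k}]: {w}" for w in frame_res.warnings
        )
        report.species.append(
            SpeciesResult(
                address_path=path + (f"payload{k}",),
                n_reads=frame_reads[(path, k)],
                consensus_payloads=list(by_index.values()),
                consensus_seq=DnaString("".join(by_index[i] for i in sorted(by_index))),
                frame=frame_res,
            )
        )
    return report


# ---------------------------------------------------------------------------
# In-silico PCR random access
# ---------------------------------------------------------------------------


def random_access(
    target: "Pool | ReadSet",
    fwd: AddressSequence,
    rev: AddressSequence,
) -> "Pool | ReadSet":
    """Select the species a PCR with this primer pair would amplify.

    Addresses are given in fragment orientation, as stored in the book: the
    physical reverse primer is the reverse complement of ``rev.seq``, so a
    species is amplifiable exactly when its data strand contains ``fwd.seq``
    followed by ``rev.seq`` (= revcomp of the reverse primer).  Returns the
    same container type; empty selections are allowed (the primer pair
    amplifies nothing).
    """
    site_f = str(fwd.seq)
    site_r = str(rev.seq)

    def amplifiable(seq: str) -> bool:
        s = str(seq)
        i = s.find(site_f)
        return i >= 0 and s.find(site_r, i + len(site_f)) >= 0

    if isinstance(target, Pool):
        selected = Pool()
        for frag, copies in target.members():
            if amplifiable(frag.seq):
                selected.add(frag, copies)
        selected.provenance = target.provenance + [
            f"random_access fwd={fwd.id} rev={rev.id}"
        ]
        return selected
    keep = []
    for read in target.reads:
        if amplifiable(read.seq) or amplifiable(revcomp(read.seq)):
            keep.append(read)
    ids = {r.id for r in keep}
    truth = target.truth[target.truth["read_id"].isin(ids)].reset_index(drop=True)
    return ReadSet(keep, truth, paired=target.paired)
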