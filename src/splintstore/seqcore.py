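"""Sequence primitives, validation and FASTA/FASTQ I/O.

All sequences are single-stranded 5'->3' strings over the strict four-letter
alphabet {A, C, G, T}.  Coordinates are 0-based half-open internally;
user-facing reports convert to 1-based closed positions.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

ALPHABET = frozenset("ACGT")

_COMPLEMENT = str.maketrans("ACGT", "TGCA")


class DnaString(str):
    """A validated DNA sequence (5'->3', upper-case A/C/G/T only).

    Lowercase input is accepted and upcased; IUPAC ambiguity codes (including
    N) are rejected because the codec alphabet is strictly four-letter.
    """

    __slots__ = ()

    def __new__(cls, seq: str, *, allow_empty: bool = True) -> "DnaString":
        s = str(seq).upper()
        for i, ch in enumerate(s):
            if ch not in ALPHABET:
                raise ValueError(
                    f"invalid base {ch!r} at position {i + 1} (1-based); "
                    "only A/C/G/T are allowed"
                )
        if not s and not allow_empty:
            raise ValueError("empty sequence not allowed here")
        return super().__new__(cls, s)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"DnaString({str.__repr__(self)})"


def revcomp(seq: str) -> DnaString:
    """Reverse complement of a DNA sequence.

    An involution: ``revcomp(revcomp(s)) == s``.
    """
    s = DnaString(seq)
    return DnaString(s.translate(_COMPLEMENT)[::-1])


def hamming(a: str, b: str) -> int:
    """Number of mismatching positions between two equal-length sequences."""
    if len(a) != len(b):
        raise ValueError(f"length mismatch: {len(a)} vs {len(b)}")
    return sum(x != y for x, y in zip(a, b))


def max_homopolymer_run(seq: str) -> int:
    """Length of the longest run of identical consecutive bases (0 if empty)."""
    best = run = 0
    prev = None
    for ch in seq:
        run = run + 1 if ch == prev else 1
        prev = ch
        if run > best:
            best = run
    return best


# ---------------------------------------------------------------------------
# Address sequences
# ---------------------------------------------------------------------------

ADDRESS_LENGTH = 20
ROLES = ("forward", "internal", "reverse")


@dataclasses.dataclass(frozen=True)
class AddressSequence:
    """A fixed 20-nt address/primer sequence with a positional role.

    Addresses flank or separate payloads; they double as PCR random-access
    handles and as synchronisation markers for the decoder's address scan.
    """

    id: str
    seq: DnaString
    role: str = "internal"

    def __post_init__(self) -> None:
        object.__setattr__(self, "seq", DnaString(self.seq, allow_empty=False))
        if len(self.seq) != ADDRESS_LENGTH:
            raise ValueError(
                f"address {self.id!r}: length {len(self.seq)} != {ADDRESS_LENGTH}"
            )
        if self.role not in ROLES:
            raise ValueError(f"address {self.id!r}: unknown role {self.role!r}")


class AddressBook:
    """Ordered collection of addresses, unique by id and by sequence.

    ``min_distance`` (pairwise Hamming, default 8) is enforced at construction
    so that 15-of-20 partial matching during decoding is unambiguous; pass
    ``min_distance=0`` for externally designed books.
    """

    def __init__(self, entries: Iterable[AddressSequence], *, min_distance: int = 8):
        self.entries: list[AddressSequence] = list(entries)
        self._by_id: dict[str, AddressSequence] = {}
        self._by_seq: dict[str, AddressSequence] = {}
        for e in self.entries:
            if e.id in self._by_id:
                raise ValueError(f"duplicate address id {e.id!r}")
            if e.seq in self._by_seq:
                raise ValueError(f"duplicate address sequence for id {e.id!r}")
            self._by_id[e.id] = e
            self._by_seq[e.seq] = e
        if min_distance > 0:
            for i, a in enumerate(self.entries):
                for b in self.entries[i + 1 :]:
                    d = hamming(a.seq, b.seq)
                    if d < min_distance:
                        raise ValueError(
                            f"addresses {a.id!r} and {b.id!r} are Hamming "
                            f"distance {d} apart (< {min_distance})"
                        )

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self) -> Iterator[AddressSequence]:
        return iter(self.entries)

    def __contains__(self, key: object) -> bool:
        return key in self._by_id or key in self._by_seq

    def by_id(self, id: str) -> AddressSequence:
        return self._by_id[id]

    def by_seq(self, seq: str) -> AddressSequence:
        return self._by_seq[str(seq).upper()]

    def with_role(self, role: str) -> list[AddressSequence]:
        return [e for e in self.entries if e.role == role]


def random_address_book(
    roles: Sequence[str],
    *,
    seed: int = 0,
    min_distance: int = 8,
    max_tries: int = 100_000,
) -> AddressBook:
    """Generate a synthetic address book by seeded rejection sampling.

    ``roles`` gives one role per requested address, e.g.
    ``["forward", "reverse", "forward", "reverse"]``.  Candidate 20-mers are
    drawn uniformly and rejected until every pair is >= ``min_distance``
    mismatches apart and no address equals (or nearly equals) the reverse
    complement of another — both directions are scanned during decoding.
    """
    rng = np.random.default_rng(seed)
    chosen: list[DnaString] = []
    bases = np.array(list("ACGT"))
    for _ in range(max_tries):
        if len(chosen) == len(roles):
            break
        cand = DnaString("".join(rng.choice(bases, size=ADDRESS_LENGTH)))
        ok = True
        for prev in chosen:
            if (
                hamming(cand, prev) < min_distance
                or hamming(cand, revcomp(prev)) < min_distance
            ):
                ok = False
                break
        if ok and hamming(cand, revcomp(cand)) >= min_distance:
            chosen.append(cand)
    if len(chosen) < len(roles):
        raise RuntimeError("rejection sampling failed; lower min_distance")
    counters = {r: 0 for r in ROLES}
    entries = []
    for role, seq in zip(roles, chosen):
        counters[role] += 1
        prefix = {"forward": "F", "internal": "M", "reverse": "R"}[role]
        entries.append(AddressSequence(f"addr{prefix}{counters[role]}", seq, role))
    return AddressBook(entries, min_distance=min_distance)


# ---------------------------------------------------------------------------
# FASTA / FASTQ I/O (Biopython-backed)
# ---------------------------------------------------------------------------


@dataclasses.dataclass
class FastaRecord:
    id: str
    seq: DnaString
    description: str = ""


@dataclasses.dataclass
class FastqRecord:
    id: str
    seq: DnaString
    qual: str
    description: str = ""

    def __post_init__(self) -> None:
        if len(self.qual) != len(self.seq):
            raise ValueError(
                f"record {self.id!r}: quality length {len(self.qual)} != "
                f"sequence length {len(self.seq)}"
            )


def read_fasta(path: str | Path) -> list[FastaRecord]:
    out = []
    for rec in SeqIO.parse(str(path), "fasta"):
        desc = rec.description
        if desc.startswith(rec.id):
            desc = desc[len(rec.id) :].strip()
        out.append(FastaRecord(rec.id, DnaString(str(rec.seq)), desc))
    return out


def write_fasta(path: str | Path, records: Iterable[FastaRecord]) -> None:
    seqrecs = [
        SeqRecord(Seq(str(r.seq)), id=r.id, description=r.description)
        for r in records
    ]
    SeqIO.write(seqrecs, str(path), "fasta")


def read_fastq(path: str | Path) -> list[FastqRecord]:
    out = []
    for rec in SeqIO.parse(str(path), "fastq"):
        qual = "".join(
            chr(q + 33) for q in rec.letter_annotations["phred_quality"]
        )
        desc = rec.description
        if desc.startswith(rec.id):
            desc = desc[len(rec.id) :].strip()
        out.append(FastqRecord(rec.id, DnaString(str(rec.seq)), qual, desc))
    return out


def write_fastq(path: str | Path, records: Iterable[FastqRecord]) -> None:
    seqrecs = []
    for r in records:
        sr = SeqRecord(Seq(str(r.seq)), id=r.id, description=r.description)
        sr.letter_annotations["phred_quality"] = [ord(c) - 33 for c in r.qual]
        seqrecs.append(sr)
    SeqIO.write(seqrecs, str(path), "fastq")


def write_address_book(path: str | Path, book: AddressBook) -> None:
    """Serialize an address book as FASTA with the role in the description."""
    write_fasta(
        path,
        [FastaRecord(e.id, e.seq, f"role={e.role}") for e in book],
    )


def read_address_book(path: str | Path, *, min_distance: int = 0) -> AddressBook:
    entries = []
    for rec in read_fasta(path):
        role = "internal"
        for tok in rec.description.split():
            if tok.startswith("role="):
                role = tok[5:]
        entries.append(AddressSequence(rec.id, rec.seq, role))
    return AddressBook(entries, min_distance=min_distance)
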