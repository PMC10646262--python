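"""Synthetic NGS read simulator with a per-base substitution/indel model.

Stands in for amplicon sequencing of assembled pools so every decoder path
is testable without any download.  Reads cover the full fragment (species
are <= 500 nt); each fragment is sequenced from either strand with equal
probability; errors are drawn i.i.d. per base.  A truth ledger records the
origin species, orientation and every edit of every read, so
decoder-independent error-class fractions are exact.

Per-base default rates are small (sub 2e-3, del 1e-3, ins 1e-3): real runs
report per-READ class fractions that entangle synthesis, ligation, PCR and
sequencing, from which no per-base rate is derivable; these defaults
produce the same order of per-read imperfection on ~200-nt amplicons.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd

from .assembly_sim import Pool
from .seqcore import DnaString, FastqRecord, revcomp

_BASES = "ACGT"
_ALTERNATIVES = {b: [c for c in _BASES if c != b] for b in _BASES}


@dataclasses.dataclass
class ErrorProfile:
    """Per-base error rates; each must lie in [0, 0.5)."""

    p_sub: float = 0.002
    p_del: float = 0.001
    p_ins: float = 0.001
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("p_sub", "p_del", "p_ins"):
            p = getattr(self, name)
            if not 0 <= p < 0.5:
                raise ValueError(f"{name}={p} outside [0, 0.5)")


ERROR_FREE = ErrorProfile(0.0, 0.0, 0.0)


@dataclasses.dataclass
class ReadSet:
    reads: list[FastqRecord]
    truth: pd.DataFrame  # read_id, species_id, mate, flipped, n_sub, n_del, n_ins
    paired: bool = False

    @property
    def r1(self) -> list[FastqRecord]:
        return [r for r in self.reads if not r.id.endswith("/2")]

    @property
    def r2(self) -> list[FastqRecord]:
        return [r for r in self.reads if r.id.endswith("/2")]


def _apply_errors(
    seq: str, profile: ErrorProfile, rng: np.random.Generator
) -> tuple[str, int, int, int]:
    """Mutate one template; returns (read, n_sub, n_del, n_ins).

    Insertions place a uniform random base before the current position;
    substitutions draw uniformly from the three alternatives.
    """
    out = []
    n_sub = n_del = n_ins = 0
    for base in seq:
        while rng.random() < profile.p_ins:
            out.append(_BASES[rng.integers(4)])
            n_ins += 1
        if rng.random() < profile.p_del:
            n_del += 1
            continue
        if rng.random() < profile.p_sub:
            out.append(_ALTERNATIVES[base][rng.integers(3)])
            n_sub += 1
        else:
            out.append(base)
    return "".join(out), n_sub, n_del, n_ins


def simulate_reads(
    pool: Pool,
    depth: int,
    profile: ErrorProfile = ERROR_FREE,
    paired: bool = False,
) -> ReadSet:
    """Simulate ``depth`` reads per species, sampled proportional to copies.

    Total reads = depth x (number of species with copies > 0), allocated to
    species by a multinomial on copy numbers.  Each read's template strand
    is flipped with probability 0.5 (both strands are sequenced); in paired
    mode R1 is the drawn strand and R2 the reverse complement of the same
    molecule, each with independent errors.  Deterministic given
    ``profile.seed``.
    """
    if depth < 1:
        raise ValueError("depth must be >= 1")
    members = [(f, c) for f, c in pool.members() if c > 0]
    if not members:
        raise ValueError("pool has no species with positive copy number")
    rng = np.random.default_rng(profile.seed)
    copies = np.array([c for _, c in members], dtype=float)
    counts = rng.multinomial(depth * len(members), copies / copies.sum())

    reads: list[FastqRecord] = []
    rows = []
    serial = 0
    for (frag, _), n in zip(members, counts):
        for _ in range(int(n)):
            serial += 1
            flipped = bool(rng.random() < 0.5)
            template = revcomp(frag.seq) if flipped else str(frag.seq)
            mates = [("/1" if paired else "", template)]
            if paired:
                mates.append(("/2", revcomp(template)))
            for mate, tmpl in mates:
                read_seq, n_sub, n_del, n_ins = _apply_errors(tmpl, profile, rng)
                rid = f"read{serial:06d}{mate}"
                reads.append(
                    FastqRecord(rid, DnaString(read_seq), "I" * len(read_seq))
                )
                rows.append(
                    {
                        "read_id": rid,
                        "species_id": frag.id,
                        "mate": mate.lstrip("/") or "1",
                        "flipped": flipped,
                        "ref_length": len(frag),
                        "n_sub": n_sub,
                        "n_del": n_del,
                        "n_ins": n_ins,
                    }
                )
    return ReadSet(reads, pd.DataFrame(rows), paired=paired)


CLASSES = ("perfect", "substitution", "deletion_1_2", "insertion", "other")


def classify_by_length(read_len: int, ref_len: int, identical: bool) -> str:
    """The length-based error taxonomy used throughout decoding.

    Equal length and equal sequence -> perfect; equal length, any mismatch
    -> substitution; 1-2 nt short -> deletion_1_2; longer -> insertion;
    anything else -> other.
    """
    if read_len == ref_len:
        return "perfect" if identical else "substitution"
    if ref_len - 2 <= read_len < ref_len:
        return "deletion_1_2"
    if read_len > ref_len:
        return "insertion"
    return "other"


def class_fractions(
    readset: ReadSet, references: dict[str, str] | None = None
) -> tuple[dict[str, float], pd.Series]:
    """Per-class read fractions plus the read-length histogram.

    With ``references`` (species_id -> full sequence) each read is compared
    to its true origin; otherwise classification falls back to the truth
    ledger's edit counts, which is exact for the simulator's own output.
    Fractions sum to 1.
    """
    truth = readset.truth.set_index("read_id")
    counts = dict.fromkeys(CLASSES, 0)
    lengths = []
    for read in readset.reads:
        row = truth.loc[read.id]
        lengths.append(len(read.seq))
        if references is not None:
            ref = references[row["species_id"]]
            oriented = revcomp(read.seq) if row["flipped"] else str(read.seq)
            if row["mate"] == "2":
                oriented = revcomp(oriented)
            cls = classify_by_length(
                len(read.seq), len(ref), identical=(oriented == ref)
            )
        else:
            identical = row["n_sub"] == row["n_del"] == row["n_ins"] == 0
            cls = classify_by_length(
                len(read.seq), int(row["ref_length"]), identical
            )
        counts[cls] += 1
    total = max(len(readset.reads), 1)
    fractions = {k: v / total for k, v in counts.items()}
    hist = pd.Series(lengths, dtype=int).value_counts().sort_index()
    return fractions, hist


def write_truth(readset: ReadSet, path) -> None:
    readset.truth.to_csv(path, sep="\t", index=False)
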