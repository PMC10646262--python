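"""Two-pixel-per-codon encoding of 16x16 four-colour frames into 90-nt oligos.

Two 2-bit pixels (4 bits) map to one of 16 three-base codons chosen so that
no codon contains an adjacent repeated base.  Because every table codon is
internally repeat-free, any concatenation of codons has a maximum
homopolymer run of 2 — the property that motivates codon encoding for
images, where constant-colour areas would otherwise produce long runs.
Logical density is 4 bits per 3 bases (1.33 bits/bp).

Oligo layout (90 nt): forward address (20) | index (2) | payload (48 = 16
codons = 32 pixels) | reverse address (20).  A 16x16 frame therefore
fragments into exactly 8 oligos, indexed 0-7 in row-major pixel order.
"""

from __future__ import annotations

import dataclasses
import itertools
from pathlib import Path

import numpy as np

from .seqcore import AddressSequence, DnaString, max_homopolymer_run
from .text_codec import BASE_OF_2BITS, BITS_OF_BASE

FRAME_WIDTH = 16
FRAME_HEIGHT = 16
N_COLORS = 4
PIXELS_PER_OLIGO = 32
CODON_LENGTH = 3
INDEX_LENGTH = 2
OLIGO_LENGTH = 90
PAYLOAD_LENGTH = 48

#: information content of the codon code, in bits per base
BITS_PER_BASE = 4 / 3


@dataclasses.dataclass(frozen=True)
class PixelFrame:
    """A 16x16 frame of 2-bit colour codes (values 0-3)."""

    pixels: np.ndarray

    def __post_init__(self) -> None:
        arr = np.asarray(self.pixels, dtype=int)
        if arr.shape != (FRAME_HEIGHT, FRAME_WIDTH):
            raise ValueError(
                f"frame must be {FRAME_HEIGHT}x{FRAME_WIDTH}, got {arr.shape}"
            )
        if arr.min() < 0 or arr.max() >= N_COLORS:
            raise ValueError("pixel colour codes must be in 0..3")
        object.__setattr__(self, "pixels", arr)

    def __eq__(self, other: object) -> bool:
        return isinstance(other, PixelFrame) and np.array_equal(
            self.pixels, other.pixels
        )


class CodonTable:
    """Bijection between 4-bit values and 16 repeat-free 3-base codons."""

    def __init__(self, codons: list[str]):
        if len(codons) != 16 or len(set(codons)) != 16:
            raise ValueError("a codon table needs 16 distinct codons")
        for c in codons:
            c = DnaString(c)
            if len(c) != CODON_LENGTH:
                raise ValueError(f"codon {c!r} is not {CODON_LENGTH} bases")
            if max_homopolymer_run(c) > 1:
                raise ValueError(f"codon {c!r} has an adjacent repeated base")
        self.codons = [DnaString(c) for c in codons]
        self._inverse = {c: i for i, c in enumerate(self.codons)}

    def encode(self, value: int) -> DnaString:
        return self.codons[value]

    def decode(self, codon: str) -> int | None:
        """4-bit value, or None for a codon outside the table (erasure)."""
        return self._inverse.get(str(codon).upper())

    def __len__(self) -> int:
        return 16


def build_codon_table(seed: int | None = None) -> CodonTable:
    """Pick 16 codons from the 36 with no adjacent repeat.

    Unseeded, the table is the lexicographically smallest valid set (the
    first 16 repeat-free codons in sorted order); with a seed, a random
    16-subset is drawn.  Every repeat-free codon is junction-safe: a run of
    3 across a junction would need a repeat inside one of the two codons.
    """
    candidates = [
        "".join(c)
        for c in itertools.product("ACGT", repeat=CODON_LENGTH)
        if c[0] != c[1] and c[1] != c[2]
    ]
    assert len(candidates) == 36
    if seed is None:
        chosen = candidates[:16]
    else:
        rng = np.random.default_rng(seed)
        chosen = list(rng.choice(candidates, size=16, replace=False))
    return CodonTable(chosen)


def codon_junction_check(table: CodonTable) -> int:
    """Worst homopolymer run over all 256 ordered codon concatenations."""
    return max(
        max_homopolymer_run(c + d) for c in table.codons for d in table.codons
    )


@dataclasses.dataclass
class PixelOligo:
    """One 90-nt data oligo: fwd address | 2-nt index | 48-nt payload | rev address."""

    frame_id: str
    forward_address: AddressSequence
    index: int
    payload: DnaString
    reverse_address: AddressSequence

    def __post_init__(self) -> None:
        if not 0 <= self.index < 16:
            raise ValueError(f"index ordinal {self.index} outside 0..15")
        if len(self.payload) != PAYLOAD_LENGTH:
            raise ValueError(
                f"payload is {len(self.payload)} nt, expected {PAYLOAD_LENGTH}"
            )

    @property
    def index_seq(self) -> DnaString:
        return index_to_bases(self.index)

    @property
    def full_seq(self) -> DnaString:
        return DnaString(
            self.forward_address.seq
            + self.index_seq
            + self.payload
            + self.reverse_address.seq
        )


def index_to_bases(ordinal: int) -> DnaString:
    """2-nt big-endian base-4 index under the shared 2-bit base map."""
    if not 0 <= ordinal < 16:
        raise ValueError(f"index ordinal {ordinal} outside 0..15")
    return DnaString(BASE_OF_2BITS[ordinal >> 2] + BASE_OF_2BITS[ordinal & 0b11])


def bases_to_index(seq: str) -> int:
    s = DnaString(seq)
    if len(s) != INDEX_LENGTH:
        raise ValueError(f"index must be {INDEX_LENGTH} nt")
    return (BITS_OF_BASE[s[0]] << 2) | BITS_OF_BASE[s[1]]


def encode_frame(
    frame: PixelFrame,
    table: CodonTable,
    fwd: AddressSequence,
    rev: AddressSequence,
    frame_id: str = "frame",
) -> list[PixelOligo]:
    """Fragment a frame into 8 ninety-nt oligos, row-major, 32 pixels each."""
    if fwd.seq == rev.seq:
        raise ValueError("forward and reverse addresses must be distinct")
    flat = frame.pixels.ravel()  # row-major, top-left origin
    oligos = []
    for ordinal, start in enumerate(range(0, flat.size, PIXELS_PER_OLIGO)):
        chunk = flat[start : start + PIXELS_PER_OLIGO]
        payload = "".join(
            table.encode((int(chunk[i]) << 2) | int(chunk[i + 1]))
            for i in range(0, len(chunk), 2)
        )
        oligos.append(PixelOligo(frame_id, fwd, ordinal, DnaString(payload), rev))
    return oligos


@dataclasses.dataclass
class FrameDecodeResult:
    frame: PixelFrame
    mask: np.ndarray  # True where the pixel was recovered
    warnings: list[str]

    @property
    def complete(self) -> bool:
        return bool(self.mask.all())


def decode_frame(
    payloads: "list[PixelOligo] | dict[int, str]",
    table: CodonTable,
    n_oligos: int = 8,
) -> FrameDecodeResult:
    """Reassemble a frame from indexed oligos or consensus payloads.

    ``payloads`` is either a list of :class:`PixelOligo` (input order is
    irrelevant; the index drives placement) or a mapping of index ordinal to
    48-nt payload sequence.  Missing indices leave a masked hole and a
    warning; a codon outside the table marks its pixel pair unrecovered.
    """
    if isinstance(payloads, dict):
        by_index = {int(k): DnaString(v) for k, v in payloads.items()}
    else:
        by_index = {o.index: o.payload for o in payloads}
    pixels = np.zeros(FRAME_HEIGHT * FRAME_WIDTH, dtype=int)
    mask = np.zeros(FRAME_HEIGHT * FRAME_WIDTH, dtype=bool)
    warnings = []
    for ordinal in range(n_oligos):
        base = ordinal * PIXELS_PER_OLIGO
        if ordinal not in by_index:
            warnings.append(
                f"missing oligo index {ordinal}: pixels "
                f"{base}-{base + PIXELS_PER_OLIGO - 1} unrecovered"
            )
            continue
        payload = by_index[ordinal]
        if len(payload) != PAYLOAD_LENGTH:
            warnings.append(
                f"oligo index {ordinal}: payload length {len(payload)} != "
                f"{PAYLOAD_LENGTH}; skipped"
            )
            continue
        for ci in range(PAYLOAD_LENGTH // CODON_LENGTH):
            codon = payload[ci * CODON_LENGTH : (ci + 1) * CODON_LENGTH]
            value = table.decode(codon)
            pos = base + 2 * ci
            if value is None:
                warnings.append(
                    f"oligo index {ordinal}: unknown codon {codon!r} at codon "
                    f"{ci}; pixels {pos},{pos + 1} unrecovered"
                )
                continue
            pixels[pos] = value >> 2
            pixels[pos + 1] = value & 0b11
            mask[pos] = mask[pos + 1] = True
    return FrameDecodeResult(
        PixelFrame(pixels.reshape(FRAME_HEIGHT, FRAME_WIDTH)),
        mask.reshape(FRAME_HEIGHT, FRAME_WIDTH),
        warnings,
    )


# ---------------------------------------------------------------------------
# Frame I/O: plain-text digit matrices and paletted PNG
# ---------------------------------------------------------------------------

DEFAULT_PALETTE = [(255, 255, 255), (228, 26, 28), (55, 126, 184), (77, 175, 74)]


def read_frame_txt(path: str | Path) -> PixelFrame:
    rows = []
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if line:
            rows.append([int(ch) for ch in line.replace(" ", "")])
    return PixelFrame(np.array(rows))


def write_frame_txt(path: str | Path, frame: PixelFrame) -> None:
    Path(path).write_text(
        "\n".join("".join(str(v) for v in row) for row in frame.pixels) + "\n"
    )


def read_frame_png(path: str | Path) -> PixelFrame:
    from PIL import Image

    img = Image.open(path)
    if img.mode != "P":
        img = img.convert("P", palette=Image.Palette.ADAPTIVE, colors=N_COLORS)
    arr = np.asarray(img, dtype=int)
    return PixelFrame(arr)


def write_frame_png(path: str | Path, frame: PixelFrame, palette=None) -> None:
    from PIL import Image

    img = Image.fromarray(frame.pixels.astype(np.uint8), mode="P")
    flat = [c for rgb in (palette or DEFAULT_PALETTE) for c in rgb]
    img.putpalette(flat)
    img.save(path)


def raw_payload_bytes(frame: PixelFrame) -> float:
    """Raw pixel payload of a frame in bytes (256 pixels x 2 bits = 64 B)."""
    return frame.pixels.size * 2 / 8
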