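"""ASCII word <-> DNA payload codec with shortened Reed-Solomon ECC.

Each word is encoded independently: its 7-bit ASCII character codes are the
message symbols of a shortened RS code over GF(2^7); two parity symbols are
appended (correcting any one character); the resulting bitstream is mapped
two bits per base (00->A, 01->C, 10->G, 11->T) and flanked by 20-nt forward
and reverse address sequences to form a ligatable word fragment.

For an n-character word the payload is ceil(7*(n+2)/2) bases; when the bit
total is odd a single 0 pad bit is appended before base conversion and the
``padded`` flag recorded in the fragment metadata.
"""

from __future__ import annotations

import dataclasses
import math

from . import gf128
from .seqcore import AddressSequence, DnaString

BASE_OF_2BITS = {0b00: "A", 0b01: "C", 0b10: "G", 0b11: "T"}
BITS_OF_BASE = {v: k for k, v in BASE_OF_2BITS.items()}


@dataclasses.dataclass(frozen=True)
class EccConfig:
    """Shortened Reed-Solomon configuration over GF(2^7).

    ``parity_symbols = 2`` corrects t = 1 symbol, i.e. one 7-bit character;
    those two parity symbols are 14 bits = 7 bases at 2 bits/base.
    """

    field_order: int = 128
    symbol_bits: int = 7
    parity_symbols: int = 2
    primitive_polynomial: int = gf128.PRIMITIVE_POLY
    shortened: bool = True

    def __post_init__(self) -> None:
        if self.field_order != 128 or self.symbol_bits != 7:
            raise ValueError("only GF(2^7) with 7-bit symbols is supported")
        if self.parity_symbols < 0 or self.parity_symbols % 2:
            raise ValueError("parity_symbols must be a non-negative even count")

    @property
    def max_message_symbols(self) -> int:
        return 127 - self.parity_symbols


DEFAULT_ECC = EccConfig()


def ascii_to_symbols(text: str) -> list[int]:
    """One 7-bit symbol per character, order preserved."""
    symbols = []
    for ch in text:
        code = ord(ch)
        if code > 127:
            raise ValueError(f"non-ASCII character {ch!r} (code {code})")
        symbols.append(code)
    return symbols


def symbols_to_ascii(symbols: list[int]) -> str:
    return "".join(chr(s) for s in symbols)


def rs_encode(symbols: list[int], cfg: EccConfig = DEFAULT_ECC) -> list[int]:
    """Systematic codeword: message symbols followed by the parity symbols."""
    if len(symbols) > cfg.max_message_symbols:
        raise ValueError(
            f"message of {len(symbols)} symbols exceeds shortened bound "
            f"{cfg.max_message_symbols}"
        )
    return gf128.rs_encode(symbols, cfg.parity_symbols)


def rs_decode(
    codeword: list[int], cfg: EccConfig = DEFAULT_ECC
) -> tuple[list[int], int, bool]:
    """Return (message, corrections_applied, ok)."""
    return gf128.rs_decode(codeword, cfg.parity_symbols)


def bits_to_bases(bits: str) -> DnaString:
    """Map a bitstring to bases, 2 bits per base (00A 01C 10G 11T)."""
    if len(bits) % 2:
        raise ValueError(f"odd bit count {len(bits)}; caller must pad")
    return DnaString(
        "".join(
            BASE_OF_2BITS[int(bits[i : i + 2], 2)] for i in range(0, len(bits), 2)
        )
    )


def bases_to_bits(seq: str) -> str:
    return "".join(format(BITS_OF_BASE[b], "02b") for b in DnaString(seq))


@dataclasses.dataclass
class WordFragment:
    """An address-flanked DNA word: forward address | payload | reverse address."""

    word: str
    forward_address: AddressSequence
    payload: DnaString
    reverse_address: AddressSequence
    padded: bool

    @property
    def full_seq(self) -> DnaString:
        return DnaString(
            self.forward_address.seq + self.payload + self.reverse_address.seq
        )

    def __len__(self) -> int:
        return 40 + len(self.payload)


def payload_length(n_chars: int, cfg: EccConfig = DEFAULT_ECC) -> int:
    """Payload bases for an n-character word: ceil(7*(n + parity)/2)."""
    return math.ceil(cfg.symbol_bits * (n_chars + cfg.parity_symbols) / 2)


def encode_payload(text: str, cfg: EccConfig = DEFAULT_ECC) -> tuple[DnaString, bool]:
    """Encode text to a DNA payload; returns (payload, padded flag)."""
    codeword = rs_encode(ascii_to_symbols(text), cfg)
    bits = "".join(format(s, "07b") for s in codeword)
    padded = bool(len(bits) % 2)
    if padded:
        bits += "0"
    return bits_to_bases(bits), padded


def encode_word(
    text: str,
    fwd: AddressSequence,
    rev: AddressSequence,
    cfg: EccConfig = DEFAULT_ECC,
) -> WordFragment:
    """Deterministically encode one ASCII word into an address-flanked fragment."""
    if fwd.seq == rev.seq:
        raise ValueError("forward and reverse addresses must be distinct")
    payload, padded = encode_payload(text, cfg)
    return WordFragment(text, fwd, payload, rev, padded)


@dataclasses.dataclass
class WordDecodeResult:
    text: str | None
    corrections: int
    ok: bool
    reason: str = ""


def decode_word(
    payload: str,
    cfg: EccConfig = DEFAULT_ECC,
    expected_length_hint: int | None = None,
) -> WordDecodeResult:
    """Invert :func:`encode_word` on a payload, applying RS correction.

    Structural failures (a base count consistent with no integer symbol
    count, or a length contradicting the hint) are reported in the result,
    not raised: they model unrecoverable reads, not programming errors.
    """
    seq = DnaString(payload)
    if expected_length_hint is not None and len(seq) != expected_length_hint:
        return WordDecodeResult(None, 0, False, "length differs from hint")
    bits = bases_to_bits(seq)
    nsym, rem = divmod(len(bits), cfg.symbol_bits)
    if rem not in (0, 1) or nsym <= cfg.parity_symbols:
        return WordDecodeResult(
            None, 0, False, f"{len(bits)} bits is not a valid codeword length"
        )
    codeword = [
        int(bits[i * cfg.symbol_bits : (i + 1) * cfg.symbol_bits], 2)
        for i in range(nsym)
    ]
    message, corrections, ok = rs_decode(codeword, cfg)
    if not ok:
        return WordDecodeResult(None, corrections, False, "ECC failure")
    return WordDecodeResult(symbols_to_ascii(message), corrections, True)
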