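"""Storage-arithmetic calculators: ligation yields, oligo layout, capacity.

Pure functions, exact to double precision.  Percentages are rounded
half-away-from-zero to one decimal, the convention used for all printed
efficiency figures; GB means 10^9 bytes (decimal).
"""

from __future__ import annotations

import dataclasses
import math

GB = 1e9  # decimal gigabyte


def round1(x: float) -> float:
    """Round half away from zero to 1 decimal (printed-percentage convention)."""
    return math.floor(abs(x) * 10 + 0.5) / 10 * (1 if x >= 0 else -1)


def ligation_efficiency(ligated: float, input_copies: float) -> float:
    """Single-junction ligation efficiency in percent, to 1 decimal.

    E.g. a qPCR-measured 1.67e12 ligated copies from 9.04e12 input copies
    gives 18.5%.
    """
    if input_copies <= 0:
        raise ValueError("input copy number must be positive")
    if ligated > input_copies:
        raise ValueError("ligated copies cannot exceed input copies")
    if ligated < 0:
        raise ValueError("copy numbers must be >= 0")
    return round1(100.0 * ligated / input_copies)


def serial_efficiency(e: float, n: int) -> float:
    """Compound yield of n serial ligations at per-junction efficiency e (%).

    Serial junctions multiply: four ligations at 18.5% leave ~0.1% of the
    input as full-length product.
    """
    if not 0 < e <= 1:
        raise ValueError("efficiency must be in (0, 1]")
    if n < 1:
        raise ValueError("need at least one junction")
    return round1(100.0 * e**n)


def oligos_per_frame(
    pixels: int = 256,
    colors: int = 4,
    oligo_len: int = 90,
    index_len: int = 2,
    addr_len: int = 20,
    pixels_per_codon: int = 2,
    codon_len: int = 3,
) -> int:
    """Number of oligos needed to carry one frame under the codon layout.

    payload = oligo_len - index_len - 2*addr_len bases; at 2 pixels per
    3-base codon a 90-nt oligo carries 32 pixels, so a 16x16 frame needs 8.
    """
    if colors != 4:
        raise ValueError("the codon code carries 2-bit (4-colour) pixels")
    payload = oligo_len - index_len - 2 * addr_len
    if payload <= 0 or payload % codon_len:
        raise ValueError(f"payload of {payload} nt is not a whole codon count")
    pixels_per_oligo = pixels_per_codon * payload // codon_len
    return math.ceil(pixels / pixels_per_oligo)


def codon_bits_per_base(bits: int = 4, bases: int = 3) -> float:
    """Logical density of the codon code: 4 bits / 3 bases = 1.33 bits/bp."""
    return bits / bases


def bytes_per_oligo(file_kb: float, n_oligos: int) -> float:
    """Per-oligo byte share of a file split over n oligos (kB = 1000 B)."""
    if n_oligos < 1:
        raise ValueError("need at least one oligo")
    return file_kb * 1000.0 / n_oligos


@dataclasses.dataclass(frozen=True)
class CapacityParams:
    """Inputs to the single-droplet capacity estimate.

    ``redundancy`` is physical copies per unique oligo kept to survive the
    lossy ligation; ``bytes_per_oligo`` is the file bytes carried per oligo.
    """

    droplet_copies: float = 9.04e12
    redundancy: float = 1000.0
    bytes_per_oligo: float = 33.7

    def __post_init__(self) -> None:
        if self.droplet_copies < 0:
            raise ValueError("copy numbers must be >= 0")
        if self.redundancy < 1:
            raise ValueError("redundancy must be >= 1")
        if self.bytes_per_oligo <= 0:
            raise ValueError("bytes_per_oligo must be positive")


def droplet_capacity(p: CapacityParams = CapacityParams()) -> float:
    """Storage capacity of one droplet in decimal GB.

    (unique oligos = copies / redundancy) x bytes per oligo / 1e9.  With
    9.04e12 copies, 1000x redundancy and 33.7-35 B/oligo this lands in the
    ~305-316 GB range.
    """
    return p.droplet_copies / p.redundancy * p.bytes_per_oligo / GB
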