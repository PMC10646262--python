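"""In-silico droplet splint-ligation assembly.

Models the droplet-controlled-fluidics (DCF) scheme in which droplets merge
at y-junctions and single-stranded data fragments are joined by T4 ligase
across a 30-nt splint that hybridises 15 nt to the upstream fragment's 3'
end and 15 nt to the downstream fragment's 5' end.  Splints are junction
validators only — their sequence is the reverse complement of the junction
and they never enter products.

Yield bookkeeping follows a single per-junction ligation efficiency
(default 18.5%, the qPCR-measured value for one splint ligation): in
expectation mode copy numbers are thinned deterministically by that factor
and conservation (product + leftovers == inputs) holds exactly; in
Bernoulli mode each copy ligates independently under a seeded RNG.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
import yaml

from .seqcore import DnaString, revcomp

SPLINT_ARM = 15
SPLINT_LENGTH = 2 * SPLINT_ARM

DEFAULT_LIGATION_EFFICIENCY = 0.185  # qPCR: 1.67e12 ligated of 9.04e12 input


@dataclasses.dataclass
class Fragment:
    """A single-stranded 5'->3' data fragment with optional metadata."""

    id: str
    seq: DnaString
    phosphorylated: bool = True  # 5'-phosphate required for ligation (T4 PNK)
    meta: dict = dataclasses.field(default_factory=dict)

    def __post_init__(self) -> None:
        self.seq = DnaString(self.seq, allow_empty=False)

    def __len__(self) -> int:
        return len(self.seq)


@dataclasses.dataclass(frozen=True)
class SplintOligo:
    """30-nt bridging oligo complementary to a 15+15 junction."""

    id: str
    seq: DnaString
    upstream_target: str
    downstream_target: str

    def __post_init__(self) -> None:
        if len(self.seq) != SPLINT_LENGTH:
            raise ValueError(f"splint {self.id!r} is {len(self.seq)} nt, not 30")


def design_splint(upstream: Fragment, downstream: Fragment) -> SplintOligo:
    """Splint bridging upstream's last 15 nt to downstream's first 15 nt."""
    if len(upstream) < SPLINT_ARM or len(downstream) < SPLINT_ARM:
        raise ValueError("fragments must be at least 15 nt to design a splint")
    junction = upstream.seq[-SPLINT_ARM:] + downstream.seq[:SPLINT_ARM]
    return SplintOligo(
        f"splint:{upstream.id}+{downstream.id}",
        revcomp(junction),
        upstream.id,
        downstream.id,
    )


def splint_matches(splint: SplintOligo, a: Fragment, b: Fragment) -> bool:
    """Exact-hybridisation check of a splint against an (a, b) junction."""
    return revcomp(splint.seq) == a.seq[-SPLINT_ARM:] + b.seq[:SPLINT_ARM]


@dataclasses.dataclass
class YieldModel:
    """Per-junction ligation yield.

    mode 'expectation': deterministic fractional thinning (default);
    mode 'bernoulli': per-copy coin flips, requires a seed.
    """

    per_ligation_efficiency: float = DEFAULT_LIGATION_EFFICIENCY
    mode: str = "expectation"
    seed: int | None = None

    def __post_init__(self) -> None:
        if not 0 < self.per_ligation_efficiency <= 1:
            raise ValueError("efficiency must be in (0, 1]")
        if self.mode not in ("expectation", "bernoulli"):
            raise ValueError(f"unknown yield mode {self.mode!r}")
        if self.mode == "bernoulli" and self.seed is None:
            raise ValueError("bernoulli mode requires an explicit seed")
        self._rng = (
            np.random.default_rng(self.seed) if self.mode == "bernoulli" else None
        )

    def thin(self, available: float) -> float:
        if self.mode == "expectation":
            return available * self.per_ligation_efficiency
        return float(
            self._rng.binomial(int(round(available)), self.per_ligation_efficiency)
        )


class Pool:
    """A droplet's contents: a multiset of fragments with copy numbers."""

    def __init__(self, members: Iterable[tuple[Fragment, float]] = ()):
        self._members: dict[str, tuple[Fragment, float]] = {}
        self.provenance: list[str] = []
        for frag, copies in members:
            self.add(frag, copies)

    def add(self, frag: Fragment, copies: float) -> None:
        if copies < 0:
            raise ValueError("copy numbers must be >= 0")
        if frag.seq in self._members:
            old_frag, old_copies = self._members[frag.seq]
            self._members[frag.seq] = (old_frag, old_copies + copies)
        else:
            self._members[frag.seq] = (frag, copies)

    def members(self) -> list[tuple[Fragment, float]]:
        return list(self._members.values())

    def copies_of(self, frag_id: str) -> float:
        for frag, copies in self._members.values():
            if frag.id == frag_id:
                return copies
        return 0.0

    def total_copies(self) -> float:
        return sum(c for _, c in self._members.values())

    def species(self) -> list[Fragment]:
        return [f for f, _ in self._members.values()]

    def __len__(self) -> int:
        return len(self._members)


@dataclasses.dataclass
class LigationOutcome:
    product: Fragment | None
    product_copies: float
    leftover_a: float
    leftover_b: float
    note: str = ""


def ligate(
    a: Fragment,
    b: Fragment,
    splint: SplintOligo,
    model: YieldModel,
    copies_a: float = 1.0,
    copies_b: float = 1.0,
) -> LigationOutcome:
    """Join a (upstream) and b (downstream) across a splint.

    A splint mismatch or an unphosphorylated downstream 5' end is a
    no-product outcome (failed hybridisation / missing 5'-phosphate), not an
    exception.  Product sequence is the exact concatenation — no bases are
    gained or lost at the junction.
    """
    if not splint_matches(splint, a, b):
        return LigationOutcome(None, 0.0, copies_a, copies_b, "splint mismatch")
    if not b.phosphorylated:
        return LigationOutcome(
            None, 0.0, copies_a, copies_b, "downstream 5' end not phosphorylated"
        )
    available = min(copies_a, copies_b)
    made = model.thin(available)
    product = Fragment(
        f"{a.id}+{b.id}",
        DnaString(a.seq + b.seq),
        phosphorylated=a.phosphorylated,
        meta={"parents": (a.id, b.id), "junction_splint": splint.id},
    )
    return LigationOutcome(product, made, copies_a - made, copies_b - made)


@dataclasses.dataclass
class AssemblyStep:
    """One y-junction association of two droplets.

    ``kind`` 'serial' carries a single splint; 'parallel' carries k >= 2
    distinct splints sharing one upstream address, producing k product
    species in the merged droplet.
    """

    out: str
    upstream: str
    downstream: str
    splints: list[SplintOligo]
    kind: str = "serial"

    def __post_init__(self) -> None:
        if self.kind not in ("serial", "parallel"):
            raise ValueError(f"unknown step kind {self.kind!r}")
        if self.kind == "serial" and len(self.splints) != 1:
            raise ValueError("a serial step takes exactly one splint")
        if self.kind == "parallel" and len(self.splints) < 2:
            raise ValueError("a parallel step needs k >= 2 distinct splints")


@dataclasses.dataclass
class AssemblyProgram:
    steps: list[AssemblyStep]

    def validate(self, inputs: Mapping[str, Pool]) -> None:
        known = set(inputs)
        for step in self.steps:
            for ref in (step.upstream, step.downstream):
                if ref not in known:
                    raise ValueError(
                        f"step {step.out!r} references unknown droplet {ref!r}"
                    )
            known.add(step.out)


def run_program(
    program: AssemblyProgram,
    inputs: Mapping[str, Pool],
    model: YieldModel | None = None,
) -> dict[str, Pool]:
    """Execute an assembly program over named input pools.

    Returns the full droplet namespace (inputs plus every step output); the
    last step's output is the final pool.  Unligated leftovers stay in the
    merged droplet.  The program is validated before any step runs.
    """
    model = model or YieldModel()
    program.validate(inputs)
    pools: dict[str, Pool] = dict(inputs)
    for step in program.steps:
        up_pool, down_pool = pools[step.upstream], pools[step.downstream]
        merged = Pool()
        merged.provenance = list(up_pool.provenance) + list(down_pool.provenance)
        up_remaining = {f.seq: [f, c] for f, c in up_pool.members()}
        down_remaining = {f.seq: [f, c] for f, c in down_pool.members()}
        for splint in step.splints:
            for ua in up_remaining.values():
                for da in down_remaining.values():
                    if not splint_matches(splint, ua[0], da[0]):
                        continue
                    outcome = ligate(ua[0], da[0], splint, model, ua[1], da[1])
                    if outcome.product is not None and outcome.product_copies > 0:
                        merged.add(outcome.product, outcome.product_copies)
                        merged.provenance.append(
                            f"{step.out}: {ua[0].id} + {da[0].id} via {splint.id} "
                            f"-> {outcome.product_copies:.4g} copies"
                        )
                        ua[1] = outcome.leftover_a
                        da[1] = outcome.leftover_b
        for frag, copies in list(up_remaining.values()) + list(
            down_remaining.values()
        ):
            if copies > 0:
                merged.add(frag, copies)
        pools[step.out] = merged
    return pools


def final_pool(
    program: AssemblyProgram,
    inputs: Mapping[str, Pool],
    model: YieldModel | None = None,
) -> Pool:
    if not program.steps:
        # empty program: inputs unchanged; a single input pool is "the" result
        if len(inputs) == 1:
            return next(iter(inputs.values()))
        raise ValueError("empty program over multiple pools has no single output")
    return run_program(program, inputs, model)[program.steps[-1].out]


def size_ladder(pool: Pool) -> pd.DataFrame:
    """Virtual gel: distinct lengths ascending with species and copy counts.

    Supports the size-based multi-bit readout in which a 100-bp band is the
    least significant and a 500-bp band the most significant bit.
    """
    rows: dict[int, dict] = {}
    for frag, copies in pool.members():
        row = rows.setdefault(len(frag), {"length": len(frag), "species": 0, "copies": 0.0})
        row["species"] += 1
        row["copies"] += copies
    return pd.DataFrame(
        sorted(rows.values(), key=lambda r: r["length"]),
        columns=["length", "species", "copies"],
    )


# ---------------------------------------------------------------------------
# YAML program / pool serialization
# ---------------------------------------------------------------------------


def load_program(path: str | Path, splints: Mapping[str, SplintOligo]) -> AssemblyProgram:
    """Load a program from YAML: a list of steps with splint ids.

    Schema: ``steps: [{out, upstream, downstream, splints: [id, ...],
    kind: serial|parallel}, ...]``.
    """
    doc = yaml.safe_load(Path(path).read_text())
    steps = []
    for raw in doc["steps"]:
        steps.append(
            AssemblyStep(
                out=raw["out"],
                upstream=raw["upstream"],
                downstream=raw["downstream"],
                splints=[splints[sid] for sid in raw["splints"]],
                kind=raw.get("kind", "serial"),
            )
        )
    return AssemblyProgram(steps)


def write_pool(pool: Pool, fasta_path: str | Path, tsv_path: str | Path) -> None:
    """Pool as FASTA plus a sidecar copy-number table (species, length, copies)."""
    from .seqcore import FastaRecord, write_fasta

    members = pool.members()
    write_fasta(fasta_path, [FastaRecord(f.id, f.seq) for f, _ in members])
    pd.DataFrame(
        [
            {"species_id": f.id, "length": len(f), "copies": c}
            for f, c in members
        ]
    ).to_csv(tsv_path, sep="\t", index=False)


def read_pool(fasta_path: str | Path, tsv_path: str | Path | None = None) -> Pool:
    from .seqcore import read_fasta

    copies = {}
    if tsv_path is not None:
        table = pd.read_csv(tsv_path, sep="\t")
        copies = dict(zip(table["species_id"], table["copies"]))
    pool = Pool()
    for rec in read_fasta(fasta_path):
        pool.add(Fragment(rec.id, rec.seq), float(copies.get(rec.id, 1.0)))
    return pool
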