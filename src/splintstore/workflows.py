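"""End-to-end assembly workflows: sentence, parallel and movie-pool builds.

These compose the codecs with the assembly simulator into the three pool
architectures the toolkit models:

* a serial sentence pool — word fragments chained in programmed order;
* a parallel pool — a shared sentence head ligated to k alternative tail
  words in one droplet, giving k sentence species;
* a movie pool — three 16x16 frames encoded as 8 indexed 90-nt oligos
  each, then the index-i oligos of the three frames serially ligated into
  eight 270-nt products.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .assembly_sim import (
    AssemblyProgram,
    AssemblyStep,
    Fragment,
    Pool,
    SplintOligo,
    YieldModel,
    design_splint,
    final_pool,
    run_program,
)
from .pixel_codec import CodonTable, PixelFrame, build_codon_table, encode_frame
from .seqcore import AddressBook, random_address_book
from .text_codec import DEFAULT_ECC, EccConfig, WordFragment, encode_word


@dataclasses.dataclass
class SentenceBuild:
    words: list[str]
    book: AddressBook
    word_fragments: list[WordFragment]
    splints: list[SplintOligo]
    program: AssemblyProgram
    pool: Pool


def _word_fragments(
    words: list[str], book: AddressBook, cfg: EccConfig
) -> list[WordFragment]:
    fwd = book.with_role("forward")
    rev = book.with_role("reverse")
    return [
        encode_word(w, fwd[i], rev[i], cfg) for i, w in enumerate(words)
    ]


def build_sentence_pool(
    words: list[str],
    seed: int = 0,
    cfg: EccConfig = DEFAULT_ECC,
    copies: float = 1e6,
    model: YieldModel | None = None,
    order: list[int] | None = None,
) -> SentenceBuild:
    """Encode words and serially ligate them in programmed order.

    ``order`` permutes the assembly (the programmable-ordering property):
    the same fragments with different splints yield a different sentence.
    """
    book = random_address_book(["forward"] * len(words) + ["reverse"] * len(words), seed=seed)
    frags = _word_fragments(words, book, cfg)
    order = order or list(range(len(words)))
    chain = [
        Fragment(f"word:{frags[i].word}", frags[i].full_seq, meta={"word": frags[i].word})
        for i in order
    ]
    splints = [design_splint(chain[i], chain[i + 1]) for i in range(len(chain) - 1)]
    pools = {f"w{i}": Pool([(frag, copies)]) for i, frag in enumerate(chain)}
    steps = []
    prev = "w0"
    for i, splint in enumerate(splints):
        out = f"s{i + 1}"
        steps.append(AssemblyStep(out, prev, f"w{i + 1}", [splint], "serial"))
        prev = out
    program = AssemblyProgram(steps)
    pool = final_pool(program, pools, model)
    return SentenceBuild(
        [frags[i].word for i in order], book, frags, splints, program, pool
    )


@dataclasses.dataclass
class ParallelBuild:
    head_words: list[str]
    tail_words: list[str]
    book: AddressBook
    splints: list[SplintOligo]
    pool: Pool


def build_parallel_pool(
    head_words: list[str],
    tail_words: list[str],
    seed: int = 0,
    cfg: EccConfig = DEFAULT_ECC,
    copies: float = 1e6,
    model: YieldModel | None = None,
) -> ParallelBuild:
    """A shared serial head ligated in parallel to k alternative tail words.

    The parallel step carries k distinct splints sharing the head's 3' end;
    the merged droplet holds k sentence species, PCR-selectable by the tail
    words' reverse addresses.
    """
    n = len(head_words) + len(tail_words)
    book = random_address_book(["forward"] * n + ["reverse"] * n, seed=seed)
    fwd, rev = book.with_role("forward"), book.with_role("reverse")
    head_frags = [
        Fragment(f"word:{w}", encode_word(w, fwd[i], rev[i], cfg).full_seq)
        for i, w in enumerate(head_words)
    ]
    tail_frags = [
        Fragment(
            f"word:{w}",
            encode_word(w, fwd[len(head_words) + i], rev[len(head_words) + i], cfg).full_seq,
        )
        for i, w in enumerate(tail_words)
    ]
    pools = {f"h{i}": Pool([(f, copies)]) for i, f in enumerate(head_frags)}
    pools["tails"] = Pool([(f, copies) for f in tail_frags])
    steps = []
    prev = "h0"
    splints = []
    for i in range(1, len(head_frags)):
        s = design_splint(head_frags[i - 1], head_frags[i])
        # serial head chain: each junction extends the running product
        steps.append(AssemblyStep(f"head{i}", prev, f"h{i}", [s], "serial"))
        splints.append(s)
        prev = f"head{i}"
    head_product = head_frags[0]
    for i in range(1, len(head_frags)):
        head_product = Fragment(
            head_product.id + "+" + head_frags[i].id,
            head_product.seq + head_frags[i].seq,
        )
    par_splints = [design_splint(head_product, t) for t in tail_frags]
    splints += par_splints
    steps.append(AssemblyStep("final", prev, "tails", par_splints, "parallel"))
    program = AssemblyProgram(steps)
    pool = final_pool(program, pools, model)
    return ParallelBuild(head_words, tail_words, book, splints, pool)


@dataclasses.dataclass
class MovieBuild:
    frames: list[PixelFrame]
    book: AddressBook
    table: CodonTable
    oligo_pools: list[list]  # per frame, 8 PixelOligos
    pool: Pool  # eight 270-nt serial products (plus leftovers)


def random_frames(n: int = 3, seed: int = 0) -> list[PixelFrame]:
    """Synthetic 16x16 four-colour frames (sprite-like stand-ins)."""
    rng = np.random.default_rng(seed)
    frames = []
    for _ in range(n):
        frames.append(PixelFrame(rng.integers(0, 4, size=(16, 16))))
    return frames


def build_movie_pool(
    frames: list[PixelFrame] | None = None,
    seed: int = 0,
    copies: float = 1e6,
    model: YieldModel | None = None,
    table: CodonTable | None = None,
) -> MovieBuild:
    """Encode frames to 90-nt oligo pools and ligate index-matched triples.

    Each index i gets its own pair of droplets so that the shared frame
    addresses cannot cross-pair oligos of different indices; the final pool
    is the union of the eight per-index serial products.
    """
    frames = frames if frames is not None else random_frames(3, seed)
    table = table or build_codon_table()
    roles = []
    for _ in frames:
        roles += ["forward", "reverse"]
    book = random_address_book(roles, seed=seed)
    fwd, rev = book.with_role("forward"), book.with_role("reverse")
    oligo_pools = [
        encode_frame(f, table, fwd[j], rev[j], frame_id=f"frame{j}")
        for j, f in enumerate(frames)
    ]
    combined = Pool()
    for idx in range(len(oligo_pools[0])):
        chain = [
            Fragment(f"frame{j}_idx{idx}", oligo_pools[j][idx].full_seq)
            for j in range(len(frames))
        ]
        pools = {f"f{j}": Pool([(frag, copies)]) for j, frag in enumerate(chain)}
        steps = []
        prev = "f0"
        for j in range(1, len(chain)):
            splint = design_splint(chain[j - 1], chain[j])
            steps.append(AssemblyStep(f"p{j}", prev, f"f{j}", [splint], "serial"))
            prev = f"p{j}"
        product_pool = final_pool(AssemblyProgram(steps), pools, model)
        for frag, c in product_pool.members():
            combined.add(frag, c)
        combined.provenance += product_pool.provenance
    return MovieBuild(list(frames), book, table, oligo_pools, combined)


def products_only(pool: Pool, min_length: int) -> Pool:
    """Strip leftover inputs, keeping species of at least ``min_length`` nt
    (a size-selection step, like cutting a band from the gel)."""
    out = Pool()
    for frag, copies in pool.members():
        if len(frag) >= min_length:
            out.add(frag, copies)
    out.provenance = pool.provenance + [f"size-select >= {min_length} nt"]
    return out
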