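# splintstore

An in-silico toolkit for DNA digital data storage built on **programmable
splint-ligation assembly**. It models a droplet-controlled-fluidics (DCF)
workflow end to end: digital data are encoded into short address-tagged
ssDNA fragments, fragments are joined into larger data species by splint
ligation in programmed serial/parallel order, the resulting pools are
"sequenced" by an error-bearing read simulator, and the data are recovered
by an address-primer scanning decoder with consensus calling, error
correction and in-silico PCR random access.

It is aimed at researchers prototyping molecular data-storage encodings and
pooling architectures who want a fully simulated, seeded, reproducible
pipeline before (or instead of) wet-lab work.

## The model

**Text.** Each ASCII word is a message over GF(2⁷): one 7-bit symbol per
character. A shortened systematic Reed–Solomon code (primitive polynomial
x⁷+x³+1) appends 2 parity symbols, correcting any t = 1 symbol — one
character — per word. The codeword bits map to bases 2 bits at a time
(00→A, 01→C, 10→G, 11→T) and the payload is flanked by fixed 20-nt forward
and reverse address sequences:

    fragment = addr_fwd (20 nt) ∥ payload (⌈7(n+2)/2⌉ nt) ∥ addr_rev (20 nt)

**Images.** A 16×16 frame with four colours (2 bits/pixel) is encoded two
pixels per 3-base codon from a 16-codon table in which no codon contains an
adjacent repeated base — so any codon concatenation has a maximum
homopolymer run of 2, even for constant-colour frames. Logical density is
4/3 ≈ 1.33 bits/bp. Each frame fragments into exactly eight 90-nt oligos:
20-nt forward address ∥ 2-nt base-4 index ∥ 48-nt payload (32 pixels) ∥
20-nt reverse address.

**Assembly.** A 30-nt splint bridges the last 15 nt of an upstream fragment
and the first 15 nt of a downstream fragment; ligation concatenates the two
data strands exactly. Each junction succeeds with efficiency e (default
18.5%, the qPCR-measured single-junction value); n serial junctions
compound to eⁿ, and a parallel step with k distinct splints sharing one
upstream yields k product species in one droplet.

**Decoding.** Payload sizes and positions are unknown a priori. Reads are
oriented by their address content (reverse-complemented reads are flipped
back), then every 20-nt address is scanned — full windows with ≤5
mismatches, or exact ≥15-nt matches at read ends — forward addresses
anchoring within the first 20 bases. Payloads are the spans between
consecutive hits; reads sharing an address path are grouped, restricted to
the modal payload length, and reduced to a per-position plurality
consensus before codec decoding. PCR random access keeps exactly the
species that contain a chosen forward address followed by the chosen
reverse address.

## Worked example

```
$ splintstore demo --seed 1 --out demo
splintstore INFO demo sentence: ['DNAdata Stores Apple']
splintstore INFO demo movie: 3/3 frames recovered
sentence: ['DNAdata Stores Apple']; frames: 3/3
```

The demo (1) encodes the words "DNAdata", "Stores", "Apple" into three
address-flanked fragments, serially ligates them into one 205-nt sentence
species, simulates 50× reads with per-base substitution/indel errors, and
decodes the sentence back exactly; and (2) encodes three random 16×16
frames into 24 indexed 90-nt oligos, ligates index-matched triples into
eight 270-nt products, and recovers all three frames from simulated reads.
`demo/demo.json` records the recovered sentence and frame count; reruns
with the same seed are byte-identical.

The calculators give the headline storage arithmetic:

```
$ splintstore quantify efficiency --ligated 1.67e12 --input 9.04e12
18.5
$ splintstore quantify serial --junctions 4
0.1
$ splintstore quantify capacity
304.6
```

i.e. a measured single-junction ligation efficiency of 18.5%, a compound
yield of 0.1% after four serial junctions, and a single-droplet capacity of
304.6 GB at 9.04×10¹² oligo copies, 1000× copy redundancy and 33.7 B per
oligo.

Library use mirrors the CLI:

```python
from splintstore import workflows, read_sim, address_decoder

build = workflows.build_sentence_pool(["DNAdata", "Stores", "Apple"], seed=1)
pool = workflows.products_only(build.pool, min_length=150)
reads = read_sim.simulate_reads(pool, depth=50, profile=read_sim.ErrorProfile(seed=1))
report = address_decoder.decode_pool(reads, build.book, codec="text", min_reads=3)
print(report.recovered_texts())   # {'addrF1|...|addrR3': 'DNAdata Stores Apple'}
```

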