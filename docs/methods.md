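# Methods

This document records the models implemented by `l1trace`, the default
parameters and why they were chosen, the numerical techniques used, and
the simulator's known limitations.

## 1. Biological and protocol model

### 1.1 Surrogate sequences

The real assay's primer, adapter and UMI designs are not public, so the
simulator and parser share explicit surrogate constants
(`l1trace.config`):

* `L1HS_CONSENSUS_3P` — a fixed synthetic 600 nt stand-in for the L1HS
  3′-end consensus. It was generated once from a seeded random stream
  and is free of TaqI (`TCGA`) and FspBI (`CTAG`) recognition sites, so
  digestion can never sever the primer landing from the junction.
* `L1HS_PRIMER_LANDING` — the consensus' last 25 nt; every amplified
  molecule begins with this sequence (the semi-nested inner primer).
* `ADAPTER_STEM` — a fixed 40 nt stem-loop adapter constant, also
  site-free, preceding the 8 nt UMI on the adapter-side mate.

These are configuration data, not claims about the original reagents;
tests may substitute arbitrary enzymes and lengths.

### 1.2 Reference genomes

`simulate_reference` draws a uniform random genome and embeds
`n_ref_l1` L1HS 3′ segments (one per equal-width bin, so copies never
collide), each a randomly 5′-truncated consensus tail (200–600 nt) plus
a 15 nt poly(A), mutated at `copy_divergence` = 1.5 % per base to model
inter-copy divergence. A fixed fraction (default 80 %) of copies is
*amplifiable*: their primer landing is left intact. The rest have the
landing scrambled, modeling 3′-degenerate copies the primer cannot
bind; they are catalogued but produce no molecules.

### 1.3 Insertions

A planted insertion is parameterized by target position, strand,
5′-truncated length (≥ the 25 nt landing), poly(A) length, TSD length,
origin (germline/somatic), cell fraction, and the samples carrying it.
In a carrier haplotype it materializes as

```
genome[:p] | TSD | L1-tail | poly(A) | TSD | genome[p:]
```

The *sequenced junction* (the coordinate the pipeline can observe) is
`p` for a plus-strand insertion and `p + tsd_len` for a minus-strand
insertion, because sequencing walks off the element's 3′ end across the
second TSD copy.

### 1.4 Library generation

Per sample, each locus present in that sample contributes
`Binomial(genome_equivalents, cell_fraction)` original molecules
(germline and reference loci have fraction 1). Each molecule is the
restriction fragment starting at the primer landing:
`landing + poly(A) + genomic flank to the first TaqI/FspBI cut site`
(site search spans the junction). Each molecule receives a fresh random
UMI and `Poisson(mean_reads_per_molecule)` duplicate read pairs:

* mate 1 (L1 side): `molecule [+ revcomp(UMI) + revcomp(stem)]`,
  truncated/padded to 150 nt;
* mate 2 (adapter side): `stem + UMI + revcomp(molecule)`, truncated or
  padded to 150 nt.

Padding uses `G`, imitating the no-signal dark base of two-channel
(NextSeq-style) chemistry; the parser strips trailing G runs of ≥ 5 nt.
Substitution errors are applied per base at `subst_error_rate`; a
`chimera_rate` fraction of molecules has its genomic flank swapped for
a random locus, modeling ligation/PCR chimeras. Everything is
deterministic given the configuration: the reference uses the seed
stream `[seed, 1]`, each sample's library `[seed, 2, sample_index]`.

## 2. Calling pipeline

### 2.1 Read-structure parsing (`ingest`)

Checks run in a fixed order, and the first failure is the reported
reason: adapter stem (≤ 1 mismatch) → UMI free of `N` → L1 primer
landing on mate 1 (≥ 15 nt at ≥ 90 % identity) → a mappable flank of
≥ 20 nt.

The extracted flank is **junction-anchored**: its first base is the
first genomic base after the poly(A) tail. Two paths provide it:

* *Adapter side* — when mate 2 (reverse-complemented) reads through a
  landing suffix and/or a leading poly(A) run, what follows is the
  anchored flank.
* *L1 side* — mate 1 always starts at the landing; after trimming the
  leading poly(A) run (≥ 5 A's, tolerating one non-A) and any adapter
  read-through, the remainder is the anchored flank.

The anchored adapter-side flank is preferred (it is read with fewer
preceding cycles); whichever flank is not chosen is retained for mate
concordance. Poly(A)/flank ambiguity is resolved by *left
normalization*: if the genomic flank itself begins with adenosines they
are indistinguishable from the tail and are trimmed with it, so the
observed junction shifts past them deterministically.
`simulate.observed_breakpoint` applies the same rule to the reference,
giving the exact coordinate the caller will report for any planted
insertion.

### 2.2 Flank mapping (`mapping`)

A self-contained seed-and-extend aligner sized for desk-scale genomes
(a few Mb): the forward strand is indexed as sorted 2-bit 15-mer codes
over a concatenated genome array; a query is seeded at up to 8 evenly
spaced offsets in both orientations; seed hits vote for (strand,
diagonal); the best diagonals are scored by ungapped extension (match
+1 / mismatch −1). An alignment below 90 % identity is unmapped;
`unique` requires the best score to beat the best alignment at any
*other* locus by ≥ 5 points. Non-unique flanks are dropped — multi-
mapping junctions are an artifact class, not evidence. There is no
gapped alignment: amplicon flanks are short and indel-free by design
(no indel error model; see section 4).

### 2.3 Clustering and molecule counting (`calling`)

Junction coordinates from unique-mapping reads are single-linkage
clustered within a 15 nt window per contig; the cluster breakpoint is
the lower-median member coordinate and the strand is the member
majority (ties toward `+`). UMIs are collapsed into molecule counts as
connected components under Hamming distance ≤ 1, absorbing sequencing
errors in the UMI. A cluster is flagged `is_known_l1` when its
breakpoint lies within 100 nt of the 3′ junction of an amplifiable
catalogued copy. The concordant fraction is the share of member reads
whose other mate's flank tells the same story (same contig and strand
within 600 nt; an uninformative other mate — the read ended inside
L1/poly(A) — counts as concordant by convention).

### 2.4 Somatic filter cascade (`somatic`)

For each subject and treatment arm, the callset whose timepoint equals
the baseline label anchors the arm; every other callset of the arm is
compared against it:

1. **Baseline subtraction** — drop follow-up clusters with any baseline
   cluster within 25 nt (strand-agnostic; germline and clonal loci are
   shared across serial samples).
2. **Cross-condition exclusion** — flag loci recurring within 25 nt in
   a different arm of the same subject (independent insertions into the
   same locus in different cells are vanishingly unlikely; recurrence
   marks a library artifact). Single-arm designs are unaffected.
3. **Known-copy exclusion** — flag `is_known_l1` clusters.
4. **Evidence thresholds** — read support strictly greater than 10
   (`>10`), UMI support of at least 2 (`≥2`), concordant fraction
   ≥ 0.5.

A record is a candidate iff every flag passes; rejected records are
retained with their first failing filter, so for every sample
`clusters_total = baseline_matched + final_candidates + Σ rejections`
(asserted in tests). Deliberately, there are no multiple-testing
statistics: the cascade is a deterministic filter funnel.

## 3. Study conditions and their sizing

The shipped study scale (also `SimConfig`'s defaults) was fixed ahead
of any end-to-end run, from closed-form expectations:

* 2 Mb genome, 30 reference copies, 10 germline insertions — enough
  known loci that baseline subtraction and known-copy exclusion do real
  work, while one replicate stays in seconds.
* `genome_equivalents` G = 1000 and mean PCR duplication μ = 3: a
  fraction-f insertion yields `Binomial(1000, f)` molecules, each with
  `Poisson(3)` reads. At f = 1 % that is ~10 molecules (≥ 2 UMIs with
  probability ≈ 1 − 11·e⁻¹⁰ ≈ 0.9995) and ~30 reads
  (P(reads > 10) ≈ 0.98 when ≥ 2 molecules survive duplication), so
  per-replicate recall is predicted ≈ 0.97–0.98 — comfortably above
  the 90 % bar. At f = 0.3 % (3 expected molecules, ~9 expected
  reads) P(reads > 10) ≈ 0.3: the grid is expected to fail below 1 %,
  which is the point — the evidence thresholds, not the mapper, set
  the sensitivity floor.
* Error rate 0.1 % per base and chimera rate 0.002 (0.005 in the
  specificity study) are plausible library-noise magnitudes; results
  are not sensitive to them at these scales because chimeric flanks
  scatter across the genome and rarely co-locate twice within 15 nt
  with ≥ 2 UMIs and > 10 reads.
* Planted insertions are rejection-sampled so their fragment leaves a
  mappable flank of ≥ 40 nt and sites keep ≥ 2.5 kb spacing. This is a
  *protocol observability* constraint decided a priori: a junction
  whose first cut site is < 20 nt away is invisible to any 3′-junction
  assay of this design (with four-cutter sites every ~128 bp on
  average, ~15 % of uniform positions would fail it), and planting
  unobservable insertions would measure the placement lottery, not the
  pipeline.

## 4. Simulator limitations

* No indel or quality-score error model (constant Q40); the aligner is
  correspondingly ungapped.
* No 5′-junction reads, inversions, 3′ transductions, or non-L1 mobile
  elements (Alu/SVA); the protocol models the L1HS 3′ junction only.
* Chimeras are modeled at fragment level as a flank swap; real
  libraries also contain partial-molecule artifacts.
* Reference copies diverge by independent point substitution only — no
  structural polymorphism within the catalogue.
* PCR duplication is Poisson per molecule with no amplification-bias
  correlation between duplicates; UMI errors arise only from the
  per-base substitution model.
* One contig per simulated reference ("chr1"); the caller itself is
  multi-contig.

## 5. Numerical and implementation choices

* **Determinism** — all stochastic stages use seeded
  `numpy.random.default_rng` with structured seed lists (e.g.
  `[seed, 2, sample_index]`), so samples are independent but
  reproducible; identical configurations produce byte-identical FASTQ.
* **2-bit k-mer index** — the genome is encoded as `uint8` codes; k-mer
  codes are rolled into a sorted `uint64` array queried with
  `searchsorted` (no hash map). Query codes are passed as NumPy
  `uint64` scalars: a Python `int` key would silently promote the whole
  haystack array inside `searchsorted` and dominate the run time.
* **Memoized parsing and mapping** — PCR duplicates and sibling
  molecules of one locus differ only in their UMI, so the parser caches
  per-mate results (keyed by the L1-side sequence and by the
  adapter-side remainder past stem+UMI) and the pipeline caches
  `map_flank` by flank string; deep libraries then cost near-constant
  time per read.
* **UMI collapse** — for the default Hamming radius 1, components are
  found in O(n·L) by grouping UMIs on (position, string-with-position-
  deleted) keys (two UMIs are within Hamming 1 iff they share such a
  key) with union-find; larger radii fall back to chunked vectorized
  pairwise distances. Both paths are oracle-tested against graph
  components.
* **Clustering** — per-contig sort plus gap-splitting gives
  permutation-invariant single-linkage clusters in O(n log n); the
  lower median makes the breakpoint a member coordinate.
* **Coordinates** — 0-based half-open everywhere internally; BED on
  disk.
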