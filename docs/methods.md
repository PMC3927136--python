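# Methods

## Scope and model

`pmoaclass` classifies amplicon reads of *pmoA* — the gene encoding a subunit
of the particulate methane monooxygenase — against a fixed hierarchical
taxonomy of the copper-containing membrane-bound monooxygenase (CuMMO) family.
The taxonomy splits at the top into `MOB_like` (methanotroph *pmoA* and
relatives, 53 genus-level leaf clades) and `AOB_like` (betaproteobacterial
ammonia monooxygenase, one leaf, co-amplified by broad *pmoA* primers); the
packaged transcription lists 6628 curated reference sequences across 54
leaves.  Two independent classification routes are implemented and can be run
side by side:

1. **Naive Bayesian k-mer classifier** (word-presence model).  Each training
   sequence contributes the set of k-mers it contains.  With `N` training
   sequences of which `n(w)` contain word `w`, the prior is
   `P(w) = (n(w)+0.5)/(N+1)`; for a leaf `G` with `M` sequences of which
   `m(w)` contain `w`, `P(w|G) = (m(w)+P(w))/(M+1)`.  A read with word set `V`
   is scored by `sum_{w in V} log P(w|G)`; both orientations are scored and
   the better one kept.  Confidence comes from 100 bootstrap draws of
   `ceil(|V|/8)` words with replacement; a node's confidence is the share of
   draws won by its descendant leaves, and the read is reported at the deepest
   node reaching the cutoff (default 80%).
2. **Search + LCA.**  A seed-and-extend local aligner (exact shared word of 28
   nt required, megablast-style) scores reads against every candidate
   reference with affine-gap Smith–Waterman; raw scores become bit scores via
   Karlin–Altschul rescaling `bits = (lambda*S - ln K)/ln 2`.  The best hit per
   taxon is kept, taxa within the `top_percent` margin of the best bit score
   (default 5%, multiplicative) are retained, and the read is assigned to
   their lowest common ancestor.

Novelty detection layers four tiers on these outputs, from most to least
divergent: reads with **no nucleotide hits** are re-queried with a six-frame
translated search (BLOSUM62, word size 3) — genuine but deeply divergent CuMMO
reads score above `translated_rescue_min_bits` (default 50) while unrelated
contaminants do not; reads with best nucleotide bits below
`divergent_flag_max_bits` are **moderately divergent** new-clade candidates;
reads whose LCA lands on an **internal node** suggest lineages branching
between known taxa; the remaining **leaf-assigned** reads are screened for
*conserved mismatches* — reference columns where most reads of a group share
one non-reference base — which indicate genus-level novelty inside an existing
clade.

## Parameters that matter

| parameter | default | rationale |
|---|---|---|
| filter: min length / max homopolymer / max ambiguous | 300 bp / 8 / 0 | standard pyrosequencing quality rules; runs strictly longer than 8 are rejected |
| NBC: k, bootstrap, subsample, cutoff | 8, 100, 1/8, 80% | the word size and cutoff used for this marker; bootstrap settings follow the established RDP-style convention |
| search: match/mismatch, gap open/extend | +1/−2, 5/2 | megablast-like scheme; a gap of length L costs 5+2L raw units |
| search: lambda, K (nucleotide) | 1.28, 0.46 | published Karlin–Altschul values for +1/−2 |
| search: lambda, K (translated) | 0.267, 0.041 | published values for BLOSUM62 with gap 11/1 |
| word size (nucleotide / translated) | 28 / 3 | seeding asymmetry is the point: 28-nt words make divergent homologs invisible, 3-residue words recover them |
| LCA top percent | 5% | retains taxa with `bits >= 0.95 * best` |
| novelty: rescue bits / flag bits | 50 / 150 | the flag threshold is *engine-calibrated*, see below |
| conserved mismatches: fraction / coverage | 0.8 / 5 | a column counts when ≥80% of ≥5 covering reads share one non-reference base; formalizes what is otherwise judged by eye on summary alignments |

### Calibrating the new-clade flag

A "low bit score" threshold is only meaningful relative to the scoring scheme,
the read length, and how distinct the reference taxa are.  Reference taxa are
mutually >5% divergent, so a best hit implying more than ~5% divergence marks
a candidate new clade.  `pmoaclass.search.expected_bit_score(L, d)` converts a
divergence `d` at alignment length `L` into this engine's bit currency
(`expected_bit_score(400, 0.05)` ≈ 629 bits); the test suite and acceptance
script use that value when recovering planted novelty.  The shipped default of
150 bits is kept for continuity with external search engines but is near the
bottom of this engine's scale for full-length 400-bp alignments; users
changing the scoring scheme should re-derive the flag with
`expected_bit_score`.

## The synthetic testbed

Real curated reference sets are not shipped; the `synthetic` module builds a
deterministic mock database (~69 sequences, 18 populated leaf taxa across all
major groups) by evolving one coding-like ancestor down the taxonomy with
codon-aware substitutions (no in-frame stops): ~10% per top-level edge, ~7%
per subgroup edge, ~6% per leaf edge, ~1.5% per individual reference.  This
yields ≥10% divergence between any two taxa (sister taxa ~11–13%) and ≤3%
within a taxon — a small-scale caricature of the real database's >5%
inter-taxon separation.  `gp23` is generated as a single reference 25%
diverged from its subgroup, reproducing the database's divergent-singleton
configuration.

The read generator draws `read_length` (default 400 bp) windows at
codon-aligned offsets and emulates the survey read classes: uniform
substitutions at a requested divergence (sampled per read from a range);
synonymous-biased divergence (third-position synonymous changes first, so the
protein stays ≥90% intact while the nucleotide sequence diverges ~30% —
invisible to 28-mer seeding, visible to translated search); planted shared
substitutions (identical columns in every read of a group, spaced ≥5 apart,
≥5 from window ends, with one ≥32-bp clean corridor so a seed word always
exists and the optimal alignment provably retains every planted column);
i.i.d. random contaminants; two-parent chimeras; homopolymer run
extensions/contractions.

What the generator does **not** emulate: flowgram-specific error profiles,
quality-score structure, PCR bias, real contaminant genes (contaminants are
uniform random DNA), or intra-taxon phylogenetic structure beyond star-like
divergence from a leaf ancestor.  Passing tests therefore demonstrate the
correctness and calibration of the algorithms under controlled divergence,
not field accuracy on any particular sequencing platform.

## Numerical and design choices

* **Extension is exact.**  Seeding decides which read/reference pairs are
  aligned; the alignment itself is full-matrix affine Smith–Waterman (numba
  kernel), so the reported raw score is optimal under the configured scheme.
  Heuristic truncation (banding, X-drop) is omitted: at amplicon scale
  (≤0.5 kb vs ≤0.6 kb) the full matrix costs milliseconds, and score
  optimality is what makes bit-score thresholds and the exhaustive-oracle
  property meaningful.  E-values are not computed; the procedure works
  entirely in bit scores.
* **Traceback ties** prefer substitution over gap columns; argmax ties in the
  NBC resolve to the lexicographically smallest taxon; map-file identifiers
  are assigned in depth-first preorder — all outputs are deterministic and
  diffable, and a fixed seed reproduces every artifact byte for byte.
* **Identity percent** counts identical columns over all alignment columns,
  gaps included.
* **Filter reasons** are reported in the fixed priority length > ambiguity >
  homopolymer so rejection accounting is reproducible; the filter is
  idempotent.
* **Tier precedence**: the no-hit test runs before the low-score flag, and the
  flag is evaluated on best nucleotide bits regardless of LCA depth (a read
  under the flag threshold is a new-clade candidate even if it still wins a
  leaf).  Tiers partition the reads.
* **Chimera detection is delegated**: the pipeline applies an externally
  produced name list; it does not re-implement the detection algorithm.
* The duplicated level code printed for the TypeII and pXMO_like groups in the
  source table is resolved by renumbering pXMO_like (and descendants) to a
  distinct sibling code; names, not codes, are authoritative.
* Goodall's similarity is not among the distance measures: multiple
  incompatible definitions exist and none is fixed by the procedure this
  package implements.  Kulczynski is returned in distance form
  (1 − similarity).

## Known limitations

* **The singleton attractor is k-invariant here.**  The word-presence model
  gives sparsely represented taxa a structural advantage: for a word absent
  from every taxon the score difference in favour of a singleton against an
  `M`-sequence taxon is `log((M+1)/2)` per word, independent of k and of the
  bootstrap draw.  Uniform random reads are therefore captured by the
  divergent singleton (`gp23`) at full bootstrap confidence at k = 8 *and*
  k = 10 — the attractor itself is reproduced, but increasing k does not
  mitigate it in this model.  Mitigation observed in practice on real surveys
  presumably rides on real contaminants sharing 8-mers (but not 10-mers) with
  well-populated taxa; uniform random contaminants share essentially nothing
  at either word size.  The BLAST/LCA route is the robust alternative: random
  contaminants produce no nucleotide hits and fail the translated rescue, so
  they tier as contaminants.
* Bit scores are internally consistent but not numerically comparable to any
  external search engine's output; thresholds are ordinal contracts
  (ranking, margins), not absolute values.
* The LCA implementation has no minimum-support filter; every read is
  assigned independently.
* Translated-search coordinates are reported per frame in amino-acid space,
  not projected back to nucleotide positions.
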