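# Methods

This note documents the models, parameter choices and numerical conventions
behind `ogsdelta`, and what the synthetic fixtures do and do not establish
about behaviour on real genomes.

## Coordinates and formats

All in-memory coordinates are 0-based half-open on the forward strand;
GFF3 I/O converts to/from 1-based inclusive at the file boundary and the
conversion is involutive (write∘read is byte-stable). Gene sets are
hierarchical GFF3 (gene → mRNA → CDS, parsed with gffutils); block
alignments are BED12 (no identity/coverage fields), PSL (identity =
matches/(matches+mismatches), coverage = aligned query bases / qSize) or
flat GFF3 `match`/`match_part` rows. An alignment counts as *spliced* when
some block gap is ≥ 30 bp; the spliced/unspliced boundary is not standardised
anywhere, 30 bp is below essentially all real introns and above indel noise,
and it is configurable (`SplicedAlignment.MIN_INTRON`).

## Built-in CDS→old-assembly mapper

The built-in mapper is a deterministic exact-k-mer anchor-and-chain aligner,
adequate for the regime it is used in (the old assembly is, up to deletions
and breaks, a subsequence of the new one); users with diverged real
assemblies should supply splice-aware external alignments, which share the
same downstream filtering and classification.

- k = 15; k-mers occurring > 20 times in the old assembly are treated as
  repetitive and skipped. The anchor requirement plays the role of a
  homology-search prefilter.
- Co-diagonal anchors merge into maximal exact segments; segments shorter
  than 23 bp (k + 8) are discarded — in 80% AT sequence, chance 15-mer
  collisions are expected in the hundreds per 100 kb, but the probability of
  a chance *run* reaching 23 bp is ~2·10⁻⁴ per collision, so 23 bp cleanly
  separates signal from low-complexity noise while real retained exon
  fragments (exons are ≥ 30 bp) stay visible.
- Chaining is an O(n²) DP maximising covered query bases minus a 12-base
  per-junction cost (so distant chance segments cannot inflate a chain).
  Target gaps up to 20 kb are treated as introns; a large query gap is
  unaligned query (it reduces coverage, not identity); mismatch columns are
  inferred only from comparable gaps < 30 bp on both sides. Overall identity
  is matched/(matched+mismatch columns), coverage is
  (matched+mismatch)/query length — one overall value per chain, not
  per block.

## Classification

Thresholds: identity ≥ 0.95 with coverage ≥ 0.80 (stringent) or ≥ 0.50
(relaxed); both modes are always computed, and relaxing coverage can only
move genes out of Type I. Overlap for the Type II / Previously Known
decision is the per-base union of retained-alignment blocks against
old-gene *coding exons* on the same strand; one base pair suffices. A gene
whose alignments touch two or more old genes is Previously Known with a
`multi_overlap` flag (split/merge cases are a curation problem, not a
classification one).

## Synthetic-data generator (the study conditions)

The generator is the minimal structure that reproduces the documented
phenomena — bimodal GC, genes concentrated in AT-rich domains, and new-gene
classes with known causes:

- **Genome**: 10 scaffolds × 100 kb in the study fixture; domains with
  exponential lengths (mean 20 kb, min 4 kb) and i.i.d. bases at GC 0.20 or
  0.45, alternating levels — a piecewise-homogeneous caricature of a
  10–70% GC range genome.
- **Genes**: 100 per Mb; a gene is placed with probability 0.75 in the
  lowest-GC domain class (its midpoint is kept inside the chosen domain so
  the bias is exact); 1–10 coding exons (15% single-exon mass), CDS length
  3 × clip(lognormal(ln 280, 0.6), 27, 1500) nt ≥ 81 nt, ATG…stop with no
  internal stop and codons drawn at the domain's GC propensity; introns
  60–400 bp, GT/AG except a 2% non-canonical minority; genes never overlap.
  The sequence under each gene is overwritten, so every ORF is real.
- **Degradation**: deletions (exponential lengths, mean 2 kb) with expected
  deleted fraction 0.12 in the lowest-GC domain class vs 0.02 elsewhere,
  plus scaffold breaks at 2·10⁻⁵ per bp; a lift table records every
  surviving base. Ground truth: a gene is Type I when its best
  per-old-scaffold retained CDS fraction is < 0.80 (< 0.50 for the relaxed
  column). *Retained* counts only fragments ≥ 23 bp — the mapper's minimum
  anchorable segment — because no seeded local alignment can recover shorter
  fragments, and a truth label that no correct pipeline could reproduce
  would test nothing. Retained genes enter the simulated old gene set with
  probability 0.85, multiplied by 0.35 when the CDS is < 600 nt: earlier
  annotations demonstrably missed short genes, and this is what makes the
  Type II class short — annotated genes become Previously Known truth,
  unannotated ones Type II.
- **Evidence**: four single-tissue libraries (brain, antennae, ovary,
  testes), per-gene per-tissue expression probability 0.55, spliced
  alignments (reproducing the exact intron coordinates) with probability
  0.9 and single-block unspliced reads with probability 0.7 per expressed
  pair; optional antisense spliced noise; homolog alignments per source
  proteome (generic metazoan 0.45, Dipteran reference 0.08) at ≥ 62%
  coverage / ≥ 65% identity; peptides are tryptic fragments (cut after K/R,
  ≥ 6 aa) of the true proteins at 0.4 expected peptides per gene;
  conservation flags per informant (0.85 / 0.78); domain-table rows at 0.5.
  Breadth truth is recorded from the actual spliced emissions; single-exon
  genes can never have spliced support, so their breadth truth is "none".
  Evidence probabilities are class-independent — the generator does not make
  new genes harder to support, so per-class evidence percentages on fixtures
  are flat and only the structural/compositional contrasts are meaningful.

Same specs and seeds give byte-identical files. What passing fixtures shows:
the pipeline's bookkeeping (coordinates, strands, thresholds, truth
recovery) is exact under conditions where the answer is known. What it does
not show: mapper behaviour under real sequence divergence, repeat families,
alternative isoforms, or fragmented gene models — real-data use should lean
on external aligners and treat the built-in mapper as a fixture tool.

## GC segmentation

Recursive binary segmentation on the G/C indicator with the Jensen–Shannon
divergence (entropy in bits); the split must beat the 1 − α quantile of the
maximal divergence over `null_replicates` simulated homogeneous Bernoulli
sequences of the same length and composition. The published segmentation
tools use an analytic dynamic threshold; the empirical null here is a
deliberate stand-in with the same contract (reject splits a homogeneous
sequence would produce), documented as such. Defaults: α = 0.01 with 200
replicates — the test is applied once per recursion node, so a small
per-node α keeps the expected number of false domain boundaries per
scaffold well below one; min domain 3 kb; scaffolds < 10 kb are returned
whole and flagged, and genes on them are excluded from (and counted out of)
the weighted-GC analysis. Positions that are not A/C/G/T are excluded from
every numerator and denominator, and runs of ≥ 10 Ns split candidate
domains outright so assembly gaps cannot pose as compositional boundaries.
Non-coding GC masks coding exons of both strands; a fully coding domain has
undefined non-coding GC and is skipped with weight renormalisation in the
gene-weighted average, which weights by the fraction of the gene's genomic
extent (first to last coding base — not the exon-only footprint, which is
available behind `exon`-level weighting if ever needed) in each domain.

## ENC, splice sites, N50

Wright's estimator as specified in the README formula; the class average is
over amino acids observed ≥ 2 times; Ile's three-fold class falls back to
(F2+F4)/2; Nc is undefined (with a recorded reason) if a class average is
missing or zero, and truncated at 61. CDS lengths not divisible by 3 are
analysed as the longest in-frame prefix with a warning. Note EMBOSS `chips`
treats six-fold classes differently; one documented dialect beats silent
divergence, so only Wright's is implemented.

Splice-site canonicality reads the two intronic bases at each end
(reverse-complemented for minus-strand genes) and counts only introns whose
exact coordinates are confirmed by a same-strand spliced alignment gap;
introns < 4 bp are flagged invalid. N50 is the smallest length L such that
sequences ≥ L contain half the total bases.

## Statistics and report

Frequencies: Pearson chi-square, 1 df, no continuity correction (Yates is
applied only in the protein-domain 2×2 contrast, mirroring standard
practice for those small expected counts). Means: two-sided KS and Welch,
reporting the *least* significant P-value — deliberately conservative and
assumption-free. No multiple-testing correction across the feature
comparisons; the report footer says so. Derived arithmetic: deltas are
exact integers; percent changes print one decimal; the ortholog-reduction
metric prints an integer. Identical inputs yield byte-identical reports.

## Problem sizes

The study fixture is one megabase with ~100 genes — large enough that every
class is populated and small enough that the full analysis (simulation,
mapping, segmentation with empirical nulls, evidence, statistics) runs in
well under a minute on one core; the statistical calibration checks use
1,000 null replicates.

## Known limitations

- The built-in mapper has no substitution model; identity < 1 arises only
  from inferred mismatch columns, so it is not a divergence-tolerant aligner.
- One transcript per gene; no UTR inference (UTRs are carried through I/O
  only) and no isoforms.
- The generator does not model false genes in the *old* set (how many such
  artifacts real first-generation sets contained is not established), so
  "Previously Known" truth never shrinks from old-set errors.
- Conservation and domain support are consumed as precomputed tables;
  running translated searches or domain scans is out of scope.
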