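# Methods

This note records the statistical conventions gaoxkit implements, the
choices made where the field offers more than one convention, and what the
synthetic-data validation does and does not demonstrate.

## Sequence handling

Coordinates are 1-based and inclusive at every public interface, matching
GFF3. A coding sequence excludes the stop codon: `extract_cds` tolerates a
trailing stop and strips it with a warning, so `len(cds) = 3 × len(protein)`
always holds. Codons containing `N` translate to `X`, are excluded from all
codon statistics (tallied separately), and pairs containing them are dropped
from codon alignments. Promoters are anchored at the translation start
(ATG), not the transcript start, because the gene models this package
targets are CDS-level; the window (default 3000 bp) is taken 5′ of the
first coding base on the coding strand and clipped, with a flag, at contig
edges.

## Protein properties

Molecular weight is the sum of average (not monoisotopic) residue masses
plus one water (18.015 Da), with the mass table used by the ExPASy Compute
pI/Mw tool — the convention of record for gene-family survey tables.
The isoelectric point solves net-charge(pH) = 0 by bisection on [0, 14]
(tolerance 0.001) with the Bjellqvist pKa set: side chains D 4.05, E 4.45,
C 9.0, Y 10.0, H 5.98, K 10.0, R 12.0; C-terminus 3.55 (4.55/4.75 when the
terminal residue is D/E); N-terminus 7.5 with residue-specific values for
A, M, S, P, T, V, E. Cysteines are treated as free. The charge function is
strictly decreasing in pH, so the root is unique; the test suite checks this
monotonicity numerically and cross-checks both quantities against
Biopython's independent implementations of the same conventions (agreement
is well inside 0.005 kDa and 0.02 pH units on 330-residue proteins).

One subtlety: because the C-terminal pKa is residue-specific, appending D
to a peptide both adds an acidic side chain and weakens the terminal
carboxyl (3.55 → 4.55), and the pI can rise slightly. The monotonicity
property "adding an acidic residue never raises pI" therefore only holds
with the termini held fixed, which is how the property test states it.
Classification is `basic` iff pI > 7.0, with 7.0 exactly counted acidic.

## Codon usage

All statistics operate on per-gene counts over the 61 sense codons.

* **RSCU**: for codon *j* in a synonymous family of size *k*,
  RSCU = x_j · k / Σx; a family with zero total yields NA (exported blank,
  never 0). Family RSCU values sum to *k*.
* **Third-position composition (A3s/T3s/G3s/C3s)**: plain base fractions at
  position 3 over synonymous codons only (Met/ATG and Trp/TGG excluded);
  they sum to 1 and GC3s = G3s + C3s. CodonW, the classic implementation,
  uses idiosyncratic per-base denominators instead; the convention here is
  self-consistent and preserves every qualitative ordering (which is what
  the downstream contrasts rely on), but its numbers are not interchangeable
  with CodonW output. This is a deliberate, documented divergence.
* **Positional GC**: GC1/GC2/GC3 over *all* sense codons;
  GC12 = (GC1 + GC2)/2.
* **ENC**: Wright's Nc = 2 + 9/F̄₂ + 1/F̄₃ + 5/F̄₄ + 3/F̄₆, with family
  homozygosity F = (nΣp² − 1)/(n − 1) and F̄ₖ the mean over that degeneracy
  class (2-fold: the nine two-codon families; 3-fold: Ile; 4-fold: five
  families; 6-fold: Leu/Ser/Arg). Families with n < 2 or F ≤ 0 are
  unusable; a class with no usable family borrows the mean of the observed
  class means, except F̄₃, which preferentially borrows (F̄₂ + F̄₄)/2. The
  result is capped at 61. Genes under 50 codons trigger a high-variance
  warning. The ENC-plot expected curve is
  ENC_exp(s) = 2 + s + 29/(s² + (1−s)²).
* **PR2**: x = G3s/(G3s + C3s), y = A3s/(A3s + T3s); (0.5, 0.5) is parity.
* **Correlations**: Pearson r with the two-sided t-transform p-value,
  across genes, between {A3s, T3s, G3s, C3s, GC3s, GC, GC12}; constant
  columns yield NA rather than a spurious value.

## Ka/Ks

The estimator is Nei–Gojobori (1986) with equal pathway weighting and
Jukes–Cantor correction — the classical default of the desktop tools used
for within-family selection scans. Synonymous site counts reduce the
denominator by stop-creating changes (at each codon position, the
synonymous fraction is counted over the non-stop single-nucleotide
neighbours); difference counts average over all m! mutational pathways
between two codons, excluding pathways through stop codons. S and N are
averaged across the two sequences; ps = Sd/S and pn = Nd/N are corrected as
d = −(3/4)ln(1 − 4p/3), with p ≥ 3/4 reported as saturated (NA). Ka/Ks is
NA when Ks = 0.

Codon alignment is protein-guided: the translations are globally aligned
(BLOSUM62, gap open −10, extend −0.5 — fixed defaults, configurable, so
results are reproducible bit-for-bit) and threaded back onto codons;
columns with a gap in either sequence are dropped. The whole machinery is
tested against exhaustive neighbour/pathway enumeration for all 61 codons
and all codon pairs, and against a brute-force dynamic-programming aligner
on short pairs.

## Cis-element scanning

Motifs are IUPAC consensus strings scanned on both strands with overlaps
counted; positions are 1-based on the promoter's coding-strand orientation;
`N` in a promoter never matches. A palindromic consensus at one locus
yields one hit per strand — both are counted by default (symmetric rule),
and a dedupe option collapses them. The bundled library encodes widely
published consensus strings for the eight hormone/stress categories (ABA,
GA, SA, auxin, MeJA, light, low temperature, defense/stress) and is
config-replaceable; curated web databases keep their exact element
definitions private, so the library reproduces the counting machinery, not
any specific database's counts.

## Expression

TPM divides counts by effective length in kb and rescales each sample to
1e6; effective length is CDS length, since quantification upstream of the
count matrix is out of scope. ΔΔCt averages technical replicates within
each biological replicate, computes per-replicate ΔCt against the reference
gene, subtracts the mean calibrator ΔCt, and summarises biological
replicates on the log2 scale (mean ΔΔCt ± SE), so the reported fold
2^(−mean ΔΔCt) is a geometric mean and the calibrator fold is exactly 1.
The reference gene is a required user parameter. Responsiveness is called
when log2 fold change strictly exceeds the threshold (default 3).

## Synthetic data: what it emulates, and what passing tests show

Each generator draws from a named stream of a single integer seed
(`default_rng([seed, stream_id])`), so outputs are byte-reproducible and
adding a generator never perturbs existing ones. Defaults are chosen to
mirror the study system this package was built around: genes of 350 codons
(the real family spans 244–430 aa), 3000-bp promoters, Ct tables with
three biological × three technical replicates, panels of 20 genes per
regime.

* **CDS panels** draw amino acids uniformly and pick synonymous codons with
  weight exp(bias_strength) when the third base falls in the targeted class
  (GC when gc3_target > 0.5, AT below). bias_strength 3.0 with gc3_target
  0.9 lands mean ENC near 34 — the strongly biased, monocot-like regime —
  while bias 0 gives ENC 50–61, the no-preference regime. Real codon bias
  also involves amino-acid composition effects and gene-length/expression
  covariates that this generator deliberately omits; the tests show the
  statistics rank regimes correctly, not that they reproduce any particular
  genome's values.
* **Ortholog pairs** evolve a descendant by acceptance sampling: uniform
  single-nucleotide proposals, synonymous changes always accepted,
  nonsynonymous accepted with probability ω, stop-creating changes
  rejected, until a target synonymous divergence (default 0.1 per
  synonymous site) is reached. This is not a continuous-time codon model:
  the estimated Ka/Ks converges to ω only at low divergence, which is the
  regime tested (500 codons, 20 replicates recover ω ∈ {0.2, 0.5, 1.0}
  within 0.1 mean error). No indels are simulated.
* **Promoters** plant concrete motif instances at non-overlapping random
  positions (buffered by the longest library motif) on a uniform background
  that is iteratively scrubbed of chance matches outside planted intervals;
  the emitted truth counts, per library motif, the occurrences the planted
  instances account for — including inherent sub-matches (an ABRE core
  inside a planted G-Box) and palindromic double-counting. Real promoters
  have composition structure and element clustering the uniform background
  lacks.
* **qPCR tables** set Ct = baseline − log2(fold) + N(0, σ); with σ = 0 the
  pipeline recovers planted folds exactly. Amplification-efficiency
  deviations from 2.0 are not modelled.
* **Count matrices** are multinomial draws with probability ∝ TPM × length,
  the standard length-biased sampling; at library size 1e7 the pipeline
  recovers true TPM within 1%.

## Problem sizes and determinism

The validation suite runs desk-scale versions of each analysis: panels of
20 + 20 genes × 350 codons for the bias contrast, 3 × 20 replicates of
500-codon pairs for dN/dS recovery, three planted-promoter plans, and a
1e7-read multinomial for TPM — sizes chosen so the full suite completes in
well under a minute while leaving the statistical conclusions
seed-insensitive. All analysis operations are deterministic; randomness
exists only in the generators and is fully governed by the seed.

## Known limitations

* The X3s convention differs numerically from CodonW (documented above).
* NG86 with equal pathway weighting is a deliberate scope choice; no
  maximum-likelihood (GY94), LWL85 or YN00 estimators.
* The acceptance-sampling evolver biases Ka/Ks estimates slightly upward
  at higher divergence or ω near 1; keep the synonymous divergence target
  at or below ~0.15 when using it for calibration.
* The motif library is a literature-consensus stand-in, not a database
  export; counts on real promoters will differ from any specific curated
  service.
* ΔΔCt assumes perfect doubling per cycle and a stable reference gene.
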