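# Methods

## Expression screen

**Normalization.** Between-sample normalization uses the trimmed mean of
M-values (TMM). The reference sample is the one whose upper-quartile count
fraction is closest to the *median* of those fractions across samples.
For every other sample, genes with a zero count in either library are
dropped; the top and bottom 30% of genes by M-value (log₂ expression
ratio vs the reference) and 5% by A-value (mean log₂ abundance) are
trimmed on ranks (midrank ties); the log₂ factor is the
precision-weighted mean of the surviving M-values, with delta-method
weights 1/v, v = (N−y)/(Ny) summed over the two libraries. Factors are
rescaled to geometric mean 1 and near-zero log factors (<10⁻⁶) are
snapped to 0. The trim fractions and the weighting follow the original
TMM publication's defaults; the implementation agrees with the standard
R implementation to ~10⁻¹⁰ on fixtures where both reference-sample rules
pick the same sample (the rules differ only in median vs mean).

Normalized expression is counts per million on TMM-effective library
sizes: value(g,s) = count/(library·factor)·10⁶, optionally divided by
gene length in kb when effective lengths are supplied.

**Dispersion.** A single common negative-binomial dispersion φ is
estimated by the method of moments on library-equalized pseudo-counts:
per gene and phenotype group, (s² − m)/m²; group values are averaged per
gene (the combination rule is a package choice — nothing in the two-group
design privileges one group) and the estimate is the median over genes of
max(0, ·). Genes with zero mean are skipped; an uninformative matrix
returns 0.

**Exact test.** Each gene's two group sums (of equalized pseudo-counts,
rounded) are tested conditionally on their total s. Under the null, the
group-A sum given s follows the negative-binomial conditional law with
weights Γ(k+r₁)/k!·Γ(s−k+r₂)/(s−k)!, rᵢ = nᵢ/φ, which reduces to
Binomial(s, n_a/(n_a+n_b)) at φ = 0. The two-sided p-value sums P(k|s)
over all outcomes no more probable than the observed one (minimum-
likelihood method), with a 10⁻¹⁰ log-scale tolerance on the probability
comparison to absorb floating-point ties. This test is a documented
stand-in reproducing the behaviour of the conditional exact tests used
for small-replicate RNA-seq count designs; it is verified against an
independent joint-pmf enumeration oracle for all totals ≤ 50.

**Thresholds.** FDR is Benjamini–Hochberg (step-up with monotonicity
enforcement). A gene is a DEG iff FDR < 10⁻⁵ **and** |log₂FC| > 1, the
conservative double threshold this kind of candidate-panel screen uses.
log₂FC = log₂((mean_blue + c)/(mean_orange + c)) on normalized
expression with pseudo-count c = 0.125 (configurable), which tolerates
group means of exactly zero. Published log-fold-change columns produced
by shrinkage estimators will differ slightly from this raw ratio; exact
reproduction of such a column is not a goal.

**Reported fold ratios** are mean_high/mean_low rounded half-away-from-
zero to one decimal below 10 and to the nearest integer at ≥ 10, with an
∞ sentinel when the low-group mean is 0. This rule reproduces every
printed panel ratio we recompute (2.5×, 2.9×, 3.5×, 5.3×, 26×, 950×).

**Wilcoxon rank-sum.** W is the Mann–Whitney statistic (rank-sum of x
minus n_x(n_x+1)/2) with midranks for ties; p is exact by enumeration of
all labelings when n_x+n_y ≤ 12, otherwise a normal approximation with
continuity and tie corrections. Used to compare core-pathway (ABP) vs
non-ABP normalized expression.

**Heatmap scaling** is per-gene centering and unit-variance scaling with
the sample standard deviation (ddof = 1); constant genes map to all-zero
rows.

## SNP characterization

Heterozygosity can be encoded either as IUPAC two-base codes in a single
sequence per sample or as two haplotype records (`/1`, `/2` suffixes);
both canonicalize to per-site allele sets. Gaps, N, and ambiguity codes
implying more than two alleles are masked. The study species is
tetraploid; dosage is collapsed to a homozygote/heterozygote dichotomy,
so a fixed sample contributes two copies of its allele and a heterozygote
one of each; frequencies are over unmasked samples and sum to 1 across
segregating alleles. The designated allele for reporting is the
overall-minor allele; Δfreq is invariant to the designation at biallelic
sites. A site is "color-differentiating" when Δfreq ≥ `min_diff`
(default 0.25 — deliberately permissive, catching sites with any clear
tendency to separate the morphs; configurable).

Coordinates are 1-based inclusive. CDS sites are reported CDS-relative
("bpN"); codon index = ⌈offset/3⌉. Effect annotation translates each
allele's codon, completing the other two positions from the carrying
sample's own calls; if that sample is heterozygous there too, the
group-majority allele is substituted and the record is flagged
`phase_assumed` (phase is unknowable from unphased consensus sequences).
Synonymous = all amino-acid states identical; non-synonymous = exactly
two; more than two states (or a masked codon position) gives effect NA,
and the BLOSUM62 score is NA exactly when the effect is NA or synonymous
or a stop codon is involved. The effect caller is verified against a
full-CDS-translation diff oracle over 1,000 random codon contexts.

Amino-acid biochemical classes: positively charged {R,H,K}, negatively
charged {D,E}, polar uncharged {S,T,N,Q,C,Y}, hydrophobic
{A,V,I,L,M,F,W}, special {G,P}.

Residue numbers are local ungapped consensus numbering; mapping to a
named reference numbering (e.g. the grapevine DFR structure) is a pure
offset: reference = local − offset, with offset +2 for that map.

Genes assembled into multiple isotigs keep per-isotig records, and a
pooled record is additionally computed by treating each sample×isotig
pair as one observation — how per-isotig frequencies should pool is not
uniquely defined, so both views are emitted.

## Paralog comparison

Paralogs are compared on a provided pairwise alignment (alignment
computation is out of scope). Per residue, each sample contributes the
amino-acid states its codon can encode (IUPAC heterozygotes expand to
both); the consensus is the majority state, ties broken lexicographically
and flagged, and a residue is variable when any second state occurs. An
internal stop in the consensus is an error naming the residue.
Comparison classes: identical, fixed_difference (both copies invariant,
states differ), variable_in_A/B/both (variability takes precedence over
the state comparison). Domain counts tally fixed differences inside the
annotated interval.

## Synthetic data generator

The generator emulates the targeted study design; its defaults are the
study conditions: 8 samples per phenotype group; 200 background genes
with lognormal(0,1) relative abundances; library sizes uniform in
100k–200k; negative-binomial counts with common dispersion φ = 0.1; 10%
of genes planted at |log₂FC| = 3 (balanced up-in-blue/up-in-orange); one
DFR-2-like gene with relative abundance ×10⁻⁴ in blue (near-silent, as a
recruited paralog copy would be); a candidate gene with 60 bp 5′UTR,
900 bp CDS, 90 bp 3′UTR carrying 4 fixed non-synonymous inter-group
SNPs, 6 sites heterozygous in blue samples at rate 0.25 per sample, and
4 fixed UTR SNPs; and a paralog pair differing at exactly 13 of the 26
residues of a declared 133–158 substrate-specificity region, the second
copy present in orange samples only, plus 2/1 planted variable residues
outside the region. Counts and sequences use separate child RNG streams
of the one seed, so changing one block does not perturb the other.
Heterozygotes are emitted as IUPAC codes by default; haplotype-pair
emission is behind a flag. Tetraploid dosage is not simulated beyond the
hom/het dichotomy.

What the generator does **not** emulate: read-level noise and assembly
artifacts (counts are drawn directly, not assembled), isoform/splice
structure, mapping bias, linkage between sites, hybrid individuals, and
tagwise dispersion heterogeneity. Passing recovery tests therefore shows
the statistical machinery is correct under the declared model, not that
real libraries meet that model.

## Numerical and design choices

- Exact-test pmf comparisons use a 10⁻¹⁰ relative tolerance on log
  probabilities; conditional pmfs are normalized with log-sum-exp.
- BH adjustment enforces monotonicity from the largest rank down and
  caps at 1.
- Rounding of reported ratios is half-away-from-zero (not banker's).
- TMM with no genes surviving the trim yields factor 1 for that sample.
- The bundled BLOSUM62 is the standard NCBI matrix in NCBI text format;
  the loader validates symmetry and completeness for any user matrix.
- Simulation seeds are folded modulo 2³¹ into per-component child
  streams.
- Test and acceptance problem sizes (200-gene panels, 20 replicate
  seeds, totals ≤ 50 for oracle enumeration) are chosen as desk-scale
  renditions of the study design that keep the full suite in the
  minutes range.

## Known limitations

- The common-dispersion exact test has no tagwise/trended dispersion or
  GLM path; multi-factor designs are out of scope.
- Transcriptome-wide quantities (genome-wide DEG totals, assembly
  statistics, transcriptome-wide rank tests) require the deposited raw
  reads and are explicitly not reproduced.
- Frequency calculations collapse tetraploid dosage; allele frequencies
  in a true tetraploid differ when dosage varies among heterozygotes.
- Phase for double-heterozygous codons is assumed (majority background)
  and flagged, never inferred.
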