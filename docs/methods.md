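# Methods

## Genic methylation classification

Per-cytosine calls (allc-style: chromosome, 1-based position, strand,
trinucleotide context, methylated reads, total reads, methylated call)
are summarized over the CDS intervals of each gene's primary transcript.
The primary transcript is the one with the longest total CDS, ties broken
by lexicographic transcript id; sites on both strands count toward a gene
regardless of gene strand, following gene-body-methylation convention.
Contexts are derived from the trinucleotide: a following G gives CG, a G
in the third position CHG, otherwise CHH; non-CG pools CHG and CHH.
Sites with zero coverage are retained in the input but excluded from
site counts and read sums.

The background rate *b* per context is the unweighted mean over genes of
(methylated sites / covered sites), computed per species by default
(pooling summaries across species gives the pooled mode). Each gene is
tested per context with a one-tailed upper binomial p-value
P(X ≥ k), X ~ Binomial(n, b), and q-values are obtained by
Benjamini–Hochberg within each context over genes with defined p
(genes with no covered sites in a context are excluded from that family).

The decision tree is applied in the order **missing** (no covered CDS
cytosines in any context) → **teM** (q < α for CHG, CHH or non-CG with
≥ 10 sites in that context) → **gbM** (q_CG < α, ≥ 10 CG sites, CHG and
CHH non-significant) → **unM** (≤ 1 methylated site summed over CG, CHG
and CHH, or weighted methylation ≤ 2% in each of the three contexts) →
**unclassified**. α = 0.05 on q. Placing teM above gbM makes a gene
enriched in both CG and non-CG a teM gene, which the gbM rule's
"non-significant CHG/CHH" clause already forces; placing enrichment above
the absolute unM criteria resolves the (only theoretically possible)
conflict between them in favour of enrichment. The "≤ 1 methylated site"
clause is interpreted as a total across contexts, matching its paired
"≤ 2% in all contexts" alternative; a per-context interpretation is
available (`unm_rule="per-context"`). Contexts without coverage carry no
evidence against unM. A per-site binomial re-caller (error rate
ε = 0.005, call threshold p < 0.01) is provided for inputs lacking the
call column; the simulator uses the same rule to emit calls.

## Duplicate typing

Protein-level hits are filtered: self-hits removed, e-value < 1e−5,
optional same-orthogroup restriction, reciprocal duplicates collapsed to
the smaller e-value. Collinear blocks are chains of anchor pairs found by
O(n²) dynamic programming per chromosome pair and orientation: a match
extends a chain when both rank gaps lie in [1, max_gap] (max_gap = 25,
the convention of collinearity tools), with b-ranks decreasing for
inverted chains. Chains are extracted greedily best-first; chains with
fewer than 5 anchors are dropped. In self comparisons, matches closer
than max_gap ranks to the plot diagonal are excluded before chaining:
independent local duplicates (tandem/proximal pairs) otherwise line up
along the diagonal and chain into spurious "blocks" whose two segments
overlap — the standard self-synteny precaution. A genuine intra-
chromosomal duplicated segment with copies further apart is detected
normally.

To avoid overcounting, each gene retains only its lowest-e-value pair
(ties broken toward the lexicographically smaller partner); the retained
pair set is deduplicated. Pairs are then typed with priority
WGD > tandem > proximal > translocated > dispersed: WGD if the pair is an
anchor pair of an intra-genome block; tandem if rank-adjacent on one
chromosome; proximal if 2–11 ranks apart (≤ 10 intervening genes);
translocated if exactly one gene is syntenic (an anchor of any intra- or
outgroup block), that gene being the parent; dispersed otherwise. A pair
that is both adjacent and a block anchor is WGD by priority. Epochs of
translocated duplicates use a ladder of outgroups ordered closest-first:
the epoch is the 1-based index of the first outgroup against which the
daughter locus is syntenic, 0 if none (youngest) — a deliberate
simplification of sequential-exclusion epoch machinery, adequate for the
monotone age ordering it is used for.

Pair methylation classes are unordered label pairs over {gbM, unM, teM}
(six classes, gbM < unM < teM in the printed name); pairs with a missing
or unclassified gene are excluded. For translocated pairs, the parental
(syntenic) locus is taken as the ancestral state and a differing daughter
records a switch "to-<daughter label>".

## Orthogroups

Core orthogroups occur in at least ceil(0.879 × n_species) species
(51 of 58 for the default panel size; the fraction form lets any panel
reproduce the cutoff logic). Core groups are single-copy when the
fraction of species carrying exactly one gene is ≥ 0.70; the denominator
is the species in which the group is present (the "all species"
denominator is available — the phrasing "≥ 70% species" is genuinely
ambiguous and both modes are implemented). Non-core groups are
cross-family (≥ 2 families), family-specific (≥ 2 species, one family)
or species-specific (one species); genes absent from every orthogroup
become species-specific singleton pseudo-groups. Within core single-copy
groups, a species with one copy yields an SC-singleton and a species
that retained several copies yields SC-intermediates; methylation
contrasts between the two use a pooled two-proportion Z-test.

## Ka/Ks (NG86)

Synonymous site counts per codon are the fraction of the nine possible
single-nucleotide changes that preserve the amino acid (changes to stop
codons count as nonsynonymous); S is averaged over the two sequences and
N = 3 × codons − S. Observed differences are averaged with equal weight
over all orderings of the differing positions, excluding pathways through
stop codons (if every pathway is blocked — possible only for some
three-difference codon pairs — all pathways are used with stop-passing
steps counted as nonsynonymous, so difference mass is not lost). Codons
with gaps, ambiguity or an observed stop are dropped pairwise. Distances
use Jukes–Cantor, d = −(3/4) ln(1 − 4p/3), undefined at saturation
(p ≥ 0.75, flagged). ω = Ka/Ks is undefined when Ks = 0. NG86 stands in
for rate-heterogeneous codon estimators because it is exactly
specifiable and testable against brute-force pathway enumeration; an
import path for externally computed Ka/Ks tables preserves fidelity for
real-data reruns. No default Ks cap is applied; `max_ks` filters
saturated pairs on request.

## Expression specificity

τ = Σᵢ (1 − xᵢ / max x) / (n − 1) on linear normalized values (log2(x+1)
mode available; linear is the default because a log transform forces a
pseudo-count choice). Silent genes (max = 0) are excluded as τ is
undefined. Matrix columns are used as conditions as given; replicate
collapsing belongs upstream. Pair divergence is the Pearson correlation
across conditions (undefined for zero-variance profiles) and |Δτ|.

## Association statistics

Fisher tests are two-sided by the minimum-likelihood convention (sum of
hypergeometric probabilities ≤ that of the observed table, within 1e−7
relative tolerance); odds ratios ad/bc carry ±∞/0 sentinels for zero
cells plus a Haldane–Anscombe (+0.5) version for plotting. Enrichment
scans cross a label partition with a category partition over one gene
universe — genes labelled missing/unclassified are excluded by default
(the analyses test gbM/unM/teM only) — and BH is applied across all
tests of one scan. TE association extends the gene body by 1 kb on both
sides. Sliding windows tile each chromosome from 0 (100-kb windows,
50-kb steps, last window truncated); a gene is counted in every window
containing its midpoint (avoiding gene-length bias; each gene falls in
exactly one window of each 50-kb phase), and windowed class counts are
correlated (Pearson, t-based p, BH) with gene counts, TE counts and TE
base pairs. PAV genes have coverage < 0.2 (strict) in ≥ 1 accession.
Population epiallele frequencies are per-gene class fractions over
accessions with data; bins are exactly-0, then left-closed: 0%, (0,25)%,
[25,50)%, [50,75)%, [75,100]% — the bin labels overlap at their printed
boundaries, so the left-closed rule is fixed here and applied
consistently.

## Synthetic data

The generator emulates the statistical structure the analysis assumes,
with every stochastic draw flowing from one integer seed through named
substreams per output (adding an output never perturbs another; identical
seed + config give byte-identical files).

- **Genome**: 3 chromosomes × 300 genes (uniform 5-kb spacing, single
  1.2-kb CDS per gene), mirrored gene-for-gene by an outgroup genome so
  ancestral genes are syntenic. Planted events occupy reserved,
  non-overlapping rank windows: one 10-gene WGD block copied to another
  chromosome, and 20 each of tandem (adjacent copy), proximal (2–10
  intervening genes), translocated (daughter inserted on another
  chromosome, absent from the outgroup) and dispersed (two distant
  ancestral genes). Planted hit e-values are ≪ 1e−5; spurious hits
  (default off, 5% in robustness tests) are drawn between random genes
  at higher e-values.
- **Methylome**: site counts per context are Poisson around 30 CG /
  25 CHG / 60 CHH per gene; coverage is Poisson(20); methylated reads
  are Binomial(coverage, rate) with class rates gbM (0.85, 0.01, 0.01),
  teM (0.90, 0.65, 0.10), unM (0.005, 0.005, 0.005) for (CG, CHG, CHH);
  the call column applies the binomial re-caller at ε = 0.005. The class
  mix is 30% gbM, 25% teM, 45% unM.
- **Sequences**: ancestors uniform over sense codons (300 codons); one
  lineage accrues round(Ks·S) synonymous and round(ω·Ks·N) nonsynonymous
  substitutions with stop codons rejected, so NG86 estimates scatter
  around the targets (median ω recovered within 20% at Ks ≈ 0.2).
- **Expression**: profiles are Dirichlet draws whose mean realizes the
  target τ exactly (one dominant condition, others at 1 − τ) at high
  concentration (3 × 10⁴), chosen from the analytic bias estimate so the
  max-normalized τ of a draw is unbiased within 0.05 even at low
  targets; class targets are gbM 0.2, unM 0.5, teM 0.8 (broad gbM,
  narrow teM). Rows are scaled lognormally.
- **Orthogroups**: a 58-species, 8-family panel mirrors the default
  core threshold (51) literally; categories are planted by construction
  and recovered exactly by the deterministic rules.
- **TEs** are placed within 1 kb upstream of genes with probability 0.8
  (teM) vs 0.1 (others), the gene spacing guaranteeing a TE associates
  only with its own gene.
- **Population**: 928 accessions; each accession keeps a gene's base
  class or switches per a configurable rate matrix (defaults: small
  rates, teM→unM largest at 0.10), with 2% missing data.
- **PAV coverage**: ~1× lognormal coverage with 5% of genes dropped
  below 0.2 in one accession.

What the simulator does *not* emulate: linked methylation along
chromosomes, realistic TE sequence content, gene-length and GC
heterogeneity, partial bisulfite non-conversion, expression replicate
structure, and population structure among accessions. Passing recovery
tests therefore demonstrates correctness of the inference rules under
the stated generative model, not robustness to every artefact of real
WGBS data.

## Numerical choices and degenerate inputs

Binomial tails come from the scipy survival function; b = 0 gives p = 0
for any methylated site (logged) and p = 1 otherwise; contexts absent
from the whole dataset get undefined background and undefined p.
Weighted methylation, τ, Pearson r, Ks/Ka at saturation and ω at Ks = 0
are NaN ("undefined") rather than sentinel numbers, and NaNs are
excluded from BH families and group summaries with counts reported.
E-value and chain ties break lexicographically (logged where relevant);
DP chain ties prefer the earliest match. The two-proportion Z-test
returns (0, 1) for pooled proportions of 0 or 1. Problem sizes in tests
(≈ 1,000–2,000 simulated genes, 90 planted pairs, 500 oracle codon
pairs, 1,000 null scans) were chosen as the smallest sizes at which the
recovery and calibration properties are statistically meaningful.

## Known limitations

- NG86 underestimates ω when transition/transversion bias or codon
  frequencies matter; import externally computed tables for real data.
- The collinearity chainer resolves overlapping chains greedily and does
  not score blocks by e-value; it is a block *detector*, not a
  polyploidy dater.
- The epoch ladder assumes outgroup order equals divergence order and
  ignores lineage-specific losses.
- Orthogroup categorization trusts the input membership table; no
  inference is attempted.
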