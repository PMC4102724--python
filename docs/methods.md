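# Methods

## The problem and the model

A draft genome assembled from pyrosequencing reads carries single-base
insertion/deletion errors concentrated in homopolymer runs (the
flow-signal intensity saturates with run length). Inside coding regions
such an indel frameshifts the gene model, typically splitting one gene into
two annotated fragments or creating a spurious pseudogene. Two orthogonal
evidence layers can repair and audit the annotation:

* **Transcript depth and variant calls.** Deep RNA-seq alignments against
  the draft call the indels directly. We accept a call when it is a
  single-base indel in homopolymer context, or otherwise corroborated.
* **Peptide identifications.** MS/MS spectra searched against a naive
  database built from six-frame translation of the raw sequence — rather
  than from annotated proteins — detect coding regions independently of the
  gene caller, flagging missed genes, wrong frames and short-started genes.

## Coordinate and sequence conventions

All coordinates are 1-based inclusive on the forward strand of a single
replicon; GFF3 input is converted at the boundary. Wrap-around
(origin-spanning) features are rejected. Frame labels are +1/+2/+3
(starting at positions 1/2/3) and −1/−2/−3 (starting at the last position
of the reverse complement). Translation uses the standard code; start-codon
nuances are irrelevant because stop-to-stop extraction needs no starts.
Codons containing N translate to X, and X terminates an element — a
conservative rule that never fabricates peptides from ambiguous sequence.

## Proteogenomic database

Each source sequence is translated in all six frames; maximal stop-free
segments (*stop-to-stop elements*) of ≥ 7 residues are kept. Elements are
digested with trypsin: cleave after K or R, suppressed before P (the
standard rule; configurable off), fragments with ≤ 1 missed cleavage and
length 7–50 aa. The length bounds follow MS detectability norms; the
digestion parameters are the workflow's stated ones. The database is a set
union over elements — duplicate peptides collapse, every origin
`(source, frame, offset)` is recorded, and the FASTA export groups peptides
by element ("collections of connected tryptic peptides"), which is how such
databases are fed to spectrum search engines.

A consequence worth noting: a protein's N-terminal tryptic peptide is *not*
a digest product of its surrounding stop-to-stop element (the element's
upstream boundary is a stop codon, not a cleavage site), so the synthetic
generator samples internal fragments only when emulating detected
peptides.

## Peptide classification

Peptides passing the reporting filter (log10 expectation < −1, strict) are
searched exactly (substring, I/L distinct by default; an I/L-equivalent
mode folds both to L). Categories, in precedence order per peptide:

1. **assigned** — some hit lies fully inside an annotated CDS in that CDS's
   frame;
2. **alternate_frame** — a hit inside a CDS span but in a different frame;
3. **extension** — a hit upstream of a CDS start, in the CDS frame, within
   the same stop-to-stop element (no intervening stop);
4. **novel_gene_evidence** — ≥ 2 same-frame peptides, pairwise gap ≤ 2000
   bp, overlapping no annotation (the proximity window quantifies "nearby
   coordinates", which the workflow leaves informal);
5. **unassigned** — everything else, including peptides with no genomic hit.

Extension and alternate-frame hits are deliberately excluded from the
missed-gene grouping: an analyst explains a peptide against existing gene
models before positing a new gene, and without this precedence the two
extension peptides of a short-started gene would masquerade as a novel ORF.
Multi-locus peptides count toward coverage at every in-CDS hit and are
flagged rather than disambiguated (paralogy resolution by homology search
is out of scope).

Per-protein coverage is the percent of residues touched by ≥ 1 assigned
peptide, nearest integer, half up; protein length excludes the stop codon.

## Retention-time validation

Identification quality is audited globally: predicted hydrophobicity
`H = Σ residue coefficients − 0.30·max(0, L − 10)` (first-order additive
coefficients after Krokhin et al. 2004, shipped as package data; the mild
length term damps the naive sum for long peptides — the full SSRCalc
algorithm is deliberately out of scope) is correlated with observed
retention time; R² is the squared Pearson correlation. Genuine assignments
correlate strongly, spurious ones sit near zero. The synthetic generator
produces retention times as `RT = 8.0 + 0.55·H + N(0, σ)` minutes for
genuine peptides (σ = 1.0 by default) and uniform over the elution window
for decoys, so the noiseless case is exactly collinear (R² = 1) and the
decoy case is independent of H.

## Base pair maps and coverage

A base map is one numeric value per genome position: read depth densified
from a `(position, depth)` track, or peptide evidence where every hit adds
its weight (1 per identification, or spectra count as the available
intensity proxy) to each encoding nucleotide. A position is covered at
value ≥ 1 — the depth cutoff is not specified by the workflow, so ≥ 1 is
declared, and "completely covered" means every base covered at that
threshold. Coverage is positional, not stranded. Percent formatting
follows the printed style of genome reports: nearest integer (half up),
except one decimal place within 5 points of 0 or 100, where integer
rounding misleads (97.50% must not print as 98%). Masked FASTA atlases
write covered bases as themselves and uncovered bases as dashes, wrapped
at 70 columns.

## Correction and liftover

Variant calls are classified against the genome being corrected: an indel
is homopolymer-class when the indel base plus identical adjacent bases
forms a run ≥ `min_run` (default 3; for deletions the run containing the
deleted base, for insertions the neighbours plus the inserted base). This
symmetric rule makes the inverse of a homopolymer error homopolymer-class
itself, which the round-trip invariants require. Application policy:
homopolymer indels are applied; substitutions and complex variants only
when corroborated by a review suggestion at the same locus or by an
independent genome sequence; everything else is recorded unapplied. The
policy is declared, not derived — the source workflow never states why
specific calls were left unapplied.

Edits are specified in original coordinates (insertions land after their
position), checked against the reference allele, required non-overlapping,
and applied in one left-to-right pass. The offset map stores
`(threshold, cumulative shift)` breakpoints — prefix sums of applied
offsets — so liftover is `p ↦ p + shift(p)`; a boundary inside a
multi-base deleted block is an error naming the locus. Output tables
report positions in the printed-table convention: corrected-sequence
coordinates for insertions and substitutions, former coordinates for
deletions. Two calls at the same position are treated as independent rows.

## Annotation review

Decision rules are total over suggestions: a pseudogene flag with 0%
peptide coverage is confirmed, with any coverage rejected; a join is
applied when a member has coverage and an applied correction restores the
frame, otherwise rejected; other suggestion kinds record `no_change`.
"Frame restored" is operationalized as: the joined interval, after
correction and liftover, translates stop-free from the upstream start to
the downstream stop (the source workflow says only that frames were intact
after correction).

Clusters are maximal runs of same-category, same-strand, consecutive loci;
singletons count as clusters — required to reconcile the transporter
table's 42 rows with its fully-covered-cluster count of 8 (a figure legend
counting only multi-gene systems says seven; the text's definition is
followed). Pathway completeness matches curated product-name patterns per
role symbol (EC matching would be an extension); a step with no matching
annotation is flagged missing, and a present step with 0% coverage is
present-but-unsupported.

## The synthetic world

Defaults scale the study system down ~50×: a 60 kb circular genome, 40
non-overlapping ATG..stop ORFs of 80–280 aa (GC 0.40), 4 RNA genes, 2
pseudogenes. The homopolymer error rate of 0.5/kb keeps the *absolute*
error count (~30) comparable to the real study's 35 on a 50× smaller
genome; two substitution miscalls and three spurious variant calls are
added. Depth is 1 + Poisson(24) per base with 2 uncovered gaps of 200–600
bp placed uniformly. Protein detectability is Bernoulli(0.68) per
non-pseudo CDS with ~4 sampled tryptic peptides per detected protein and a
4.5% decoy fraction (residue shuffles verified absent from all six frame
translations) — the 0.68, ~4 and 4.5% come from the study's printed counts
(1755/2580 proteins, 6611 peptides, 312/6923 unassigned). Three novelties
are planted per dataset: an unannotated ORF with two uniquely mapping
peptides, a gene annotated 24 codons downstream of its true start with two
peptides in the extension, and a stop-free 12-codon out-of-frame window
inside an annotated gene. Genes receive real pathway product names with
transaldolase deliberately withheld, so pathway review always finds
exactly that hole. A single seeded generator stream drives everything;
one integer reproduces a dataset byte for byte.

What the generator does **not** emulate: read-level sequencing (no FASTQ
qualities, no alignment), search-engine score distributions (log(e) values
are uniform), peptide ion currents (spectra counts stand in), operon
structure, overlapping genes, and wrap-around features. A green test
therefore establishes the correctness of the pipeline's arithmetic and
classification logic on data with the stated structure — not robustness to
alignment artifacts or spectral misidentification beyond the decoy model.

## Numerical choices and degenerate inputs

Rounding is half-up throughout (matching printed tables, not banker's
rounding). R² is defined as 0.0 for fewer than three points or zero
variance. Empty correction sets are the identity; an empty peptide
database is produced with a warning. Ties in edit positions are an
overlap error rather than silently ordered. The detection-probability
calibration test uses 200 replicates of a reduced configuration (20 genes,
24 kb) purely for speed; the replicate checks of correction round-trips,
selection precision/recall and novelty recovery use 20 seeds of the
default configuration.

## Known limitations

* Exact substring matching cannot model peptides spanning sequencing
  errors; classification is therefore run on the corrected genome.
* The corroboration model for substitutions (suggestion locus or
  independent-genome concordance) is binary; no quality scores are
  propagated.
* Cluster detection assumes a correctly ordered annotation; it does not
  re-examine intergenic distances.
* The packaged study tables are transcriptions of printed tables; where the
  source prose and its own table disagree (a gene-count total, a
  corroboration tally), the table as printed wins.
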