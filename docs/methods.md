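# Methods

This note documents the models and procedural choices behind
`paleoplastid`: what each stage computes, the parameters that matter, what
the synthetic datasets do and do not emulate, and where the design was
genuinely open.

## The reconstruction problem

A secondary plastid is serviced by hundreds of nucleus-encoded,
plastid-targeted proteins. Reconstructing the *ancestral* plastid proteome
of a lineage, and assigning each protein an evolutionary donor, requires
chaining several analyses that are individually simple but interact
tightly: orthogroup assembly, taxonomic conservation calls, alignment
curation, gene-tree interpretation, residue-level synapomorphy counting,
chimera detection and enrichment statistics. The package implements that
chain as a library of small, separately testable operations plus an
orchestrating pipeline.

## Orthogroup assembly with a floating threshold

Orthologue admission is relative, not absolute: each seed's hits against a
designated outgroup library (every lineage without a history of secondary
endosymbiosis) define a cap — the e-value, bitscore and rank of the
rank-1 outgroup hit. A candidate joins the seed's group only when its
e-value is *strictly below* the cap; when both e-values underflow to zero
the hit-list rank decides. An absent outgroup hit yields an *open* cap,
which admits everything and is flagged for review. Seed merging is the
transitive closure of the same admission predicate over all seed pairs,
with one seed retained per cluster — first by a configurable organism
precedence list (genome species first), then by the lowest e-value against
the seed's own outgroup top hit. Members are N-terminally trimmed to their
first methionine before taxonomic binning; members without a methionine are
excluded with a log message.

## Conservation patterns and curation

The three patterns (chrysista ≥ 2/3 ∧ diatoms ≥ 3/5; chrysista ≥ 2/3 ∧
hypogyristea ≥ 2/3; chrysista ≥ 1/3 ∧ hypogyristea ≥ 2/3 ∧ diatoms ≥ 3/5)
are evaluated inclusively on counts of sub-categories with at least one
member. `select_conservation_patterns` ranks arbitrary candidate patterns
by a 2×2 Pearson χ² (no continuity correction) of pass/fail against
positive/negative control sets, so the built-in patterns can be re-derived
from controls rather than assumed.

Curation formalises what is usually done by eye: the conserved domain is
bounded by the first and last alignment column in which ≥ 70% of members
are identical or BLOSUM62-positive to the column's modal residue. A member
is removed when its first residue lies more than 50 *consensus positions*
(columns with ≥ 50% occupancy) after the domain start — the length scale of
a plastid-targeting presequence — or when its last residue precedes the
domain end. Conservation is re-evaluated afterwards; groups that no longer
pass any pattern are eliminated. Column trimming follows trimAl's
gap-threshold semantics: a column is kept iff its non-gap fraction is
≥ 0.5, boundary inclusive.

The gene-tree check accepts a group when some clade (either side of any
edge, so unrooted trees are handled) holds enough ochrophyte
sub-categories to satisfy a pattern while its non-ochrophyte leaves all
belong to a single one of five interrupting groups (prokaryotes, red
algae, green algae, aplastidic stramenopiles, other eukaryotes); leaves
from lineages with histories of higher-order endosymbiosis (CASH,
chlorarachniophytes, euglenids) are transparent to this test. Trees with
fewer than four leaves are uninformative.

## Origin assignment

Two independent signals are combined. The ranked-hit rule reports the
lineage of the rank-1 hit, *determined* only when the first three or more
hits share it. The tree rule first prunes CASH-lineage leaves (their
placement is the subject of a separate analysis, below), then roots the
tree and reads the focal clade's sister. "Root on the most phylogenetically
complex node" is operationalised as: among all edges except the focal
clade's own subtending edge, take the side containing no focal leaves and
root on the edge whose far side spans the most distinct lineages (ties:
most sub-categories, then most leaves, then the lexicographically smallest
leaf label). Excluding the focal edge is essential — otherwise the
complement of the focal clade always wins and the sister group degenerates
to the entire rest of the tree. The sister contributes an origin only when
the focal lineage is monophyletic, exactly one sister exists, and the
sister holds ≥ 2 sequences from ≥ 2 sub-categories of one lineage.
Agreement of the two signals gives a high-confidence combined origin;
disagreement leaves the call unresolved, annotated by the tree sister when
available, else by the top-hit lineage. Deeper affinities iterate the same
rules on the suffix after the primary lineage's hit prefix, or on the
sister of the (focal + primary sister) clade.

The CASH position analysis classifies where a lineage's clade attaches
relative to the focal clade (internal to one of the three ochrophyte
groups, internally ambiguous, immediate sister, within red, within green,
or elsewhere), recording a position only when the lineage forms a single
clade with ≥ 2 sub-categories (alveolates, cryptomonads, haptophytes) and
≥ 1 plastid-predicted member (dinotoms, cryptomonads, haptophytes). A
clade whose closest non-CASH context is the *complete* focal clade is
external (immediate sister), not internal.

## Synapomorphic residues

After a strict vertical-inheritance screen of the gene tree (no watched
lineage may split into two multi-sequence clades separated by ≥ 2 outside
sequences, with documented paraphyly allowances) and per-sequence
ranked-hit validation, alignments are reduced to one sequence per
sub-category and scanned column by column. A column qualifies when some
residue is held by ≥ 2/3 of the ungapped focal sequences, at least one
donor holds it, no exclusion sequence holds it, and at least one exclusion
sequence is ungapped there (so absence is evidence, not missing data).
Each residue maps to the deepest node of a reference topology whose clade
has more matching than non-matching-or-gapped leaves; in earliest mode
gaps count as matches. Candidate nodes are restricted to ancestors of the
matching leaves, which guarantees the earliest node is an ancestor-or-equal
of the observed one. Composition-bias filtering flags amino acids whose
frequencies differ between two lineages (per-residue 2×2 χ², p ≤ 0.05) and
gaps them out of the alignment.

## Chimera detection

Hits at e-value ≤ 1e-5 (boundary inclusive) become components labelled
with their subject's lineage. Components overlapping by more than 70% of
*each* length join one family (transitive closure); families whose span is
covered > 70% by another's are merged, applied in canonical span order so
the fixed point is deterministic and input-order invariant. A family's
origin is the unanimous lineage of its top three members by bitscore
(unanimity over what exists for smaller families — the published rule is
silent below three). A protein is chimeric when two assigned families of
different lineages fail the mutual-overlap rule; N- and C-terminal domains
are ordered by span midpoint.

## Decontamination

For every ordered library pair, each contig contributes the percent
identity of its best significant (e ≤ 1e-5) cross-library hit to a
1-point histogram over [0, 100]. After moving-average smoothing (window 3,
edge-replicated so the terminal bin is not diluted), the threshold is the
valley minimum strictly between the highest between-species peak and the
near-identity ([99,100]) mass, ties toward the lowest identity; no
near-identity mass, a unimodal shape, or a valley not strictly below both
peaks gives no threshold. A contig is flagged when its best cross-library
identity exceeds the pair's threshold *and* lies in the near-identity
region (≥ 97%) where verbatim assembly carryover is expected — a
mid-identity cross-library match is ordinary interspecies homology. When
per-contig coverage is available, the higher-coverage copy of a flagged
pair is retained (flagging requires the contig's abundance to fall below
one fifth of its partner's): a genuine transcript and its carryover copy
are sequence-identical, so relative abundance is the only signal that
distinguishes source from contaminant, as in published cross-contamination
screens of multi-species transcriptome projects.

## Targeting

The built-in plastid predictor implements the synthetic presequence
grammar: an N-terminal hydrophobic signal region (a run of ≥ 6 hydrophobic
residues beginning within the first 15) followed by an ASAFAP-like motif
within the first ~60 residues. It is a stand-in with the same interface as
external predictor adapters (TSV of seq id, tool, call, score), not a
reimplementation of any published tool. The mitochondrial scorer is a
composition rule — net R/K minus D/E charge of the first 20 residues,
scaled to [0, 1]. The dual-targeting screen scores the full N-terminus
and, when a methionine occurs at precursor positions 2–31, the alternative
N-terminus from the first such methionine; a plastid-targeted protein is
dual when either score reaches 0.35. Family consensus requires the
plurality call to cover ≥ 2/3 of members (for three-member haptophyte-style
families, the ≥ 2/3 rule alone).

## Enrichment statistics

All observed-versus-expected tests use a two-cell goodness-of-fit χ² on
[in-category, remainder] vs [expected, total − expected] with one degree
of freedom; its type-I error at α = 0.05 is verified to sit in
[0.03, 0.07] over 2000 multinomial null simulations. The
uniquely-shared-group expectation offers two corrections. The default
(`published`) reproduces the published worked arithmetic exactly: for an
ordered (focal, partner) pair with involvement proportions p, E = total ×
p_f·p_p / (1 − p_p²), so proportions (1/2, 1/2) give one third. The
alternative (`normalized`) rescales all cross-pair products so the
expectations sum exactly to the observed cross-pair total. The two differ
because the published arithmetic excludes only the partner lineage's
diagonal mass; both are exposed because no single formula satisfies both
the published example and mass conservation.

Coexpression analysis computes Pearson correlations over all gene pairs,
grouped into origin-pair classes. An origin class is *flagged* as showing
origin-specific coregulation only when its within-class mean exceeds every
cross-class mean with each one-way comparison significant at a
Bonferroni-adjusted level (α divided by the number of separation
comparisons in the whole table), so α acts as a family-wise error rate.
With a dozen raw tests per dataset, a per-comparison flag rule would
produce spurious "origin-specific coregulation" in roughly half of all
null datasets; the family-wise rule keeps the per-dataset null flag rate
near 2%. Pair correlations sharing a gene are not independent; the raw
p-values are heuristic and interpreted only through this conservative
flag rule.

## The synthetic data generator

The generator is the package's study design. Families of designated donor
origin (defaults: 10 red algal, 6 green algal, 5 host/aplastidic
stramenopile, 5 prokaryotic) evolve from random root sequences (BLOSUM62
background composition, 240 residues) along per-origin gene-tree templates
in which the ochrophyte clade nests *inside* the donor lineage's clade.
Branch lengths come in three classes — short ochrophyte-internal edges
(0.7 units), donor/outgroup edges (1.8) and deep rooting edges (5.0), at
0.05 substitutions per site per unit — chosen so that in-group hits always
outrank the outgroup cap, donor hits outrank deep outgroups, and sister
libraries sit near 93% identity, clearly below the near-identity
contamination peak. Indels (0.004 events/site/unit, lengths 1–3) are
tracked against a master column registry so true multiple alignments are
emitted alongside the sequences. Plastid-targeted families (85/80/35/35%
per origin, planting the endosymbiotic targeting-enrichment signal) carry
per-member presequences of 30–50 residues; 15% of plastid families are
dual-targeted via an internal methionine followed by an R/K-rich stretch;
truncated members (4%) and per-member presequence dropout (5%) exercise
curation and consensus calls. Contamination copies contigs verbatim into
foreign transcriptome libraries at rate 0.02 with carryover-scale
abundance (0.5–5% of the source). Six fusion proteins join mature halves
of two plastid families with different origins (breakpoints at 40–60% of
each parent) and then diverge by ~12.5% so they resemble genes, not
contaminants. Haptophyte clades nest inside the hypogyristea in 25% of
plastid families and attach as immediate sister to the ochrophytes in a
further 15%, planting the CASH position signal. Expression profiles share
correlation blocks assigned independently of origin (ρ = 0.6, 24
conditions) — a built-in null for the coexpression analysis.

The similarity scorer computes exact best local alignments (BLOSUM62,
affine gaps 11/2) via Biopython's pairwise aligner, converts scores with
Karlin–Altschul constants (λ = 0.267, K = 0.041) and e-value = m·n·2^(−bit),
and prefilters candidate pairs by shared 4-mers (≥ 3). One optimal local
alignment can bridge two homologous regions of a fused protein through a
weakly scoring junction, which no per-hit e-value filter can undo; emitted
hits are therefore segmented BLAST-style — at gap runs longer than 10
columns, at sustained negative-similarity stretches (25-column sums
negative across ≥ 15 consecutive offsets; genuine HSPs score positively on
average, random bridges do not), and by X-drop (35) within a segment. The
practical consequence of occasionally splitting a genuine alignment is two
same-lineage hits, which no downstream rule misreads.

What the generator does **not** emulate: realistic site-rate heterogeneity
or substitution processes (substitutions are i.i.d. draws from background
composition), gene duplication and loss, alignment error (emitted
alignments are exactly true), targeting-signal divergence (presequences
are generated per member, not evolved, so the built-in predictor's
near-perfect accuracy says nothing about real predictors), incomplete
lineage sorting, or assembly artefacts other than verbatim carryover.
Passing recovery tests therefore demonstrates the *pipeline logic* —
thresholds, closures, tree rules, counting — not robustness to real-data
noise.

## Problem sizes and determinism

The default design (26 families, ~470 sequences, 11 ochrophyte libraries)
runs end-to-end in well under a minute and is the scale at which the
recovery tests and the acceptance script operate; the oracle-equivalence
suites run 100 random instances each at up to 30 sequences, 50 columns or
15 components. Every random choice in the generator and pipeline flows
from one integer seed through `numpy.random.default_rng`; stage outputs
are written in sorted order and reruns are byte-identical, which the test
suite and the acceptance script both verify by hashing all tabular
outputs.

## Known limitations

* The single-run pipeline replaces the triplicated manual tree annotation
  of interactive workflows; for a deterministic implementation the
  consistency step is vacuous.
* Multiple-testing correction is reported raw by default (a
  Benjamini–Hochberg column can be enabled) to match standard practice in
  this analysis family.
* The CASH position classifier reads the closest non-CASH context above
  the clade; reticulate placements (a lineage attaching twice) are
  reported as not recorded rather than resolved.
* `expected_unique_shared` exposes two incompatible corrections (see
  above); consumers must choose explicitly.
* Percent identity is computed over alignment columns of the reported
  segment, which for heavily gapped hits differs from identity over
  matched positions only.
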