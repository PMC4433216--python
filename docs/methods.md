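# Methods

## The authentication problem

A market sample is sold under the name of one of eight approved medicinal
species. Authentication asks two separable questions: *is it the labelled
species?* (molecular) and *does it carry the required chemical marker at the
pharmacopoeial minimum?* (chemical). The package answers both and fuses
them, because each control alone admits dangerous failure modes: a
substitute can pass chemistry (non-specific markers such as tannins) and a
correct species can fail it (degraded or adulterated material).

## Molecular identification

**Quality filtering.** Trace-derived sequences carry per-base Phred quality
values. Bases with QV < 15 (error probability ≈ 3.2%) are masked to N; a
record whose low-quality fraction exceeds 0.5 — "the majority" of the
sequence — is discarded and the sample propagates as *no sequence* at that
marker. The 0.5 operationalization is a deliberate literal reading of a
qualitative discard rule; it is configurable. Database references carry no
QV and pass through with a warning.

**Alignment.** References and queries are star-aligned into the coordinate
frame of an anchor sequence (the first reference) with match +1 /
mismatch −1 / gap −2 and free terminal gaps, so truncated fragments align at
no cost. Equal-length sequences are taken as positionally homologous
without invoking the aligner: the markers are near-indel-free coding
regions, and running an end-gap-free aligner on equal-length pairs would
spuriously trim terminal mismatches. Insertions relative to the anchor have
no column and are dropped. A full progressive MSA was rejected as
unverifiable by brute force for no benefit at these divergences. Distances
are computed on the complete-deletion mask: every column carrying a gap or
ambiguous base in any row is removed, which makes the mask independent of
row order. Combined-marker analyses concatenate masked columns in matK,
rbcL, ITS2 order; samples missing any constituent marker are excluded and
reported.

**Distances.** The p-distance is mismatches over mutually unambiguous
sites; similarity is 100·(1 − p). The K2P distance is
d = −½ ln[(1−2P−Q)√(1−2Q)] with P, Q the transition/transversion
proportions. Saturated pairs (1−2P−Q ≤ 0 or 1−2Q ≤ 0) are flagged
undefined, never returned as infinities; tree building refuses matrices
with undefined entries. d ≥ p always holds on the valid domain; the
triangle inequality is *not* guaranteed for K2P and nothing downstream
assumes it.

**Similarity rule.** The operative identification criterion is the 98%
similarity cutoff, with similarity defined as percent identity on the
pairwise-comparable masked sites (the source workflow never defines
"similarity"; p-distance identity is the conventional barcode-database
choice, and the definition is recorded in every run log). References within
the cutoff and within 0.2 percentage points of the best hit form the hit
set; "equal similarity" as exact float equality is measure-zero, so the tie
tolerance is explicit and configurable. Rank assignment: one species →
species; several species of one genus → genus; several genera of one family
→ family; otherwise (or no hit ≥ 98%) unidentified; missing marker → no
sequence. Consolidation across markers and marker combinations lets the
finest rank win and backs off to the deepest common ancestor rank on
conflicts, setting a conflict flag. NJ trees are retained as a QC
artifact; identification is similarity-based because that is the only
quantified rule.

**Neighbor joining.** Standard agglomeration on Q(i,j) = (r−2)d(i,j) −
Σd(i,·) − Σd(j,·) with the usual branch-length and reduction formulas.
Ties in Q are broken by the lexicographically smallest contained-label
pair, making topology independent of input order. Negative branch lengths
are clamped to zero with the deficit moved to the sibling edge
(Kuhner–Felsenstein) and logged. Trees are unrooted (degree-3 seed node);
bootstrap resamples masked columns with replacement (default 500
replicates), maps bipartition frequencies onto the point-estimate tree
(rather than building a majority-rule consensus — the point-tree convention
was chosen for interpretability), and redraws replicates with undefined
distances up to 10 times before counting them as non-supporting.

## Barcode gap

Per genus and per marker frame, reference pairwise distances split into
intraspecific and interspecific multisets (|intra| + |inter| = n(n−1)/2).
"Clear distinction" between the classes is operationalized as strict
separation, max(intra) < min(inter) — the only parameter-free reading; the
frequency histogram (default bin width 0.001 substitutions/site) is a
report artifact and never enters the decision. A monotypic genus has no
interspecific class and the gap is *not applicable*. Classification of a
within-genus query uses its minimum distance to any conspecific voucher
(nearest-voucher convention): above max(intra) → substitution; at or below
it → authentic in the default *resolved* mode when a gap exists, otherwise
inconclusive (*strict* mode never resolves to authentic, preserving the
cautious reading). Gap analyses are computed on references only; queries
can be included by flag. In the pipeline, a species-rank assignment
matching the labelled species is authentic directly; the gap refines the
genus-rank (species-unresolved) cases, in the widest marker frame the query
covers.

## Chemistry and fusion

Each marketed species has a `ChemicalSpec`: marker compound, minimum
concentration (% m/m or mg/g), assay (HPLC or UV), after a TLC presence
screen. `meets_minimum` uses ≥, not >: a measurement exactly at the
minimum passes (the inclusive boundary is required by a printed
boundary-case sample described as meeting its minimum). A TLC-negative
sample quantified above minimum is flagged inconsistent.

Concordance colours partition the {expected-side, not-expected} ×
{present, absent} grid plus a *missing* class:

- missing — no sequence, or chemistry not tested;
- red — marker absent;
- green — marker present and molecular evidence expected-side (authentic,
  or within the expected genus pending species resolution);
- yellow — marker present but molecular evidence not expected-side
  (substitute or unidentifiable).

The grid cell "expected-side but marker absent" genuinely occurs in market
data; it is coloured red and carries the hazard flag
`authentic_fails_chemistry`, keeping *red ⟹ marker absent* exact and the
three colours a clean partition. The other hazards are
`substitute_passes_chemistry` (substitute ∧ meets minimum — the consumer-
safety case) and `authentic_fails_concentration` (correct species below
minimum; encoded as a flag rather than a fourth colour because presence and
concentration are successive tiers of the same chemical test).

**Accounting.** Study summaries use a fixed three-tier denominator scheme,
printed with every row: total samples → sequenced (total minus no-sequence)
→ conclusive (sequenced minus inconclusive). Percent inconclusive is
reported on the sequenced denominator; percent substitute and authentic on
the conclusive denominator, so they sum to 100%. Unidentifiable sequences
count as substitutes by default (they demonstrably are not the labelled
species); this is configurable. Percentages are formatted to two decimals
with a configurable rounding convention (round-half-up default, truncation
available, because published tables mix both).

## Synthetic-data generator

The generator defines the study conditions rather than emulating any real
dataset. Topology is fixed and deterministic: one global root; genus
ancestors at depth `intergenus_scale/2` (default 0.10); species ancestors
radiating star-like from each genus ancestor at `inter_scale/2` (default
0.03); vouchers (default 5 per species) at `intra_scale/2` (default 0.002).
Expected pairwise divergence is thus ≈ intra within species, ≈ inter + intra
within a genus, ≈ intergenus between genera. Sites evolve independently
under a two-rate (Kimura-type) process with transition/transversion ratio
κ = 2, rates normalized so branch lengths are in expected substitutions per
site — the regime in which the K2P estimator is consistent, enabling exact
calibration checks. Fixed star topologies were chosen over birth–death
sampling for reproducibility and closed-form expectations.

Defaults per marker: matK 500 bp, rbcL 550 bp, ITS2 350 bp. Queries
(default 200) are authentic with probability 0.3, congeneric substitutes
0.1, intergeneric substitutes 0.6 — the substitute-heavy mix of an
adulterated market. Intergeneric substitutes are drawn from
`n_offtarget_genera` (default 3) genera present in the reference library
but never marketed, mirroring the practice of adding externally identified
non-target genera to the reference set; without them an out-of-target flag
would be unfalsifiable. Each marker drops out independently with
probability 0.15 (the order of real per-marker protocol failure rates), and
surviving sequences are truncated to a uniform 100–199 bp prefix with
probability 0.1, emulating short nuclear-marker fragments. Chemistry:
authentic samples draw concentrations lognormally about 1.5× the species
minimum (σ = 0.2); substitutes cross-react with probability 0.1 (about
1.0× minimum), otherwise the marker is absent with a zero or sub-minimum
trace reading; TLC reads present above a detection floor of 0.3× minimum.
All randomness derives from one root seed through fixed per-stage
sub-streams (library / queries / chemistry), so outputs are byte-identical
given a configuration and stages are individually reproducible.

**What the generator does not emulate** — and hence what passing tests do
not show about real data: rate heterogeneity across sites and lineages,
codon structure, indels (an optional flag exists but the default is
indel-free), chimeric or mixed-tissue samples, sequencing chromatogram
artifacts beyond the QV mask, reference-database misannotation, and
chemically realistic assay error structure (the lognormal noise is a
convenience). Real reference libraries also sample species unevenly;
the generator's balanced design is favourable to gap detection.

## Numerical choices

- Base codes order purines (A, G) before pyrimidines (C, T) so a one-bit
  shift separates the classes for transition counting; gaps and all IUPAC
  ambiguity codes are excluded pairwise from counts.
- K2P saturation is detected on the exact domain conditions, not by
  catching log errors; undefined pairs are carried as a list on the matrix.
- NJ tie-breaking and the deterministic simulation streams make every
  reported number reproducible bit-for-bit under a fixed seed.
- Internally 0-based, half-open coordinates; FASTA is untouched.
- Problem sizes in the shipped tests and the acceptance script (200-query
  surveys, 100 replicate single-genus libraries at 500 bp, 500 bootstrap
  replicates on 6-leaf alignments) were chosen as the smallest designs at
  which the stochastic checks have comfortable margins.

## Known limitations

- The star alignment assumes near-indel-free markers; heavily gapped
  regions (real ITS2 across families) would need a proper MSA upstream.
- Equal-length inputs bypass the aligner; an equal-length sequence pair
  containing compensating indels would be misprojected.
- The 98% cutoff and 0.2-point tie tolerance are fixed conventions, not
  estimated quantities; sensitivity to them is the user's to explore.
- K2P can be undefined for highly divergent pairs; such references should
  be pruned rather than force-included.
- Barcode-gap thresholds estimated from few vouchers are noisy maxima;
  the strict-separation criterion is conservative but the threshold itself
  is not bias-corrected.
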