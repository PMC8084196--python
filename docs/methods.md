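# Methods

## The design rule

SpCas9 cuts bluntly 3 bp 5' of the NGG PAM, between protospacer positions
17 and 18; the toolkit encodes this as an inter-base cut boundary `c` on
the reference (0-based half-open coordinates everywhere). A guide is
RFLP-compatible when some restriction-enzyme recognition motif `[a, b)`
satisfies `a < c < b` — strictly, so at least one motif base lies on each
side of the cut. Under this rule any insertion or deletion at the cut
necessarily changes the recognition sequence, which is what makes loss of
digestion a faithful proxy for editing. Motifs that merely abut the
boundary are rejected: an indel could then fall entirely outside the site.

The shipped catalog favours enzymes whose recognition sequences can contain
an NGG (so the PAM itself sits inside the site) and are long and degenerate
(BslI `CCNNNNNNNGG`, XcmI `CCANNNNNNNNNTGG`, BstXI `CCANNNNNNTGG`): large
sites maximize the chance an indel disrupts them, and degenerate positions
make the assay robust to polymorphisms. `pam_compatible` is computed, not
asserted: a motif is flagged iff some concrete expansion contains NGG on
either strand. Motif/offset values are REBASE-standard reference data in
`data/enzymes.tsv`, deliberately shipped as data rather than code. Only the
top-strand cut offset is modelled; that suffices for fragment-length
prediction, and double-strand cut geometry, methylation sensitivity and
star activity are out of scope.

Candidate ranking follows screening practice: RFLP-compatible first, then
overlap with user-supplied functional domains, then proximity to the CDS
start (early frameshifts are most likely to produce a premature stop),
with start/strand tie-breaks for determinism. Non-compatible candidates are
retained but flagged, so the tool doubles as a plain guide designer; the
CLI filters them out by default. No off-target search is performed — the
screening strategy controls off-target risk by limiting guide number, and
a genome-wide aligner would be a different tool.

## RFLP quantification

Lane efficiency is the normalized fraction
`undigested / (undigested + Σ digested)`, clipped to [0, 1]. The
normalized form (rather than a raw undigested:digested quotient) is forced
by the requirement that the statistic run from 0 to 1. Intensities are
assumed background-subtracted upstream; the CSV reader rejects negative
values by default and can clamp them to zero on request. Bands that are
neither full-length amplicon nor predicted fragments (heteroduplexes,
partial digests) go in a third column and are excluded from the ratio —
the conservative choice, since their template of origin is ambiguous.

Aggregation across the injected embryos (default 8, with 4 uninjected
controls) is the arithmetic mean; per-embryo values are always carried in
the output so users can re-aggregate (e.g. median) without re-reading
gels. QC requires every control lane at or below 0.05 efficiency
(boundary inclusive); with no control lanes QC fails, because complete
control digestion is the only evidence that enzyme, DNA and detection all
worked. The haCR call is strict: aggregate > 0.90 *and* QC pass. An
aggregate of exactly 0.90 is therefore not a haCR.

## Knockout probability model

Default parameters: per-site edit probability `e = 1` (the operational
assumption for a guide that passed the >90% pre-screen), frameshift
fraction given an indel `f = 2/3` (one third of random indel lengths is a
multiple of three), ploidy 2, independence across sites and across
alleles. The default model counts an allele disrupted if *any* site
carries a frameshift:

    P(allele) = 1 − Π_i (1 − e_i f)        → 1 − (1/3)^n at defaults
    P(cell)   = P(allele)^ploidy

Whole-percent reporting truncates toward zero (66, 79, 92 from 66.7, 79.0,
92.7; likewise clone rates 24/33 → 72, 29/33 → 87); the two-site
per-allele value is conventionally quoted rounded to nearest (88.9 → 89),
so `whole_percent` exposes both modes and each caller documents its
choice.

The any-site rule ignores frame compensation between sites: a +1 at one
site and a +2 at another restore the reading frame (though the intervening
protein sequence is garbled, and with typical cut sites tens of bp apart
the deletion-bridging case is not modelled). `exact_frame_prob` quantifies
this by convolving per-site shifts over Z/3. Its default residue
distribution given an indel is uniform on {0, 1, 2} — equivalently,
residues 1 and 2 split `f` evenly — under which the net-frameshift
probability is exactly 2/3 for *every* n ≥ 1 (the uniform distribution on
Z/3 is a convolution fixed point). This is the cleanest illustration of
why the model choice matters, and why the any-site rule — which matches
how sequenced clones are actually tallied — is the default. The exact
model is a labelled alternative and is never silently substituted.

`simulate_clones` draws alleles i.i.d. (each site edited with probability
`e_i`, sizes from the model's signed-size distribution, default
{±1: f/2 each, ±3: (1−f)/2 each}). Real clone sequencing draws cloned PCR
products pooled across embryos, which may sample alleles unevenly; the
i.i.d. assumption is documented rather than modelled.

## Screen statistics

Arms are (bridged, total) counts paired with same-experiment lesioned
controls; baseline control bridging is 40% at 24 hpl and 80% at 48 hpl.
The two-sided Fisher exact p uses the point-probability criterion —
conditional on the margins, sum P(table) over tables whose probability is
at most the observed table's, with a 1 + 1e−7 relative tolerance for
float ties — because "two-sided Fisher" has competing definitions and
this is the one mainstream statistical software implements. It is checked
in the tests against a full enumeration oracle in exact rational
arithmetic. Zero-margin tables return p = 1 with a warning.

Hit calling uses raw p < α (default 0.05), matching how small targeted
screens report uncorrected per-gene tests at each timepoint;
Benjamini–Hochberg q-values are available behind a flag for wider
screens. Counts are pooled per arm — per-clutch stratification is out of
scope. Power is estimated by simulation (binomial draws at
`p_control · effect_ratio` vs `p_control`, Fisher test per replicate, with
a result cache over the discrete count pairs); at the null it recovers
the test's size, which for exact tests runs conservative (~0.03 at
n = 40 per arm and α = 0.05, comfortably inside the 0.01–0.07 calibration
band the tests enforce).

## Synthetic fixtures

The generators produce the statistical structure the analysis assumes, not
the physics upstream of it.

- **Sequences**: i.i.d. background at configurable GC, with concrete
  expansions of PAM-compatible enzyme motifs implanted at non-overlapping
  positions with ≥25 nt flanks. Each implant is verified at generation
  time to support at least one RFLP-compatible guide (bounded retries,
  then error), and ground-truth coordinates are emitted alongside. The
  background can, by chance, contain additional real motif occurrences;
  ground truth covers implants only.
- **Gel lanes**: per-embryo mosaic fractions are Beta(mκ, (1−m)κ) around
  the guide's true efficiency m (κ default 100) — beta is the minimal
  bounded-support choice for embryo-to-embryo spread, which is observed
  but not modelled in the wet protocol. Band intensities are proportional
  to the mosaic fraction (undigested) and its complement (digested, split
  60/40 across two fragments), each multiplied by lognormal noise
  (σ default 0.1, because densitometry error scales with intensity), plus
  an additive residual background (default 0, representing post-subtraction
  data). At zero noise the lane ratio recovers m exactly. Defaults are 8
  injected + 4 control lanes per guide.
- **Screen counts**: binomial per arm/timepoint at
  `p_control(t) · effect_ratio`, with one shared control group per
  timepoint and ground-truth effect labels.

What passing tests on these fixtures show: the estimators invert the
generative models they assume, at the stated noise levels. What they do
not show: robustness to gel saturation, partial digestion, heteroduplex
migration, clutch effects, or non-binomial overdispersion in screen
counts — all of which real data can exhibit and the QC/stratification
caveats above are for.

## Numerical and testing choices

Simulation sizes were chosen to keep the full suite under about half a
minute while leaving Monte-Carlo error far smaller than the tolerances
tested: 1e5 clones for parameter recovery (binomial SE ≈ 0.001), 2000
replicates for null calibration and power curves, 250 paired replicates
for haCR classification accuracy, and full enumeration (not sampling) for
every 2×2 table with margins ≤ 15. All randomness flows through explicit
`numpy.random.default_rng` seeds; fixture generation is bit-reproducible.

Known limitations, beyond the fixture caveats: SpCas9/NGG only; no
guide-RNA secondary-structure or chemical-modification modelling; the
positional and GA scorers implement published rule sets but the weighted
scorer ships only an illustrative table (externally trained weights load
verbatim from TSV); paired-guide deletion design is limited to reporting
cut distances.
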