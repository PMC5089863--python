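# Methods

## The screen and its forward model

The assay measures relative phosphorylation efficiencies for hundreds of
peptide variants at once: each *E. coli* cell displays one peptide variant,
a purified kinase domain phosphorylates the displayed peptides in bulk, the
reaction is quenched early, phosphorylation is read out with a fluorescent
pan-phosphotyrosine antibody, and FACS collects the brightest slice of the
population. Deep sequencing of sorted and unsorted pools converts selection
into per-variant enrichment values.

The simulator (`sortscreen.screen`) states this world explicitly:

1. **Rates.** Each variant carries a relative rate
   *k*ᵥ = exp(base + Σ effects). Effects are additive in log-rate, defined per
   (offset from the focal tyrosine, amino acid), and are preference
   *differences* to the wild-type residue, so every wild-type effect is
   exactly 0. Focal-tyrosine substitutions and stop variants are
   phosphorylation-null (*k*ᵥ = 0).
2. **Reaction.** First-order kinetics stopped early:
   *p*ᵥ = 1 − exp(−*k*ᵥτ), with τ solved (Brent root-finding) so the
   pool-averaged completion Σ *f*ᵥ *p*ᵥ equals the configured cap (default
   0.30, the assay's "quench before 30% complete" rule). Solving for an exact
   completion rather than drawing a random quench time keeps runs
   deterministic.
3. **Fluorescence.** One lognormal display multiplier per cell (unit mean,
   σ = 0.3 by default) times *p*ᵥ. Antibody binding and detector response are
   collapsed into this single noisy linear readout; there is no saturation
   and no per-variant display difference by default (an optional override,
   `input_freq`, changes the input pool instead).
4. **Gate and sampling.** The gate keeps the brightest `gate_fraction`
   (default 0.20, constrained to the assay's stated 15–25% window unless
   explicitly overridden) of a 10⁶-cell pool, with random tie-breaking so a
   no-noise, no-selection pool gates exchangeably. Both collected populations
   are *n_cells* multinomial draws. Sequencing is either multinomial read
   sampling at `reads_per_variant × n_DNA_members` total reads (count-level
   path) or actual paired FASTQ with per-base substitution errors and
   Phred+33 qualities derived from the error rate (Q = −10·log₁₀ e, flat
   across cycles).

### Preset effect magnitudes

The `zap70-like` preset encodes: K/R penalised at every offset within ±7 of
the tyrosine, a milder histidine penalty, small acidic bonus, a strong −1 Asp
preference, +1 Glu/hydrophobic and +3 hydrophobic bonuses. The `lck-like`
preset encodes a −1 bulky-hydrophobic preference, −1 Asp penalty, K/R
penalised at +1..+3 but favoured at +4..+7, and a mostly-downstream acidic
penalty. Magnitudes (in `PresetMagnitudes`, natural-log units on the rate)
are set on the *kinetic* scale measured with purified peptides — single
charge-altering substitutions change rates by tens of percent (≈0.4–0.5
nats), not orders of magnitude. The narrow fluorescence gate then amplifies
these modest rate effects into the order-of-magnitude enrichment differences
the screens report: with display noise σ = 0.3, a 1.6-fold rate reduction
already costs ~1.3 log₁₀ enrichment units at a 20% gate. An early draft used
order-of-magnitude rate penalties instead; that pushed every K/R variant onto
the same sampling floor as the tyrosine-null variants, which is inconsistent
with the screens (the null variants set the floor *below* the charge
effects), and was corrected once. A small seeded jitter (σ = 0.05) on every
preference breaks ties; presets are deterministic given their seed. Preset
effects cover offsets within ±7; positions further away (a 20-mer with the
tyrosine at offset +12 from its N-terminus has five such) are neutral in the
truth model.

### What a green simulation test does and does not establish

The generator emulates: the pooled NNS composition with its ~20-fold WT
over-representation, partial-completion kinetics, a quantile gate on noisy
fluorescence, finite cell and read sampling, and substitution sequencing
errors. It does **not** emulate: per-variant display-level differences,
antibody saturation or epitope effects, PCR amplification bias,
quality-by-cycle structure, indels, or cross-replicate batch effects.
Parameter-recovery tests therefore establish that the statistics recover a
known additive log-rate model through this idealized channel — not that real
screens are free of the listed confounders.

## Library design

NNS randomization gives 32 codons per position: all 20 amino acids (with
multiplicities 1–3) plus the single stop TAG. Variant identity is pooled at
the amino-acid level because enrichment is reported per amino acid; stop
members are retained with a `*` suffix and excluded from heatmaps by default.
The parent template's codons are not part of the statistic; a fixed
NNS-compatible codon table is used for reverse translation so the wild-type
DNA is itself a sub-library member. Expected pooled frequency of a key is its
codon count over 32·L; consequently the WT : mean-single-mutant ratio for a
20-mer is 380·Σnᵂᵀ/(620 − Σnᵂᵀ + …) — ≈ 20 for a composition-representative
peptide, and between ~13 (all-multiplicity-1 parents) and ~25 (Leu/Arg/Ser
rich parents). User-facing coordinates always use source-protein numbering
through an explicit offset.

## Read processing

Simplified, fully specified stand-ins for the usual external merge/trim
tools: merging scans every overlap of the forward mate against the
reverse-complemented reverse mate, scores matches − mismatches, requires a
positive score over ≥ `min_overlap` bases, resolves conflicts toward the
higher-quality base (ties to read 1), and rejects merged reads with mean
quality < 30. Adapter trimming is substitution-only full-length matching
(≤ 2 mismatches per adapter by default). Matching translates the insert and
diffs it against the parent: 0 differences → WT, 1 → that variant, ≥ 2 →
rejected (scanning libraries contain only single mutants). A sequencing error
inside the randomized codon is therefore accepted as a miscall — a known,
documented limitation shared with the count-by-identity strategy itself.
Every rejected pair is tallied by reason and the accounting identity
Σcounts + Σrejects = total is asserted on every run. Phred+64 input fails
loudly. Identical read pairs are memoized, which makes error-free deep
counting of a 640-member pool (~320k pairs, 640 distinct) run in seconds.

## Enrichment

Frequencies use a configurable pseudocount (default 0.5 on every variant in
both populations) so that dropout variants keep finite log values at 500×
depth; the pseudocount is recorded on the table. Enrichment values are scale
invariant in the counts and exactly 1 (log₁₀ exactly 0) for the reference.
Replicates are averaged on the log scale (mean of per-replicate log₁₀
enrichments, sample SD with ddof = 1, SD = 0 flagged at n = 1), matching the
convention of reporting averaged log-transformed enrichment values.
Variants with zero unsorted frequency (possible only with pseudocount 0) are
masked, never silently dropped. The detection floor is the mean of the focal
Y→X cells; below-floor cells are annotated, not censored.

## Feature analytics

Net charge is the coarse integer count (#K + #R) − (#D + #E); histidine is
neutral here even though the screens show a histidine penalty — the charge
statistic and the screen are kept distinct on purpose. Binning uses BLOSUM62
(the matrix is a parameter) to order the −1 axis by similarity to Asp, ties
alphabetical; raw counts are always exported, with a Gaussian-smoothed copy
(default bandwidth 1 charge unit × 1 rank unit) for contours only. Logos are
computed from pre-aligned, gap-free windows: IC = log₂20 − H per column in
bits, optional small-sample correction (19/(2·ln2·n)), X padding excluded
from counts. The synthetic substrate generator draws three documented
classes — LAT-like (−1 Asp, charge −8..−4, no K/R), ITAM-like (−1 Leu/Ile,
charge −1..+1, K/R only downstream), generic (broad) — with a default mix of
10/20/70%, reflecting that strongly acidic substrates are rare outliers in a
kinome-wide list; it reproduces the qualitative structure of curated
phosphosite tables, not their actual sequences.

## Numerical choices and degenerate inputs

- τ search brackets by doubling and uses Brent's method (xtol 1e−12); an
  all-null library is a hard error ("degenerate screen"), and an unattainable
  completion target runs phosphorylatable variants to completion.
- Gate size is max(1, round(gate_fraction·n)); quantile ties are broken by a
  seeded permutation, not by array order.
- FASTQ read allocation is largest-remainder (deterministic), so the written
  read multiset is an exact oracle for the counting path at error rate 0.
- All randomness flows from explicit integer seeds through
  `numpy.random.default_rng`; identical inputs reproduce outputs
  bit-for-bit, including FASTQ bytes.

## Known limitations

Substitution-only error and adapter models (no indels); one variant per cell
(copy-number variation folded into display noise); no antibody-specific
calibration between different pan-phosphotyrosine antibodies; enrichment is
not converted to kinetic constants (the enrichment–rate relation is monotone
but gate-shaped); the demo peptide's five N-terminal residues are a synthetic
extension of the printed 15-residue LAT Tyr 226 window, used only as
scaffolding for the 20-position library format.
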