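# Methods

This note documents the models, parameter choices and numerical conventions
behind `spotarray`, and what the synthetic validation does and does not
demonstrate about real data.

## Signal model

Metabolic ³²P labeling incorporates radioactive phosphate into all cellular
RNA in proportion to phosphate content. tRNAs are of near-equal length, so
the radioactivity of a tRNA species is proportional to its molar abundance,
and a hybridized spot's phosphorimager signal is a direct, amplification-free
proxy for tRNA level. All downstream math assumes this linearity; saturation
of the storage phosphor screen is not modeled (in practice exposure time is
adjusted instead).

### Labeling statistics

With a spike of activity *A* (µCi/ml) at specific activity *S* (Ci/mmol),
the tracer molarity is *A/S* µmol/L; dividing the cold media phosphate
(default 22 mM, a defined-media value) by it gives the isotopic dilution
*D*. A tRNA of length *L* has ≈*L* phosphates, each radioactive
independently with probability 1/*D*, so the label count is Poisson with
λ = *L*/*D*. At the default 10 µCi/ml and 1 Ci/mmol, *D* = 2200 and
λ ≈ 0.035: the probability of two or more labels is ~6×10⁻⁴, so essentially
every labeled molecule carries exactly one atom and intensity is linear in
molecule count. The spike's own contribution to the phosphate pool
(≈0.05 %) is neglected in *D*.

## Probe design

Probes are the reverse complement of the 3'-terminal window of each mature
tRNA body, with the universal terminal CCA removed first (it carries no
discriminating information). Defaults: window 70 nt, discrimination
threshold 8 mismatches, [Na⁺] 0.3 M.

- **Mismatch metric.** Windows are compared under 3'-anchored, ungapped
  alignment; a length difference contributes one mismatch per unpaired 5'
  residue. Hybridization is anchored at the tRNA 3' end and tRNA bodies are
  colinear, so gapped alignment would add complexity without a mechanism.
- **Clustering.** Single linkage over the graph whose edges join pairs with
  *fewer than* the threshold number of mismatches. The strict inequality is
  deliberate: species differing by the threshold or more are deemed
  distinguishable, and any chain of mutually similar isodecoders must share
  a probe. Tie-breaking and output order are lexicographic in species id,
  making the design a pure function of the catalog.
- **Degenerate consensus.** Per column, the IUPAC code of the union of
  observed bases; shorter windows are padded at the 5' side as fully
  degenerate. Every cluster member's window is therefore a realization of
  the consensus (a tested invariant).
- **Tm model.** Salt-adjusted Marmur–Schildkraut–Doty,
  Tm = 81.5 + 16.6·log₁₀[Na⁺] + 0.41·GC% − 675/N, with GC of ambiguous
  positions scored as the expected G+C fraction under a uniform base choice.
  This composition-only formula is appropriate for 70-mers and is
  documented as replaceable; nearest-neighbor duplex thermodynamics is out
  of scope. [Na⁺] defaults to 0.3 M, the NaCl concentration of the 2X SSC
  hybridization buffer.
- **Cross-hybridization audit.** Every probe is compared against every
  non-target species (IUPAC-aware, a window base matching any base of the
  consensus code counts as a match); pairs under the threshold are flagged.
  A pair can only be flagged when the audit threshold is stricter than the
  design threshold, since single-linkage merges everything below the design
  threshold by construction.

## Array model and simulation

Spots are printed in 8 contiguous replicates per probe, row-major on a grid
with 800 µm pitch and 300 µm nominal spot diameter, with a one-pitch margin
(defaults chosen so that, at 50 µm scanning resolution, integration disks
and background annuli of neighboring spots never overlap). A seeded
`shuffle` option scatters replicates for robustness testing.

The simulator renders per-pixel expected counts as
`background + exposure · Σ_spots signal · ∫pixel Gaussian(center, σ)`,
with the Gaussian integral computed exactly per pixel as a product of
normal-CDF differences (separable). Realized images are Poisson draws with
an explicit seed; a `noise=False` path returns the expectation itself and
is used for oracle tests. Defaults: pixel 50 µm (typical phosphorimager
scan), PSF σ 75 µm (1.5 px; a plausible storage-phosphor blur, configurable
because real values vary by screen and scanner), background 2 counts/pixel,
exposure gain 5×10⁴ expected counts per unit signal — chosen so that a
median probe on a 48-species array collects ~10³ counts per spot, i.e.
realistic counting noise of a few percent.

What the simulator does **not** emulate: spot-morphology defects (comets,
donuts), print-pin offsets, grid rotation, screen saturation, scratches, or
sequence-dependent hybridization efficiency. Passing recovery tests
therefore demonstrates the correctness of the quantification chain under
the stated noise model, not robustness to every real-world artifact.

## Quantification

- **Registration:** translation-only, integer-pixel search maximizing total
  in-disk intensity; ties break toward the smallest displacement so a flat
  image registers at (0,0). Manual gridding in imaging software has no
  published model; translation is the minimal useful one.
- **Spot integration:** pixel sum over a disk (default radius 5 px);
  background is the *median* of an annulus from 1× to 2× the disk radius —
  robust to tails of neighboring spots. A per-spot local estimate is used
  rather than a global background so slow spatial background variation
  cancels.
- **Clamping:** net signal = max(0, raw − background·n_pixels). Negative
  radioactivity is unphysical, but the clamp biases zero-signal spots
  slightly upward; relevant when interpreting species at the detection
  floor (e.g. selenocysteine tRNA).
- **Replicates:** median of the 8 replicate net signals after flagging
  replicates more than 3 MAD from the replicate median (with MAD = 0 only
  exact deviants flag). An error is raised only if every replicate flags.
- **Normalization:** percent of total — each probe's aggregated signal over
  the summed panel signal ×100 — which cancels exposure time, specific
  activity and loaded RNA mass, making arrays directly comparable.

## Downstream analytics

- Replicate statistics report per-probe median, sample SD (ddof = 1) and
  CV% across biological-replicate arrays; the CV is the technical "false
  change" floor. The panel-level medians of these are also reported.
- Class fractions sum percent levels by size class; a probe whose targets
  straddle classes is an error (cannot happen for panels designed from a
  coherent catalog).
- Fold change is the ratio of percent levels; zero-control probes are
  reported as undefined (NaN), never infinite. Note that percent-of-total
  normalization compresses fold changes: overexpressing one species
  inflates the total, so the measured fold is below the molar fold.
- Per-copy views divide a probe's level by the summed gene copies of its
  targets; with BED loci the output is ordered along the chromosome.
  Operon grouping averages per-copy levels within annotation groups
  (unlabeled genes fall into "other"); SD uses ddof = 1.
- **Wobble decoding.** The default table for anticodon position 34 against
  the codon third base is the standard Crick set — G reads C/U, C reads G,
  U reads A/G, and A is treated as inosine (reads U/C/A) — overridable per
  anticodon. Codon usage is shared *equally* among all decoders of a codon,
  the simplest rule that conserves total usage mass (a tested invariant);
  a winner-takes-all mode exists for sensitivity analysis. Probes targeting
  selenocysteine tRNA are excluded from codon–abundance correlations by
  default because UGA decoding is context-dependent; the exclusion is a
  parameter.
- Correlations report squared Pearson r, with the exclusion list applied
  before computing; zero-variance input is an error rather than r² = 0.

## Synthetic study conditions

No real genome ships with the package. `datasets.synthetic_catalog` builds
a seeded random gene set with the *structure* of the E. coli K-12 tRNA
complement: 86 genes, copy counts 1–6 summing to 86 over 48 unique species,
40 anticodon families, eight of which hold an isodecoder pair — six pairs
within probe-sharing distance (1–5 window mismatches, yielding six
degenerate probes) and two beyond it — so the panel design returns 42
probes. Window bases are drawn at 57% GC so the designed panel reproduces
the GC/Tm uniformity of a real tRNA probe panel. Fourteen genes across five
operon labels emulate tRNAs co-transcribed with rRNA. Abundance profiles
are log-normal (σ = 1 by default), giving the >10-fold max/min spread
characteristic of cellular tRNA pools. Because sequences are random, tests
validate counting structure and pipeline correctness — not probe behavior
on the actual E. coli genome, which requires feeding a real gene set to
`parse_gene_fasta`.

## Problem sizes and determinism

Validation runs use the full 42-probe × 8-replicate array at 50 µm
resolution (≈416×256 px images), 10 seeded arrays for the noisy recovery
estimate and 3 for replicate statistics; these sizes give stable estimates
while keeping the whole suite fast. Every stochastic step — truth sampling,
Poisson rendering, layout shuffling, catalog generation — takes an explicit
seed, and design/layout are deterministic functions of their inputs, so all
outputs are exactly reproducible.

## Known limitations

- The mismatch threshold (8) is a hybridization heuristic, not a
  thermodynamic computation; borderline pairs (7–8 mismatches) may behave
  differently in practice.
- Quantification assumes the layout is approximately correct; rotation or
  nonuniform pitch errors are not corrected.
- The clamp at zero biases species near the detection floor upward.
- Effective codon frequency uses a single global wobble table; organism- or
  modification-specific decoding (e.g. lysidine-modified isoleucine tRNA)
  must be supplied via per-anticodon overrides.
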