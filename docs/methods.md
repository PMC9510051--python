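# Methods

## The phasing model

A trisomic cell carries three homologs of one chromosome, labelled P
(paternal) and M1/M2 (maternal). Four cell lines are observed: the
trisomy (carrying {P, M1, M2}) and three corrected disomies, each
lacking exactly one homolog (ΔP carries {M1, M2}, ΔM1 {P, M2}, ΔM2
{P, M1}). All four are sequenced and, at each SNP, reduced to a
per-sample *present set* of bases. The model assumes:

* every line is clonal and karyotypically stable, so a sample's reads at
  a site come only from its listed homologs (plus sequencing error);
* read sampling is uniform across homolog copies, so a base on *k* of a
  sample's *c* copies has expected BAF *k/c* — 1/3 or 2/3 in the
  trisomy, 1/2 in a heterozygous disomy;
* sites are independent: each site is phased on its own, and the phase
  is global by construction because the homolog labels are shared
  across sites by the cell lines themselves (no phase-set linkage is
  needed).

**Identifiability.** An assignment maps each homolog to a base; a sample's
implied base set is the image of its homolog set. Exhaustively checking
all observable present-set patterns (the test suite does this) shows the
four-sample design is injective: distinct assignments always produce
distinct pattern signatures, so a pattern is matched by either exactly
one assignment (`PHASED` / `UNINFORMATIVE_HOMOZYGOUS`) or none
(`CONFLICT`). The `AMBIGUOUS` status (two or more consistent
assignments) is kept as a defensive classification — it can matter for
degenerate designs a user might supply — but is unreachable with the
standard trisomy + three-disomy layout. This is why the method needs no
statistical inference.

The constructive subtraction rule ("a candidate absent from Δh alone
belongs on h") is implemented alongside the enumeration; each site's
result is the oracle's, and a diagnostic note is recorded if the
constructive path ever disagrees.

## Filters and thresholds

| parameter | default | meaning |
|---|---|---|
| `min_depth` | 10 reads | every sample must reach it; inclusive (depth 10 kept) |
| `tau_present` | 0.06 | BAF at or above which a base counts as present; inclusive |
| `bin_size` | 10,000 bp | heterozygosity bin width for the recombination scan |
| `min_run_bins` | 5 | minimum empty-bin run length to call a homozygous segment |
| `min_flank_density` | 1.0 het/bin | required mean density of the `min_run_bins` bins flanking a run |

The presence threshold is stated for the trisomy sample by the source
protocol; the per-sample selection conditions it references are not
published, so this package applies the same inclusive threshold
symmetrically to every sample to declare presence/absence. That single
rule reproduces both published worked examples and is the package's own
reconstruction; it is the main place a reimplementation could
legitimately differ. A base passing the threshold in a disomy but not in
the trisomy is excluded everywhere and surfaced in the profile's
diagnostics.

The run-detection thresholds operationalize what was originally a
visual judgement of a binned heterozygosity histogram. The flank-density
guard exists because an empty bin is only evidence of homozygosity when
neighbouring bins show the scan had power to detect heterozygous sites
there; with the defaults, a false run needs five consecutive empty bins
inside a region averaging ≥ 1 het site per bin, which has negligible
probability under any realistic site density.

## The simulator

`simgen` emulates the data the four-line experiment produces, at the
allele-count level (reads, read length and alignment are upstream of the
method and not modelled):

* **Haplotypes** — `n_sites` distinct positions uniform on the
  chromosome; each site drawn from seven configuration classes
  (monomorphic; P-, M1-, M2-private; P+M1- and P+M2-shared alternate;
  triallelic) with default weights 0.30 / 0.40 / 0.07 / 0.07 / 0.07 /
  0.07 / 0.02. P-private sites dominate the heterozygous classes,
  encoding that the two maternal homologs are genetically much closer to
  each other than to the paternal one — the signature of a maternal
  meiotic origin of the trisomy. The exact proportions are a free
  parameter; no published class breakdown exists to calibrate them.
* **Depth** — Poisson with mean `depth_mean · c / 2` for a sample with
  *c* copies of the chromosome; `depth_mean` is diploid-equivalent
  coverage (default 30), so the trisomy sees ~45× on the trisomic
  chromosome and disomy totals are ~2/3 of the trisomy's, matching the
  mapped-read-fraction drop seen after elimination.
* **Counts** — each read's true base is uniform over the sample's
  homolog copies (multinomial per site); with probability `error_rate`
  (default 0.001, a typical short-read substitution rate) a read's base
  is replaced uniformly by one of the other three.
* **Recombination** — `apply_recombination` overwrites M2 by M1 in
  alternating segments between breakpoints, creating the ΔP
  homozygosity footprint of an M1/M2 first-meiosis crossover.
* **Reproducibility** — all draws derive from a single seed; haplotype,
  read and error draws use separate derived streams, so switching
  `error_rate` to 0 yields the identical count table minus the errors
  (the degradation tests rely on this).

What the simulator does **not** emulate: mapping artefacts and
reference bias, indels and structural variants, GC-dependent coverage
waves, linked errors within read pairs, contamination or karyotype
mosaicism, and LD structure between sites. Passing tests therefore show
the algorithmic pipeline is exact under its stated sampling model, not
that real libraries are free of systematic error — on real data the
`CONFLICT` fraction is the relevant dial to watch.

## Numerical and edge-case choices

* Threshold comparisons are inclusive (≥) at both boundaries, matching
  the protocol wording ("at least 10", "0.06 or more"); 3/50 = 0.06
  passes exactly.
* Percentages print with half-up rounding to 2 decimals
  (`round_percent`), matching the published precision (1.81 %, 3.48 %).
* Depth is the caller's DP when reported, else the AD sum; multiallelic
  records are kept as single sites; the gVCF `<NON_REF>` placeholder is
  used to write monomorphic records and stripped on read.
* Sites with zero depth in any sample must be removed by `filter_sites`
  before base-set computation (zero depth raises); a kept site where no
  base passes `tau_present` in the trisomy sample becomes `FILTERED`.
* Enumeration iterates assignments in lexicographic base order, making
  ties (which cannot occur with the standard design, see above)
  deterministic anyway.
* `theoretical_combinations` uses the inclusion–exclusion surjection
  count per site, raised to the number of sites; with more alleles than
  homologs it returns 0.

## Scale of the shipped checks

The acceptance-style tests run at desk scale, chosen to finish quickly
while keeping every statistical margin wide: recovery and
error-robustness runs use 50,000 sites on a 46.7-Mb chromosome at 30×
(matching the real chromosome's scale and roughly its phased-SNP count),
and the crossover-localization sweep uses 100 seeds of 10,000 sites on a
1.5-Mb chromosome (150 bins), where the ΔP heterozygous density
(~10 sites/bin) makes both false and missed runs vanishingly unlikely.
The crossover sweep runs error-free because it probes breakpoint
geometry; the error axis is covered separately by the 1 %-error run.

## Known limitations

* The symmetric presence rule (see above) is a reconstruction of an
  unpublished selection table.
* Phasing is per-site; the package does not attempt to rescue
  `CONFLICT` sites using neighbours, which a haplotype-aware
  error model could.
* The MLPA classifier implements only the published decision rule
  (≥ 4 of 8 probe ratios ≥ 1.30 ⇒ trisomy); probe-level normalization
  is the kit software's job.
* Parental origin of homologs (the P/M1/M2 labels themselves) comes
  from STR genotyping upstream; in simulations the labels are ground
  truth by construction.
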