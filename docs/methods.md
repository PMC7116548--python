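# Methods

This note documents the models, defaults and design choices behind the
package, in the order data flows through it.

## Measurement model and correction chain

An instrument sequence is an ordered list of injections of one element
(C or N). A 7-amino-acid standard mixture (Ala, Val, Leu, Ile, Met, Glu,
Phe) with certified δ values opens and closes the sequence, three injections
per bracket, and a bracket is inserted after at most 18 sample injections.
`SequenceRun` validation enforces exactly this contract: terminal standards
present and no more than `bracket_limit` consecutive sample injections
anywhere (checked by a direct scan of the injection order).

**Bracket averaging.** Amino acids differ in heteroatoms and functional
groups, hence in combustion efficiency and drift. Drift within a sequence is
therefore summarized per amino acid as the arithmetic mean of the opening
and closing bracket standards, not interpolated against injection index. An
index-interpolating mode was considered and deliberately left out of the
default chain; the averaging scheme is the one the acquisition protocol
prescribes.

**Nitrogen calibration.** One ordinary least-squares regression per sequence
of certified δ15N (response) on bracket-mean measured δ15N (predictor),
pooled across the seven standard amino acids. Pooling is the only option
that yields a regression at all — each amino acid contributes a single
certified value — and the certified range (−6.69 to +43.25‰, extended by
certified Ala +43.25‰ and Val +30.19‰ reference materials) anchors the slope
well. The orientation (certified on measured) makes application a direct
affine map with no inversion at apply time; the opposite orientation differs
only at order noise²/range² here. A per-amino-acid mode exists behind a
switch and is offset-only (slope 1), since a within-amino-acid regression
has zero response variance by construction. Standards pass through the same
map; their residuals are the sequence's QC diagnostics.

**Derivatization correction.** Propyl-chloroformate-style derivatization
adds reagent carbon; the mole balance
`ncd·δ13C_cd = nc·δ13C_c + nd·δ13C_dcorr` is solved per amino acid for
δ13C_dcorr from the sequence's own standards (certified δ13C_c, bracket-mean
measured δ13C_cd) and inverted for samples. Because δ13C_dcorr is re-derived
from the standards of every sequence, any additive per-amino-acid offset in
the carbon measurements cancels exactly in the corrected values — but a
multiplicative drift term is not identifiable from a single standard level,
which is why the simulator's default carbon drift is additive only while
nitrogen drift is fully affine (slope 0.9–1.1, offset ±2‰ in the recovery
studies). Nitrogen itself needs no derivatization correction (the reagents
add no nitrogen); this is asserted, not configurable.

The packaged carbon counts assume each carboxyl gains a propyl ester (+3 C)
and each amine a propoxycarbonyl group (+4 C): e.g. Ala 3→10, Glu 5→15
(two carboxyls), Phe 9→16. Reagent chemistry varies between laboratories, so
the counts are a documented, overridable table (`aa_registry(counts=...)`,
CSV schema in `aacsia.io`); internal consistency between calibration and
correction is what matters, since the empirical δ13C_dcorr absorbs residual
error. Note the inversion multiplies measurement noise by ncd/nc (≈1.8 for
Phe, 3 for Glu) — duplicate injections and the reported dispersion make this
visible rather than hiding it.

**Replicate aggregation** uses the n−1 standard deviation; a single
replicate yields dispersion 0 with a warning.

## Trophic position and diet mass balance

TP = (δ15N_Glu − δ15N_Phe − β)/TDF + 1 with defaults β = −0.36‰ and
TDF = 4.54‰, the standard Glu/Phe values for marine food webs; both are
`TrophicParams` fields. The per-sample standard error propagates the
replicate dispersion of Glu and Phe in quadrature
(SE² = (sd²_Glu/n + sd²_Phe/n + sd²_β)/TDF²), optionally including parameter
uncertainty; the TDF term needs the TP estimate itself (sensitivity
−(TP−1)/TDF). Group tables report the across-colony mean ± SD of TP — the
dispersion field ecologists report — separately from the propagated
instrument error, which is typically smaller.

The heterotrophy fraction is a two-endmember linear mixture:
f_het = (TP − 1)/(2.86 − 1). The heterotrophic endmember 2.86 is an external
empirical constant (a fully heterotrophic coral measured by the same
method), configurable, not recomputed. Raw fractions outside [0, 1] are
clamped with a flag rather than rejected: replicate noise routinely pushes a
TP-1 symbiont slightly below the autotrophy endmember, and rejecting such
samples would bias group summaries upward. At the configured design TPs the
balance gives f_het = 0.376 for TP 1.7 and 0.108 for TP 1.2.

## Carbon-source fingerprinting

The fingerprint matrix is samples × {Val, Leu, Ile, Met, Phe} of corrected
δ13C, complete cases only (exclusions logged). PCA runs on mean-centered,
unscaled data by default — all columns share ‰ units — with unit-variance
scaling behind a flag.

PERMANOVA uses Euclidean distances. One-way pseudo-F is
(SS_between/df_between)/(SS_within/df_within) with SS terms computed from
the pairwise squared-distance matrix; p = (1 + #{permuted F ≥ observed F})/
(1 + n_permutations), ties counting toward the numerator (conservative).
Permutations shuffle group labels with a seeded generator; the seed is a
required argument — there is no silent default randomness anywhere in the
package. The default permutation count is 9,999. A sequential two-factor
additive variant (treatment, then fraction given treatment) partitions the
Gower-centered distance matrix by hat-matrix projections and permutes raw
observations; simpler permutation schemes than residual permutation are
adequate at these group sizes, and the sequential decomposition matches the
behavior of distance-based redundancy analysis implementations. Pairwise
group tests are Benjamini–Hochberg-adjusted (step-up, capped at 1, returned
in input order).

## The simulator

`paper_like_config()` encodes the study conditions: true TP
(host, symbiont) = (1.7, 1.3) in shallow and mesophotic groups and
(1.2, 0.9) in transplants; essential amino-acid δ13C means identical for
shallow and transplant and shifted lighter for mesophotic (−2.5‰ on Leu and
Phe, −1.5 on Ile, −1.0 on Val, −0.2 on Met); 3 colonies per group, host and
symbiont fractions sharing a colony's Phe baseline (4.0‰, between-colony SD
0.5‰); triplicate N and duplicate C injections; per-injection noise SD 0.3‰
(N) and 0.5‰ (C) — stated assumptions for a well-behaved GC-IRMS, not
measured values. Between-colony biological variation is placed on the Phe
baseline and on TP (SD 0.2, chosen so the realized across-colony TP SD
matches the ±0.2 a field study of this size reports); how variance splits
between baseline and TP is a simulator choice. Non-essential amino acids are
carried through I/O at fixed offsets but unused by inference. Drift is
injected as the exact inverse of the correction's affine map, so the
correction target is well-defined; nonlinear drift is out of scope.

What the simulator does **not** emulate: chromatographic peak shape and
integration error, peak-size (linearity) effects, blank contributions,
memory/carry-over between injections, non-Gaussian outliers, and any
time-course of acclimation. Passing recovery tests therefore demonstrate
that the reduction chain is algebraically correct and statistically
calibrated under the stated noise model — not that real chromatograms of
arbitrary quality will behave as well.

## Verification design and problem sizes

- Noise-free simulation → correction → TP is exact to machine precision
  (the chain is an algebraic inverse of the forward model), and the carbon
  correction is property-tested as the exact inverse of forward mixing over
  random counts and δ values.
- Calibration unbiasedness: 500 simulated sequences with per-sequence random
  drift; per-amino-acid bias of corrected sample means is required to stay
  below 0.1‰ for both elements. Group-TP recovery: 200 simulated studies;
  the across-study mean of each group's estimated TP must sit within 0.15 of
  the configured truth. Both are bias checks across studies: with colony SD
  0.2 and n = 3, a single study's group mean has SE ≈ 0.12, so a per-study
  bound at that level would mostly measure sampling noise.
- PERMANOVA: the statistic is checked against an independent loop-based
  oracle (to 1e-10, including an exhaustive 70-permutation enumeration at
  n = 8), against scikit-bio's implementation, and — for the two-factor
  decomposition — against values frozen from vegan's `adonis2`. Type-I
  calibration uses 1,000 null datasets (n = 18, 3 groups, 999 permutations)
  with the α = 0.05 rejection rate required to fall in [0.03, 0.07].
- Fingerprint pattern: in 200 simulated studies the pairwise BH-adjusted
  tests must separate mesophotic from both other groups and not separate
  shallow from transplant in ≥90% of runs.

These sizes keep the full suite near ten seconds while leaving every Monte
Carlo bound several standard errors away from its threshold (the one
exception, per-study carbon bias at 30 sequences in the unit suite, uses a
wider bound justified by the ncd/nc noise amplification).

## Known limitations

- The affine drift model is per-sequence constant; slow within-sequence
  drift that the bracket average cannot capture will appear as (reported)
  replicate dispersion, not be corrected.
- Carbon multiplicative drift is uncorrectable under the single-level
  standard protocol; if an instrument shows it, the correction is biased by
  (1/slope − 1)·(δ_sample − δ_standard) per amino acid.
- The two-endmember mixing model inherits the uncertainty of the 2.86
  endmember, which is treated as known; no Bayesian mixing over more sources
  is attempted.
- PERMANOVA assumes exchangeability under the null; with only three colonies
  per group the permutation distribution is coarse at the pairwise level
  (minimum attainable p = 1/(n_permutations + 1), but the effective number
  of distinct group relabellings is small).
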