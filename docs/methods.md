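# Methods

## The measurement being modeled

Cells growing in media containing ~5 % heavy water (²H₂O) incorporate
deuterium into C–H bonds of nonessential amino acids, and hence into every
protein synthesized after labeling begins. For a tryptic peptide observed
by LC-MS, the envelope of mass isotopomers (m0, m1, m2, ...) therefore
shifts from its natural-abundance baseline toward a heavier, fully-labeled
plateau as old protein is replaced by new. Because old and new protein mix
linearly, the envelope at any time is a weighted average of baseline and
plateau, with weight equal to the fraction `f` of newly synthesized
protein. Tracking `f` over time gives the fractional synthesis rate; in
proliferating cells, subtracting the cell growth rate leaves the protein
turnover rate.

Applied to HLA class I heavy chains, the extra ingredient is attribution:
a donor expresses up to six allelic variants at three loci (HLA-A, -B,
-C), and a tryptic peptide reports on a specific allele or isotype only if
its sequence is unique to it within the donor's genotype. The package
digests the genotype's protein sequences in silico and classifies each
peptide as allele-specific, isotype-specific, or ambiguous; ambiguous
peptides (present at two or more loci) are excluded from kinetics.

## Models

**Natural envelope.** The mass isotopomer distribution of a peptide with
elemental composition CcHhNnOoSs is the convolution of per-atom isotope
distributions over unit-mass offsets. Defaults: heavy carbon 1.09 %
(the dominant contribution), ²H 0.0115 %, ¹⁵N 0.364 %, ¹⁷O/¹⁸O
0.038 %/0.205 %, ³³S/³⁴S/³⁶S 0.75 %/4.25 %/0.01 %; fully overridable.
Envelopes are truncated to the channels retaining ≥ 99.9 % of cumulative
abundance (at most 10) and renormalized to sum exactly to 1.

**Labeled envelope (MIDA).** New protein carries excess deuterium at an
effective number `n` of incorporation sites, each enriched to the media
enrichment `p` (default 0.05). The fully-labeled envelope is the natural
envelope convolved with Binomial(n, p). `p` is treated as excess
enrichment above natural ²H; ignoring natural deuterium at the labeled
sites errs by < 0.3 % relative at p = 0.05 and is absorbed by the baseline.
`n` is an integer (a count of C–H positions) fitted by grid search
minimizing the RMSD between model and data, ties toward smaller `n`.

**Plateau estimation without a plateau sample.** When the time course is
not long enough for complete labeling, the pipeline fits `n` jointly with
per-time mixing fractions: for each candidate `n`, each observed envelope
is projected onto the segment between the baseline and the labeled model
(closed-form least squares, clipped to [0, 1]), and `n` minimizes the
pooled residual RMSD. This is exact on noise-free data and uses the whole
time course rather than the last sample only. The alternative
`plateau_mode="latest"` treats the final sample as fully labeled, and
`baseline_mode="measured"` substitutes the observed t = 0 envelope for the
theoretical baseline (on clean data the two baselines are equivalent).

**Fractional synthesis.** For each channel whose baseline-to-plateau
shift is at least `min_shift` (default 0.08 absolute fractional abundance;
smaller shifts give poor estimates), `f_i = (obs_i − base_i) /
(plat_i − base_i)`. The point estimate is the unweighted mean of the
informative channels (usually 2–4), and their SD is the analytical error.
The 0.08 threshold is read as absolute, not relative, abundance
difference; it is configurable.

**Quality control.** Configurable thresholds exclude peptides liable to
yield poor `f`: total ion abundance < 1e5 (arbitrary units), plateau-model
RMSD > 0.01, per-point SD > 0.15, points implying `f` outside [0, 1]
beyond 5 SD (with a 1e-9 epsilon so exact boundary values survive
round-off), and — an identifiability criterion — site fits whose best `n`
beats the runner-up by < 5 % relative RMSD. The last matters because an
ill-determined `n` mis-scales the plateau and biases the whole series'
rate multiplicatively; in simulations, nearly all site-count misses fall
below this margin while 95 % of correct fits exceed it.

**Kinetics.** `f(t) = 1 − exp(−k_obs·t)` is fitted by nonlinear least
squares over `k ≥ 0` with the plateau fixed at exactly 1 (complete
replacement; no free-plateau option). Default weighting is none; optional
1/sd². The standard error comes from the linearized curvature at the
optimum with residual df = n − 1, and the 95 % CI is the asymptotic
t-interval. Rate equality across peptide series is tested by the
extra-sum-of-squares F test between the pooled (one shared `k`) and
separate models; `F = ((RSS_sh − RSS_sep)/(df_sh − df_sep)) /
(RSS_sep/df_sep)`. When p > α (default 0.05) the pooled per-isotype fit
is reported as primary, and the comparison is run per locus. Raw p-values
are reported without multiple-comparison correction.

**Growth correction.** Cell counts are fitted by linear regression of
ln(count) on time; `k_cell` is the slope (clamped at 0 and flagged
`non_proliferating` when non-positive) and the doubling time is
ln 2 / k_cell. At steady state the contributions are additive, `k_obs =
k_cell + k_TO`, so `k_TO = k_obs − k_cell`, clamped at 0 and flagged
`turnover_not_measurable` when synthesis does not exceed growth. The
turnover half-life is ln 2 / k_TO; its SEM combines both fit SEMs in
quadrature (the growth-uncertainty propagation is this package's choice).

## Synthetic experiments

The generator produces complete seeded experiments with known truth:

* **Panels.** All loci descend from one random ancestral 360-residue
  protein; each locus consensus mutates 10 % of positions (giving ~81 %
  pairwise locus identity, matching real HLA class I similarity) and each
  allele mutates 4 % of its consensus. This reproduces the observed
  structure: alleles of a locus share most tryptic peptides
  (isotype-specific), a minority are allele-specific, and a few conserved
  peptides recur across loci (ambiguous; ~20 % of selected peptides are
  included deliberately to exercise the exclusion path).
* **Envelopes.** Per peptide, `n` is drawn uniformly in 10–40 (clamped to
  the hydrogen count) and each time point's true envelope is the exact
  baseline/plateau mixture at `f(t) = 1 − exp(−k_obs·t)` with
  `k_obs = k_cell + k_TO(locus)`.
* **Noise.** Multiplicative Gaussian noise per channel (CV 1.5 % by
  default, chosen so the model-vs-data RMSD of a simulated unlabeled
  envelope is ~0.2 % absolute fractional abundance, the accuracy of
  integrated Orbitrap ion chromatograms in this assay class), an optional
  additive floor and Poisson-free drawn total abundance, and 5 % CV on
  cell counts. Raw spectra, chromatography, retention times, and
  identification errors are not simulated — inputs begin at integrated
  isotopomer abundances, as in the analysis itself. Passing tests
  therefore validate the quantification and inference stages, not peak
  processing.
* **Presets.** `kg1`: doubling 31 h, HLA-A/-B turnover half-life 20 h,
  HLA-C 9 h. `lcl721`: doubling 24 h, HLA-A 65 h, HLA-B no measurable
  turnover, HLA-C 17 h. `modc`: non-proliferating, all isotypes 7 h.
  `modc-lps`: the same with a 2-fold slow-down. Default sampling at
  0, 6, 24, 48, 72, 96 h (72 h for the dendritic-cell presets).

## Numerical choices and calibration behavior

* Envelope convolutions use exact binary-exponentiation convolution;
  acceptance-grade tests compare against exhaustive isotopologue
  enumeration (≤ 6 atoms, 1e-9) and a closed-form binomial case.
* Site-fit ties break toward smaller `n`; the mixture fit's λ is clipped
  to [0, 1]; degenerate inputs (empty ranges, n exceeding hydrogens,
  all-zero channels, non-positive counts) raise typed errors.
* Exponential fits use analytic Jacobians with tight tolerances (xtol
  1e-14), so noise-free inputs are recovered to machine precision; a
  zero-noise simulated experiment round-trips every turnover rate to
  ≥ 4 significant digits.
* The F test is exactly calibrated when series share a noise level
  (empirical type-I error ~5 % at α = 0.05). When peptide series differ
  in precision — which different envelope shapes and channel counts
  produce — the classical unweighted extra-sum-of-squares test is mildly
  anti-conservative: in simulated experiments with equal true rates,
  pooling is retained in roughly 85 % of runs rather than 95 %. This is a
  property of the prescribed test under heteroscedasticity, not of the
  implementation; inverse-variance weighting is available but per-point
  SDs estimated from 2–4 channels are themselves noisy.
* All outputs are deterministic: fixed seeds give byte-identical CSVs and
  reports (fixed float formatting, sorted rows).
* Problem sizes used by the test suite and acceptance script (e.g. 200
  replicate fits per rate, 1000 null F-test simulations, 50-seed pipeline
  replication) were chosen to make the Monte-Carlo bands tight at
  desk scale.

## Limitations

* Single-compartment, single-exponential kinetics only: no delay,
  lysosomal-inhibition, or surface-vs-intracellular pool models.
* Signal-peptide trimming is the caller's responsibility; classification
  operates on sequences as supplied.
* The generator's multiplicative noise omits correlated channel errors
  (e.g. coeluting contaminants), so the QC reason codes for contamination
  are exercised only via thresholds, not realistic interference.
* Half-lives approaching the growth-rate scale (the slow-turnover
  B-lymphoblastoid scenario) are differences of two similar rates and
  carry large relative uncertainty, as reflected in their SEMs.
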