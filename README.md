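# turnoverlab

Protein turnover analysis from heavy-water (²H₂O) metabolic labeling,
built for the question of whether HLA class I (MHCI) alleles and isotypes
differ in their degradation rates.

Cells cultured in ~5 % ²H₂O incorporate deuterium into newly synthesized
protein. A tryptic peptide's mass isotopomer envelope (m0, m1, m2, ...)
then shifts from its natural-abundance baseline toward a fully-labeled
plateau, and the fraction of new protein at time t is read off as the
fractional shift. `turnoverlab` implements the full analysis:

* **Peptide attribution** — in-silico tryptic digestion of a donor's HLA
  allele sequences (cleavage after K/R except before P, configurable
  missed cleavages) and classification of every peptide as
  *allele-specific*, *isotype-specific*, or *ambiguous* within the
  genotype; ambiguous peptides are excluded from kinetics.
* **MIDA quantification** — natural and labeled mass isotopomer
  distributions from elemental composition (labeled = natural ⊛
  Binomial(n, p) at precursor enrichment p), fitting of the effective
  number of ²H incorporation sites n, and per-time-point fractional
  synthesis f with analytical error and QC filtering.
* **Kinetics** — nonlinear least-squares fits of f(t) = 1 − e^(−k_obs·t),
  rate-equality testing across peptides by extra-sum-of-squares F test
  (pooled fits reported as primary when not rejected), exponential
  growth fits of cell counts, and growth-corrected turnover:
  k_obs = k_cell + k_TO, t½ = ln 2 / k_TO.
* **Synthetic experiments** — a seeded generator producing allele panels
  with realistic sequence sharing, isotopomer time courses, and growth
  curves with known ground truth, so the whole pipeline is testable
  without instrument data.

See `docs/methods.md` for the models, defaults, and assumptions.

## Worked example

Generate a synthetic experiment emulating a proliferating myeloid cell
line (doubling time 31 h; true turnover half-lives 20 h for HLA-A/-B and
9 h for HLA-C), then analyze it:

```bash
turnoverlab simulate --preset kg1 --seed 1 --out-dir demo/in
cat > demo/run.toml <<'EOF'
[paths]
fasta = "demo/in/panel.fasta"
genotype = "demo/in/genotype.csv"
quant = "demo/in/quant.csv"
counts = "demo/in/counts.csv"
out_dir = "demo/out"
EOF
turnoverlab run --config demo/run.toml
```

which prints (abridged):

```
Cell growth: k_cell = 0.02212/h (doubling time 31.34 h)

## Pooled isotype fits
- HLA-A: k_obs = 0.05727 ± 0.0007386/h (95% CI 0.05578–0.05875), t_half = 12.1 h, n = 48 points
- HLA-B: k_obs = 0.05669 ± 0.0004523/h (95% CI 0.05578–0.0576), t_half = 12.23 h, n = 52 points
- HLA-C: k_obs = 0.09864 ± 0.001246/h (95% CI 0.09612–0.1012), t_half = 7.027 h, n = 44 points

## Rate-equality F tests (per locus)
- HLA-A: F(7, 40) = 1.583, p = 0.1685 → pooled fit primary
- HLA-B: F(8, 43) = 1.418, p = 0.2165 → pooled fit primary
- HLA-C: F(7, 36) = 1.41, p = 0.2317 → pooled fit primary

## Growth-corrected turnover
- HLA-A: k_TO = 0.03515 ± 0.0009165/h, t_half(TO) = 19.72 h
- HLA-B: k_TO = 0.03457 ± 0.0007064/h, t_half(TO) = 20.05 h
- HLA-C: k_TO = 0.07652 ± 0.001359/h, t_half(TO) = 9.059 h

25 peptide series fitted; 5 series with exclusions (see exclusions.csv).
```

Reading this: the observed synthesis rates (k_obs) of all three isotypes
exceed the cell growth rate, the per-locus F tests find no rate
differences among peptides tracking the same isotype (so pooled fits are
primary), and subtracting growth recovers the generating turnover
half-lives — 19.7 / 20.0 h for HLA-A/-B and 9.1 h for HLA-C — with the
faster HLA-C turnover clearly resolved. `demo/out/` also contains
`fits.csv` (per-peptide, per-allele, per-isotype), `comparisons.csv`,
`turnover.csv`, `mida_fits.csv` (fitted n, RMSD), `exclusions.csv`
(every dropped peptide with a machine-readable reason), and `run.log`
(all parameters used).

Other subcommands: `turnoverlab classify` (peptide specificity TSV),
`turnoverlab mida-fit` (site fits + fractional synthesis from a quant
CSV), `turnoverlab fit-kinetics` (exponential fits, F test, growth
correction from point tables). Presets: `kg1`, `lcl721`, `modc`,
`modc-lps`.

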