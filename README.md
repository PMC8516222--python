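# hsgwas

A tested, reusable pipeline for genotype-by-*time-lagged* heat-stress
interaction GWAS in dairy cattle: weekly temperature-humidity-index (THI)
exposures for the last eight gestation weeks before an animal's birth,
genotype quality control, VanRaden genomic relationship matrices, AI-REML
variance components with a genotype-by-heat-stress term, a per-SNP
generalized-least-squares scan for main and interaction effects with
inflation diagnostics and LD-aware significance thresholds, and
candidate-gene window annotation. A first-class synthetic-data module
generates genotypes, station weather, herd geography, exposures and
phenotypes with known ground truth, so the whole pipeline is testable
end-to-end without any data download.

## Models

Variance components (per trait and gestation week, restricted maximum
likelihood with average-information updates and EM fallback):

    y = Xb + Zg + e                      V = G*s2g + I*s2e
    y = Xb + Zg + W*g_hs + e             V = G*s2g + W*G_hs*W'*s2ghs + I*s2e

where `G` is the VanRaden relationship matrix `M M' / (2*sum p(1-p))`, `G_hs`
its principal submatrix on the heat-stress-exposed animals, and the exposure
flag is `weekly THI >= 60`. Ratios reported: `h2_g = s2g/(s2g+s2e)` and, for
the interaction model, `h2_c = s2g/total` and `r_hs = s2ghs/total`.

Per-SNP scan: the fixed design is augmented with the centered dose column
`x_snp = m - 2p` and its exposed-only copy `x_inter`; `b1 = (X1'V^-1X1)^-1
X1'V^-1 y` with V assembled once from the pre-estimated components, solved
via one cached Cholesky factorization plus a rank-2 Schur update per marker.
Wald chi-squares (1 df), inflation factor `lambda = median(chi2)/0.4549`,
Bonferroni (`0.05/n_snps`) and suggestive (`0.05/n_independent`, LD pruning
at R^2 <= 0.15 in consecutive 500-SNP windows) thresholds.

## CLI

```bash
hsgwas simulate --config run.yaml --out sim/ --seed 1
hsgwas thi --weather w.csv --herds h.csv --stations s.csv --animals a.csv --out exposure.csv
hsgwas qc --dosage sim/genotypes.csv --markers sim/markers.csv --out qc/
hsgwas grm --dosage qc/genotypes_qc.csv --markers qc/markers_qc.csv --out grm
hsgwas reml --grm grm --pheno sim/phenotypes.csv --exposure exposure.csv --trait y --week 2 --model whs
hsgwas scan --grm grm --dosage qc/genotypes_qc.csv --markers qc/markers_qc.csv \
            --pheno sim/phenotypes.csv --exposure exposure.csv --trait y --week 2 --out scan.tsv
hsgwas annotate --hits scan.tsv --genes genes.gff3 --out candidates.csv
hsgwas run-all --config run.yaml --seed 1
```

`run-all` fans out over every configured (trait, week) cell, writes
per-stage artifacts plus a `manifest.json` with seeds and artifact hashes,
and is bit-reproducible for a fixed config and seed. A minimal YAML config:

```yaml
out_dir: out
weeks: [1, 2, 3, 4, 5, 6, 7, 8]
simulation:
  n_animals: 500
  n_snps: 2000
  n_herds: 10
  n_stations: 5
  variance_components: [0.3, 0.1, 0.6]
  hs_target_prevalence: 0.25
```

## Layout

    src/hsgwas/
      synthdata.py    synthetic genotypes / weather / population / phenotypes
      climate.py      THI, daily & weekly aggregation, station assignment, HS flags
      geno_qc.py      QC filters, mean imputation, VanRaden GRM, relationship pruning
      varcomp.py      design building, class binning, AI-REML, ratios
      gwas_inter.py   GLS scan, inflation factor, LD-independent counting, thresholds
      annotate.py     gene-window candidate lookup (GFF3/BED)
      pipeline.py     run-all orchestration + manifest
      io.py           PLINK bed/bim/fam codec, CSV/TSV/JSON formats
      cli.py          click command group (`hsgwas`)
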