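# breedauth

Breed authentication from SNP genotype panels: selection of maximally
breed-informative markers from dense genotype data, partial-Bayesian
individual assignment and exclusion testing against breed reference
populations, and forensic pairwise-contrast power analysis yielding
posterior probabilities of correct breed assignment. A Balding–Nichols
breed-genotype simulator makes every stage testable offline.

## What it does

- **`genotype_io`** — genotype data model (alt-allele dosage coding with a
  distinct missing sentinel), PLINK-style PED/MAP and CSV readers/writers,
  call-rate QC (per-breed or overall scope), allele-frequency estimation
  with leave-one-out support.
- **`synthetic_data`** — Balding–Nichols simulation of breed-structured
  genotype datasets: per-breed divergence `F`, weakly diverged close pairs
  via a shared intermediate ancestor, optional admixed individuals,
  correlated-locus copies (for LD screening), missingness; frozen
  benchmark scenarios (`two_pop_simple`, `british_pigs_like`,
  `close_pair_only`); fully seed-reproducible.
- **`marker_informativeness`** — per-locus delta (mean absolute
  allele-frequency difference over all breed pairs), deterministic
  ranking, cumulative-panel self-assignment curve, top-N panel selection,
  post-hoc within-breed LD screen of same-chromosome panel pairs.
- **`assignment_engine`** — partial-Bayesian genotype likelihoods
  (Dirichlet-posterior predictive with uniform 1/2-per-allele prior,
  log10 scale), leave-one-out self-assignment, and the
  exclusion-simulation test (per-breed null likelihood distributions from
  10,000 simulated genotypes, quantile rejection at a configurable alpha).
- **`forensic_power`** — per breed-pair log(LR) distributions,
  false-positive/true-positive rates at log(LR) thresholds (normal
  approximation by default, empirical counting as a fallback), and the
  equal-prior posterior probability of correct assignment
  `odds/(odds+1)` with `odds = tp/alpha`.
- **`popgen_stats`** — Weir & Cockerham (1984) F_ST (ratio-of-sums
  multi-locus aggregation), Reynolds (1983) coancestry distance in the
  frequency-only locus-summed form
  `D = Σ_l (p1−p2)² / Σ_l (1 − Σ_a p1a p2a)`, Saitou–Nei neighbour joining
  with deterministic tie-breaks, locus-bootstrap branch support, and
  two-locus r² from unphased genotypes via EM haplotype estimation.
- **`cli_reporting`** — YAML-configurable pipeline orchestration and a
  `breedauth` CLI with per-stage subcommands.

## CLI

```sh
# one shot: simulate the 14-breed benchmark and run every stage
breedauth run-all --scenario british_pigs_like --seed 1 --out-dir out/

# or stage by stage
breedauth simulate --scenario british_pigs_like --out data/ref
breedauth qc     --genotypes data/ref.csv --map data/ref.loci.csv \
                 --out data/filtered.csv --report out/qc_report.csv
breedauth rank   --genotypes data/filtered.csv --out out/delta_ranking.csv
breedauth select --ranking out/delta_ranking.csv --size 96 --out out/panel.txt
breedauth assign --genotypes data/filtered.csv --panel out/panel.txt \
                 --out out/assignments.csv
breedauth exclude --genotypes data/filtered.csv --panel out/panel.txt \
                  --out out/exclusions.csv
breedauth power  --genotypes data/filtered.csv --panel out/panel.txt \
                 --out-prefix out/posterior_matrix
breedauth tree   --genotypes data/filtered.csv --panel out/panel.txt \
                 --out out/tree.nwk
```

`run-all` emits `qc_report.csv`, `delta_ranking.csv`,
`assignment_curve.csv/.png`, `panel.txt`, `assignments.csv`,
`exclusions.csv`, `posterior_matrix_t0.csv`, `posterior_matrix_t2.csv`,
`fst_matrix.csv`, `reynolds_matrix.csv`, `tree.nwk`, `ld_screen.csv` and a
`run_log.yaml` with the master seed and derived per-stage seeds. Identical
config + seed reproduces every CSV byte-for-byte.

## File dialects

- **CSV genotypes**: header `sample_id,breed,<locus ids...>`; cells are
  `0`/`1`/`2` (alternate-allele dosage) or empty for missing. An optional
  companion locus map CSV (`locus_id,chromosome,position_bp,ref_allele,
  alt_allele`) carries map information; positions are 1-based and
  `Undetermined` marks unmapped loci.
- **PED/MAP**: standard 6-column PED prefix with the family column used as
  the breed label; `0` is a missing allele; MAP chromosome `0` marks
  unmapped loci.

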