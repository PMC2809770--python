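# dfemk

Inference of negative and positive selection on protein-coding genes from
within-species polymorphism and between-species divergence.

The package annotates multi-individual coding alignments by codon
degeneracy (0-fold / 2-fold / 4-fold / intron, with splice-window exclusion
and CpG-prone flagging), computes diversity and divergence summary
statistics with locus bootstraps, builds folded site frequency spectra
grouped by per-site allele number, fits a gamma distribution of deleterious
fitness effects (DFE) together with a step-change demographic model by
maximum likelihood on Wright-Fisher transition-matrix expectations, and
estimates the fraction of adaptive amino acid substitutions (alpha) both
from the fitted DFE (model-based) and by frequency-filtered
McDonald-Kreitman counting.  A seeded synthetic-data generator emulates the
study design this pipeline assumes (amplicon loci, 15 diploid individuals,
one close and one distant outgroup, per-site missing data, inbreeding) and
doubles as the brute-force oracle for the inference code.

## Modules

| module | purpose |
| --- | --- |
| `dfemk.simulate` | synthetic locus sets / population SFSs with ground truth; forward Wright-Fisher engine and exact Markov-chain oracles |
| `dfemk.annotate` | per-site degeneracy class, splice exclusion, CpG-prone status, coverage |
| `dfemk.stats` | theta_pi, Watterson's theta, Tajima's D (20-allele downsampling), Jukes-Cantor divergence, Weir-Cockerham F_IS, N_e from diversity, locus bootstrap |
| `dfemk.sfs` | grouped folded spectra, hypergeometric downsampling, one-allele-per-individual resampling |
| `dfemk.dfe` | transition-matrix expected SFSs, gamma-DFE + step-change demography ML fit, weighted recent population size, N_e s class proportions |
| `dfemk.alpha` | model-based alpha, alpha_FWW (with >10% frequency filter), demographic-bias relation, bootstrap contrasts |
| `dfemk.pipeline` | end-to-end orchestration with TSV/JSON reports and logging |

## Command line

```bash
dfemk simulate --config sim.yaml --out data/ --seed 1
dfemk validate --in data/
dfemk annotate --in data/
dfemk stats    --in data/ --classes 0fold,2fold,4fold,intron
dfemk sfs      --in data/ --class 0fold --neutral 4fold
dfemk fit-dfe  --in data/ --selected 0fold --neutral 4fold --seed 1
dfemk alpha    --in data/ --method model --outgroup close --neutral 4fold --boot 200 --seed 1
dfemk pipeline --config run.yaml
```

A pipeline `run.yaml` names either an input directory (FASTA alignments +
`features.tsv`) or a `simulation:` block, plus `out_dir`, `seed`, the
neutral reference (`4fold` or `intron`), the outgroup (`close` or `far`)
and bootstrap replicate count.  Input format: one FASTA per locus with
records `reference`, `indNN_a`/`indNN_b` (two alleles per individual,
`N` = missing, `-` = gap), `outgroup_close`, `outgroup_far`; the feature
table has columns `locus  start  end  feature  frame  strand` (0-based,
half-open; feature is `CDS` or `intron`).

## Conventions worth knowing

- Folded spectra index sites by minor-allele count; cell 0 holds
  monomorphic sites; the n/2 cell for even n is counted once.
- The DFE fit reports selection on the *weighted recent population size*
  scale, N_w = N1(1-f2) + N2 f2 with f2 = 1 - exp(-t/(2 N2)) — a
  pair-coalescence stand-in convention, labelled in every output.
- The demographic-bias relation alpha_est = 1 - (1 - alpha_true) λ^(-b)
  is a reconstruction validated against published worked values (see
  `dfemk.alpha.BIAS_RELATION_LABEL`).
- Population sizes in the likelihood are scaled grid units (default
  2N1 = 100 chromosomes); only the size ratio and scaled times are
  identifiable.
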