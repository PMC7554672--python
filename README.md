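# ancrec — ancestral growth temperatures and gene-family repertoires

`ancrec` reconstructs two ancestral properties of prokaryotic lineages on
a rooted species tree, for evolutionary microbiologists asking questions
like "was the ancestor of this clade a thermophile, and what genes did it
carry?":

1. **A molecular thermometer.** Stem (paired) regions of the 16S rRNA
   keep a G+C content that tracks optimal growth temperature (OGT). The
   package calibrates OGT = a·stemGC% + b on extant taxa (with a
   phylogenetic-independent-contrasts diagnostic), fits a nonhomogeneous
   Tamura-92 substitution model with a branch-specific equilibrium GC
   θ_b, a global transition/transversion ratio κ and a free root
   composition by maximum likelihood, samples joint posterior replicates
   of ancestral stem sequences, and converts each replicate to an
   ancestral OGT with a 95% interval that propagates calibration
   uncertainty.

2. **Gene-family content.** Each protein family's copy number evolves as
   a birth–death chain — innovation 0→1 at rate g, per-copy duplication
   λ, per-copy loss μ. Per-family rates are fitted by ML (optionally with
   empirical-Bayes pooling across families), exact posterior copy-number
   distributions are computed at every ancestral node, and per-branch
   gains / losses / expansions / contractions are called where their
   exact joint parent–child posterior exceeds 0.5.

A SiLiX-style front end builds the families from an all-vs-all hit table
(identity ≥ 35%, alignment covering ≥ 70% of both sequence lengths,
E < 1e-4; single-linkage components). Synthetic-data generators with
recorded ground truth make every stage testable without downloads.
Models, study conditions and limitations are documented in
[docs/methods.md](docs/methods.md).

## Worked example

The numbered scripts under `analysis/` run the whole pipeline on a
synthetic 16-genome data set with recorded truth:

```
python analysis/01_simulate_inputs.py
python analysis/02_cluster_families.py
python analysis/03_thermometer.py
python analysis/04_gene_content.py
python analysis/05_recovery_studies.py
```

Steps 02–04 print, on the packaged simulation:

```
409 hits -> 203 surviving edges -> 12 families
planted partition recovered exactly: True

calibration: OGT = 1.374 * stemGC% + -19.55  (r = 0.615, PIC r = 0.378, n = 16)
root OGT: 74.5 degC [67.6, 85.4] (simulated truth 75.0 degC)

50 families on 16 genomes, tau = 0.5
root content: 34 families called present (simulated truth 34)
gain rate, ancestral vs terminal branches: rank-sum statistic 209.0, p = 0.7182
gains-per-family vs branch length: r = 0.875 over 14 ancestral branches
```

Reading this: the clustering screens left 203 of 409 hits and their
connected components reproduce the 12 planted families exactly. The
root-node OGT estimate (74.5 °C, CI 67.6–85.4 °C) brackets the simulated
truth of 75 °C — on this small demonstration tree the 16 tips span only
~16 °C of OGT, so the calibration slope is noisy (the replicated study in
step 05 runs the calibrated conditions). The content track called
exactly the 34 families truly present at the root; gain rates do not
differ between ancestral and terminal branches (p ≈ 0.72), as expected
for a simulation whose rates are branch-homogeneous, while the
per-branch proportion of gained families scales with branch length
(r ≈ 0.88).

Step 05 replicates the recovery studies at the calibrated conditions and
prints:

```
thermometer (50 replicates): slope median 2.18 (truth 2.0),
  root OGT median |error| 2.76 degC, CI coverage 98%
rate recovery: median relative error loss 2.1%, gain 1.9% over 993 families
presence calls: accuracy 98.0% over 1080 informative node calls;
  branch-gain Spearman 0.91
birth-death kernel vs Monte Carlo: max |z| = 1.47
```

The same machinery is scriptable as a CLI (`ancrec simulate | cluster |
thermometer | gene-content | all`, YAML config + flag overrides,
deterministic given `--seed`) or as a library:

```python
from ancrec import thermometer, genefam_bd
```

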