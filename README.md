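# repfrac

Copy-number fractioning and generalized similarity indices for bulk TCRβ
repertoires.

## The problem

An immune response against a large, complex antigen (sheep red blood cells
is the motivating model) recruits T cell clones so diverse that no shared
CDR3 motif marks them. What *is* detectable is their effect on average
repertoire properties: expanding antigen-specific private clones displace
the public clonotypes — shared, high-copy-number, VJ-restricted, multiply
encoded sequences — from whichever copy-number region the specific clones
occupy. `repfrac` implements the analysis stack that localizes this
displacement:

* **Systematic log2 copy-number fractioning.** Repertoires are split into
  10 fractions by clonotype copy number CN: fraction k (k = 1..9) holds
  2^(k−1) < CN ≤ 2^k and fraction 10 holds CN > 512. Each fraction is
  analysed separately, so an effect confined to, say, the high-CN region is
  not averaged away by the ~10⁴–10⁵ low-CN clonotypes.
* **Generalized Simpson-type indices.** For any reflexive, symmetric
  similarity relation R over clonotypes,
  `RHI_R(X) = #{i<j : x_i R x_j} / C(m,2)` is the probability that a random
  clonotype pair is similar (*Repertoire Homogeneity Index*). Shipped
  relations: equal V and J segments (RHI_VJ), CDR3β Levenshtein distance ≤ 1
  (RHI_LD), CDR3 identity, and nucleotide-coding count. The *Coding
  Diversity Index* `CDI(X) = mean_x [1 − Σ_i (ν(x⁽ⁱ⁾)/ν(x))²]` measures how
  diversely each clonotype is encoded at the nucleotide level. The
  cross-repertoire *Repertoire Similarity Index* RSI_R generalizes Sørensen
  (and, copy-number weighted, Morisita–Horn), and
  `d_{α,R} = 1 − Σ α_i·min(RSI_{R_i}, 1)` turns it into a dissimilarity.
* **Fraction-wise group statistics.** Per fraction, immunized vs control
  animals are compared with the Mann–Whitney U test; each 10-fraction row is
  Holm-corrected independently.
* **Classification.** Sub-repertoires (X_top: CN > 64, X_bottom: CN ≤ 4) are
  clustered with K-medoids on `d_V,J` or `d_NC` matrices, embedded by metric
  MDS, and classified by leave-one-out nearest-medoid with an exact Fisher
  evaluation.
* **Synthetic cohorts.** A seeded generator produces labeled cohorts with
  the public/private architecture above and an injectable immunization
  effect, so the whole stack is testable without sequencing data.

## Worked example

```python
from repfrac import (day3_like_config, generate_cohort, split_log2,
                     rhi, cdi, relation_vj, sub_repertoire,
                     dissimilarity_matrix, loo_classify, compare_cohorts)
import numpy as np

cohort = generate_cohort(day3_like_config(seed=1, n_control=8, n_treated=4))
rep = cohort.repertoires[0]
print(f"{rep.sample_id}: {len(rep)} clonotypes, {rep.total_reads} reads")

fr9 = split_log2(rep)[8]                      # fraction 9: 256 < CN <= 512
print(f"fraction 9: n={len(fr9)}, RHI_VJ={rhi(fr9, relation_vj()).value:.3f}, "
      f"CDI={cdi(fr9).value:.3f}")

cmp = compare_cohorts(cohort.controls(), cohort.treated(), "rhi_vj",
                      alternative="less")
print("RHI_VJ Holm-adjusted p per fraction:",
      np.array2string(cmp.p_adjusted, precision=3))

tops = [sub_repertoire(r, "top") for r in cohort.repertoires]
res = loo_classify(dissimilarity_matrix(tops, "vj"), cohort.labels)
print(f"LOO on X_top with d_V,J: accuracy={res.accuracy:.2f}, "
      f"Fisher p={res.fisher_p:.2e}")
```

prints

```
control_01: 3000 clonotypes, 64452 reads
fraction 9: n=13, RHI_VJ=0.051, CDI=0.471
RHI_VJ Holm-adjusted p per fraction: [1.    1.    1.    0.371 1.    1.    0.113 0.073 0.371 0.02 ]
LOO on X_top with d_V,J: accuracy=1.00, Fisher p=2.02e-03
```

The cohort here carries an "early response" effect: 40 animal-unique
specific clones injected into fractions 7–10 of each treated animal. The
one-sided comparison finds the RHI_VJ decrease only in the targeted high-CN
fractions (adjusted p = 0.02 in fraction 10; small cohort, so the
neighbouring fractions stay above 0.05), and leave-one-out classification of
the CN > 64 sub-repertoire separates treated from control animals perfectly.
With the full default cohort (20 control + 10 treated) several target
fractions reach adjusted significance; see `scripts/acceptance.py`.

## Command line

Every stage is also a subcommand of `repfrac`:

```bash
repfrac simulate --config study.yaml --out-dir sim/ --seed 1
repfrac preprocess --in sample.tsv --dialect airr --downsample-to 1600000 --seed 1 --out clean.tsv
repfrac fractions --in clean.tsv --scheme log2 --out-prefix sample
repfrac compare --control 'sim/control_*.tsv' --treated 'sim/immunized_*.tsv' \
                --index rhi_vj,rhi_ld,cdi --alternative less --out heatmap.tsv
repfrac classify --cohort 'sim/*.tsv' --labels sim/labels.tsv --sub top \
                 --criterion vj --mode loo --out cls
repfrac run --config study.yaml --out results/   # full pipeline, one config
```

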