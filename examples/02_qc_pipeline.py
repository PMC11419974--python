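"""Quality-control cascade on a deliberately messy genotype panel.

Missingness filter (SNPs then samples) -> MAF >= 0.05 -> Hardy-Weinberg
p >= 1e-6 -> genotype PCA; covariate gaps are mean/mode imputed and the
5-point CDR outcome is dichotomized at 0.5.
"""

import numpy as np
import pandas as pd

from bless import (
    GenotypeMatrix, SampleTable, run_qc, impute_simple, dichotomize_cdr,
)

rng = np.random.default_rng(2)
n, p = 120, 60
dosages = rng.binomial(2, rng.uniform(0.1, 0.5, p), size=(n, p)).astype(float)
dosages[:, 0] = rng.binomial(2, 0.02, n)            # rare variant -> MAF filter
dosages[:, 1] = rng.choice([0.0, 2.0], n)           # no hets -> HWE filter
dosages[:20, 2] = np.nan                            # 17% missing -> missingness
G = GenotypeMatrix([f"s{i}" for i in range(n)],
                   [f"rs{j:03d}" for j in range(p)], dosages)

cdr = rng.choice([0, 0.5, 1, 2], n, p=[0.55, 0.25, 0.15, 0.05])
age = np.where(rng.random(n) < 0.1, np.nan, rng.normal(70, 5, n))
S = SampleTable(pd.DataFrame({"cdr": cdr, "age": age},
                             index=pd.Index(G.samples, name="sample")),
                "cdr", ["age"])

S = impute_simple(S)
imputed = S.imputation_counts
S.data["y"] = dichotomize_cdr(S.data["cdr"].to_numpy())
S = SampleTable(S.data, "y", ["age"])
Gq, Sq, report = run_qc(G, S, miss_thr=0.05, maf_thr=0.05, hwe_thr=1e-6,
                        n_pcs=5)

for step in report.steps:
    print(f"{step['step']:>22}: -{step['snps_removed']} SNPs, "
          f"-{step['samples_removed']} samples")
print(f"survivors: {Gq.n_snps} SNPs x {Gq.n_samples} samples; "
      f"imputed cells: {imputed}")
print(f"covariates now include PCs: {Sq.covariates}")
print(f"impairment prevalence after dichotomization: {Sq.data['y'].mean():.2f}")
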