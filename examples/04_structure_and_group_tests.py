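"""Population structure by PCA and rank-based group comparison.

Simulates two populations diverged at 800 structure sites (Balding–Nichols
divergence 0.15), runs PCA on the variance-standardized genomic relationship
matrix, and tests a per-individual metric between populations with the
Kruskal–Wallis test and Dunn's post hoc comparisons.
"""

import numpy as np

from erodescan import (
    GenomeLayout,
    dosage_matrix,
    dunn_posthoc,
    kruskal_wallis,
    pca,
    standardized_grm,
)
from erodescan.simulate import PopulationSim, SimConfig, simulate_population

layout = GenomeLayout(scaffolds=(("scaf1", 5_000_000),))
config = SimConfig(
    layout=layout,
    populations=[PopulationSim("west", n=8, theta_bg=0.1),
                 PopulationSim("east", n=8, theta_bg=0.1)],
    snp_spacing_bp=1_000,
    n_structure_sites=800,
    structure_fst=0.15,
    seed=1,
)
matrix, _, _, metadata = simulate_population(config)

grm = standardized_grm(dosage_matrix(matrix))
res = pca(grm, k=3, samples=matrix.samples, n_snps=matrix.n_sites)
print("variance explained: "
      + ", ".join(f"PC{i+1} {v:.1%}" for i, v in
                  enumerate(res.variance_fraction)))
pc1 = res.coordinates["PC1"]
print(f"PC1 population means: west {pc1[:8].mean():+.2f}, "
      f"east {pc1[8:].mean():+.2f}  (opposite signs = separation)")

# rank tests on an arbitrary per-individual metric: here PC1 itself
groups = [pc1[:8].to_numpy(), pc1[8:].to_numpy()]
kw = kruskal_wallis(groups, grouping="population")
dunn = dunn_posthoc(groups, labels=["west", "east"])
print(f"\nKruskal-Wallis: H = {kw.h_statistic:.2f}, df = {kw.df}, "
      f"p = {kw.p_value:.2g}")
print(dunn.round(4).to_string(index=False))
print("\nPC1 separates the planted populations; the tie-corrected H and "
      "Dunn z quantify\nthe between-group difference without any normality "
      "assumption.")
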