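"""Plant runs of homozygosity of known age class and recover them.

Simulates one individual on a 120 Mb three-scaffold genome with planted IBD
tracts (10% historical, 5% intermediate, 10% recent inbreeding), calls ROH
with the sliding-window caller, and compares the recovered per-bin genomic
inbreeding coefficient F_ROH against the planted truth.
"""

from erodescan import AgeModel, GenomeLayout, call_roh_matrix, froh
from erodescan.simulate import PopulationSim, SimConfig, simulate_population

layout = GenomeLayout(scaffolds=tuple((f"scaf{i}", 40_000_000) for i in range(3)))
config = SimConfig(
    layout=layout,
    populations=[PopulationSim("fox", n=1, theta_bg=0.25,
                               froh_targets=(0.10, 0.05, 0.10))],
    snp_spacing_bp=1_000,
    seed=1,
)
matrix, _, truth, _ = simulate_population(config)
print(f"simulated {matrix.n_sites:,} SNP sites; "
      f"{len(truth.tracts['fox_00'])} planted tracts")

segments = call_roh_matrix(matrix, layout)["fox_00"]
result = froh(segments, layout, individual="fox_00")
age_model = AgeModel()

print(f"\ncalled {len(segments)} ROH segments; "
      f"longest {max(s.length_mb for s in segments):.1f} Mb")
print(f"{'bin':>14}{'planted F':>11}{'recovered F':>13}{'age range (gen)':>18}")
for i, label in enumerate(age_model.bin_labels):
    young, old = age_model.bin_age_range(i)
    rng_txt = f"{young:.0f}-{old:.0f}" if young else f"<{old:.0f}"
    print(f"{label:>14}{truth.froh['fox_00'][label]:>11.4f}"
          f"{result.per_bin[label]:>13.4f}{rng_txt:>18}")
print(f"{'total':>14}{sum(truth.froh['fox_00'].values()):>11.4f}"
      f"{result.total:>13.4f}")
print("\nEach row is the fraction of the analyzable genome in ROH of that "
      "length class;\nthe age range is g = 100/(2 r L) at r = 0.6 cM/Mb. "
      "Recovered F tracks planted F\nto a few percent relative — the caller's "
      "boundary error is about one window of SNPs.")
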