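"""Build a completeness-cutoff dataset family from a panel with
restriction-site allelic dropout.

Each cutoff is the minimum number of genotyped individuals a locus needs
to be retained; the summary mirrors a study-design table: locus count,
percent of individuals required, and percent of missing cells left.
"""

from radmiss import (
    SimConfig,
    apply_allelic_dropout,
    build_dataset_family,
    simulate_snp_panel,
)

gm, truth = simulate_snp_panel(SimConfig(n_loci=2000, target_fst=0.10, seed=2))
gm, _ = apply_allelic_dropout(gm, truth, seed=2)

family = build_dataset_family(gm, cutoffs=[83, 75, 65, 50, 30, 1])
print(family.summary().to_string(index=False))
print("\nStricter cutoffs keep fewer, more complete loci; the weakest "
      "cutoff keeps every locus called at least once.")
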