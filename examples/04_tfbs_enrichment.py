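"""Promoter-window TFBS enrichment of a candidate gene set.

Simulates a conserved-TFBS resource in which one TF preferentially targets
a 60-gene set (probability 0.5 vs background 0.1), maps sites to 4 kb
TSS-centered promoter windows, and runs the per-TF Fisher/BH enrichment.
"""

from mitocoex import build_promoters, map_tfbs, rank_tfs, tf_enrichment
from mitocoex.simulate import TfbsSimConfig, generate_tfbs_annotation

genes = [f"g{i:04d}" for i in range(2000)]
candidates = set(genes[:60])

config = TfbsSimConfig(
    n_tfs=50, p0=0.1, p1=0.5,
    enriched_genes=tuple(sorted(candidates)),
    seed=5,
)
annotation = generate_tfbs_annotation(genes, config)
print(f"simulated {len(annotation.sites)} conserved sites for "
      f"{len(set(annotation.motif_map.values()))} TFs "
      f"({len(annotation.motif_map)} motifs)")

promoters = build_promoters(annotation.tss, half_width=2000)
targets = map_tfbs(annotation.sites, annotation.motif_map, promoters)
table = tf_enrichment(candidates, set(genes), targets)
report = rank_tfs(table, alpha=0.05)

print(report.head(5)[["a", "c", "fold", "p_raw", "p_bh", "significant_bh"]].to_string())
n_sig = int(report["significant_bh"].sum())
print(f"{n_sig} TF(s) BH-significant at α = 0.05 "
      f"(planted: {config.enriched_tf_label})")
# The planted TF should top the ranking with a fold enrichment near
# p1/p0 = 5 and survive BH correction; background TFs should not.
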