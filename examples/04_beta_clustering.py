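"""Beta-diversity partition and neighbor-joining site clustering.

Partitions multi-site Sorensen dissimilarity per mountain into
turnover (beta_SIM) and nestedness (beta_SNE), then clusters all
trapping locations of both mountains by pairwise Sorensen distance
with neighbor-joining.  High beta_SIM means elevational assemblages
replace one another rather than being nested subsets.
"""
import elevdiv as ed

ds, _ = ed.simulate_survey(ed.paperlike_preset(), seed=1)
im = ed.build_abundance_matrix(ed.filter_records(ds)).to_incidence()

for mountain in ds.mountains():
    part = ed.multisite_partition(im.for_mountain(mountain))
    print(f"Mountain {mountain}: beta_SOR={part.beta_sor:.2f} "
          f"beta_SIM={part.beta_sim:.2f} beta_SNE={part.beta_sne:.2f} "
          f"({part.n_sites} sites, {part.n_species} species)")

pw = ed.pairwise_partition(im)
tree = ed.nj_tree(ed.to_distance_matrix(pw.sor))
print("\nNeighbor-joining tree of trapping locations (Newick):")
print(ed.write_newick(tree))
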