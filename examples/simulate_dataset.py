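"""Simulate a small two-guild proteome dataset with known ground truth.

The generator plants universal single-copy core families, patchy
accessory families, guild-biased families and a guild-marker family on
a Yule species tree, then evolves protein sequences along it.
"""

from guildphylo import evolve_sequences, simulate_families, simulate_species_tree
from guildphylo.synthetic_genomes import guild_assignment

tree = simulate_species_tree(n_taxa=10, seed=42, mean_branch=0.025)
guilds = guild_assignment(tree, "clade")
truth = simulate_families(tree, guilds, n_core=10, n_accessory=8, n_biased=8, seed=43)
proteomes = evolve_sequences(truth, root_len=80, seed=44)

print("species tree:", tree.to_newick(precision=3))
print("guilds:", guilds)
for p in proteomes[:3]:
    print(f"{p.genome_id}: {len(p)} genes, {len(p.annotations)} annotated")
kinds = {}
for fam in truth.families.values():
    kinds[fam.kind] = kinds.get(fam.kind, 0) + 1
print("family kinds:", kinds)
# Each genome carries the core families once, about half the accessory
# families, and the guild-biased families mostly when they match its guild.
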