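"""Megaphylogeny housekeeping: grafting, pruning, PD and topology indices.

Shows the tree-side utilities: attach missing species at congeneric or
family nodes, prune to a site's species list, and summarise the site tree.
"""

import dendropy

from phylodom import (TreeIndex, faith_pd, graft_species, prune_to_site,
                      site_tree_stats)

tree = dendropy.Tree.get(
    data="((Poa_alpina:30,Poa_annua:30):30,"
         "(Festuca_rubra:40,Bromus_erectus:40):20);",
    schema="newick", preserve_underscores=True)
tree.is_rooted = True

grafted, report = graft_species(
    tree, ["Poa_pratensis", "Lolium_perenne"],
    family_of={g: "Poaceae" for g in ("Poa", "Festuca", "Bromus", "Lolium")})
print(report.to_string(index=False))
# Poa_pratensis attaches at the MRCA of its congeners; Lolium has no
# congener, so it drops to the family node.

site_species = ["Poa_alpina", "Poa_pratensis", "Festuca_rubra"]
idx = TreeIndex(grafted)
print("Faith's PD of the site:", faith_pd(idx, site_species))
site_tree = prune_to_site(grafted, site_species)
print("pruned newick:", site_tree.as_string(schema="newick").strip())
print(site_tree_stats(grafted, site_species, site_id="alp01"))
# gamma < 0 means the site tree's nodes sit deep; Colless/Sackin summarise
# its shape imbalance.
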