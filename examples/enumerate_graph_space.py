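"""Exhaustive admixture-graph topology catalogs for small problems.

Counts all distinct leaf-labeled topologies after isomorphism
deduplication.  With no admixture events these are the rooted binary trees
((2n-3)!!); with two admixture events on five populations the catalog
reaches 32,745 topologies -- the space used for exhaustive model-ranking
studies.
"""

import time

from ascbias import enumerate_topologies

for n_leaves, n_admix in [(4, 0), (5, 0), (4, 1), (4, 2), (5, 1)]:
    cat = enumerate_topologies(n_leaves, n_admix)
    print(f"{n_leaves} leaves, {n_admix} admixture events: {len(cat):6d} topologies")

t0 = time.time()
cat = enumerate_topologies(5, 2)
print(f"5 leaves, 2 admixture events: {len(cat):6d} topologies "
      f"({time.time()-t0:.0f}s)")
# one catalog entry is an AdmixtureGraph ready for fitting:
print("example topology:")
print(cat[0].to_text())
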