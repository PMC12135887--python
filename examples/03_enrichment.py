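"""Gene-set enrichment: hypergeometric over-representation of a hit list and
preranked GSEA on a fold-change ranking.
"""

import numpy as np

from tmtboot import fisher_ora, gsea_preranked
from tmtboot.types import GeneSet, GeneSetCollection

rng = np.random.default_rng(3)
universe = [f"GENE{i:03d}" for i in range(200)]

# a ranking in which the first 20 genes carry strong positive scores
metric = np.concatenate([rng.normal(2.0, 0.5, 20), rng.normal(0, 1, 180)])

sets = GeneSetCollection()
sets.add(GeneSet("responsive_pathway", "overlaps the signal", tuple(universe[:15])))
sets.add(GeneSet("random_pathway", "no overlap structure",
                 tuple(rng.choice(universe, 15, replace=False))))

res = gsea_preranked(universe, metric, sets, nperm=2000, min_size=5, seed=1)
print("preranked GSEA (positive NES = concentrated at the top of the ranking):")
for r in res:
    print(f"  {r.set_name}: ES {r.es:+.2f}, NES {r.nes:+.2f}, p {r.p_perm:.4f}, "
          f"q {r.q_bh:.4f}, leading edge {len(r.leading_edge)} genes")

hits = universe[:25]  # e.g. the differentially abundant proteins
ora = fisher_ora(hits, universe, sets)
print("\nover-representation of the hit list (one-sided hypergeometric):")
for r in ora:
    print(f"  {r.set_name}: overlap {r.overlap}/{r.set_size}, p {r.p:.2e}, q {r.q_bh:.2e}")
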