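"""Region-set overlap enrichment (location overlap analysis).

A query region set is tested against a database of region sets with a 2x2
Fisher's exact test per database set, counted over universe units.  Here
the query is built to overlap one database set strongly; that set should
rank first with a large odds ratio.
"""

import numpy as np

from epirewire.enrichment import RegionDatabase, build_universe, region_enrichment
from epirewire.regions import GenomicRegion, RegionSet

rng = np.random.default_rng(0)
genome = {"chr1": 10_000_000}


def units(ids, name):
    return RegionSet(
        name,
        [GenomicRegion("chr1", 1000 * i, 1000 * i + 400, ".", f"{name}_{i}") for i in ids],
        genome,
    )


# 500 universe units; query overlaps "tf_sites" on 60% of its units,
# the two control sets only at random (~10%)
query_ids = sorted(rng.choice(500, 100, replace=False))
query = units(query_ids, "query_peaks")
db = RegionDatabase({
    "tf_sites": units(sorted(set(rng.choice(query_ids, 60, replace=False))
                             | set(rng.choice(500, 40, replace=False))), "tf_sites"),
    "control_a": units(sorted(rng.choice(500, 100, replace=False)), "control_a"),
    "control_b": units(sorted(rng.choice(500, 100, replace=False)), "control_b"),
})
universe = build_universe(query, db, user_universe=units(range(500), "universe"))

res = region_enrichment(query, db, universe)
print(res[["set", "a", "b", "c", "d", "odds_ratio", "p", "fdr", "rank"]].to_string(index=False))
# a = universe units in both query and set; the planted "tf_sites" set ranks
# first with an odds ratio far above the overlap-by-chance controls.
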