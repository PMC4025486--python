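"""Cluster unique sites into PACs and assign them to genic regions.

Microheterogeneity scatters reads around each biological site, so
adjacent unique sites (>= 3 reads each) are merged into poly(A) site
clusters, and each cluster's representative site is placed into
5'-UTR / CDS / intron / 3'-UTR (with a 50-nt downstream extension) or
intergenic space.
"""

import apakit as ak

cfg = ak.SimConfig(seed=11)
genome, models, truth = ak.make_genome(cfg)
reads, _ = ak.simulate_reads(genome, truth, cfg)
res = ak.run_pipeline(genome, reads, ak.TailParams.for_mode("NGS"),
                      models=models, min_support=3, max_span=24)

print(f"{len(res.sites)} unique sites -> {len(res.pacs)} PACs "
      f"(span cap 24 nt, support filter >= 3 reads)")
print(res.pac_table.head(5).to_string(index=False))

dist = ak.region_distribution(res.assignments)
print("\nregional distribution of PAC representatives (%):")
print(dist.round(2).to_string())
print("\nPlanted sites sit in 3'-UTRs (some only reachable through the"
      "\n50-nt extension) and introns; the percentages above recover the"
      "\nplanted proportions.")
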