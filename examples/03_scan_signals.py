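"""Scan PAC flanks for poly(A) signals and score them against a Markov
background.

Flanks are 150-mers (-100..+50, site at -1).  The NUE window (-28..-5)
is scanned for pentamers in frequency mode (one count per sequence, the
occurrence closest to the site) and each motif's count is compared with
its expectation under an order-3 Markov model of the same sequences.
"""

import warnings

import apakit as ak

cfg = ak.SimConfig(seed=1)
genome, models, truth = ak.make_genome(cfg)
reads, _ = ak.simulate_reads(genome, truth, cfg)
res = ak.run_pipeline(genome, reads, ak.TailParams.for_mode("NGS"),
                      models=models)

utr3 = set(res.assignments.query("region == 'UTR3'")["pac_id"])
flanks = [f.sequence for f in res.flanks if f.pac_id in utr3]
print(f"scanning {len(flanks)} 3'-UTR PAC flanks, NUE window -28..-5")

spec = ak.ScanSpec(k=5, window=(-28, -5), mode="frequency")
table = ak.scan_kmers(flanks, spec)
with warnings.catch_warnings():
    warnings.simplefilter("ignore")  # toy data are sparse for order 3
    bg = ak.train_markov(flanks, order=3)
scored = ak.score_motifs(table, bg)
top = scored.sort_values("rank").head(5)
print(top[["count", "frequency", "zscore", "rank"]].round(3).to_string())

prof = ak.nucleotide_profile(flanks)
print("\nU frequency around the planted NUE (labels -24..-18):")
print(prof.loc[-24:-18, "U"].round(2).to_string())
print("\nThe planted UGUAA tops the ranking with a Z-score far above the"
      "\nMarkov expectation; the single-nucleotide profile shows the"
      "\nmatching U/A peaks just upstream of the site.")
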