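"""Flow signatures, pattern tabulation and top-k ranking concordance.

The five-super-taxon ring has six gain sites; each floods a distinct
informative presence/absence pattern (its flow signature).  We simulate a
whole-genome-style ortholog table evolved on that ring and ask whether
the six signatures are exactly the six most gene-rich of the 25
informative patterns — and how improbable that agreement would be by
chance.
"""

from ringroot import datasets, flow_signatures, tabulate_patterns, top_k_concordance
from ringroot.pattern_flows import pattern_string, rank_concordance_p
from ringroot.synthetic_data import default_config, simulate_flows

ring = datasets.inner_ring_five()
sites = datasets.inner_ring_five_gain_sites()
sigs = flow_signatures(ring, sites, datasets.FIVE_TAXA)
print("Flow signatures (taxon order A D F H E):")
for sid, pat in sigs.signatures.items():
    print(f"  {sid:10s} {pattern_string(pat, datasets.FIVE_TAXA)}")

cfg = default_config(seed=7, loss_prob=0.02)
table, _ = simulate_flows(cfg)
pt = tabulate_patterns(table, datasets.FIVE_TAXA)
print(f"\nTop 8 of the {len(pt.counts)} informative patterns "
      f"({cfg.n_families} simulated families, loss rate {cfg.loss_prob}):")
print(pt.to_frame().head(8))

report = top_k_concordance(pt, sigs)
print(f"\ntop-{report['k']} match: {report['match']}   "
      f"p = {report['p']:.3e}" if report["p"] else
      f"\ntop-{report['k']} match: {report['match']}")
print(f"exact null probability 1/C(25,6) = "
      f"{rank_concordance_p(25, 6, exact=True)}")

print()
print("A full match at p ~ 5.6e-6 means the ranking agreement between the")
print("indel-predicted flows and the ortholog counts is no coincidence.")
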