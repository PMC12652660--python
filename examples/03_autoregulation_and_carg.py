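"""Detect autoregulatory binding sites and CArG-box consensus matches.

A TF whose own promoter is in the panel can bind itself: planting TF000's
consensus inside its own promoter produces a self-site, and the CArG matcher
screens any sequence for the MADS-domain consensus CC(A/T)6GG.
"""

import promotif as pm

pfms = pm.simulate_pwms(2, 10, 0.97, seed=61)
pwms = [pm.pfm_to_pwm(p) for p in pfms]
# TF000's own gene is GENE01; plant its motif there and elsewhere
plants = [
    pm.PlantSpec("GENE01", pfms[0].matrix_id, -1024, "+"),
    pm.PlantSpec("GENE02", pfms[0].matrix_id, -350, "-"),
]
promoters, _ = pm.simulate_promoters(2, pfms, plants, seed=62)
hits = pm.scan_collection(pwms, promoters)

tf_map = pm.TFGeneMap({"TF000": "GENE01"})
report = pm.detect_autoregulation(hits, tf_map, gene_ids={"GENE01", "GENE02"})
print("autoregulatory sites of TF000 in its own promoter:")
for h in report.sites["TF000"]:
    print(f"  {h.start:>6} {h.strand}  p = {h.pvalue:.2e}  [{h.tier}]")
print("high-stringency self-site:", report.has_high_stringency_site("TF000"))

seq = "TTTCCAATTAAGGAAACCTTTTTTGGT"
print(f"\nCArG-box matches in {seq}:")
for pos, word in pm.match_carg(seq):
    print(f"  offset {pos}: {word}")

# A stringent site in a TF's own promoter is the sequence-level signature of
# an autoregulatory feedback loop; CC(A/T)6GG is its own reverse complement,
# so the forward-strand search covers both strands.
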