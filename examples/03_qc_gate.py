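"""Array QC: MAPD and the pass/fail gate.

MAPD (median absolute pairwise difference of consecutive LogR values) is
the standard array noise metric; tracks above 0.30 are rejected.  The
vendor metric ndSNPQC, when supplied, must reach 26.
"""

import hrdscar as h

genome = h.load_genome("hg19")

for sigma in (0.10, 0.35):
    _, track = h.simulate_sample(
        genome, h.SimConfig(seed=2, sigma_logr=sigma, n_loh=0, n_lst=0, n_tai=0)
    )
    qc = h.qc_gate(h.QCMetrics(mapd=h.mapd(track), nd_snp_qc=30.0))
    status = "pass" if qc.passed else f"fail ({'; '.join(qc.reasons)})"
    print(f"sigma_logr={sigma:.2f}: MAPD={qc.mapd:.3f} -> {status}")

# boundary semantics are inclusive on both rules
print(h.qc_gate(h.QCMetrics(mapd=0.30, nd_snp_qc=26)).passed, "<- 0.30 / 26 both pass")
print(h.qc_gate(h.QCMetrics(mapd=0.31, nd_snp_qc=25)).reasons)
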