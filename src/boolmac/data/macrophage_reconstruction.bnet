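# Macrophage differentiation regulatory network -- SYNTHETIC RECONSTRUCTION.
#
# 29 nodes, 52 interactions between distinct nodes (plus the 9 input
# self-copies and one SOCS1 self-sustain loop).  This rule set is NOT the
# original supplementary truth table of the published model; it was
# reconstructed from the structural and behavioral constraints stated in the
# article text (node inventory, named circuits, micro-environment
# definitions, marker semantics, mutant phenotypes).  See the package methods
# note for the rule-by-rule rationale and for which published observations
# the reconstruction does and does not reproduce.
#
# Naming: _e = extrinsic cytokine (input, self-copy rule), _out = cytokine
# produced by the macrophage, STAT3_s = IL-10 dependent STAT3 signaling
# (displayed as "STAT3*"); STAT3 = IL-6/EGF dependent STAT3 signaling.
targets, factors
IFNG_e, IFNG_e
GMCSF_e, GMCSF_e
LPS_e, LPS_e
IL4_e, IL4_e
IC_e, IC_e
IL1B_e, IL1B_e
IL10_e, IL10_e
NECA_e, NECA_e
EGFR_e, EGFR_e
TLR4, LPS_e
IL1R, IL1B_e
FCGR, IC_e
IL4R, IL4_e
IL6R, IL6_out & !SOCS3
IL10R, IL10_e
STAT1, IFNG_e & !SOCS1 & !STAT6 & !STAT3_s
STAT5, GMCSF_e & !SOCS1 & !STAT3_s
STAT6, IL4R & !SOCS1 & !STAT1
STAT3, (IL6R | EGFR_e) & !SOCS1
STAT3_s, IL10R & !STAT3 & !STAT6
SOCS1, (STAT3_s & !FCGR) | (STAT1 & STAT6) | (SOCS1 & IL4R & (TLR4 | IFNG_e))
SOCS3, STAT3
NFKB, (TLR4 | IL1R | EGFR_e) & !SOCS1
PPARG, STAT6
HIF1A, (NECA_e & NFKB) | (FCGR & STAT6 & IL10R)
IL12_out, STAT1 & NFKB
IL6_out, (STAT3 | (NFKB & IL6R)) & !STAT6
IL10_out, PPARG | STAT3_s | (FCGR & NFKB)
VEGF_out, HIF1A
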