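"""Threshold scan of the fixture's MI matrix.

Binarizes the MI matrix at every R in 0.001..0.999 (step 0.001), tracking
edge density and connectivity, and reports the largest threshold that keeps
the network a single component.
"""

from acunet import lbp_fixture, mi_matrix, scan_thresholds

mi = mi_matrix(lbp_fixture())
scan = scan_thresholds(mi)

print(f"largest R keeping the network connected: {scan.r_max_connected}")
df = scan.to_frame()
in_band = df[(df.edge_density >= 0.39) & (df.edge_density <= 0.50)
             & (df.fully_connected == 1)]
print(f"connected networks with density in [0.39, 0.50]: {len(in_band)}")
print(in_band.head(8).to_string(index=False))
# Raising R prunes weak edges (density falls monotonically); past
# r_max_connected the network fragments and path-based metrics lose meaning.
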