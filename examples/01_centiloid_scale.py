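"""Convert amyloid-PET SUVR values to the harmonized Centiloid scale.

The map is an affine fit through two published calibration pairs; applying it
to a mean cortical SUVR tells you where a scan sits on the 0 (young controls)
to 100 (typical AD) Centiloid axis, and the 1.42 SUVR threshold dichotomizes
scans into amyloid negative/positive.
"""

from amyloidcast import amyloid_status, default_centiloid_map

cmap = default_centiloid_map()
print(f"map: CL = {cmap.slope:.1f} * SUVR + {cmap.intercept:.1f}")
for suvr in (1.20, 1.42, 1.75, 2.48, 2.94):
    cl = float(cmap.to_centiloid(suvr))
    status = "positive" if amyloid_status(suvr) else "negative"
    print(f"SUVR {suvr:.2f} -> {cl:6.1f} Centiloids  (amyloid {status})")
# A scan at 2.94 SUVR (~85 CL) carries roughly the amyloid burden of a
# typical symptomatic AD patient; 1.42 SUVR (16.4 CL) is the positivity cut.
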