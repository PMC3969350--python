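"""Inspect the packaged lipophilicity scale and recompute a maximal
side-chain surface area.

The scale maps each side chain's raw logP through two affine steps so
that Gly is 0 and the Arg+ -> Ile range spans exactly 1; His enters as a
pH 7.4 protonation mixture.  The maximal side-chain SASA — the exposure
denominator of the lipophilic intensity — is the side-chain area of X in
an extended Gly-X-Gly tripeptide.
"""

from cyclodesc.lipo_scale import (
    his_protonated_fraction,
    load_default_scale,
    max_sidechain_sasa,
    scale_and_normalize,
)

scale = load_default_scale()
print("normalized lipophilicity (packaged):")
for code in ("GLY", "ILE", "ARG", "TRP", "CYS", "ACK", "CDR"):
    e = scale[code]
    print(f"  {e.name:>5}: {e.normalized:+.3f}   (SASA_max {e.sasa_max:.2f} A^2)")

scaled, norm = scale_and_normalize(raw_logp=2.657, scaled_gly=0.62)
print(f"\nIle anchor: raw 2.657 -> scaled {scaled:.3f}, normalized {norm:+.3f}")
f = his_protonated_fraction(ph=7.4, pka=6.50)
print(f"His at pH 7.4: {100 * f:.1f}% protonated / {100 * (1 - f):.1f}% neutral")

for code in ("GLY", "ALA", "TRP"):
    print(f"recomputed SASA_max({code}) = {max_sidechain_sasa(code):.2f} A^2"
          f"   (packaged {scale.sasa_max(code):.2f})")
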