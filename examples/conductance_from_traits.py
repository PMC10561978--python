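"""Anatomical maximum stomatal conductance from measured traits.

Takes per-image mean stomatal length SL, mean guard-cell width l (used as
the pore-depth proxy) and stomatal density SD, and evaluates

    g_smax = d · SD · α_max / ( v · (l + (π/2)·√(α_max/π)) ),  α_max = π·SL²/4

at 25 °C / 101.3 kPa.  The printed value is the theoretical upper bound on
water-vapour conductance the anatomy allows (mol m⁻² s⁻¹) — larger pores,
denser stomata or shallower pores raise it.
"""

from stomakit import alpha_max, gsmax

TRAITS = [  # (mean length µm, mean width µm, density mm⁻²)
    (42.09, 14.35, 53.74),
    (46.04, 17.01, 34.54),
    (31.92, 16.85, 53.74),
]

print(f"{'SL (um)':>8} {'l (um)':>7} {'SD (mm^-2)':>10} "
      f"{'a_max (um^2)':>12} {'g_smax':>7}")
for sl, lumen, density in TRAITS:
    print(f"{sl:8.2f} {lumen:7.2f} {density:10.2f} "
          f"{alpha_max(sl):12.1f} {gsmax(sl, lumen, density):7.2f}")
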