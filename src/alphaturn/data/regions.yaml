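# Default phi/psi conformational-region map for turn designation.
# Rectangles are evaluated in order, closed at the lower bound and open at
# the upper bound (a bound of 180 is treated closed, since 180 == -180);
# anything unmatched falls back to "X".  These rectangles are calibrated
# stand-ins for the alpha-turn region typology of the protein-structure
# literature, not a reproduction of any published region set; substitute
# your own file to use the literature definition.
fallback: X
regions:
  - label: A
    phi: [-140.0, -30.0]
    psi: [-90.0, 45.0]
  - label: B
    phi: [-180.0, -30.0]
    psi: [45.0, 180.0]
  - label: "αL"
    phi: [30.0, 180.0]
    psi: [-10.0, 120.0]
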