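# Bondi van der Waals radii (Angstrom) used for accessible-surface
# computation, identical to the set used for conventional polar surface
# area.  Override any entry, or add elements, by passing your own file.
radii:
  C: 1.70
  N: 1.55
  O: 1.52
  H: 1.20
  S: 1.80
# Distance-based bond inference: i-j bonded iff
#   d_ij <= bond_scale * (r_i + r_j) + tolerance   (tolerance default 0.0 A)
bond_scale: 0.6
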