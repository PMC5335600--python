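# Default thresholds for the rule-based filters, the bioavailability radar,
# the Abbott bioavailability score and the BOILED-Egg geometry.
#
# The BOILED-Egg ellipses are a synthetic axis-aligned approximation built
# from the published extents of the two regions (the original best-fit
# ellipse coefficients are not public); replace with fitted coefficients for
# exact reproduction.

filters:
  lipinski:            # rule-of-five; "pass" tolerates one violation
    mw_max: 500.0
    mlogp_max: 4.15
    hbd_max: 5
    hba_max: 10
    max_violations_for_pass: 1
  ghose:               # closed intervals (boundaries pass)
    mw_min: 160.0
    mw_max: 480.0
    wlogp_min: -0.4
    wlogp_max: 5.6
    mr_min: 40.0
    mr_max: 130.0
    atoms_min: 20
    atoms_max: 70
  veber:
    rotatable_bonds_max: 10
    tpsa_max: 140.0
  egan:
    wlogp_max: 5.88
    tpsa_max: 131.6
  muegge:
    mw_min: 200.0
    mw_max: 600.0
    logp_min: -2.0
    logp_max: 5.0
    tpsa_max: 150.0
    rings_max: 7
    carbons_min_exclusive: 4
    heteroatoms_min_exclusive: 1
    rotatable_bonds_max: 15
    hba_max: 10
    hbd_max: 5
  leadlikeness:
    mw_min: 250.0
    mw_max: 350.0
    logp_max: 3.5
    rotatable_bonds_max: 7

radar:                  # per-axis compliant ranges [min, max]
  lipophilicity: [-0.7, 6.0]   # XLOGP3-slot value; alternative ceiling 5.0
  size: [150.0, 500.0]         # MW, g/mol
  polarity: [20.0, 130.0]      # TPSA, A^2
  insolubility: [-6.0, .inf]   # ESOL log S floor
  insaturation: [0.25, 1.0]    # fraction Csp3
  flexibility: [0.0, 9.0]      # rotatable bonds

bioavailability_score:
  anion_low_tpsa: 0.85         # anion, TPSA <= 75
  anion_mid_tpsa: 0.56         # anion, 75 < TPSA <= 150
  anion_high_tpsa: 0.11        # anion, TPSA > 150
  default_pass: 0.56           # non-anion passing the rule-of-five
  default_fail: 0.17           # non-anion failing the rule-of-five
  anion_tpsa_low: 75.0
  anion_tpsa_high: 150.0

boiled_egg:
  white: {cx: 71.0, cy: 2.25, rx: 71.0, ry: 4.55, rotation: 0.0}
  yolk: {cx: 39.5, cy: 3.2, rx: 39.5, ry: 2.8, rotation: 0.0}
  tpsa_range: [0.0, 200.0]
  wlogp_range: [-4.0, 8.0]
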