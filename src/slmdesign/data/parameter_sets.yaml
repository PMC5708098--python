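# Synthetic default kinetic parameter sets for the sequence-level model.
#
# Seven sets (ids 1-7) are provided so that consensus design over several
# model variants can be exercised.  The values below are defaults authored
# for this package: they span the documented parameter vocabulary of the
# model family (binding scale K, activation strength, short-range quenching,
# pairwise cooperativity, coactivation of Hunchback by Bicoid, direct
# repression) with magnitudes chosen so that a consensus site at peak
# factor concentration carries a statistical weight K * [TF] * e^LLR of
# order 1-10 (occupancy 0.5-0.9) while near-threshold sites are weakly
# occupied.  They are not a fit to reporter data.  Set 7 declares Zelda as
# a uniformly expressed activator at a constant concentration of 100.
#
# Units: concentrations are arbitrary atlas units (0-100-ish); binding_scale
# converts concentration x e^LLR into a dimensionless statistical weight;
# ranges and gaps are in bp; r_max is on the 0-255 display scale.

parameter_sets:
  1:
    factors: &base_factors
      bcd:
        binding_scale: 3.0e-05
        role: activator
        activation_strength: 2.0
        cooperativity: {partner: bcd, strength: 5.0, max_gap: 12}
      hb:
        binding_scale: 5.5e-06
        role: coactivatable-repressor
        activation_strength: 1.5
        quench_efficiency: 0.5
        quench_range: 100
        coactivation: {partners: [bcd], range: 150}
      Kr:
        binding_scale: 5.5e-07
        role: repressor
        quench_efficiency: 0.95
        quench_range: 100
        direct_repression_strength: 0.2
      gt:
        binding_scale: 6.0e-07
        role: repressor
        quench_efficiency: 0.95
        quench_range: 100
        direct_repression_strength: 0.2
      kni:
        binding_scale: 3.0e-06
        role: repressor
        quench_efficiency: 0.95
        quench_range: 100
        direct_repression_strength: 0.2
    r_max: 255.0
    response_midpoint: 4.0
    response_steepness: 1.5
  2:
    factors:
      <<: *base_factors
      bcd:
        binding_scale: 4.0e-05
        role: activator
        activation_strength: 1.8
        cooperativity: {partner: bcd, strength: 8.0, max_gap: 10}
    r_max: 255.0
    response_midpoint: 4.2
    response_steepness: 1.4
  3:
    factors:
      <<: *base_factors
      Kr:
        binding_scale: 7.0e-07
        role: repressor
        quench_efficiency: 0.9
        quench_range: 120
        direct_repression_strength: 0.3
      gt:
        binding_scale: 7.5e-07
        role: repressor
        quench_efficiency: 0.9
        quench_range: 120
        direct_repression_strength: 0.3
    r_max: 255.0
    response_midpoint: 3.8
    response_steepness: 1.6
  4:
    factors:
      <<: *base_factors
      hb:
        binding_scale: 8.0e-06
        role: coactivatable-repressor
        activation_strength: 1.8
        quench_efficiency: 0.6
        quench_range: 90
        coactivation: {partners: [bcd], range: 120}
    r_max: 255.0
    response_midpoint: 3.8
    response_steepness: 1.5
  5:
    factors:
      <<: *base_factors
      bcd:
        binding_scale: 2.0e-05
        role: activator
        activation_strength: 2.4
        cooperativity: {partner: bcd, strength: 4.0, max_gap: 15}
    r_max: 255.0
    response_midpoint: 4.0
    response_steepness: 1.3
  6:
    factors:
      <<: *base_factors
      bcd:
        binding_scale: 3.0e-05
        role: activator
        activation_strength: 2.0
        cooperativity: {partner: bcd, strength: 6.0, max_gap: 12}
      hb:
        binding_scale: 4.0e-06
        role: coactivatable-repressor
        activation_strength: 1.2
        quench_efficiency: 0.4
        quench_range: 110
        coactivation: {partners: [bcd], range: 160}
    r_max: 255.0
    response_midpoint: 4.2
    response_steepness: 1.5
  7:
    factors:
      <<: *base_factors
      zld:
        binding_scale: 2.0e-06
        role: activator
        activation_strength: 1.0
      Dst:
        binding_scale: 2.5e-07
        role: activator
        activation_strength: 2.5
    uniform_factors:
      zld: 100.0
    r_max: 255.0
    response_midpoint: 4.5
    response_steepness: 1.5
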