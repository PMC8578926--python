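# Packaged reference geometry of the reduced systemic arterial tree.
#
# The reference state corresponds to a 180 cm individual with an aortic
# root diameter of 3.32 cm and an aortic distensibility of 5.86e-3/mmHg.
# Peripheral branches are stiffer than the aorta: per-segment
# distensibility = aortic distensibility * stiffness_ratio.
#
# Terminal records carry the three-element Windkessel constants:
#   R_c       characteristic resistance, mmHg·s/ml (kept fixed)
#   R_p_ratio relative peripheral resistance; the set is uniformly
#             rescaled so the parallel total of (R_c + R_p) matches the
#             requested total peripheral resistance
#   C_t       terminal compliance at reference, ml/mmHg
#   P_out     distal (venous) pressure, mmHg
reference:
  height_cm: 180.0
  aortic_diameter_cm: 3.32
  distensibility_e3_per_mmhg: 5.86

segments:
  - id: ascending_aorta
    parent: null
    length_cm: 5.0
    d_in_cm: 3.32
    d_out_cm: 3.15
    stiffness_ratio: 1.0
  - id: aortic_arch_a
    parent: ascending_aorta
    length_cm: 2.5
    d_in_cm: 3.15
    d_out_cm: 3.0
    stiffness_ratio: 1.0
  - id: brachiocephalic
    parent: aortic_arch_a
    length_cm: 3.5
    d_in_cm: 1.3
    d_out_cm: 1.1
    stiffness_ratio: 0.7
  - id: right_subclavian
    parent: brachiocephalic
    length_cm: 18.0
    d_in_cm: 1.0
    d_out_cm: 0.55
    stiffness_ratio: 0.5
    terminal:
      R_c: 2.2
      R_p_ratio: 4.43
      C_t: 0.05
      P_out: 3.0
  - id: left_carotid
    parent: aortic_arch_a
    length_cm: 12.0
    d_in_cm: 0.75
    d_out_cm: 0.55
    stiffness_ratio: 0.6
    terminal:
      R_c: 2.0
      R_p_ratio: 5.17
      C_t: 0.04
      P_out: 3.0
  - id: aortic_arch_b
    parent: aortic_arch_a
    length_cm: 4.0
    d_in_cm: 3.0
    d_out_cm: 2.8
    stiffness_ratio: 1.0
  - id: left_subclavian
    parent: aortic_arch_b
    length_cm: 4.0
    d_in_cm: 1.0
    d_out_cm: 0.9
    stiffness_ratio: 0.6
  - id: left_axillary
    parent: left_subclavian
    length_cm: 12.0
    d_in_cm: 0.9
    d_out_cm: 0.7
    stiffness_ratio: 0.5
  - id: left_brachial
    parent: left_axillary
    length_cm: 22.0
    d_in_cm: 0.7
    d_out_cm: 0.45
    stiffness_ratio: 0.45
  # lumped radial + ulnar run-off distal to the brachial measurement site,
  # so the recorded brachial wave is interior to the network rather than
  # sitting directly on a Windkessel load
  - id: left_forearm
    parent: left_brachial
    length_cm: 24.0
    d_in_cm: 0.45
    d_out_cm: 0.25
    stiffness_ratio: 0.4
    terminal:
      R_c: 5.0
      R_p_ratio: 5.17
      C_t: 0.03
      P_out: 3.0
  - id: thoracic_aorta
    parent: aortic_arch_b
    length_cm: 16.0
    d_in_cm: 2.8
    d_out_cm: 2.1
    stiffness_ratio: 0.95
  - id: abdominal_aorta
    parent: thoracic_aorta
    length_cm: 15.0
    d_in_cm: 2.1
    d_out_cm: 1.6
    stiffness_ratio: 0.9
  - id: iliac
    parent: abdominal_aorta
    length_cm: 12.0
    d_in_cm: 1.4
    d_out_cm: 1.1
    stiffness_ratio: 0.6
    terminal:
      R_c: 0.5
      R_p_ratio: 1.0
      C_t: 0.22
      P_out: 3.0
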