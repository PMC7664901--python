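# Default parameter set for the actomyosin cross-bridge model.
#
# Energies: basal levels in kBT (referenced to MT = 0), elastic terms from
# stiffness in pN/nm.  Lengths in nm, rates in 1/s.
#
# Anchored quantities: cross-bridge stiffness 2.8 pN/nm; target-zone repeat
# 36 nm; MgATP free energy 25 kBT with kBT = 4 pN*nm (so a 4 nm step against
# 30 pN, 120 pN*nm, is 30 kBT); minima ordered x2 < x11 < x1 with
# x11 = x1 - 0.5 nm.  Rate constants are set to values typical of fast
# skeletal actomyosin at room temperature (attachment a few hundred per
# second, Pi release and the strokes fast, ADP release strain-gated and
# rate-limiting at positive strain, ATP-induced detachment ~1e4/s at mM
# MgATP); see docs/methods.md for the reasoning behind each choice.

kbt: 4.0
ks: 2.8
ks_compliant: 0.28
elasticity: linear
dg_atp: 25.0

x1: 5.5
x11: 5.0
x2: 1.0

site_spacing: 36.0
sites_per_zone: 1
intra_zone_spacing: 5.5

rate_cap: 1.0e+6

basal_energy:
  MT: 0.0
  MDP: -1.0
  AMDP_PP: -2.5
  AMDP_PiR: -3.5
  AMD_L: -6.5
  AMD_H: -17.0
  AM: -21.0
# AM -> MT closure drop is implied: dg_atp - 21 = 4 kBT.

transitions:
  # ATP hydrolysis (detached); one-way at this resolution.
  - {from: MT, to: MDP, k0: 100.0, reversible: false}
  # Attachment, Gaussian-weighted around x1 (split 1 -> strain-independent
  # early detachment).
  - {from: MDP, to: AMDP_PP, k0: 400.0, reversible: true, split: 1.0}
  # First (0.5 nm) stroke.
  - {from: AMDP_PP, to: AMDP_PiR, k0: 5000.0, reversible: true, split: 0.5}
  # Pi release (no elastic shift: both minima at x11).
  - {from: AMDP_PiR, to: AMD_L, k0: 3000.0, reversible: true, split: 0.5}
  # Main power stroke x11 -> x2.
  - {from: AMD_L, to: AMD_H, k0: 1.0e+4, reversible: true, split: 0.5}
  # ADP release with final ~1 nm swing; strain-gated.
  - {from: AMD_H, to: AM, k0: 800.0, reversible: true, split: 0.8}
  # ATP-induced detachment at mM MgATP; irreversible.
  - {from: AM, to: MT, k0: 1.0e+4, reversible: false}
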