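# Condition preset registry: ground-truth relative permeabilities
# (normalized to SLO3-mutant non-capacitated P_K = 1.0 at pH 7.4),
# recording-bath compositions (mM), and blocker/media modifiers.
#
# pH-keyed P_Na values are deliberately not reconciled across pH labels:
# 0.13 at pH 7.4, 0.15 at pH 7, 0.12 for the mutant at pH 8 (both printed
# conventions are kept as presets).

baths:
  normal:
    K_out: 5.0
    Na_out: 151.0
    Cl_out: 143.0
    K_in: 120.0
    Na_in: 14.0
    Cl_in: 40.0
    temperature_C: 37.0
  # impermeant substitutions (NMDG+ / methanesulfonate) modelled as
  # concentration changes only
  low-na:
    Na_out: 1.0
  low-cl-44:
    Cl_out: 44.0
  low-cl-5:
    Cl_out: 5.0

permeabilities:
  wild-type:
    non-capacitated:
      "7":   {p_k: 1.6, p_na: 0.15, p_cl: 0.6}
      "7.4": {p_k: 1.6, p_na: 0.13, p_cl: 0.6}
      "8":   {p_k: 8.2, p_na: 0.13, p_cl: 0.6}
    capacitated:
      "7":   {p_k: 1.6, p_na: 0.15, p_cl: 0.6}
      "7.4": {p_k: 4.38, p_na: 0.13, p_cl: 0.6}
      "8":   {p_k: 8.2, p_na: 0.13, p_cl: 0.6}
  slo3-mutant:
    non-capacitated:
      "7":   {p_k: 1.0, p_na: 0.15, p_cl: 0.6}
      "7.4": {p_k: 1.0, p_na: 0.13, p_cl: 0.6}
      "8":   {p_k: 1.2, p_na: 0.12, p_cl: 0.6}
    capacitated:
      "7":   {p_k: 1.0, p_na: 0.15, p_cl: 0.6}
      "7.4": {p_k: 1.2, p_na: 0.13, p_cl: 0.6}
      "8":   {p_k: 1.2, p_na: 0.12, p_cl: 0.6}

modifiers:
  # amiloride blocks the epithelial-type Na+ channel: P_Na divided by 6.5
  amiloride_p_na_factor: 6.5
  # Ba2+/clofilium remove the SLO3 component of wild-type P_K, leaving the
  # mutant residual value for the same state/pH
  slo3_blockers: [barium, clofilium]
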