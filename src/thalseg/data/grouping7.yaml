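# Default 13-nuclei -> 7-group unification scheme.
#
# Nucleus label ids follow the package's alphabetical convention:
#   1 AN, 2 CL, 3 CM, 4 LD, 5 LP, 6 MD, 7 PuA, 8 PuI,
#   9 VA, 10 VLA, 11 VLP, 12 VPL, 13 VPM
#
# The nucleus-to-group assignment is annotation-protocol configuration, not
# code: edit this file to match your own protocol. The assignment below is a
# best-effort anatomical default (Morel-style major groups). Labels absent
# from `mapping` pass through unchanged; background 0 and the unlabeled
# sentinel 100 are never remapped.

groups:
  1: Anterior
  2: Medial
  3: Midline
  4: VentralAnterior
  5: VentralPosterior
  6: VentralLateral
  7: Posterior

mapping:
  1: 1    # AN   -> Anterior
  2: 3    # CL   -> Midline (intralaminar)
  3: 3    # CM   -> Midline (intralaminar)
  4: 1    # LD   -> Anterior
  5: 7    # LP   -> Posterior
  6: 2    # MD   -> Medial
  7: 7    # PuA  -> Posterior
  8: 7    # PuI  -> Posterior
  9: 4    # VA   -> VentralAnterior
  10: 6   # VLA  -> VentralLateral
  11: 6   # VLP  -> VentralLateral
  12: 5   # VPL  -> VentralPosterior
  13: 5   # VPM  -> VentralPosterior
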