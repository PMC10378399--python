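# Normalization of raw in-silico predictor output codes onto the
# damaging / tolerated / unknown vocabulary.  Program-specific sections take
# precedence over the default map because single-letter codes collide
# across programs (e.g. "P" = possibly damaging for PolyPhen2 but
# polymorphism for MutationTaster).  Edit to match your annotation
# toolchain's encodings.
default:
  D: damaging
  damaging: damaging
  deleterious: damaging
  T: tolerated
  tolerated: tolerated
  B: tolerated
  benign: tolerated
  N: tolerated
  neutral: tolerated
  unknown: unknown
SIFT:
  D: damaging
  T: tolerated
PolyPhen2:
  D: damaging  # probably damaging
  P: damaging  # possibly damaging
  B: tolerated
MutationAssessor:
  H: damaging  # high functional impact
  M: damaging  # medium
  L: tolerated
  N: tolerated
PROVEAN:
  D: damaging
  N: tolerated
MutationTaster:
  A: damaging  # disease causing automatic
  D: damaging  # disease causing
  N: tolerated
  P: tolerated  # polymorphism
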