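# Default impact-weight configuration.
#
# Magnitude classes follow the EICAT-style ordering (minimal .. massive);
# evidence strength is a three-level scale. The numeric grid is the
# degenerate uncertainty-averse weighting: weight equals the 1-based
# magnitude rank irrespective of evidence strength, which keeps hand
# calculations exact. Revised weightings can be dropped in without code
# changes; the engine only enforces ordinality, non-negativity and
# monotonicity of weight in magnitude.
magnitude_classes: [minimal, minor, moderate, major, massive]
evidence_classes: [weak, moderate, strong]
weights:
  - [1, 1, 1]
  - [2, 2, 2]
  - [3, 3, 3]
  - [4, 4, 4]
  - [5, 5, 5]
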