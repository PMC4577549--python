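# Reference-country assignments used in the published forecast designs.
# These are data, not code: the evaluation and pipeline stages read them
# when running on externally supplied HMD-style surfaces.
retrospective:
  Spain: [Portugal]
  Hungary: [East Germany, West Germany]
  Russia: [Belarus]
prospective:
  Spain: []
  Hungary: [East Germany, West Germany]
  Russia: [Czech Republic, Poland, Hungary]
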