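# European-ancestry demographic preset (diploid sizes, generations).
#
# Piecewise schedule for the European population of the Tennessen et
# al. (2012) exome-based model, in the single-population form (no
# migration) commonly used for forward simulation: 8N ancestral
# burn-in at N=7310; ancient growth to 14474 at 5920 generations
# before present; out-of-Africa bottleneck to 1861 at 2040
# generations; second (European) bottleneck to 1032 at 920
# generations, modeled here as an instantaneous crash (1-generation
# constant epoch) followed by slow exponential growth to 9300 by 205
# generations before present; then fast exponential growth to 512000
# at present.  Generation time 25 years.  This file is configuration
# data: edit it to change the preset without touching code.
epochs:
  - {duration: 58480, start_size: 7310, end_size: 7310, mode: constant}
  - {duration: 3880, start_size: 14474, end_size: 14474, mode: constant}
  - {duration: 1120, start_size: 1861, end_size: 1861, mode: constant}
  - {duration: 1, start_size: 1032, end_size: 1032, mode: constant}
  - {duration: 714, start_size: 1032, end_size: 9300, mode: exponential}
  - {duration: 205, start_size: 9300, end_size: 512000, mode: exponential}
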