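{
 "provenance": "synthetic reference v1: fixture ensembles (helix/hairpin/two-domain, lengths 16-28, shift noise 0-1.5 ppm, matched and mismatched folds); scores are only comparable under the same reference",
 "correlation": [
  -0.453978,
  -0.350455,
  -0.165805,
  -0.007673,
  0.003823,
  0.23517,
  0.286064,
  0.320053,
  0.372669,
  0.394824,
  0.43,
  0.43,
  0.43,
  0.477332,
  0.520988,
  0.520988,
  0.521577,
  0.552074,
  0.604494,
  0.646019,
  0.677519,
  0.757401,
  0.761129,
  0.761129,
  0.76212,
  0.766424,
  0.767772,
  0.768532,
  0.782475,
  0.782475,
  0.783371,
  0.787118,
  0.788983,
  0.790175,
  0.790175,
  0.79473,
  0.800283,
  0.812432,
  0.936103,
  0.938304
 ],
 "rmsd": [
  0.003431,
  0.006054,
  0.006059,
  0.0061,
  0.006777,
  0.006885,
  0.006895,
  0.008681,
  0.009051,
  0.010408,
  0.010627,
  0.010744,
  0.011232,
  0.011293,
  0.011309,
  0.011906,
  0.012518,
  0.026295,
  0.027291,
  0.031376,
  0.034738,
  0.225436,
  0.225547,
  0.225925,
  0.23989,
  0.23989,
  0.23989,
  0.23989,
  0.248961,
  0.248961,
  0.248961,
  0.248961,
  0.249982,
  0.249982,
  0.249982,
  0.249982,
  0.250057,
  0.252118,
  0.252118,
  0.252118,
  0.252118,
  0.254923,
  0.254923,
  0.254923,
  0.254923,
  0.267261,
  0.267261,
  0.267261,
  0.267261,
  0.272354,
  0.294519,
  0.294726,
  0.329323,
  0.329323,
  0.329323,
  0.329323,
  0.33069,
  0.33069,
  0.33069,
  0.33069,
  0.353553,
  0.353553,
  0.353553,
  0.353553,
  0.353553,
  0.353553,
  0.353553,
  0.353553,
  0.353553,
  0.353553,
  0.353553,
  0.353553,
  0.422597,
  0.422597,
  0.422597,
  0.422597,
  0.443805,
  0.44509,
  0.452879,
  0.452879,
  0.452879,
  0.452879,
  0.45535,
  0.45535,
  0.45535,
  0.45535,
  0.464189,
  0.464673,
  0.466054,
  0.473611,
  0.515091,
  0.515129,
  0.51549,
  0.5155,
  0.516028,
  0.516041,
  0.588866,
  0.598718,
  0.598718,
  0.598718,
  0.598718,
  0.598724,
  0.598724,
  0.598724,
  0.599101,
  0.599101,
  0.599101,
  0.599101
 ]
}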