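# Linear decision boundary in (P1, P2) band-mass space.
# P2 = slope * P1 + intercept; GRAY (unsickled) side per orientation.
slope = -1.527
intercept = 0.633
orientation = gray_below
provenance = published
version = 1
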