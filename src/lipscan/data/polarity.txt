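# Atom polarity classes for the buried-surface polarity ratio.
# NACCESS polar/non-polar partition: N and O polar; C and S apolar.
# Sulfur's class is a convention choice; edit here to flip it.
element N  polar
element O  polar
element C  apolar
element S  apolar
element SE apolar
element P  polar
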