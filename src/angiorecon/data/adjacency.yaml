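# Anatomical adjacency of the eight recognised arteries: parent -> children.
# Used when connecting centerline fragments into complete vessels; edit to
# change which junctions the pipeline is allowed to bridge.
CCA: [ICA, ECA]
ICA: [MCA, ACA]
VA: [BA]
BA: [PCA]
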