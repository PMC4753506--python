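Place the published PDB coordinate files 3L1P.pdb (Oct4 POU:PORE) and
1HF0.pdb (Oct1 POU:PORE) in this directory to enable the structure-specific
acceptance tests. They are third-party data and are not redistributed.
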