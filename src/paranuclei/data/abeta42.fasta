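>abeta42 amyloid-beta 1-42 peptide
DAEFRHDSGYEVHHQKLVFFAEDVGSNKGAIIGLMVGGVVIA
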