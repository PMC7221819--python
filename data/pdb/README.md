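# Local structure drop-in

Place plain-text PDB files here (lower-case names, e.g. `1aq1.pdb`) to run
the crystal-structure benchmark tests in `tests/test_acceptance.py` and any
manifest that references them.  The library never downloads structures;
without these files the structure-based tests fail with a message pointing
here.
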