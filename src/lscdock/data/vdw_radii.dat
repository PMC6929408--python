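# Element-keyed van der Waals radii (Angstrom) used for grid discretization.
# Values are a conventional united-atom-style set for protein heavy atoms;
# substitute your own table with --radii-table / RadiiTable.from_file.
# Format: element symbol, radius in Angstrom. '#' starts a comment.
# The special key 'default' is used for elements not listed.
H   1.2
C   1.9
N   1.7
O   1.6
S   2.0
P   2.1
default 1.8
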