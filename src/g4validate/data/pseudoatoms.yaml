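# Pseudoatom / wildcard proton nomenclature map for DNA restraint tables.
# Keys are names as they appear in restraint files; values are the
# explicit proton names they expand to.  Back-calculation needs explicit
# coordinates, so groups are expanded at parse time and kept as
# ambiguous groups (r^-6 averaged, never summed).
"QH2'": ["H2'", "H2''"]
"H2'#": ["H2'", "H2''"]
"H2'*": ["H2'", "H2''"]
"QH5'": ["H5'", "H5''"]
"H5'#": ["H5'", "H5''"]
"H5'*": ["H5'", "H5''"]
"QM7": ["H71", "H72", "H73"]
"M7": ["H71", "H72", "H73"]
"H7#": ["H71", "H72", "H73"]
"H7*": ["H71", "H72", "H73"]
"QH2": ["H21", "H22"]
"H2#": ["H21", "H22"]
"QH4": ["H41", "H42"]
"H4#": ["H41", "H42"]
"QH6": ["H61", "H62"]
"H6#": ["H61", "H62"]
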