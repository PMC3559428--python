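table1_aa_substitutions.tsv	f7aaa3e8ff3a45e38b1ef98e03b99c91e3269be65541b0062f56140b0c49fe89
differential_abundance.tsv	baee143bcb3300cf1fa4bc3dcd96e6933d060858e13b7244aa4f249ec4ce4f12
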