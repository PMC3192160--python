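# EXTERNAL-PROVENANCE AGES -- not part of this package's primary dataset.
# Histological ages for the Jane specimen (12 yr) and the MOR specimen
# (14 or 16 yr, two published alternatives) are the only ages printed with
# the mass dataset this package reproduces.  The ages below for Stan, Sue
# and Carnegie come from, or are approximations based on, the independent
# tyrannosaur growth literature (Sue: ~28 yr from long-bone histology;
# Stan and Carnegie were never histologically aged and the values here are
# rough literature-informed placeholders).  Any result computed from this
# file is an optional, clearly flagged check, not a validated reproduction.
specimen,age_yr,provenance
Jane,12,printed_with_dataset
MOR,16,printed_with_dataset_alternative_14
Stan,18,external_approximate
Carnegie,22,external_approximate
Sue,28,external_histology_literature
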