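>docking_A material=DNA
CCACACCAACCAAC
>docking_B material=DNA
ACTTACTATATAAC
>template_sense material=DNA
CACCCACCCACACCAACCAACAAAACTTACTATATAACCCCTATAGTGAGTCGTATTAG
>template_antisense material=DNA
CTAATACGACTCACTATAGGGGTTATATAGTAAGTTTTGTTGGTTGGTGTGGGTGGGTG
>linker material=RNA
GTTGGTTGGTGTGGGTGGGTGTTTGTTATATAGTAAGT
>complement_rna material=RNA
ACUUACUAUAUAACAAACACCCACCCACACCAACCAAC
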