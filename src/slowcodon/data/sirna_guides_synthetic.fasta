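>siRNA1 synthetic guide, exact reverse complement of eGFP ORF nt 122-140
AACTTCAGGGTCAGCTTGC
>siRNA2 synthetic guide, exact reverse complement of eGFP ORF nt 433-451
CGTTGTGGCTGTTGTAGTT
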