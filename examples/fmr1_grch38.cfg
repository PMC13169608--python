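# FMR1 intron-1 retention / FMR1-217 event on GRCh38.
# The intron interval and the transcript region are the published event
# coordinates; the outer exon bounds only pad the analysis window and do not
# affect counting, which depends on the donor/acceptor sites alone.
locus_name = FMR1_intron1
chromosome = chrX
exon1 = 147,911,919-147,912,229
intron1 = 147,912,230-147,921,932
exon2 = 147,921,933-147,921,986
window_bp = 50
transcript_region = 147,912,123-147,914,451
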