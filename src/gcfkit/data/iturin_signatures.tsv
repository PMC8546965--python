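# Seven-residue adenylation-domain specificity signatures distinguishing the
# iturinic lipopeptide products.  Editable data, not code: defaults compiled
# from the published amino-acid compositions of the iturin-family peptides;
# adjust to match the predictions emitted by your annotation tool.
# product<TAB>comma-separated residues (in genomic A-domain order)
iturin A	asn,tyr,asn,gln,pro,asn,ser
bacillomycin D	asn,tyr,asn,pro,glu,ser,thr
bacillomycin F	asn,tyr,asn,gln,pro,asn,thr
bacillomycin L	asp,tyr,asn,ser,gln,ser,thr
mycosubtilin	asn,tyr,asn,gln,pro,ser,asn
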