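# Default annotation keywords for the trait-relatedness filter stage.
# One case-insensitive substring per line; lines starting with '#' are ignored.
salt
alkali
ion
transporter
kinase
ubiquitin
stress
ABA
channel
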