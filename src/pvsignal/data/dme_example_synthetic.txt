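# Synthetic illustrative stand-in for the EMA Designated Medical Events list.
# The licensed/versioned DME list is an external input; supply your own for
# real analyses.
Hepatic failure
Agranulocytosis
Toxic epidermal necrolysis
Stevens-Johnson syndrome
Anaphylactic shock
PT_001
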