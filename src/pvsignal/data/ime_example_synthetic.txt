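# Synthetic illustrative stand-in for the EMA Important Medical Events list.
# The licensed/versioned IME list is an external input; supply your own for
# real analyses.
Sepsis
Septic shock
Febrile neutropenia
Interstitial lung disease
Pancreatitis
Pneumonitis
Renal failure
PT_002
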