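# Label-listed adverse reactions for irinotecan (expectedness reference).
Diarrhoea
Neutropenia
Thrombocytopenia
Stomatitis
Enteritis
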