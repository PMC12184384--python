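# Irinotecan search-term lexicon: generic and brand names matched exactly
# (after trim / case-fold / whitespace-collapse) against verbatim drug names.
IRINOTECAN
IRINOTECAN HCL
IRINOTECAN HYDROCHLORIDE
CPT 11 IRINOTECAN
CPT 11
CAMPTOSAR
CAMPTO
ONIVYDE
IRINOTECAN LIPOSOME
イリノテカン
塩酸イリノテカン
イリノテカン塩酸塩水和物
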