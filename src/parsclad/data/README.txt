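saltans_table2.csv
------------------

Published morphological character matrix for the Drosophila saltans species
group: 19 discrete characters of the male terminalia and aedeagus scored by
scanning electron microscopy across 10 saltans-group species (all five
subgroups represented) plus D. willistoni as the outgroup.

State codes: 0 = absence, 1 = presence, 2 = presence with modifications.
All characters are unordered (non-additive) and equally weighted. The
outgroup row (willistoni) is all zeros by construction of the coding.

Character numbering (columns, left to right) follows the original table
rows 1-19; taxon order (rows) follows the original table columns. A couple
of character-name spellings were normalised during transcription
("Surtylus" -> "Surstylus", "Crestl" -> "Crest"); state codes are verbatim.
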