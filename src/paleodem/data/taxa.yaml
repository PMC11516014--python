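# Terrestrial taxa selection for the openness PCA and the open-land
# indicator set used to orient the first axis.  Editable: pollen tables
# only need to carry a subset of these columns.
selected_taxa:
  - Alnus
  - Betula
  - Corylus
  - Fagus
  - Fraxinus
  - Quercus
  - Tilia
  - Ulmus
  - Pinus
  - Calluna
  - Poaceae
  - Plantago_lanceolata
  - Rumex
  - Artemisia
  - Cerealia
open_indicators:
  - Poaceae
  - Calluna
  - Plantago_lanceolata
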