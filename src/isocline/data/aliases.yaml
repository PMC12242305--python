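# Editable mapping from free-text specimen locations to the five Suess-correction
# regions, and from location labels to POM baselines. Aliases are configuration,
# not code: add entries here for new collection localities.
region_aliases:
  MS: MS
  FI: FI
  SG: SG
  SS: SS
  RS: RS
  Strait of Magellan: MS
  Patagonia: MS
  Patagonian west coast: MS
  Patagonia/Strait of Magellan: MS
  west Patagonian shelf (Chile): MS
  polar front and southwest Patagonian shelf: MS
  Falkland Islands: FI
  east Patagonian shelf (Falkland Islands): FI
  southeast Patagonian shelf waters: FI
  Patagonian shelf: FI
  South Georgia: SG
  South Atlantic: SG
  South Shetlands: SS
  South Shetland Islands: SS
  Southern Ocean: SS
  Antarctic Peninsula: SS
  Ross Sea: RS
  Antarctic seas: RS
  Antarctic shelf waters: RS

# POM baselines are keyed on location label first (the Patagonian west coast uses
# 9.4, not the Strait-of-Magellan 8.1, although both correct with the MS a-value);
# unmatched labels fall back to the default for the resolved region code.
pom_aliases:
  Antarctic seas: Ross Sea
  Antarctic shelf waters: Ross Sea
  South Shetland Islands: South Shetlands
  Southern Ocean: South Atlantic
  Antarctic Peninsula: South Shetlands
  Patagonia: Patagonian west coast
pom_region_defaults:
  MS: Strait of Magellan
  FI: Falkland Islands
  SG: South Georgia
  SS: South Shetlands
  RS: Ross Sea

cn_window: [2.9, 3.3]
tp_bands:
  whale: [3.2, 3.4]
  seal: [3.8, 4.1]
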