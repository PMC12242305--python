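label,pom_d15n,pom_low,pom_high
Ross Sea,0.6,,
South Shetlands,1.7,,
South Atlantic,1.5,,
South Georgia,3.6,2.0,5.4
Strait of Magellan,8.1,5.6,12.2
Falkland Islands,9.4,,
Patagonian west coast,9.4,,
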