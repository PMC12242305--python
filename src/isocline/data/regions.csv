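region_code,region_name,lat_min,lat_max,lon_min,lon_max,n,total_cse,a_value
MS,Patagonia/Strait of Magellan,-55,-49,-77,-67,19,-0.91,-0.0065
FI,Falkland Islands,-52.5,-50.8,-62,-57.4,2,-0.93,-0.0066
SG,South Georgia,-56,-53,-38.7,-33.9,13,-0.73,-0.0052
SS,South Shetlands,-63,-61,-63,-57,9,-0.75,-0.0054
RS,Ross Sea,-77,-71,171,-160,173,-0.71,-0.0051
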