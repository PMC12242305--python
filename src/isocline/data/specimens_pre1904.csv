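specimen_id,species,location,year,d13c_normalized,d13c_se_printed,d15n
ZD.1880.7.28.19,Balaenoptera musculus,Strait of Magellan,March 1879,-20.07,-20.06,9.07
ZD.1879.8.21.9,Balaenoptera musculus,Strait of Magellan,March 1879,-13.91,-13.90,10.79
ZD.1879.8.21.8,Balaenoptera musculus,Strait of Magellan,February 1879,-13.14,-13.12,17.05
ZD.1852.3.11.5,Arctocephalus australis,Falkland Islands,before 1850,-12.99,-12.99,21.13
ZD.1879.8.21.5,Arctocephalus australis,Strait of Magellan,1878-1880,-12.12,-12.11,17.50
ZD.1880.7.28.12,Arctocephalus australis,Strait of Magellan,1878-1880,-11.97,-11.95,19.29
ZD.1880.7.28.13,Arctocephalus australis,Strait of Magellan,1878-1880,-11.49,-11.47,20.40
ZD.1880.7.28.14,Arctocephalus australis,Patagonian west coast,1878-1880,-12.51,-12.49,23.56
ZE.1950.11.14.3,Arctocephalus australis,Patagonian west coast,04/01/1876,-12.06,-12.05,19.84
ZE.1950.11.14.4,Arctocephalus australis,Patagonian west coast,04/01/1876,-12.78,-12.76,20.48
ZD.1843.1.8.4,Hydrurga leptonyx,Antarctic seas,1843,-22.01,-22.01,9.90
ZD.1846.4.15.23,Hydrurga leptonyx,Antarctic seas,1843,-18.39,-18.39,10.85
ZD.1846.4.15.24,Hydrurga leptonyx,Antarctic seas,1843,-21.05,-21.05,10.33
ZD.1880.7.28.5,Hydrurga leptonyx,Falkland Islands,1878-1880,-18.84,-18.83,11.27
ZD.1885.10.20.1,Hydrurga leptonyx,Falkland Islands,before 1885,-18.07,-18.05,10.71
ZD.1893.9.14.1,Hydrurga leptonyx,South Georgia,before 1893,-19.39,-19.38,10.79
ZD.1908.2.20.54,Hydrurga leptonyx,Ross Sea,1901-1904,-21.04,-21.02,9.64
ZD.1908.2.20.56,Hydrurga leptonyx,Ross Sea,1901-1904,-20.53,-20.51,10.57
GERM.325.e,Hydrurga leptonyx,Antarctic seas,1839-1843,-21.09,-21.09,9.97
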