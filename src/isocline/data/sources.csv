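source_id,consumer,region_label,region_code,n,mu_d13c,sd_d13c,mu_d15n,sd_d15n
Euphausia superba (South Shetland),blue_whale,South Shetland Islands,SS,24,-26.87,0.94,3.63,0.38
Euphausia superba (South Georgia),blue_whale,South Georgia,SG,26,-23.87,1.22,4.27,0.54
Thysanoessa spp./Euphausia frigida (polar front),blue_whale,polar front and southwest Patagonian shelf,MS,7,-23.25,1.05,5.10,0.20
Euphausia superba (Antarctic shelf),blue_whale,Antarctic shelf waters,RS,43,-31.20,0.10,2.85,0.75
Euphausia mucronata (Humboldt krill),blue_whale,west Patagonian shelf (Chile),MS,30,-16.04,0.0,12.37,0.0
Euphausia lucens (east Patagonian shelf),blue_whale,east Patagonian shelf (Falkland Islands),FI,3,-20.61,0.39,8.04,1.22
Euphausia lucens (Subantarctic),blue_whale,southeast Patagonian shelf waters,FI,7,-19.80,0.70,7.33,0.80
squid (Doryteuthis gahi),fur_seal,Patagonian shelf,FI,10,-19.00,0.60,13.60,0.70
demersal fish (Patagonotothen spp.),fur_seal,Patagonian shelf,FI,5,-19.30,0.60,14.80,1.00
small planktonic fish (Sprattus fuegensis),fur_seal,Patagonian shelf,FI,25,-20.20,1.00,13.10,0.90
piscivorous fish (hake),fur_seal,Patagonian shelf,FI,6,-14.90,0.30,17.20,0.40
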