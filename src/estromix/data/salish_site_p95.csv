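site_id,n_samples,p95_ear_mix
Port Susan,6,1338
Port Gardner,38,3119
Hood Canal,33,548
Eagle Harbor,20,436
Myrtle Edwards,15,2913
Bell Harbor,57,32346
Duwamish Wwy,47,831
Bremerton,29,830
Commencement Bay-Thea Foss Wwy,25,505
Nisqually,13,6345
Strait of Georgia,12,1831
Vendovi Island,8,1848
Port Madison,9,1273
West Point North,10,1436
West Point South,7,546
Commencement Bay-Hylebos Wwy,9,2466
Commencement Bay-Blair Wwy,10,1901
Carr Inlet,6,49519
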