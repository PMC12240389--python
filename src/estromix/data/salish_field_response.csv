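site_id,pct_male_vtg,pct_female_altered_timing
Port Susan,6.8,8
Port Gardner,18.8,9
Hood Canal,5.7,6
Eagle Harbor,0,4
Myrtle Edwards,46.9,81
Bell Harbor,37.5,65
Duwamish Wwy,17.6,0
Bremerton,5.9,6
Commencement Bay-Thea Foss Wwy,21.7,2
Nisqually,0,5
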