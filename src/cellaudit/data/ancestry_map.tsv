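verbatim_label	census_group	genotype_group
African	Black or African American	African
African American	Black or African American	African
Black	Black or African American	African
Black or African American	Black or African American	African
West African	Black or African American	African
Yoruba	Black or African American	African
European	White	European
White	White	European
Caucasian	White	European
British	White	European
German	White	European
French	White	European
Italian	White	European
Scandinavian	White	European
Dutch	White	European
Asian	Asian	Unknown
East Asian	Asian	East Asian
Han Chinese	Asian	East Asian
Chinese	Asian	East Asian
Japanese	Asian	East Asian
Korean	Asian	East Asian
Vietnamese	Asian	East Asian
Central/South Asian	Asian	Central/South Asian
Central and South Asian	Asian	Central/South Asian
South Asian	Asian	Central/South Asian
Indian	Asian	Central/South Asian
Pakistani	Asian	Central/South Asian
Bengali	Asian	Central/South Asian
Native Hawaiian	Native Hawaiian or Pacific Islander	Unknown
Pacific Islander	Native Hawaiian or Pacific Islander	Unknown
Native Hawaiian or Pacific Islander	Native Hawaiian or Pacific Islander	Unknown
American Indian	American Indian	Unknown
Native American	American Indian	Unknown
Alaska Native	American Indian	Unknown
Hispanic	Two or more races	Mixed Ancestry
Latino	Two or more races	Mixed Ancestry
Admixed	Two or more races	Mixed Ancestry
Mixed	Two or more races	Mixed Ancestry
Mixed Ancestry	Two or more races	Mixed Ancestry
Two or more races	Two or more races	Mixed Ancestry
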