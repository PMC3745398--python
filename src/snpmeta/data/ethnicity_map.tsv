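label	group
European	White
British	White
American	White
Australian	White
Icelandic	White
Caucasian	White
White	White
Chinese	EastAsian
Japanese	EastAsian
Korean	EastAsian
Asian	EastAsian
East Asian	EastAsian
EastAsian	EastAsian
African	African
African American	African
Tunisian	African
Jewish	Other
Jew	Other
Hawaiian	Other
Other	Other
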