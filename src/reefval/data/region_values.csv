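region,annual_visits_million,adults_million,existence_per_adult
hawaii,15.5,0.92,104.93
florida,18.2,3.89,104.93
puerto_rico,,2.91,104.93
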