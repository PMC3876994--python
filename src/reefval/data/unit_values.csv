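label,study_region,method,cs_per_day
Leeworthy and Bowker,Florida,travel_cost,121.04
Park et al. (contingent valuation),Florida,contingent_valuation,191.93
Park et al. (travel cost),Florida,travel_cost,65.37
Cesar et al.,Hawaii,contingent_valuation,11.18
Bhat,Florida,travel_cost,161.04
Johns et al.,Florida,contingent_valuation,14.91
Oh et al.,Gulf of Mexico,contingent_valuation,220.46
Estudios Tecnicos,Puerto Rico,travel_cost,112.86
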