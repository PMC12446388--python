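# Monthly temperature records (degrees Celsius), November and December,
# three southern-African national parks (30-year averages).
park	month	mean_daily_min	cold_nights	mean_daily_max	hot_days
Etosha	Nov	18	12	36	40
Etosha	Dec	20	14	35	39
Kruger	Nov	19	14	30	38
Kruger	Dec	20	15	30	37
Hwange	Nov	23	18	35	39
Hwange	Dec	22	18	33	38
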