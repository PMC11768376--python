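year,stage,start,end
2022,seedling,05-11,06-03
2022,flowering,06-04,07-05
2022,full_fruiting,07-06,08-02
2022,later_fruiting,08-03,08-30
2023,seedling,05-14,06-01
2023,flowering,06-02,06-30
2023,full_fruiting,07-01,07-31
2023,later_fruiting,08-01,08-31
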