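event_id,calendar_date
E1,2013-09-17
E2,2013-10-23
E3,2014-01-22
E4,2014-04-01
E5,2014-05-01
E6,2014-06-10
E7,2014-07-22
E8,2014-08-20
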