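station_id,depth,habitat
C,40,coast
B,80,bank
T,215,trough
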