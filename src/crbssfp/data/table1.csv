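mouse,group,mask_volume_w13_mm3,mask_volume_w18_mm3,dice
Ctr1,control,325.2,387.0,0.786
Ctr2,control,398.5,558.2,0.740
Ctr3,control,436.1,457.3,0.830
Ctr4,control,360.1,341.0,0.781
Ctr5,control,477.8,584.9,0.785
Ctr6,control,304.5,276.7,0.500
M1,urethane,508.0,488.3,0.903
M2,urethane,391.5,544.6,0.778
M3,urethane,468.8,416.9,0.867
M4,urethane,353.0,423.5,0.784
M5,urethane,336.4,353.1,0.836
M6,urethane,420.8,436.7,0.819
M7,urethane,433.8,452.1,0.806
M8,urethane,406.1,421.6,0.809
M9,urethane,353.2,454.7,0.782
M10,urethane,424.7,451.7,0.737
M11,urethane,250.0,409.8,0.560
M12,urethane,456.2,478.7,0.660
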