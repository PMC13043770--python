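name,volume_fraction_ethanol,epsilon,source
ethanol_000pct,0.0,80.1,literature
ethanol_010pct,0.1,73.205,maxwell_garnett
ethanol_020pct,0.2,66.694,maxwell_garnett
ethanol_030pct,0.3,60.537,maxwell_garnett
ethanol_040pct,0.4,54.705,maxwell_garnett
ethanol_050pct,0.5,49.174,maxwell_garnett
ethanol_060pct,0.6,40.594,maxwell_garnett
ethanol_070pct,0.7,36.221,maxwell_garnett
ethanol_080pct,0.8,32.247,maxwell_garnett
ethanol_090pct,0.9,28.622,maxwell_garnett
ethanol_100pct,1.0,25.3,literature
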