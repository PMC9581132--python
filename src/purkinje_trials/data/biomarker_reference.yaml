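# Control (no drug) AP biomarkers, mean and standard deviation, from the
# published reference characterization: microelectrode recordings in rabbit
# Purkinje fibers (n = 74) and the calibrated human in-silico Purkinje
# population (n = 530), at slow (0.25 Hz), normal (1 Hz) and fast (3 Hz)
# pacing.  APD in ms, dVdtMax in V/s, APA and TOP in mV.
rabbit_invitro:
  0.25: {APD90: [432, 119], APD50: [311, 107], dVdtMax: [627, 80], APA: [128, 3], TOP: [-89, 1]}
  1.0:  {APD90: [310, 52],  APD50: [239, 53],  dVdtMax: [616, 72], APA: [129, 3], TOP: [-91, 1]}
  3.0:  {APD90: [216, 24],  APD50: [162, 24],  dVdtMax: [595, 62], APA: [129, 3], TOP: [-92, 1]}
human_insilico:
  0.25: {APD90: [292, 65], APD50: [215, 59], dVdtMax: [363, 73], APA: [107, 4], TOP: [-84, 1]}
  1.0:  {APD90: [281, 55], APD50: [210, 50], dVdtMax: [419, 79], APA: [112, 4], TOP: [-87, 1]}
  3.0:  {APD90: [212, 27], APD50: [149, 22], dVdtMax: [391, 79], APA: [113, 4], TOP: [-88, 1]}
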