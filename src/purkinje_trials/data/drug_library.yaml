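# Reference compound library: per-channel IC50s (uM) measured by automated
# patch clamp on hERG (IKr), hCav1.2 (ICaL), hNav1.5 (INa) and hKv4.3 (Ito),
# the concentrations tested in the rabbit Purkinje fiber assay, the pacing
# frequencies used there, and the CredibleMeds torsade-de-pointes class
# (1 = known risk, 2 = conditional risk, NC = not classified).
# A missing channel key means no measurable effect in the tested range
# (residual current fixed at 1.0).
drugs:
  - name: astemizole
    ic50_um: {INa: 2.8, ICaL: 0.59, Ito: 22.0, IKr: 0.017}
    concentrations_um: [0.01, 0.1, 1.0, 3.0]
    frequencies_hz: [0.25, 1.0, 3.0]
    n_preparations: 6
    tdp_class: "1"
  - name: bepridil
    ic50_um: {INa: 3.1, ICaL: 6.0, Ito: 13.0, IKr: 0.19}
    concentrations_um: [0.1, 0.3, 1.0, 3.0]
    frequencies_hz: [0.2, 1.0, 3.0]
    n_preparations: 6
    tdp_class: "1"
  - name: cisapride
    ic50_um: {ICaL: 33.0, IKr: 0.015}
    concentrations_um: [0.003, 0.01, 0.03]
    frequencies_hz: [0.25, 1.0, 3.0]
    n_preparations: 6
    tdp_class: "1"
  - name: clarithromycin
    ic50_um: {INa: 163.0, ICaL: 103.0, IKr: 62.5}
    concentrations_um: [1.0, 2.4, 10.0, 30.0]
    frequencies_hz: [0.25, 1.0, 3.0]
    n_preparations: 5
    tdp_class: "1"
  - name: diltiazem
    ic50_um: {INa: 15.0, ICaL: 0.76, Ito: 84.0, IKr: 16.6}
    concentrations_um: [0.1, 1.0, 3.0, 10.0, 30.0]
    frequencies_hz: [0.25, 1.0, 3.0]
    n_preparations: 6
    tdp_class: "NC"
  - name: disopyramide
    ic50_um: {ICaL: 114.0, IKr: 14.4}
    concentrations_um: [0.3, 1.0, 3.0, 10.0, 30.0, 100.0]
    frequencies_hz: [0.2, 1.0]
    n_preparations: 5
    tdp_class: "1"
  - name: dofetilide
    ic50_um: {INa: 94.0, ICaL: 204.0, IKr: 0.047}
    concentrations_um: [0.0003, 0.001, 0.003, 0.01]
    frequencies_hz: [0.2, 1.0, 3.0]
    n_preparations: 7
    tdp_class: "1"
  - name: nifedipine
    ic50_um: {INa: 23.0, ICaL: 0.051, Ito: 31.0, IKr: 92.0}
    concentrations_um: [0.03, 0.3, 1.0, 10.0]
    frequencies_hz: [0.25, 1.0, 3.0]
    n_preparations: 6
    tdp_class: "NC"
  - name: quinidine
    ic50_um: {INa: 35.0, ICaL: 2.9, Ito: 15.0, IKr: 1.26}
    concentrations_um: [0.1, 1.0, 3.0, 10.0]
    frequencies_hz: [0.25, 1.0, 3.0]
    n_preparations: 6
    tdp_class: "1"
  - name: ranolazine
    ic50_um: {INa: 101.0, ICaL: 156.0, IKr: 24.5}
    concentrations_um: [0.3, 3.0, 10.0, 30.0]
    frequencies_hz: [0.25, 1.0, 3.0]
    n_preparations: 4
    tdp_class: "2"
  - name: risperidone
    ic50_um: {INa: 102.0, ICaL: 138.0, Ito: 43.0, IKr: 0.41}
    concentrations_um: [0.003, 0.03, 0.3]
    frequencies_hz: [0.25, 1.0]
    n_preparations: 6
    tdp_class: "2"
  - name: sotalol
    ic50_um: {IKr: 86.4}
    concentrations_um: [0.3, 1.0, 3.0, 10.0, 30.0]
    frequencies_hz: [0.25, 1.0, 3.0]
    n_preparations: 6
    tdp_class: "1"
  - name: terfenadine
    ic50_um: {INa: 3.3, ICaL: 2.2, Ito: 68.0, IKr: 0.17}
    concentrations_um: [0.03, 0.32, 1.44, 5.34]
    frequencies_hz: [0.25, 1.0, 3.0]
    n_preparations: 6
    tdp_class: "1"
  - name: verapamil
    ic50_um: {INa: 29.0, ICaL: 0.2, Ito: 58.0, IKr: 0.6}
    concentrations_um: [0.1, 1.0, 3.0]
    frequencies_hz: [0.25, 1.0, 3.0]
    n_preparations: 6
    tdp_class: "NC"
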