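# Per-compound categorical outcomes of the published reference drug trials,
# for both arms of the comparison:
#   ead            - repolarization abnormalities observed at slow pacing in
#                    at least one model (in silico) / one fiber (in vitro),
#                    at any tested concentration
#   apd90_gt10pct  - mean APD90 prolongation at 1 Hz exceeded +10% at some
#                    tested concentration
# tdp_class is the CredibleMeds clinical class (1/2 risky, NC safe).
# These flags make the risk-classification metrics testable without running
# any simulation.
source: published reference-compound characterization (desk fixture)
drugs:
  astemizole:     {tdp_class: "1",  ead_insilico: true,  ead_invitro: true,  apd90_gt10pct_insilico: true,  apd90_gt10pct_invitro: true}
  bepridil:       {tdp_class: "1",  ead_insilico: true,  ead_invitro: false, apd90_gt10pct_insilico: true,  apd90_gt10pct_invitro: true}
  cisapride:      {tdp_class: "1",  ead_insilico: true,  ead_invitro: true,  apd90_gt10pct_insilico: true,  apd90_gt10pct_invitro: true}
  clarithromycin: {tdp_class: "1",  ead_insilico: true,  ead_invitro: true,  apd90_gt10pct_insilico: true,  apd90_gt10pct_invitro: true}
  diltiazem:      {tdp_class: "NC", ead_insilico: false, ead_invitro: false, apd90_gt10pct_insilico: true,  apd90_gt10pct_invitro: false}
  disopyramide:   {tdp_class: "1",  ead_insilico: true,  ead_invitro: true,  apd90_gt10pct_insilico: true,  apd90_gt10pct_invitro: true}
  dofetilide:     {tdp_class: "1",  ead_insilico: true,  ead_invitro: true,  apd90_gt10pct_insilico: true,  apd90_gt10pct_invitro: true}
  nifedipine:     {tdp_class: "NC", ead_insilico: false, ead_invitro: false, apd90_gt10pct_insilico: false, apd90_gt10pct_invitro: false}
  quinidine:      {tdp_class: "1",  ead_insilico: true,  ead_invitro: true,  apd90_gt10pct_insilico: true,  apd90_gt10pct_invitro: true}
  ranolazine:     {tdp_class: "2",  ead_insilico: true,  ead_invitro: false, apd90_gt10pct_insilico: true,  apd90_gt10pct_invitro: true}
  risperidone:    {tdp_class: "2",  ead_insilico: true,  ead_invitro: true,  apd90_gt10pct_insilico: true,  apd90_gt10pct_invitro: true}
  sotalol:        {tdp_class: "1",  ead_insilico: true,  ead_invitro: true,  apd90_gt10pct_insilico: true,  apd90_gt10pct_invitro: true}
  terfenadine:    {tdp_class: "1",  ead_insilico: true,  ead_invitro: false, apd90_gt10pct_insilico: true,  apd90_gt10pct_invitro: false}
  verapamil:      {tdp_class: "NC", ead_insilico: false, ead_invitro: false, apd90_gt10pct_insilico: true,  apd90_gt10pct_invitro: true}
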