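# Shipped dosing-regimen presets (subcutaneous doses in mg, times in days).
# Weight-based levels use the 76 kg reference (1000 ug/kg == 76 mg); entries
# with a printed fixed-dose equivalent store that value directly.
mm1_80ugkg_qw:    {maintenance_dose: 6.08, interval: 7, maintenance_start: 1}
mm1_215ugkg_qw:   {maintenance_dose: 16.0, interval: 7, maintenance_start: 1}
mm1_360ugkg_qw:   {maintenance_dose: 28.0, interval: 7, maintenance_start: 1}
mm1_600ugkg_qw:   {maintenance_dose: 44.0, interval: 7, maintenance_start: 1}
mm1_1000ugkg_qw:  {maintenance_dose: 76.0, interval: 7, maintenance_start: 1}
# one-step priming: 600 ug/kg (44 mg) day 1, then 1000 ug/kg (76 mg) QW from day 8
one_step_priming:
  priming: [{time: 1, amount: 44.0}]
  maintenance_dose: 76.0
  interval: 7
  maintenance_start: 8
# registrational two-step priming: 12 mg d1, 32 mg d4, 76 mg QW from d8
two_step_priming_76qw:
  priming: [{time: 1, amount: 12.0}, {time: 4, amount: 32.0}]
  maintenance_dose: 76.0
  interval: 7
  maintenance_start: 8
flat_16_qw:   {maintenance_dose: 16.0,  interval: 7,  maintenance_start: 1}
flat_28_qw:   {maintenance_dose: 28.0,  interval: 7,  maintenance_start: 1}
flat_44_qw:   {maintenance_dose: 44.0,  interval: 7,  maintenance_start: 1}
flat_76_qw:   {maintenance_dose: 76.0,  interval: 7,  maintenance_start: 1}
flat_152_qw:  {maintenance_dose: 152.0, interval: 7,  maintenance_start: 1}
flat_76_q2w:  {maintenance_dose: 76.0,  interval: 14, maintenance_start: 1}
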