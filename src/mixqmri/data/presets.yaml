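# Acquisition presets for the six compared sequences.
# MIX1/MIX2 are interleaved prep-module 3D TSE acquisitions; the 2D/3D TSE
# entries are the morphologic reference sequences of matching weighting.
# 2D TSE sequences use their single TE as the readout echo time; 3D TSE
# sequences use the equivalent TE of their refocusing pattern.
MIX1:
  tr_ms: 1200
  te_equiv_ms: 46
  weighting: PD-w FS
  blocks:
    - {prep_type: t2prep, prep_time_ms: 0, fat_sat: true, label: PD-w FS}
    - {prep_type: t2prep, prep_time_ms: 50, fat_sat: false, label: T2-w}
2D TSE PD-w FS:
  tr_ms: 3000
  te_equiv_ms: 40
  weighting: PD-w FS
  blocks:
    - {prep_type: none, prep_time_ms: 0, fat_sat: true, label: PD-w FS}
3D TSE PD-w FS:
  tr_ms: 1100
  te_equiv_ms: 46
  weighting: PD-w FS
  blocks:
    - {prep_type: none, prep_time_ms: 0, fat_sat: true, label: PD-w FS}
MIX2:
  tr_ms: 600
  te_equiv_ms: 13
  weighting: T1-w
  spinlock_freq_hz: 500
  blocks:
    - {prep_type: spinlock, prep_time_ms: 0, fat_sat: false, label: T1-w}
    - {prep_type: spinlock, prep_time_ms: 25, fat_sat: true, label: T1rho-w FS TSL25}
    - {prep_type: spinlock, prep_time_ms: 50, fat_sat: true, label: T1rho-w FS TSL50}
2D TSE T1-w:
  tr_ms: 582
  te_equiv_ms: 15
  weighting: T1-w
  blocks:
    - {prep_type: none, prep_time_ms: 0, fat_sat: false, label: T1-w}
3D TSE T1-w:
  tr_ms: 400
  te_equiv_ms: 21
  weighting: T1-w
  blocks:
    - {prep_type: none, prep_time_ms: 0, fat_sat: false, label: T1-w}
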