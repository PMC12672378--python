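# Synthetic-session presets.
#
# plateau_effect_pct / artifact_effect_pct are the percent changes (at
# plateau, per stimulation epoch in protocol order) that the generator's
# ground truth targets; they are transcribed observed condition means for
# the experiments each preset emulates.  Kinetic time constants, baseline
# amplitudes (arbitrary detector counts) and bleaching rates are generator
# choices, not measurements; see docs/methods.md.
#
# Channel fluorophore names refer to columns of the packaged reference
# shapes (gcamp, gfp, venus, tdtomato).  bleach_fraction_per_min is the
# linear fading fraction per minute (0.02 = 2 %/min).

fig1h:
  description: Postsynaptic somatic calcium (GCaMP6f/tdTomato in STN neurons)
  protocol: standard
  control: tdtomato
  channels:
    gcamp6f:
      fluorophore: gcamp
      baseline_amplitude: 800.0
      bleach_fraction_per_min: 0.02
      onset_tau_s: 10.0
      offset_tau_s: 60.0
      transient_bump: {amplitude_pct: 3.0, width_s: 5.0}
      plateau_effect_pct: [-4.523, -10.94, -15.87]
    tdtomato:
      fluorophore: tdtomato
      baseline_amplitude: 1000.0
      bleach_fraction_per_min: 0.02

fig2f:
  description: Glutamatergic afferent-terminal calcium (GCaMP8f/tdTomato)
  protocol: standard
  control: tdtomato
  channels:
    gcamp8f:
      fluorophore: gcamp
      baseline_amplitude: 700.0
      bleach_fraction_per_min: 0.02
      onset_tau_s: 1.0
      offset_tau_s: 1.0
      plateau_effect_pct: [7.687, 15.09, 23.52]
    tdtomato:
      fluorophore: tdtomato
      baseline_amplitude: 1000.0
      bleach_fraction_per_min: 0.02

fig2l:
  description: GABAergic afferent-terminal calcium (GCaMP8f/tdTomato)
  protocol: standard
  control: tdtomato
  channels:
    gcamp8f:
      fluorophore: gcamp
      baseline_amplitude: 700.0
      bleach_fraction_per_min: 0.02
      onset_tau_s: 1.0
      offset_tau_s: 1.0
      plateau_effect_pct: [10.38, 15.86, 21.28]
    tdtomato:
      fluorophore: tdtomato
      baseline_amplitude: 1000.0
      bleach_fraction_per_min: 0.02

fig3r:
  description: Dual transmitter sensing (Venus-iGluSnFR + iGABASnFR + tdTomato)
  protocol: standard
  control: tdtomato
  channels:
    venus_igluesnfr:
      fluorophore: venus
      baseline_amplitude: 700.0
      bleach_fraction_per_min: 0.02
      onset_tau_s: 10.0
      offset_tau_s: 90.0
      plateau_effect_pct: [-9.302, -14.26, -22.19]
    igabasnfr:
      fluorophore: gfp
      baseline_amplitude: 600.0
      bleach_fraction_per_min: 0.02
      onset_tau_s: 10.0
      offset_tau_s: 30.0
      plateau_effect_pct: [-4.296, -6.087, -8.104]
    tdtomato:
      fluorophore: tdtomato
      baseline_amplitude: 1000.0
      bleach_fraction_per_min: 0.02

ext13-control:
  description: Non-responsive parent fluorophores (cpSFVenus + cpSFGFP + tdTomato);
    only the stimulation artifact acts
  protocol: standard
  control: tdtomato
  channels:
    cpsfvenus:
      fluorophore: venus
      baseline_amplitude: 700.0
      bleach_fraction_per_min: 0.02
      onset_tau_s: 1.0
      offset_tau_s: 1.0
      artifact_effect_pct: [0.2788, -2.596, -2.413]
    cpsfgfp:
      fluorophore: gfp
      baseline_amplitude: 600.0
      bleach_fraction_per_min: 0.02
      onset_tau_s: 1.0
      offset_tau_s: 1.0
      artifact_effect_pct: [0.08273, -2.296, -2.466]
    tdtomato:
      fluorophore: tdtomato
      baseline_amplitude: 1000.0
      bleach_fraction_per_min: 0.02

ext15-lowfreq:
  description: Low-frequency (20 Hz) stimulation; all effects null
  protocol: lowfreq
  control: tdtomato
  channels:
    gcamp6f:
      fluorophore: gcamp
      baseline_amplitude: 800.0
      bleach_fraction_per_min: 0.02
      onset_tau_s: 10.0
      offset_tau_s: 60.0
    tdtomato:
      fluorophore: tdtomato
      baseline_amplitude: 1000.0
      bleach_fraction_per_min: 0.02

fig7:
  description: Chemogenetic vs electrical inhibition of STN neurons
    (GCaMP8f/tdTomato); one session per condition
  protocol: single_epoch
  control: tdtomato
  channels:
    gcamp8f:
      fluorophore: gcamp
      baseline_amplitude: 700.0
      bleach_fraction_per_min: 0.02
      onset_tau_s: 10.0
      offset_tau_s: 60.0
    tdtomato:
      fluorophore: tdtomato
      baseline_amplitude: 1000.0
      bleach_fraction_per_min: 0.02
  conditions:
    vehicle: {gcamp8f: [-0.8995]}
    cno: {gcamp8f: [-8.031]}
    dbs: {gcamp8f: [-8.248]}
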