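- class: membrane_filter
  bands:
  - center: 1030
    width: 25
    height: 1.0
    shape: lorentzian
  - center: 1160
    width: 20
    height: 0.55
    shape: lorentzian
  - center: 2900
    width: 30
    height: 0.25
    shape: lorentzian
  - center: 3340
    width: 120
    height: 0.35
    shape: gaussian
  jitter:
    center: 0.002
    width: 0.05
    height: 0.1
  baseline_amplitude: 0.0
- class: HDPE
  bands:
  - center: 2849
    width: 12
    height: 0.9
    shape: lorentzian
  - center: 2917
    width: 12
    height: 1.0
    shape: lorentzian
  - center: 1463
    width: 10
    height: 0.3
    shape: lorentzian
  - center: 719
    width: 8
    height: 0.2
    shape: lorentzian
  jitter:
    center: 0.002
    width: 0.05
    height: 0.1
  baseline_amplitude: 0.0
- class: PMMA
  bands:
  - center: 1730
    width: 14
    height: 1.0
    shape: lorentzian
  - center: 1145
    width: 18
    height: 0.8
    shape: lorentzian
  - center: 2951
    width: 14
    height: 0.4
    shape: lorentzian
  - center: 1435
    width: 12
    height: 0.35
    shape: lorentzian
  jitter:
    center: 0.002
    width: 0.05
    height: 0.1
  baseline_amplitude: 0.0
- class: PS
  bands:
  - center: 698
    width: 8
    height: 1.0
    shape: lorentzian
  - center: 756
    width: 8
    height: 0.6
    shape: lorentzian
  - center: 1493
    width: 10
    height: 0.4
    shape: lorentzian
  - center: 3026
    width: 12
    height: 0.35
    shape: lorentzian
  jitter:
    center: 0.002
    width: 0.05
    height: 0.1
  baseline_amplitude: 0.0
- class: PTFE
  bands:
  - center: 1203
    width: 16
    height: 1.0
    shape: lorentzian
  - center: 1146
    width: 14
    height: 0.9
    shape: lorentzian
  jitter:
    center: 0.002
    width: 0.05
    height: 0.1
  baseline_amplitude: 0.0
- class: PET
  bands:
  - center: 1714
    width: 14
    height: 1.0
    shape: lorentzian
  - center: 1241
    width: 16
    height: 0.85
    shape: lorentzian
  - center: 1095
    width: 14
    height: 0.6
    shape: lorentzian
  - center: 725
    width: 10
    height: 0.5
    shape: lorentzian
  jitter:
    center: 0.002
    width: 0.05
    height: 0.1
  baseline_amplitude: 0.0
- class: PVC
  bands:
  - center: 1427
    width: 12
    height: 0.6
    shape: lorentzian
  - center: 1254
    width: 12
    height: 0.7
    shape: lorentzian
  - center: 2912
    width: 14
    height: 0.5
    shape: lorentzian
  - center: 690
    width: 14
    height: 1.0
    shape: lorentzian
  jitter:
    center: 0.002
    width: 0.05
    height: 0.1
  baseline_amplitude: 0.0
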