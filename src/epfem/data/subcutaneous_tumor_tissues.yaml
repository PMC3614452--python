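dermis_fat:
  axes:
  - E_irrev_V_per_cm: 1200.0
    E_rev_V_per_cm: 300.0
    factor: 4.0
    family: heaviside
    sigma0_S_per_m: 0.25
  - E_irrev_V_per_cm: 1200.0
    E_rev_V_per_cm: 300.0
    factor: 4.0
    family: heaviside
    sigma0_S_per_m: 0.25
  - E_irrev_V_per_cm: 1200.0
    E_rev_V_per_cm: 300.0
    factor: 4.0
    family: heaviside
    sigma0_S_per_m: 0.25
  fiber_frame:
  - - 1.0
    - 0.0
    - 0.0
  - - 0.0
    - 1.0
    - 0.0
  - - 0.0
    - 0.0
    - 1.0
muscle:
  axes:
  - E_irrev_V_per_cm: 800.0
    E_rev_V_per_cm: 80.0
    factor: 2.5
    family: heaviside
    sigma0_S_per_m: 0.75
  - E_irrev_V_per_cm: 800.0
    E_rev_V_per_cm: 200.0
    factor: 2.5
    family: heaviside
    sigma0_S_per_m: 0.135
  - E_irrev_V_per_cm: 800.0
    E_rev_V_per_cm: 200.0
    factor: 2.5
    family: heaviside
    sigma0_S_per_m: 0.135
  fiber_frame:
  - - 1.0
    - 0.0
    - 0.0
  - - 0.0
    - 1.0
    - 0.0
  - - 0.0
    - 0.0
    - 1.0
stratum_corneum_epidermis:
  axes:
  - E_irrev_V_per_cm: 1200.0
    E_rev_V_per_cm: 400.0
    factor: 100.0
    family: heaviside
    sigma0_S_per_m: 0.008
  - E_irrev_V_per_cm: 1200.0
    E_rev_V_per_cm: 400.0
    factor: 100.0
    family: heaviside
    sigma0_S_per_m: 0.008
  - E_irrev_V_per_cm: 1200.0
    E_rev_V_per_cm: 400.0
    factor: 100.0
    family: heaviside
    sigma0_S_per_m: 0.008
  fiber_frame:
  - - 1.0
    - 0.0
    - 0.0
  - - 0.0
    - 1.0
    - 0.0
  - - 0.0
    - 0.0
    - 1.0
tumor_T1:
  axes:
  - E_irrev_V_per_cm: 800.0
    E_rev_V_per_cm: 400.0
    factor: 2.5
    family: heaviside
    sigma0_S_per_m: 0.3
  - E_irrev_V_per_cm: 800.0
    E_rev_V_per_cm: 400.0
    factor: 2.5
    family: heaviside
    sigma0_S_per_m: 0.3
  - E_irrev_V_per_cm: 800.0
    E_rev_V_per_cm: 400.0
    factor: 2.5
    family: heaviside
    sigma0_S_per_m: 0.3
  fiber_frame:
  - - 1.0
    - 0.0
    - 0.0
  - - 0.0
    - 1.0
    - 0.0
  - - 0.0
    - 0.0
    - 1.0
tumor_T2:
  axes:
  - E_irrev_V_per_cm: 800.0
    E_rev_V_per_cm: 400.0
    factor: 2.5
    family: heaviside
    sigma0_S_per_m: 0.6
  - E_irrev_V_per_cm: 800.0
    E_rev_V_per_cm: 400.0
    factor: 2.5
    family: heaviside
    sigma0_S_per_m: 0.6
  - E_irrev_V_per_cm: 800.0
    E_rev_V_per_cm: 400.0
    factor: 2.5
    family: heaviside
    sigma0_S_per_m: 0.6
  fiber_frame:
  - - 1.0
    - 0.0
    - 0.0
  - - 0.0
    - 1.0
    - 0.0
  - - 0.0
    - 0.0
    - 1.0
tumor_T3:
  axes:
  - E_irrev_V_per_cm: 800.0
    E_rev_V_per_cm: 400.0
    factor: 2.5
    family: heaviside
    sigma0_S_per_m: 0.9
  - E_irrev_V_per_cm: 800.0
    E_rev_V_per_cm: 400.0
    factor: 2.5
    family: heaviside
    sigma0_S_per_m: 0.9
  - E_irrev_V_per_cm: 800.0
    E_rev_V_per_cm: 400.0
    factor: 2.5
    family: heaviside
    sigma0_S_per_m: 0.9
  fiber_frame:
  - - 1.0
    - 0.0
    - 0.0
  - - 0.0
    - 1.0
    - 0.0
  - - 0.0
    - 0.0
    - 1.0
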