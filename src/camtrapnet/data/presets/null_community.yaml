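# Fully independent community at balanced occupancy (psi = 0.5 for all
# species), the operating point where a discrete 2x2 test is least
# conservative -- the standard design for calibrating test size.
name: null_community
n_sites: 67
n_days: 365
start: 2022-06-01
species:
  - {name: sp01, psi: 0.5, mu: 5.0, k: 2.0, activity: [[1.0, 0.0, 0.0]]}
  - {name: sp02, psi: 0.5, mu: 5.0, k: 2.0, activity: [[1.0, 0.0, 0.0]]}
  - {name: sp03, psi: 0.5, mu: 5.0, k: 2.0, activity: [[1.0, 0.0, 0.0]]}
  - {name: sp04, psi: 0.5, mu: 5.0, k: 2.0, activity: [[1.0, 0.0, 0.0]]}
  - {name: sp05, psi: 0.5, mu: 5.0, k: 2.0, activity: [[1.0, 0.0, 0.0]]}
  - {name: sp06, psi: 0.5, mu: 5.0, k: 2.0, activity: [[1.0, 0.0, 0.0]]}
  - {name: sp07, psi: 0.5, mu: 5.0, k: 2.0, activity: [[1.0, 0.0, 0.0]]}
  - {name: sp08, psi: 0.5, mu: 5.0, k: 2.0, activity: [[1.0, 0.0, 0.0]]}
  - {name: sp09, psi: 0.5, mu: 5.0, k: 2.0, activity: [[1.0, 0.0, 0.0]]}
  - {name: sp10, psi: 0.5, mu: 5.0, k: 2.0, activity: [[1.0, 0.0, 0.0]]}
  - {name: sp11, psi: 0.5, mu: 5.0, k: 2.0, activity: [[1.0, 0.0, 0.0]]}
  - {name: sp12, psi: 0.5, mu: 5.0, k: 2.0, activity: [[1.0, 0.0, 0.0]]}
associations: []
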