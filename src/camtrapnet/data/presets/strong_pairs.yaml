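# Small community with several planted pairwise associations, for demos
# and recovery tests: one strong positive, one moderate negative, one
# moderate positive pair; the rest independent.
name: strong_pairs
n_sites: 200
n_days: 365
start: 2022-06-01
species:
  - {name: alpha, psi: 0.5, mu: 5.0, k: 2.0, activity: [[1.0, 1.5708, 2.0]]}
  - {name: bravo, psi: 0.5, mu: 5.0, k: 2.0, activity: [[1.0, 4.7124, 2.0]]}
  - {name: charlie, psi: 0.5, mu: 5.0, k: 2.0, activity: [[1.0, 3.1416, 2.0]]}
  - {name: delta, psi: 0.5, mu: 5.0, k: 2.0, activity: [[1.0, 0.0, 2.0]]}
  - {name: echo, psi: 0.5, mu: 5.0, k: 2.0, activity: [[1.0, 2.0, 1.0]]}
  - {name: foxtrot, psi: 0.5, mu: 5.0, k: 2.0, activity: [[1.0, 5.0, 1.0]]}
associations:
  - {pair: [alpha, bravo], phi: 0.6}
  - {pair: [charlie, delta], phi: -0.4}
  - {pair: [echo, foxtrot], phi: 0.4}
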