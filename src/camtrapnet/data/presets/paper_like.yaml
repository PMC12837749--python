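# 67-site, 1-year camera grid with 12 species: heterogeneous occupancy,
# a strong positive pair (muntjac-boar), a one-way commensal pair
# (squirrel tracking the elephant), independent remainder, and a bimodal
# crepuscular focal species. Activity components are
# [weight, mean direction (radians), concentration].
name: paper_like
n_sites: 67
n_days: 365
start: 2022-06-01
species:
  - {name: elephant, psi: 0.75, mu: 6.0, k: 1.5,
     activity: [[0.5, 1.5708, 3.0], [0.5, 4.8407, 3.0]]}
  - {name: sambar, psi: 0.90, mu: 12.0, k: 1.0,
     activity: [[0.6, 0.3, 1.5], [0.4, 4.8407, 2.0]]}
  - {name: muntjac, psi: 0.50, mu: 8.0, k: 1.0,
     activity: [[0.5, 1.8, 2.0], [0.5, 4.5, 2.0]]}
  - {name: wild_boar, psi: 0.50, mu: 5.0, k: 1.5,
     activity: [[1.0, 3.1416, 1.5]]}
  - {name: red_bellied_squirrel, psi: 0.55, mu: 7.0, k: 2.0,
     activity: [[1.0, 2.8, 2.5]]}
  - {name: macaque, psi: 0.33, mu: 5.0, k: 1.0,
     activity: [[1.0, 3.1416, 2.0]]}
  - {name: pig_tailed_macaque, psi: 0.15, mu: 3.0, k: 2.0,
     activity: [[1.0, 3.4, 2.5]]}
  - {name: red_junglefowl, psi: 0.18, mu: 7.0, k: 1.0,
     activity: [[0.5, 2.0, 3.0], [0.5, 4.3, 3.0]]}
  - {name: brush_tailed_porcupine, psi: 0.15, mu: 4.0, k: 2.0,
     activity: [[1.0, 0.0, 2.5]]}
  - {name: malayan_porcupine, psi: 0.24, mu: 4.0, k: 2.0,
     activity: [[1.0, 0.5, 2.0]]}
  - {name: leopard_cat, psi: 0.15, mu: 2.0, k: 2.0,
     activity: [[1.0, 0.2, 1.5]]}
  - {name: serow, psi: 0.10, mu: 3.0, k: 2.0,
     activity: [[0.5, 1.3, 2.0], [0.5, 5.0, 2.0]]}
# The muntjac-boar pair emulates the near-coincident spatial use reported
# for the community's most-associated herbivore pair; the elephant-squirrel
# pair plants a one-way commensal dependence (squirrel nested in elephant range).
associations:
  - {pair: [muntjac, wild_boar], phi: 0.8}
  - {pair: [elephant, red_bellied_squirrel], latent: 0.95}
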