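alpha: 0.1
candidate_forms:
- hexagonal
- community
em_finalists: 2
em_max_iter: 300
em_restarts_first: 6
em_restarts_later: 3
em_screen_iters: 30
em_tol: 1.0e-06
form: hexagonal
gamma: 0.8
inference_only: true
mode: pairs
n_blocks: 7
n_components: 7
n_sims: 10
name: fig4
obs_per_block: 150
omitted_edges:
- - 12
  - 18
- - 12
  - 23
- - 13
  - 18
- - 13
  - 19
- - 14
  - 19
- - 14
  - 20
- - 15
  - 20
- - 15
  - 21
questions_per_block: 40
resample_questions: true
seed: 0
shape:
- 6
- 6
variants:
- basis
- DA
- SR-online
- SR-A
- SRreg
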