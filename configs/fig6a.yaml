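alpha: 0.1
candidate_forms:
- community
em_finalists: 3
em_max_iter: 400
em_restarts_first: 20
em_restarts_later: 10
em_screen_iters: 40
em_tol: 1.0e-06
form: community
gamma: 0.8
inference_only: true
mode: walk
n_blocks: 7
n_components: 7
n_sims: 20
name: fig6a
obs_per_block: 180
omitted_edges: []
questions_per_block: 0
resample_questions: true
seed: 0
shape:
- 5
- 7
variants:
- basis
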