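# Full demo run: synthesize a default cohort and evaluate all three
# approaches with LOSO.  `nfspeech run --config examples/demo.yaml`
seed: 1
out: results
approaches: [semsearch, ml, llm]
synth:
  n_patients: 33
  lexicon_separation: 1.0
# approach settings (defaults shown)
embed_backend: mock
vote_k: 5
knn_k: 5
classify_family: random_forest
regress_family: random_forest
shots_classify: 6
shots_regress: 9
n_paraphrases: 9
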