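"""Watch the Q-learning controller find the most helpful bucket.

A mock environment assigns each of four buckets a probability of lowering
the validation loss during its interval (bucket 2 helps 90% of the time,
the rest 30%). After 200 simulated validations the Q-table should rank
bucket 2 on top: its score counts how often the loss fell minus how often
it rose while that bucket was active.
"""

from bucketaugment import best_bucket, run_mock_search

effects = [0.3, 0.3, 0.9, 0.3]
state = run_mock_search(effects, n_rounds=200, seed=0)

print("improvement odds per bucket:", effects)
print("final Q-table             :", list(state.q))
print("discovered policy          : bucket", best_bucket(state))
switches = sum(r.reward == -1 for r in state.history)
print(f"{len(state.history)} validations, {switches} bucket switches "
      "(one per negative reward)")
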