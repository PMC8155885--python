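"""Detecting a planted learning onset from response times.

Simulates 60 trials of four questions each; from trial 30 the fourth
question's response speeds up by 0.5 s (the participant has implicitly
learned the hidden rule linking questions 1 and 4).  The labeler
smooths the RT series, compares the smoothed Q4 RT (DRT) with a lower
bound of the smoothed Q2/Q3 average (URT), and marks trials after
three consecutive fast trials (the TRT rule).
"""

from implearn import SynthConfig, gen_rt, label_trials

cfg = SynthConfig(n_trials=60, learning_onset=30, rt_effect=0.5,
                  rt_noise_sd=0.1, seed=42)
labels = label_trials(gen_rt(cfg))

marked = labels.loc[labels["trt"], "trial"].tolist()
print(f"planted learning onset: trial {cfg.learning_onset}")
print(f"first TRT mark:         trial {marked[0]}")
print(f"total fast-labeled trials: {len(marked)} of {len(labels)}")
print(labels.loc[28:35, ["trial", "drt", "urt", "bound", "below",
                         "trt", "label"]].to_string(index=False))
print("\nThe first mark lands ~2 trials after the onset: the rule needs")
print("three consecutive below-bound trials before it fires.")
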