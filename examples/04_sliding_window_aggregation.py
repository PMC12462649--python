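"""Sliding-window inference and the four aggregation rules.

Enumerates the windows a 50-slice stack produces under both tail
policies, then aggregates a hand-picked set of window probabilities with
each rule to show how they differ — in particular how the weighted
average discounts the brain-dominated superior windows.
"""

from petmri3d import SlidingWindowConfig, WindowScores, aggregate, window_starts

for policy in ("floor", "end_aligned"):
    cfg = SlidingWindowConfig(window=32, stride=16, tail_policy=policy)
    for depth in (32, 48, 50):
        print(f"depth {depth:2d}, {policy:11s}: starts {list(window_starts(depth, cfg))}")

# A case whose only suspicious window is the most superior one (where
# the brain lives): the weighted rule discounts it the most.
ws = WindowScores(starts=(0, 16, 18), probs=(0.9, 0.3, 0.2))
threshold = 0.5
for method in ("average", "median", "weighted", "majority"):
    pred = aggregate(ws, method, threshold, case_id="demo")
    score = "NA" if pred.score != pred.score else f"{pred.score:.3f}"
    print(f"{method:9s}: score={score} decision={'positive' if pred.decision else 'negative'}")
# average 0.467 and median 0.300; the weighted average (weights 1/6,
# 2/6, 3/6 superior to inferior) lands at 0.350 because the high
# probability came from the brain-heavy top window; majority needs 2 of
# 3 windows above threshold and votes negative.
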