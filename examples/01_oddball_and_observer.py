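"""Simulate an oddball block and watch the ideal observer learn it.

Generates the default 405-trial binary stream (deviant probability 1/3),
runs the leaky-integration observer at w = 16, and prints its belief about
the deviant-after-standard transition probability at a few checkpoints.
"""

import megsurprise as ms

seq = ms.generate_oddball(T=405, p_deviant=1 / 3, seed=7)
print(f"block: {len(seq)} trials, {seq.n_deviants} deviants "
      f"({seq.n_deviants / len(seq):.3f} observed vs 0.333 nominal)")

traj = ms.belief_trajectory(seq, w=16.0)
for t in (1, 5, 50, 405):
    belief = traj.posteriors[t - 1]
    p = ms.predictive_probability(belief, prev=0, nxt=1)
    f = belief.factor_given0
    print(f"trial {t:3d}: belief about P(deviant|standard) = Beta({f.a:6.2f}, {f.b:6.2f})"
          f" -> predictive p = {p:.3f}")

# With w = 16, only the last ~16 transitions effectively count, so the
# predictive probability hovers around the generating rate (~1/3 of standards
# are followed by a deviant) without ever freezing to it.
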