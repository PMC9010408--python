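"""Simulate one closed-loop Ultimatum Game session.

A responder who accepts any offer of at least 400p plays 6 blocks of 40
trials against the adaptive proposer: faces drift happier after accepts,
offers probe around the acceptance threshold.
"""

from socialug.task_engine import (make_state_space, offer_threshold_policy,
                                  run_session, select_payout_trials)

space = make_state_space()
print(f"stimulus space: {space.n_faces} faces x {space.n_offers} offers "
      f"= {space.n_states} joint states")

session = run_session(offer_threshold_policy(400), seed=7)
print(f"trials: {len(session)}, acceptance rate: {session['choice'].mean():.2f}")
print(f"mean offer: {session['offer_pence'].mean():.0f}p "
      f"(the sampler settles near the 400p threshold)")
print(f"mean face valence: {session['phi'].mean():.2f}")

payout = select_payout_trials(session, rng=1)
print(f"payout over 20 random trials: {payout['payout_pence']}p")
# The proposer probes the responder's threshold: average offers sit close
# to 400p, and the payout reflects only the randomly selected trials.
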