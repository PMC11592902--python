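"""Deep Q-learning validated against exact value iteration.

Solves a small deterministic MDP twice — by value iteration (exact) and by
the package's DQN recipe (replay buffer, target network, epsilon-greedy) —
and prints both Q tables.  Matching greedy policies show the learner
implements the Bellman machinery correctly before it is trusted to steer
class weights during training.
"""

import numpy as np

from cytorl.rl import TabularMDP, solve_mdp_exact, train_dqn_on_mdp

# two states; in state 0 action 0 moves to state 1 (no reward) while
# action 1 stays put for +0.5; state 1 pays +1 for returning to itself
mdp = TabularMDP(transitions=((1, 0), (1, 1)),
                 rewards=((0.0, 0.5), (1.0, 0.0)))
gamma = 0.9

q_star = solve_mdp_exact(mdp, gamma)
qnet = train_dqn_on_mdp(mdp, gamma, seed=1, steps=3000)
eye = np.eye(mdp.n_states)
q_dqn = np.stack([qnet.q_values(eye[s]) for s in range(mdp.n_states)])

print("optimal Q (value iteration):")
print(np.round(q_star, 3))
print("learned Q (DQN):")
print(np.round(q_dqn, 3))
print(f"greedy policies match: "
      f"{np.array_equal(q_star.argmax(1), q_dqn.argmax(1))}")
print(f"max |Q_dqn - Q*| = {np.abs(q_dqn - q_star).max():.4f}")
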