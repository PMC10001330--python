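"""Train a tiny RBM with contrastive divergence and track exact likelihood.

The RBM is small enough (4 visible, 3 hidden units) that the partition
function can be computed by enumerating all visible configurations, so
the average log-likelihood of the training data is exact.  Data are drawn
from a planted (randomly parameterized) teacher RBM; CD-1 training should
raise the student's log-likelihood toward the teacher's.
"""

from itertools import product

import numpy as np

from mpadbn import RBMParams, exact_log_likelihood, free_energy, train_rbm_cd

rng = np.random.default_rng(0)
teacher = RBMParams(W=rng.normal(0, 2, size=(4, 3)),
                    b_vis=rng.normal(size=4), b_hid=rng.normal(size=3))
states = np.array(list(product([0.0, 1.0], repeat=4)))
p = np.exp(-free_energy(teacher, states))
p /= p.sum()
data = states[rng.choice(len(states), size=200, p=p)]

print("epochs  avg log-likelihood (exact)")
for epochs in (0, 10, 25, 50):
    student = train_rbm_cd(data, n_hidden=3, k=1, lr=0.1, epochs=epochs, seed=0)
    print(f"{epochs:6d}  {exact_log_likelihood(student, data):+.4f}")
print(f"teacher {exact_log_likelihood(teacher, data):+.4f}  (upper reference)")
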