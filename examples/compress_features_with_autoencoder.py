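"""Compress feature vectors with the stacked autoencoder.

Builds a low-rank 10-D dataset, trains a 10 -> 6 -> 2 sigmoid encoder
with a mirrored decoder, and prints the mean squared reconstruction loss
before and after training.  Because the data lie near a 2-D subspace, a
2-unit bottleneck can reconstruct them almost perfectly.
"""

import numpy as np

from mpadbn import reconstruction_loss, train_autoencoder

rng = np.random.default_rng(0)
X = rng.normal(size=(300, 2)) @ rng.normal(size=(2, 10))

untrained = train_autoencoder(X, (10, 6, 2), epochs=0, seed=1)
trained = train_autoencoder(X, (10, 6, 2), epochs=100, seed=1)
print(f"loss at init      {reconstruction_loss(untrained.reconstruct(X), X):8.3f}")
print(f"loss after train  {reconstruction_loss(trained.reconstruct(X), X):8.3f}")
print(f"bottleneck shape  {trained.encode(X).shape}  (n_samples x 2)")
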