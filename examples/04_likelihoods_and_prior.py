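"""The probability primitives: NB and ZIP laws, mixture responsibilities.

Prints a few exact values with their analytic cross-checks, the kind of
sanity arithmetic worth knowing when reading the training losses.
"""

import numpy as np

from pairedvae import GMMPrior, cluster_posterior, nb_log_pmf, zip_log_pmf

# NB as Gamma(shape a, rate b)-Poisson: a=1, b=1 is geometric(1/2)
print("NB(a=1,b=1): P(0) =", np.exp(nb_log_pmf(0, 1.0, 1.0)), "(geometric: 0.5)")
print("NB(a=1,b=1): P(1) =", np.exp(nb_log_pmf(1, 1.0, 1.0)), "(geometric: 0.25)")

# ZIP zero mass mixes structural dropout (1-tau) and Poisson zeros
p0 = np.exp(zip_log_pmf(0, 1.0, 0.5))
print(f"ZIP(mu=1, tau=0.5): P(0) = {p0:.6f} "
      f"(= 0.5 + 0.5*exp(-1) = {0.5 + 0.5 * np.exp(-1):.6f})")

# normalisation: the truncated sums reach 1
s = np.exp(nb_log_pmf(np.arange(1001), 2.5, 0.7)).sum()
print(f"sum_x NB(x; 2.5, 0.7) over x<=1000 = {s:.10f}")

# mixture responsibilities: a point midway between two equal components
prior = GMMPrior(K=2, log_pi=np.log([0.5, 0.5]),
                 mu=np.array([[-1.0, -1.0], [1.0, 1.0]]),
                 sigma=np.ones((2, 2)))
resp = cluster_posterior(np.zeros((1, 2)), prior)
print("p(c|z=0) for symmetric 2-component prior:", resp[0], "(expect [0.5 0.5])")
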