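"""Shared test utilities."""

import numpy as np


def simulate_mixture(pT, pN, pU, kappa, n, rng):
    """Draw target-relative errors and non-target offsets from a known
    three-component circular mixture; the recovery oracle for the EM fit."""
    comp = rng.choice(3, n, p=[pT, pN, pU])
    delta = rng.uniform(-np.pi, np.pi, n)  # nontarget position relative to target
    e = np.where(
        comp == 0,
        rng.vonmises(0, kappa, n),
        np.where(comp == 1, delta + rng.vonmises(0, kappa, n), rng.uniform(-np.pi, np.pi, n)),
    )
    e = np.angle(np.exp(1j * e))
    off = np.angle(np.exp(1j * (e - delta)))
    return e, off
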