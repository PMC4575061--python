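"""Independent per-individual microsimulation oracle.

Simulates each individual's yearly state by categorical sampling from the
transition matrix rows — deliberately sharing no code with the cohort
engine — so cohort occupancy can be checked against empirical frequencies
within binomial sampling error.
"""

import numpy as np


def microsim_occupancy(
    matrix: np.ndarray,
    initial_dist: np.ndarray,
    n_cycles: int,
    n_individuals: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Empirical state frequencies, shape (n_cycles + 1, n_states)."""
    n_states = matrix.shape[0]
    cum = np.cumsum(matrix, axis=1)
    states = rng.choice(n_states, size=n_individuals, p=initial_dist)
    freq = np.empty((n_cycles + 1, n_states))
    freq[0] = np.bincount(states, minlength=n_states) / n_individuals
    for t in range(1, n_cycles + 1):
        u = rng.random(n_individuals)
        states = (u[:, None] > cum[states]).sum(axis=1)
        freq[t] = np.bincount(states, minlength=n_states) / n_individuals
    return freq


def binomial_3se_band(p: np.ndarray, n: int, floor: float = 1e-4) -> np.ndarray:
    """Three binomial standard errors around true proportions ``p``.

    The floor keeps the band usable where p is 0 or 1 (finite-sample noise
    from states the chain almost never visits).
    """
    return 3.0 * np.sqrt(np.maximum(p * (1.0 - p), 0.0) / n) + floor
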