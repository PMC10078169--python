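"""Shared fixtures and enumeration helpers for the test suite."""

import itertools

import numpy as np
import pytest

from jspva.datasets import (
    AGE_AHY, AGE_ASY, AGE_SY, AugmentedState, EncounterDataset, ModelParams,
)


def all_latent_states(M, T):
    """Exhaustive generator of consistent augmented states (tiny M, T only)."""
    per = []
    for b in range(T):
        a1s = (0, 1) if b == 0 else (0,)
        for a in a1s:
            for d in range(b, T):
                per.append((b, a, d))
    per.append((T, 0, -1))
    for combo in itertools.product(per, repeat=M):
        b = np.array([c[0] for c in combo])
        a1 = np.array([c[1] for c in combo])
        z = np.zeros((M, T), dtype=np.int8)
        for i, (bb, _, dd) in enumerate(combo):
            if bb < T:
                z[i, bb:dd + 1] = 1
        yield AugmentedState(b=b, a1=a1, z=z)


def random_params(rng, T=2):
    """A random parameter draw with everything in a numerically safe range.

    pi1 and alpha are drawn jointly so that the cumulative entry
    probability can never exceed one (gamma <= alpha <= 1 - pi1), keeping
    every enumerable latent configuration feasible.
    """
    pi1 = rng.uniform(0.1, 0.6)
    return ModelParams(
        pi1=pi1,
        alpha=rng.uniform(0.2, 0.95 * (1.0 - pi1)), beta0_gamma=rng.normal(),
        beta1_gamma=rng.normal(0, 0.5), beta2_gamma=rng.uniform(0, 0.3),
        beta0_phi_sy=rng.normal(), beta0_phi_asy=rng.normal(),
        beta1_phi=rng.normal(0, 0.5), beta0_cap=rng.normal(),
        beta1_cap=rng.normal(0, 0.3), k=rng.uniform(0.2, 0.9),
        tau=rng.uniform(0.2, 0.8),
        p_eta=rng.uniform(0.5, 0.95), p_r=rng.uniform(0.3, 0.9),
        w=rng.normal(0, 1, T))


@pytest.fixture
def toy_dataset():
    """One SY female captured in year 1 and resighted in year 2; u=(1,0)."""
    return EncounterDataset(
        years=[2000, 2001],
        capture=np.array([[1, 0]], dtype=np.int8),
        age_at_capture=np.array([AGE_SY], dtype=np.int8),
        resight=np.array([[0, 1]], dtype=np.int8),
        unmarked_count=[1, 0], m=3, area_ha=2.0)


@pytest.fixture
def toy_params():
    return ModelParams(
        alpha=0.8, beta0_gamma=0.2, beta1_gamma=0.0, beta2_gamma=0.05,
        beta0_phi_sy=-0.2, beta0_phi_asy=0.4, beta1_phi=0.0,
        beta0_cap=0.3, beta1_cap=0.0, k=0.7, tau=0.4, pi1=0.3,
        p_eta=0.8, p_r=0.61, w=np.zeros(2))
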