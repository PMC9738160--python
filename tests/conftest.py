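import numpy as np
import pytest

import elastochain as ec


@pytest.fixture(scope="session")
def masp1a_chain() -> ec.ChainModel:
    """The 15-link, 8.1 Å chain at 298 K fitted to the MaSp1a fragment."""
    return ec.ChainModel(n_links=15, link_length=8.1, temperature=298.0)


@pytest.fixture(scope="session")
def masp2_chain() -> ec.ChainModel:
    return ec.ChainModel(n_links=21, link_length=8.1, temperature=298.0)


def synthetic_fragment(n_links: int, link_length: float, name: str = "synthetic") -> ec.FragmentSpec:
    """A fragment whose contour length exactly matches an N-link chain of length a.

    Used for parameter-recovery fixtures: the packaged contour lengths are not
    integer multiples of the link length.
    """
    return ec.FragmentSpec(
        name=f"{name}-N{n_links}", n_residues=n_links + 1, l_max=n_links * link_length
    )


def mc_curve(model: ec.ChainModel, fragment: ec.FragmentSpec, n_samples: int, seed: int):
    """Monte-Carlo force–extension curve from the exact sampler (axial means)."""
    rows = []
    for i, force in enumerate(fragment.force_ladder):
        vec, _ = ec.sample_fjc_end_to_end(model, force, n_samples, seed=seed + i)
        rows.append(
            (force, float(vec[:, 2].mean()), float(vec[:, 2].std(ddof=1)), n_samples)
        )
    return ec.build_curve(rows, fragment)


def noiseless_curve(model: ec.ChainModel, fragment: ec.FragmentSpec):
    """Closed-form force–extension curve (no sampling noise)."""
    rows = [
        (f, fragment.l_max * float(ec.langevin(f * model.link_length / model.kT)), 1.0, 1000)
        for f in fragment.force_ladder
    ]
    return ec.build_curve(rows, fragment)


@pytest.fixture(scope="session")
def short_zero_force_run(masp1a_chain) -> ec.Trajectory:
    """A short seeded zero-force relaxation from the extended start (shared across tests)."""
    bd = ec.BdParams(n_steps=1_000_000, seed=11)
    return ec.simulate_trajectory(ec.MASP1A, masp1a_chain, 0.0, bd)


def random_conformation(rng: np.random.Generator, n_beads: int = 12, step: float = 3.8):
    """A random-walk bead trace, a generic non-degenerate conformation."""
    steps = rng.normal(size=(n_beads, 3))
    steps /= np.linalg.norm(steps, axis=1, keepdims=True)
    return ec.Conformation(np.cumsum(step * steps, axis=0))
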