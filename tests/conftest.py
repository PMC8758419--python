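import numpy as np
import pytest

import poregate as pg


@pytest.fixture(scope="session")
def z_axis():
    return pg.PoreAxis(origin=np.zeros(3), direction=np.array([0.0, 0.0, 1.0]))


@pytest.fixture(scope="session")
def toy_channel():
    return pg.make_toy_channel(pg.ToyChannelSpec())


@pytest.fixture(scope="session")
def toy_channel_axis(toy_channel):
    return pg.fit_pore_axis(toy_channel, [f"chain {c}" for c in "ABCD"])


@pytest.fixture(scope="session")
def alpha_helix_15():
    return pg.make_ideal_helix(15, "alpha")


@pytest.fixture(scope="session")
def pi_helix_15():
    return pg.make_ideal_helix(15, "pi")


@pytest.fixture(scope="session")
def gate_barrier_field():
    """2000-frame water field against a 12.55 kJ/mol (3 kcal/mol) gate barrier.

    The barrier height is the hydration-barrier scale of a dewetted
    activation gate; the gate sits at z = -10 Angstrom (the -1 nm
    convention for the activation gate along the pore axis).
    """
    spec = pg.SolventFieldSpec(dg_profile=[(12.55, -10.0, 4.0)],
                               n_frames=2000, seed=2021)
    return spec, pg.sample_waters(spec)


def make_cylinder_structure(radius=6.0, z_values=(-2.0, -1.0, 0.0, 1.0, 2.0),
                            n_per_ring=12, element="C"):
    """Ring-of-atoms cylinder around the z axis (analytic radius fixture)."""
    serial, names, elements, rnames, rnums, chains, coords = [], [], [], [], [], [], []
    s = 1
    for zi, z in enumerate(z_values):
        for k in range(n_per_ring):
            t = 2 * np.pi * k / n_per_ring
            serial.append(s)
            names.append(f"C{k}")
            elements.append(element)
            rnames.append("CYL")
            rnums.append(zi + 1)
            chains.append("X")
            coords.append([radius * np.cos(t), radius * np.sin(t), z])
            s += 1
    return pg.Structure(serial, names, elements, rnames, rnums, chains, coords)


def make_water_structure(coords):
    coords = np.atleast_2d(np.asarray(coords, dtype=float))
    n = len(coords)
    return pg.Structure(
        serial=np.arange(1, n + 1), name=["O"] * n, element=["O"] * n,
        residue_name=["HOH"] * n, residue_number=np.arange(1, n + 1),
        chain_id=["W"] * n, coord=coords)
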