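import numpy as np
import pytest

from leafsize import (
    ProfileParams,
    SpeciesId,
    TlnGroup,
    Trait,
    build_params,
    default_parameter_set,
    leaf_dimension,
)


@pytest.fixture(scope="session")
def maize_set():
    return default_parameter_set(SpeciesId.MAIZE)


@pytest.fixture(scope="session")
def sorghum_set():
    return default_parameter_set(SpeciesId.SORGHUM)


@pytest.fixture(scope="session")
def millet_set():
    return default_parameter_set(SpeciesId.PEARL_MILLET)


@pytest.fixture(scope="session")
def maize_length_17(maize_set):
    """Generic maize blade-length parameters at TLN 17 (xs=9.09, dr=0.67)."""
    return build_params(maize_set, Trait.BLADE_LENGTH, 17)


def random_profile_params(rng, n):
    """Sample n random valid parameter vectors spanning realistic ranges."""
    out = []
    for _ in range(n):
        tb = rng.uniform(0.0, 6.0)
        out.append(
            ProfileParams(
                L1=rng.uniform(1.0, 100.0),
                cm=rng.uniform(5.0, 200.0),
                rm=rng.uniform(0.1, 3.0),
                tb=tb,
                xs=tb + 1.0 + rng.uniform(1.0, 20.0),
                dr=rng.uniform(0.05, 5.0),
                dsl=rng.uniform(0.01, 50.0),
            )
        )
    return out


def noiseless_group(pset, trait, tln, genotype="truth"):
    """A TLN group holding exact model values at integer positions 1..tln."""
    positions = np.arange(1, tln + 1, dtype=float)
    params = build_params(pset, trait, tln)
    return TlnGroup(
        species=pset.species,
        genotype=genotype,
        trait=trait,
        tln=tln,
        positions=positions,
        values=leaf_dimension(positions, params),
    )
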