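import numpy as np
import pytest
from hypothesis import settings

from tangle.synthetic import SyntheticConfig, generate_dataset

settings.register_profile("ci", deadline=None, derandomize=True)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_dataset():
    """Ten short chains shared by fast tests."""
    return generate_dataset(SyntheticConfig(n_chains=10, length_range=(30, 50),
                                            seed=7))


@pytest.fixture
def rng():
    return np.random.default_rng(42)


def write_pdb(chain, path):
    """Minimal PDB writer for toy backbone chains (test helper)."""
    aa_serial = 1
    with open(path, "w") as fh:
        for res in chain.residues:
            for atom_name, coord in (("N", res.n), ("CA", res.ca), ("C", res.c)):
                if coord is None:
                    continue
                x, y, z = coord
                fh.write(
                    f"ATOM  {aa_serial:5d}  {atom_name:<3s} {res.name:>3s} "
                    f"{chain.chain_id}{int(res.seq_position):4d}    "
                    f"{x:8.3f}{y:8.3f}{z:8.3f}  1.00  0.00           "
                    f"{atom_name[0]}\n")
                aa_serial += 1
        fh.write("END\n")
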