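import numpy as np
import pytest

import pocketsim as ps
from pocketsim import synthetic_data as sd


def pdb_line(name, resname, chain, resnum, x, y, z, *, serial=1, altloc=" ",
             icode=" ", occ=1.0, element=None, hetero=False):
    """One fixed-column PDB coordinate record."""
    record = "HETATM" if hetero else "ATOM  "
    element = element or name[0]
    aname = f" {name:<3s}" if len(name) < 4 else name
    return (f"{record}{serial:5d} {aname:4s}{altloc:1s}{resname:>3s} "
            f"{chain:1s}{resnum:4d}{icode:1s}   "
            f"{x:8.3f}{y:8.3f}{z:8.3f}{occ:6.2f}{0.0:6.2f}          "
            f"{element:>2s}")


@pytest.fixture(scope="session")
def coarse_schedule():
    return ps.radius_schedule(3.0, 10.0, 0.5, "inclusive")


@pytest.fixture(scope="session")
def fine_schedule():
    return ps.radius_schedule(3.0, 10.0, 0.1, "half-open")


@pytest.fixture(scope="session")
def dense_pocket():
    """Pocket dense enough that every coarse-schedule shell around the
    tight grid below is populated (asserted where it matters)."""
    return sd.make_toy_pocket(
        sd.PocketSpec(n_residues=20, radius_range=(2.0, 6.0), seed=0))


@pytest.fixture(scope="session")
def tight_grid():
    return ps.make_grid((0.0, 0.0, 0.0), (1.5, 1.5, 1.5), (2, 2, 2))
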