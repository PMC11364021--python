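"""Shared fixtures: synthetic structures, profiles and a tiny PDB file.

All fixtures are generated programmatically; expensive ones (SASA-annotated
globules and their Debye partial sums) are session-scoped.
"""

import numpy as np
import pytest

import saxsbench as sb
from saxsbench.profile_predictor import PartialIntensities


def _pdb_line(serial, name, res, chain, resseq, x, y, z, occ=1.0,
              element=" ", altloc=" ", record="ATOM"):
    name_f = f" {name:<3}" if len(name) < 4 else name
    return (f"{record:<6}{serial:>5} {name_f}{altloc}{res:>3} {chain}"
            f"{resseq:>4}    {x:8.3f}{y:8.3f}{z:8.3f}{occ:6.2f}{0.0:6.2f}"
            f"          {element:>2}\n")


@pytest.fixture
def dipeptide_pdb(tmp_path):
    """ALA-GLY dipeptide with an altloc CB, a water and a sulfate ion."""
    lines = [
        _pdb_line(1, "N", "ALA", "A", 1, 11.104, 6.134, -6.504, element="N"),
        _pdb_line(2, "CA", "ALA", "A", 1, 11.639, 6.071, -5.147, element="C"),
        _pdb_line(3, "C", "ALA", "A", 1, 13.006, 6.746, -5.092, element="C"),
        _pdb_line(4, "O", "ALA", "A", 1, 13.285, 7.615, -5.917, element="O"),
        _pdb_line(5, "CB", "ALA", "A", 1, 10.672, 6.718, -4.158, occ=0.60,
                  element="C", altloc="A"),
        _pdb_line(6, "CB", "ALA", "A", 1, 10.700, 6.800, -4.100, occ=0.40,
                  element="C", altloc="B"),
        _pdb_line(7, "N", "GLY", "A", 2, 13.850, 6.370, -4.130, element="N"),
        _pdb_line(8, "CA", "GLY", "A", 2, 15.170, 6.960, -3.950, element="C"),
        _pdb_line(9, "C", "GLY", "A", 2, 16.120, 6.020, -3.230, element="C"),
        _pdb_line(10, "O", "GLY", "A", 2, 15.750, 4.900, -2.890, element="O"),
        _pdb_line(11, "O", "HOH", "A", 101, 20.0, 20.0, 20.0, element="O",
                  record="HETATM"),
        _pdb_line(12, "S", "SO4", "A", 102, 25.0, 25.0, 25.0, element="S",
                  record="HETATM"),
        "END\n",
    ]
    path = tmp_path / "dipeptide.pdb"
    path.write_text("".join(lines))
    return path


@pytest.fixture
def gaussian_profile():
    """Exact Guinier-law profile: I = 5 exp(-(q Rg)^2 / 3), Rg = 14.5 A."""
    q = np.linspace(0.01, 0.35, 400)
    intensity = 5.0 * np.exp(-(q * 14.5) ** 2 / 3.0)
    return sb.SASProfile(q=q, I=intensity,
                         sigma=0.01 * intensity + 1e-4,
                         label="gaussian", mode="batch")


@pytest.fixture(scope="session")
def globule():
    """SASA-annotated 200-atom pseudo-protein globule."""
    model = sb.make_globule(n_atoms=200, radius=13.0, seed=3)
    sb.sasa_fractions(model)
    return model


@pytest.fixture(scope="session")
def globule_dimer(globule):
    dimer = sb.make_oligomer(globule, copies=2, displacement=40.0)
    sb.sasa_fractions(dimer)
    return dimer


@pytest.fixture(scope="session")
def fit_grid_q():
    return np.linspace(0.01, 0.5, 201)


@pytest.fixture(scope="session")
def globule_partials(globule, fit_grid_q):
    return PartialIntensities(globule, fit_grid_q, mode="binned")


@pytest.fixture(scope="session")
def dimer_partials(globule_dimer, fit_grid_q):
    return PartialIntensities(globule_dimer, fit_grid_q, mode="binned")


@pytest.fixture
def error_template():
    return sb.synthetic_error_template(q_max=0.5, sigma0=0.02)
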