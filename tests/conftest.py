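import numpy as np
import pytest
from hypothesis import settings

from metalswitch import ConformationalState, Ensemble, HingeToySpec, ResidueSite, make_hinge_toy

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


def pdb_atom_line(serial, name, resname, chain, resseq, xyz, occ=1.0,
                  altloc=" ", icode=" ", element=None):
    """One fixed-format ATOM record (names of < 4 chars start in column 14)."""
    element = element or name[0]
    name_field = f" {name:<3s}" if len(name) < 4 else name
    x, y, z = xyz
    return (
        f"ATOM  {serial:5d} {name_field}{altloc}{resname:>3s} {chain}{resseq:4d}{icode}"
        f"   {x:8.3f}{y:8.3f}{z:8.3f}{occ:6.2f}{0.0:6.2f}          {element:>2s}"
    )


def write_pdb(path, lines):
    path.write_text("\n".join(lines) + "\nEND\n")
    return path


def state_from_points(label, points, chain_ids=None, resnames=None, numbers=None):
    """Minimal state: one carbon atom per residue, sitting on its Cβ point."""
    points = np.asarray(points, float)
    n = len(points)
    chain_ids = chain_ids or ["A"] * n
    resnames = resnames or ["ALA"] * n
    numbers = numbers or list(range(1, n + 1))
    sites = [
        ResidueSite(c, num, rn, p)
        for c, num, rn, p in zip(chain_ids, numbers, resnames, points)
    ]
    return ConformationalState(
        label=label,
        sites=sites,
        source="synthetic",
        atom_coords=points.copy(),
        atom_elements=["C"] * n,
        atom_site_index=np.arange(n),
    )


def two_state_ensemble(closed_points, open_points, **kwargs):
    return Ensemble(
        {
            "closed": [state_from_points("closed", closed_points, **kwargs)],
            "open": [state_from_points("open", open_points, **kwargs)],
        }
    )


@pytest.fixture(scope="session")
def hinge_fixture(tmp_path_factory):
    """A small hinge toy shared by structure/design tests (40 residues/domain)."""
    spec = HingeToySpec(
        residues_per_domain=40,
        planted_pairs=[(1, 1, 10.5), (2, 2, 10.2), (3, 5, 10.8)],
        seed=11,
    )
    return make_hinge_toy(spec, tmp_path_factory.mktemp("hinge"))
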