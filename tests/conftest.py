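import numpy as np
import pytest

from packrate import GeometryRecipe, ProteinSites, SiteGeometry, make_sites


def atom_line(serial, name, resname, chain, resseq, xyz, element,
              altloc=" ", occ=1.0, icode=" "):
    """Hand-rolled, column-exact PDB ATOM record for tiny test structures."""
    name_field = f" {name:<3s}" if len(name) < 4 else name
    return (
        f"ATOM  {serial:5d} {name_field:<4s}{altloc}{resname:>3s} "
        f"{chain}{resseq:4d}{icode}   "
        f"{xyz[0]:8.3f}{xyz[1]:8.3f}{xyz[2]:8.3f}{occ:6.2f}{0.0:6.2f}"
        f"          {element:>2s}"
    )


def residue_lines(start_serial, resname, chain, resseq, atoms, **kw):
    """atoms: list of (name, xyz, element)."""
    return [
        atom_line(start_serial + k, name, resname, chain, resseq, xyz, elem, **kw)
        for k, (name, xyz, elem) in enumerate(atoms)
    ]


def backbone(origin):
    ox, oy, oz = origin
    return [
        ("N", (ox - 1.0, oy + 0.5, oz), "N"),
        ("CA", (ox, oy, oz), "C"),
        ("C", (ox + 1.2, oy + 0.6, oz), "C"),
        ("O", (ox + 1.2, oy + 1.8, oz), "O"),
    ]


@pytest.fixture
def gly_ala_pdb():
    """One Gly and one Ala; Ala's CB at a known coordinate."""
    lines = residue_lines(1, "GLY", "A", 1, backbone((0.0, 0.0, 0.0)))
    lines += residue_lines(5, "ALA", "A", 2,
                           backbone((5.0, 0.0, 0.0)) +
                           [("CB", (5.5, -1.3, 0.7), "C")])
    return "\n".join(lines + ["END"]) + "\n"


def sites_from_nodes(alphas, rhos=None, aas=None, chain="A"):
    """Build a ProteinSites directly from coordinate lists."""
    alphas = np.asarray(alphas, float)
    rhos = alphas if rhos is None else np.asarray(rhos, float)
    n = len(alphas)
    sites = []
    for i in range(n):
        distinct = not np.array_equal(alphas[i], rhos[i])
        aa = (aas[i] if aas else ("ALA" if distinct else "GLY"))
        sites.append(SiteGeometry(
            residue_id=(chain, i + 1, " "),
            amino_acid=aa,
            alpha_pos=alphas[i],
            rho_pos=rhos[i],
            has_distinct_rho=distinct,
        ))
    return ProteinSites(sites=sites, label="manual")


@pytest.fixture
def two_site_worked():
    """The worked two-site geometry: alpha/rho at known distances."""
    return sites_from_nodes(
        alphas=[(0.0, 0.0, 0.0), (3.0, 0.0, 0.0)],
        rhos=[(1.0, 0.0, 0.0), (4.0, 0.0, 0.0)],
    )


def random_sites(n, seed, gly_fraction=0.0, backbone_form=None):
    """Randomized compact geometry via the package generator."""
    if backbone_form is None:
        forms = ["ideal_helix", "random_compact_cluster", "self_avoiding_walk"]
        backbone_form = forms[seed % 3]
    return make_sites(GeometryRecipe(
        n_sites=n, backbone=backbone_form, gly_fraction=gly_fraction, seed=seed,
    ), label=f"rand_{n}_{seed}")
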