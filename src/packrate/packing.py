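"""Per-site packing-density measures and relative solvent accessibility.

Four weighted-contact-number (WCN) variants are computed from the two-node
representation; all are cutoff-free sums of inverse squared distances, in
units of 1/Angstrom^2:

* ``WCN_rho_alpharho`` — from the focal site's side-chain node rho to both
  the alpha and rho nodes of every other site. This is the side-chain contact
  density that the elastic-network stress model derives as the determinant of
  site-specific substitution rates (see :mod:`packrate.stress`).
* ``WCN_alpha_alpharho`` — the analogous sum taken from the focal C-alpha.
* ``WCN_alpha_alpha`` — the classical WCN (C-alpha to C-alpha only).
* ``WCN_rho_rho`` — side-chain centers only.

For a neighbor site without a distinct side-chain node (glycine, unresolved
side chains) the rho-node term of the alpharho-superscript measures is, by
default, still evaluated at the coincident alpha position — the single node
counts for both interaction classes, mirroring the spring network where that
node carries both roles. ``gly_rho_term="once"`` drops the duplicate instead;
the underlying data never states which convention real side-chain-less
residues should follow, so both are exposed.

RSA divides each residue's Shrake–Rupley solvent-accessible surface area
(probe radius 1.4 A, heavy atoms of the selected chain only) by the maximum
accessible area for its amino-acid type (Tien et al. normalization tables).
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Literal, TextIO

import numpy as np
from scipy.spatial.distance import cdist

from .errors import DegenerateGeometryError, SasaFailureError, UnknownResidueTypeError
from .structures import NONSTANDARD_PARENT, STANDARD_AA, ProteinSites, parse_structure

MEASURE_NAMES = (
    "WCN_rho_alpharho",
    "WCN_alpha_alpharho",
    "WCN_alpha_alpha",
    "WCN_rho_rho",
    "RSA",
)

GlyRhoTerm = Literal["duplicate", "once"]

#: Maximum accessible surface areas (A^2) per residue type, theoretical
#: (Gly-X-Gly tripeptide upper bounds) and empirical variants of the standard
#: Tien et al. normalization tables.
MAX_SA_THEORETICAL = {
    "ALA": 129.0, "ARG": 274.0, "ASN": 195.0, "ASP": 193.0, "CYS": 167.0,
    "GLN": 225.0, "GLU": 223.0, "GLY": 104.0, "HIS": 224.0, "ILE": 197.0,
    "LEU": 201.0, "LYS": 236.0, "MET": 224.0, "PHE": 240.0, "PRO": 159.0,
    "SER": 155.0, "THR": 172.0, "TRP": 285.0, "TYR": 263.0, "VAL": 174.0,
}
MAX_SA_EMPIRICAL = {
    "ALA": 121.0, "ARG": 265.0, "ASN": 187.0, "ASP": 187.0, "CYS": 148.0,
    "GLN": 214.0, "GLU": 214.0, "GLY": 97.0, "HIS": 216.0, "ILE": 195.0,
    "LEU": 191.0, "LYS": 230.0, "MET": 203.0, "PHE": 228.0, "PRO": 154.0,
    "SER": 143.0, "THR": 163.0, "TRP": 264.0, "TYR": 255.0, "VAL": 165.0,
}


@dataclass
class PackingProfile:
    """Per-site values of one structural predictor, aligned to a ProteinSites."""

    measure_name: str
    values: np.ndarray
    flags: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)


def _inverse_square(points_a: np.ndarray, points_b: np.ndarray,
                    sites: ProteinSites) -> np.ndarray:
    """Off-diagonal 1/d^2 matrix between two node sets of the same site list."""
    d = cdist(points_a, points_b)
    np.fill_diagonal(d, np.inf)  # exclude the focal site entirely (j != i)
    if np.any(d == 0.0):
        i, j = map(int, np.unravel_index(int(np.argmin(d)), d.shape))
        ids = sites.residue_ids
        raise DegenerateGeometryError(
            f"degenerate geometry: coincident nodes between sites {ids[i]} and {ids[j]}"
        )
    with np.errstate(divide="ignore"):
        inv = 1.0 / d**2
    return inv


def _alpharho_sum(focal: np.ndarray, sites: ProteinSites,
                  gly_rho_term: GlyRhoTerm) -> np.ndarray:
    inv_a = _inverse_square(focal, sites.alpha, sites)
    inv_r = _inverse_square(focal, sites.rho, sites)
    if gly_rho_term == "once":
        inv_r = inv_r * sites.has_distinct_rho[None, :]
    elif gly_rho_term != "duplicate":
        raise ValueError(f"unknown gly_rho_term {gly_rho_term!r}")
    return inv_a.sum(axis=1) + inv_r.sum(axis=1)


def wcn_rho_alpharho(sites: ProteinSites,
                     gly_rho_term: GlyRhoTerm = "duplicate") -> PackingProfile:
    """Side-chain weighted contact number: sum over j != i of
    1/d(rho_i, alpha_j)^2 + 1/d(rho_i, rho_j)^2."""
    values = _alpharho_sum(sites.rho, sites, gly_rho_term)
    return PackingProfile("WCN_rho_alpharho", values)


def wcn_alpha_alpharho(sites: ProteinSites,
                       gly_rho_term: GlyRhoTerm = "duplicate") -> PackingProfile:
    """Main-chain weighted contact number: sum over j != i of
    1/d(alpha_i, alpha_j)^2 + 1/d(alpha_i, rho_j)^2."""
    values = _alpharho_sum(sites.alpha, sites, gly_rho_term)
    return PackingProfile("WCN_alpha_alpharho", values)


def wcn_alpha_alpha(sites: ProteinSites) -> PackingProfile:
    """Classical WCN: sum over j != i of 1/d(alpha_i, alpha_j)^2."""
    values = _inverse_square(sites.alpha, sites.alpha, sites).sum(axis=1)
    return PackingProfile("WCN_alpha_alpha", values)


def wcn_rho_rho(sites: ProteinSites) -> PackingProfile:
    """Side-chain-only WCN: sum over j != i of 1/d(rho_i, rho_j)^2."""
    values = _inverse_square(sites.rho, sites.rho, sites).sum(axis=1)
    return PackingProfile("WCN_rho_rho", values)


def rsa(
    pdb_source: str | os.PathLike | TextIO,
    chain: str | None = None,
    *,
    max_sa_table: Literal["theoretical", "empirical"] | dict = "theoretical",
    probe_radius: float = 1.4,
    n_points: int = 960,
    clip: bool = False,
) -> PackingProfile:
    """Relative solvent accessibility per residue of the selected chain.

    The chain is stripped to its amino-acid heavy atoms (waters, ligands,
    other chains and hydrogens removed — the target data are monomeric
    enzymes, so accessibility is that of the isolated chain), surface areas
    are computed with the Shrake–Rupley rolling-probe method, and each
    residue's area is divided by the maximum for its type. Values above 1
    (possible for exposed termini or distorted geometries) are flagged and,
    only when ``clip`` is set, truncated to 1.
    """
    from Bio.PDB import PDBParser
    from Bio.PDB.SASA import ShrakeRupley

    from .structures import _as_handle, _select_conformer

    if isinstance(max_sa_table, str):
        table = {"theoretical": MAX_SA_THEORETICAL,
                 "empirical": MAX_SA_EMPIRICAL}[max_sa_table]
    else:
        table = dict(max_sa_table)

    # parse_structure defines the site list the profile must align to
    if hasattr(pdb_source, "read"):
        pdb_source = pdb_source.read()  # type: ignore[union-attr]
    sites = parse_structure(pdb_source, chain=chain)
    chain_id = sites.residue_ids[0][0]

    parser = PDBParser(QUIET=True, PERMISSIVE=True)
    with _as_handle(pdb_source) as fh:
        structure = parser.get_structure("input", fh)
    model = next(iter(structure))
    chain_ent = model[chain_id].copy()

    site_keys = {(rid[1], rid[2]) for rid in sites.residue_ids}
    for residue in list(chain_ent):
        hetflag, resseq, icode = residue.id
        if (int(resseq), icode) not in site_keys:
            chain_ent.detach_child(residue.id)
            continue
        for atom in list(residue):
            sel = _select_conformer(atom)
            if sel.element in ("H", "D"):
                residue.detach_child(atom.get_id())

    try:
        ShrakeRupley(probe_radius=probe_radius, n_points=n_points).compute(
            chain_ent, level="R"
        )
    except Exception as exc:
        raise SasaFailureError(f"sasa failure: {exc}") from exc

    by_key = {}
    for residue in chain_ent:
        _, resseq, icode = residue.id
        by_key[(int(resseq), icode)] = float(residue.sasa)

    values = np.empty(len(sites))
    for k, (site, rid) in enumerate(zip(sites, sites.residue_ids)):
        aa = site.amino_acid
        aa = NONSTANDARD_PARENT.get(aa, aa)
        if aa not in table:
            raise UnknownResidueTypeError(
                f"unknown residue type: {aa} at {rid} has no maximum-SA entry"
            )
        values[k] = by_key[(rid[1], rid[2])] / table[aa]

    over_one = values > 1.0
    flags = {"over_one_count": int(over_one.sum()),
             "over_one_sites": [sites.residue_ids[i] for i in np.nonzero(over_one)[0]]}
    if clip:
        values = np.minimum(values, 1.0)
    return PackingProfile("RSA", values, flags=flags)


def all_measures(
    sites: ProteinSites,
    pdb_source: str | os.PathLike | TextIO | None = None,
    chain: str | None = None,
    *,
    names: tuple[str, ...] = MEASURE_NAMES,
    gly_rho_term: GlyRhoTerm = "duplicate",
    **rsa_options,
) -> dict[str, PackingProfile]:
    """Compute the requested predictors for one structure.

    RSA needs the atomic coordinates, so it is computed only when a PDB
    source is supplied; requesting it without one is an error.
    """
    computers = {
        "WCN_rho_alpharho": lambda: wcn_rho_alpharho(sites, gly_rho_term),
        "WCN_alpha_alpharho": lambda: wcn_alpha_alpharho(sites, gly_rho_term),
        "WCN_alpha_alpha": lambda: wcn_alpha_alpha(sites),
        "WCN_rho_rho": lambda: wcn_rho_rho(sites),
    }
    out: dict[str, PackingProfile] = {}
    for name in names:
        if name == "RSA":
            if pdb_source is None:
                raise ValueError("RSA requested but no PDB source supplied")
            out[name] = rsa(pdb_source, chain=chain, **rsa_options)
        elif name in computers:
            out[name] = computers[name]()
        else:
            raise ValueError(f"unknown measure {name!r}")
    return out


def profiles_to_frame(sites: ProteinSites, profiles: dict[str, PackingProfile]):
    """Per-site table of predictor values (the per-protein profile CSV)."""
    import pandas as pd

    data = {
        "chain": [r[0] for r in sites.residue_ids],
        "resseq": [r[1] for r in sites.residue_ids],
        "icode": [r[2] for r in sites.residue_ids],
        "amino_acid": sites.amino_acids,
    }
    for name, prof in profiles.items():
        data[name] = prof.values
    return pd.DataFrame(data)
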