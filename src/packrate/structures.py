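"""Two-node-per-residue structure representation and rate-file I/O.

A protein chain is reduced to one :class:`SiteGeometry` per residue, carrying
two pseudo-atoms: the main-chain node ``alpha`` at the C-alpha position and the
side-chain node ``rho`` at the unweighted geometric center of the side-chain
heavy atoms. Glycine (and any residue whose side-chain atoms are unresolved)
contributes a single node: its rho position coincides with alpha and
``has_distinct_rho`` is False.

Empirical site-specific substitution rates are read either from Rate4Site
"grades" output or from a plain two-column TSV, and re-normalized to relative
rates (mean 1 over sites) regardless of any normalization in the input.
"""

from __future__ import annotations

import io
import logging
import os
from contextlib import contextmanager
from dataclasses import dataclass
from typing import Iterator, Literal, Sequence, TextIO

import numpy as np
import pandas as pd
from Bio.PDB import PDBParser
from Bio.PDB.Atom import DisorderedAtom

from .errors import (
    ChainNotFoundError,
    DuplicateSiteError,
    EmptyRateFileError,
    InsufficientSitesError,
    LengthMismatchError,
    NoOverlapError,
    PackrateError,
    ParseFailureError,
)

logger = logging.getLogger("packrate")

#: Backbone heavy atoms excluded from the side-chain geometric center.
BACKBONE_ATOMS = frozenset({"N", "CA", "C", "O", "OXT"})

#: The 20 standard amino acids (3-letter codes).
STANDARD_AA = frozenset(
    "ALA ARG ASN ASP CYS GLN GLU GLY HIS ILE "
    "LEU LYS MET PHE PRO SER THR TRP TYR VAL".split()
)

#: Common non-standard residues mapped to their parent standard amino acid.
NONSTANDARD_PARENT = {
    "MSE": "MET",  # selenomethionine
    "SEC": "CYS",
    "CSO": "CYS",
    "PYL": "LYS",
    "MLY": "LYS",
    "HYP": "PRO",
    "SEP": "SER",
    "TPO": "THR",
    "PTR": "TYR",
}

ResidueId = tuple[str, int, str]  # (chain id, residue sequence number, icode)


@dataclass(frozen=True)
class SiteGeometry:
    """One residue as a (C-alpha, side-chain-center) node pair."""

    residue_id: ResidueId
    amino_acid: str
    alpha_pos: np.ndarray
    rho_pos: np.ndarray
    has_distinct_rho: bool

    def __post_init__(self) -> None:
        a = np.asarray(self.alpha_pos, dtype=float)
        r = np.asarray(self.rho_pos, dtype=float)
        if a.shape != (3,) or r.shape != (3,):
            raise ValueError("node positions must be 3-vectors")
        if not (np.all(np.isfinite(a)) and np.all(np.isfinite(r))):
            raise ValueError("node positions must be finite")
        if not self.has_distinct_rho and not np.array_equal(a, r):
            raise ValueError("has_distinct_rho=False requires rho_pos == alpha_pos")
        if self.amino_acid == "GLY" and self.has_distinct_rho:
            raise ValueError("GLY cannot have a distinct rho node")
        object.__setattr__(self, "alpha_pos", a)
        object.__setattr__(self, "rho_pos", r)


@dataclass
class ProteinSites:
    """Ordered collection of sites for one chain."""

    sites: list[SiteGeometry]
    label: str = ""

    def __post_init__(self) -> None:
        if len(self.sites) < 2:
            raise InsufficientSitesError(
                f"insufficient sites: need at least 2, got {len(self.sites)}"
            )
        ids = [s.residue_id for s in self.sites]
        if len(set(ids)) != len(ids):
            raise DuplicateSiteError("duplicate site: residue ids must be unique")
        # coincident alpha nodes across sites are geometrically degenerate
        a = self.alpha
        d2 = ((a[:, None, :] - a[None, :, :]) ** 2).sum(axis=2)
        np.fill_diagonal(d2, np.inf)
        if np.any(d2 == 0.0):
            i, j = np.unravel_index(int(np.argmin(d2)), d2.shape)
            raise ValueError(
                f"coincident alpha nodes at sites {ids[i]} and {ids[j]}"
            )

    def __len__(self) -> int:
        return len(self.sites)

    def __iter__(self) -> Iterator[SiteGeometry]:
        return iter(self.sites)

    @property
    def alpha(self) -> np.ndarray:
        """(n, 3) array of C-alpha positions."""
        return np.array([s.alpha_pos for s in self.sites])

    @property
    def rho(self) -> np.ndarray:
        """(n, 3) array of side-chain-center positions."""
        return np.array([s.rho_pos for s in self.sites])

    @property
    def has_distinct_rho(self) -> np.ndarray:
        return np.array([s.has_distinct_rho for s in self.sites], dtype=bool)

    @property
    def residue_ids(self) -> list[ResidueId]:
        return [s.residue_id for s in self.sites]

    @property
    def amino_acids(self) -> list[str]:
        return [s.amino_acid for s in self.sites]


@dataclass
class RateProfile:
    """Per-site empirical substitution rates, raw and mean-1 relative."""

    entries: list[tuple[int, float, float]]  # (position, raw_rate, relative_rate)

    @classmethod
    def from_raw(cls, positions: Sequence[int], raw: Sequence[float]) -> "RateProfile":
        positions = list(positions)
        raw = np.asarray(raw, dtype=float)
        if len(positions) == 0:
            raise EmptyRateFileError("empty rate file: no parseable rows")
        if len(set(positions)) != len(positions):
            raise DuplicateSiteError("duplicate site: repeated residue position")
        rel = raw / raw.mean()
        return cls(entries=[(p, float(r), float(q)) for p, r, q in zip(positions, raw, rel)])

    @property
    def positions(self) -> list[int]:
        return [e[0] for e in self.entries]

    @property
    def raw(self) -> np.ndarray:
        return np.array([e[1] for e in self.entries])

    @property
    def relative(self) -> np.ndarray:
        return np.array([e[2] for e in self.entries])

    def __len__(self) -> int:
        return len(self.entries)


# ---------------------------------------------------------------------------
# PDB parsing
# ---------------------------------------------------------------------------

@contextmanager
def _as_handle(source: str | os.PathLike | TextIO) -> Iterator[TextIO]:
    """Yield a readable text handle; only handles we open are closed."""
    if hasattr(source, "read"):
        yield source  # type: ignore[misc]
        return
    text = str(source)
    if "\n" in text:
        yield io.StringIO(text)
        return
    fh = open(text)
    try:
        yield fh
    finally:
        fh.close()


def _select_conformer(atom):
    """Resolve alternate locations: highest occupancy, ties by altloc id."""
    if isinstance(atom, DisorderedAtom):
        children = atom.disordered_get_list()
        return min(children, key=lambda a: (-(a.get_occupancy() or 0.0), a.get_altloc()))
    return atom


def parse_structure(
    pdb_source: str | os.PathLike | TextIO,
    chain: str | None = None,
    label: str | None = None,
) -> ProteinSites:
    """Parse a PDB stream into the two-node-per-residue representation.

    Parameters
    ----------
    pdb_source
        PDB-format text, a path to a PDB file, or an open text handle.
    chain
        Chain identifier. ``None`` selects the only chain of the first model
        and is an error when several chains are present.
    label
        Structure label; defaults to the chain id.

    Only standard amino-acid residues (plus common parent-mapped variants such
    as MSE→MET) possessing a C-alpha atom form sites. Waters, ligands and
    hydrogens are ignored; only the first model of multi-model files is read;
    alternate locations resolve to the highest-occupancy conformer.
    """
    parser = PDBParser(QUIET=True, PERMISSIVE=True)
    try:
        with _as_handle(pdb_source) as fh:
            structure = parser.get_structure("input", fh)
        models = list(structure)
    except PackrateError:
        raise
    except Exception as exc:
        raise ParseFailureError(f"parse failure: {exc}") from exc
    if not models:
        raise ParseFailureError("parse failure: no models in structure")
    model = models[0]

    chain_ids = [c.id for c in model]
    if chain is None:
        if len(chain_ids) != 1:
            raise ChainNotFoundError(
                f"chain not found: no chain given and structure has chains {chain_ids}"
            )
        chain = chain_ids[0]
    if chain not in chain_ids:
        raise ChainNotFoundError(
            f"chain not found: {chain!r} not among {chain_ids}"
        )

    sites: list[SiteGeometry] = []
    for residue in model[chain]:
        hetflag, resseq, icode = residue.id
        resname = residue.get_resname().strip()
        if resname in NONSTANDARD_PARENT:
            resname = NONSTANDARD_PARENT[resname]
        elif resname not in STANDARD_AA:
            if hetflag == " ":
                logger.warning(
                    "skipping non-standard residue %s %s%s in chain %s",
                    resname, resseq, icode.strip(), chain,
                )
            continue  # waters, ligands, unmapped residues
        atoms = {}
        for atom in residue:
            sel = _select_conformer(atom)
            if sel.element in ("H", "D"):
                continue
            atoms[sel.get_name()] = np.asarray(sel.get_coord(), dtype=float)
        if "CA" not in atoms:
            logger.warning(
                "skipping residue %s %s in chain %s: no C-alpha", resname, resseq, chain
            )
            continue
        alpha = atoms["CA"]
        side = [xyz for name, xyz in atoms.items() if name not in BACKBONE_ATOMS]
        if resname != "GLY" and side:
            rho = np.mean(side, axis=0)
            distinct = True
        else:
            rho = alpha.copy()
            distinct = False
            if resname != "GLY":
                logger.warning(
                    "residue %s %s in chain %s has no resolved side-chain atoms; "
                    "rho placed at C-alpha", resname, resseq, chain,
                )
        sites.append(
            SiteGeometry(
                residue_id=(chain, int(resseq), icode),
                amino_acid=resname,
                alpha_pos=alpha,
                rho_pos=rho,
                has_distinct_rho=distinct,
            )
        )

    if len(sites) < 2:
        raise InsufficientSitesError(
            f"insufficient sites: chain {chain!r} has {len(sites)} C-alpha residues"
        )
    return ProteinSites(sites=sites, label=label if label is not None else str(chain))


# ---------------------------------------------------------------------------
# Rate files
# ---------------------------------------------------------------------------

Dialect = Literal["rate4site_grades", "two_column_tsv"]


def read_rate_file(
    source: str | os.PathLike | TextIO,
    dialect: Dialect = "two_column_tsv",
) -> RateProfile:
    """Read site-specific rates; relative rates are recomputed to mean 1.

    ``rate4site_grades`` skips '#'-prefixed header/footer lines and blank
    lines, reading the position (first) and SCORE (third) whitespace-separated
    columns. ``two_column_tsv`` reads ``position<TAB>rate`` lines.
    """
    with _as_handle(source) as fh:
        lines = fh.read().splitlines()
    positions: list[int] = []
    raw: list[float] = []
    for line in lines:
        stripped = line.strip()
        if not stripped or stripped.startswith("#"):
            continue
        fields = stripped.split()
        try:
            if dialect == "rate4site_grades":
                pos, score = int(fields[0]), float(fields[2])
            elif dialect == "two_column_tsv":
                pos, score = int(fields[0]), float(fields[1])
            else:
                raise ValueError(f"unknown dialect {dialect!r}")
        except (IndexError, ValueError):
            if dialect == "rate4site_grades":
                continue  # grades files carry trailing prose lines
            raise ParseFailureError(f"parse failure: bad rate line {line!r}")
        positions.append(pos)
        raw.append(score)
    return RateProfile.from_raw(positions, raw)


@dataclass
class AlignedRates:
    """Result of joining a rate profile onto structure sites."""

    table: pd.DataFrame  # columns: site_index, chain, resseq, icode, amino_acid, raw_rate, relative_rate
    unmatched_sites: int
    unmatched_rates: int


def align_rates_to_sites(
    sites: ProteinSites,
    rates: RateProfile,
    mode: Literal["by_position", "by_order"] = "by_position",
) -> AlignedRates:
    """Pair structure sites with rate entries.

    ``by_position`` joins on the residue sequence number; ``by_order`` zips
    the two lists and requires equal lengths. Only sites present in both
    inputs are returned, in structure order.
    """
    rows = []
    if mode == "by_order":
        if len(sites) != len(rates):
            raise LengthMismatchError(
                f"length mismatch: {len(sites)} sites vs {len(rates)} rates"
            )
        for k, (site, entry) in enumerate(zip(sites, rates.entries)):
            rows.append((k, site, entry))
        unmatched_sites = unmatched_rates = 0
    elif mode == "by_position":
        by_pos: dict[int, tuple[int, float, float]] = {}
        for entry in rates.entries:
            by_pos.setdefault(entry[0], entry)
        seen = set()
        for k, site in enumerate(sites):
            resseq = site.residue_id[1]
            if resseq in by_pos and resseq not in seen:
                rows.append((k, site, by_pos[resseq]))
                seen.add(resseq)
        unmatched_sites = len(sites) - len(rows)
        unmatched_rates = len(rates) - len(rows)
    else:
        raise ValueError(f"unknown alignment mode {mode!r}")

    if not rows:
        raise NoOverlapError("no overlap: zero matched sites between structure and rates")
    table = pd.DataFrame(
        {
            "site_index": [k for k, _, _ in rows],
            "chain": [s.residue_id[0] for _, s, _ in rows],
            "resseq": [s.residue_id[1] for _, s, _ in rows],
            "icode": [s.residue_id[2] for _, s, _ in rows],
            "amino_acid": [s.amino_acid for _, s, _ in rows],
            "raw_rate": [e[1] for _, _, e in rows],
            "relative_rate": [e[2] for _, _, e in rows],
        }
    )
    if unmatched_sites or unmatched_rates:
        logger.info(
            "alignment: %d matched, %d structure sites and %d rate entries unmatched",
            len(rows), unmatched_sites, unmatched_rates,
        )
    return AlignedRates(table=table, unmatched_sites=unmatched_sites,
                        unmatched_rates=unmatched_rates)


# ---------------------------------------------------------------------------
# Node dump (tabular round trip)
# ---------------------------------------------------------------------------

_DUMP_COLUMNS = [
    "chain", "resseq", "icode", "amino_acid",
    "alpha_x", "alpha_y", "alpha_z", "rho_x", "rho_y", "rho_z",
    "has_distinct_rho",
]


def sites_to_tsv(sites: ProteinSites) -> str:
    """Serialize to a node-dump TSV; coordinates use shortest round-trip repr."""
    out = ["\t".join(_DUMP_COLUMNS)]
    for s in sites:
        chain, resseq, icode = s.residue_id
        coords = [repr(float(v)) for v in (*s.alpha_pos, *s.rho_pos)]
        out.append("\t".join([
            chain, str(resseq), icode if icode.strip() else ".",
            s.amino_acid, *coords, "1" if s.has_distinct_rho else "0",
        ]))
    return "\n".join(out) + "\n"


def sites_from_tsv(text: str, label: str = "") -> ProteinSites:
    """Inverse of :func:`sites_to_tsv`; bit-exact on coordinates."""
    lines = [ln for ln in text.splitlines() if ln.strip()]
    if not lines or lines[0].split("\t") != _DUMP_COLUMNS:
        raise ParseFailureError("parse failure: not a packrate node dump")
    sites = []
    for ln in lines[1:]:
        f = ln.split("\t")
        icode = " " if f[2] == "." else f[2]
        sites.append(SiteGeometry(
            residue_id=(f[0], int(f[1]), icode),
            amino_acid=f[3],
            alpha_pos=np.array([float(f[4]), float(f[5]), float(f[6])]),
            rho_pos=np.array([float(f[7]), float(f[8]), float(f[9])]),
            has_distinct_rho=f[10] == "1",
        ))
    return ProteinSites(sites=sites, label=label)
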