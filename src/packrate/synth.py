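"""Synthetic protein geometries and rate profiles.

The generator stands in for a curated set of monomeric enzyme structures with
empirical rate profiles: it produces compact three-dimensional residue
geometries with distinct alpha and side-chain-center nodes, and per-site
rates that follow the stress model's decreasing linear law in a chosen
packing measure plus Gaussian noise. Every operation is a pure function of
its recipe, including the seed.

Backbone forms
--------------
* ``ideal_helix`` — canonical alpha-helix C-alpha trace (rise 1.5 A, 100
  degree twist, radius 2.3 A), side-chain nodes displaced radially outward.
* ``random_compact_cluster`` — C-alpha positions uniform in a sphere of
  radius 3.1 * n^(1/3) A (about 125 A^3 per residue, protein-like density)
  with a 3.5 A minimum pairwise separation enforced by rejection.
* ``self_avoiding_walk`` — 3.8 A virtual-bond chain with a 3.5 A excluded
  volume against all previous residues.

Side-chain offsets default to lengths ~ N(2.0, 0.6^2) A truncated at 0.5 A,
matching typical C-alpha-to-side-chain-centroid distances; a ``gly_fraction``
of randomly chosen sites gets a merged node (rho = alpha), as glycine does.
"""

from __future__ import annotations

import dataclasses
import json
import os
from dataclasses import dataclass
from pathlib import Path
from typing import Literal, Sequence

import numpy as np

from . import packing
from .errors import PackingTooDenseError, SlopeError
from .structures import ProteinSites, RateProfile, SiteGeometry

BackboneForm = Literal["ideal_helix", "random_compact_cluster", "self_avoiding_walk"]

HELIX_RISE = 1.5        # A per residue along the axis
HELIX_TWIST = 100.0     # degrees per residue
HELIX_RADIUS = 2.3      # A
MIN_CA_SEPARATION = 3.5  # A, excluded volume for cluster and walk
WALK_BOND = 3.8         # A, consecutive C-alpha distance


@dataclass(frozen=True)
class GeometryRecipe:
    """Recipe for one synthetic protein geometry."""

    n_sites: int = 150
    backbone: BackboneForm = "random_compact_cluster"
    offset_mean: float = 2.0   # A, side-chain offset length distribution
    offset_sd: float = 0.6
    offset_min: float = 0.5
    gly_fraction: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_sites < 2:
            raise ValueError("n_sites must be >= 2")
        if not 0.0 <= self.gly_fraction <= 1.0:
            raise ValueError("gly_fraction must be in [0, 1]")
        if self.offset_min < 0:
            raise ValueError("offset lengths must be >= 0")


@dataclass(frozen=True)
class RateRecipe:
    """Recipe for rates following rate = a - b * predictor + noise.

    ``slope`` must be positive: the generator encodes the decreasing rate
    law (an increasing-law experiment can negate the predictor instead).
    When ``target_r2`` is given, the noise standard deviation is derived per
    protein from the predictor's sample variance so that the population R^2
    of the linear-Gaussian model, b^2 Var(x) / (b^2 Var(x) + sigma_eps^2),
    equals the target. When ``intercept`` is None it is chosen so raw rates
    stay positive with a wide margin (the floor then essentially never
    triggers).
    """

    predictor: str = "WCN_rho_alpharho"
    intercept: float | None = None
    slope: float = 1.0
    noise_sd: float | None = 0.0
    target_r2: float | None = None
    floor: float = 1e-6
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.slope > 0:
            raise SlopeError("slope must be positive")
        if self.target_r2 is not None and not 0.0 < self.target_r2 < 1.0:
            raise ValueError("target_r2 must be in (0, 1)")


# ---------------------------------------------------------------------------
# Geometry
# ---------------------------------------------------------------------------

def _helix_alphas(n: int) -> np.ndarray:
    t = np.arange(n) * np.deg2rad(HELIX_TWIST)
    return np.column_stack([
        HELIX_RADIUS * np.cos(t),
        HELIX_RADIUS * np.sin(t),
        np.arange(n) * HELIX_RISE,
    ])


def _cluster_alphas(n: int, rng: np.random.Generator) -> np.ndarray:
    radius = 3.1 * n ** (1.0 / 3.0)
    placed: list[np.ndarray] = []
    attempts, cap = 0, 2000 * n
    while len(placed) < n:
        attempts += 1
        if attempts > cap:
            raise PackingTooDenseError(
                f"packing too dense: placed {len(placed)}/{n} sites "
                f"in {cap} attempts"
            )
        p = rng.uniform(-radius, radius, size=3)
        if p @ p > radius**2:
            continue
        if placed and np.min(np.linalg.norm(np.array(placed) - p, axis=1)) < MIN_CA_SEPARATION:
            continue
        placed.append(p)
    return np.array(placed)


def _walk_alphas(n: int, rng: np.random.Generator) -> np.ndarray:
    for _ in range(50):  # whole-walk restarts
        placed = [np.zeros(3)]
        ok = True
        for _ in range(n - 1):
            for _ in range(500):
                step = rng.normal(size=3)
                step *= WALK_BOND / np.linalg.norm(step)
                p = placed[-1] + step
                d = np.linalg.norm(np.array(placed) - p, axis=1)
                if d.min() >= MIN_CA_SEPARATION:
                    placed.append(p)
                    break
            else:
                ok = False
                break
        if ok:
            return np.array(placed)
    raise PackingTooDenseError("packing too dense: self-avoiding walk failed to complete")


def make_sites(recipe: GeometryRecipe, label: str = "synthetic") -> ProteinSites:
    """Generate a synthetic ProteinSites; deterministic given the seed."""
    rng = np.random.default_rng(recipe.seed)
    n = recipe.n_sites
    if recipe.backbone == "ideal_helix":
        alphas = _helix_alphas(n)
    elif recipe.backbone == "random_compact_cluster":
        alphas = _cluster_alphas(n, rng)
    elif recipe.backbone == "self_avoiding_walk":
        alphas = _walk_alphas(n, rng)
    else:
        raise ValueError(f"unknown backbone form {recipe.backbone!r}")

    lengths = np.clip(rng.normal(recipe.offset_mean, recipe.offset_sd, size=n),
                      recipe.offset_min, None)
    if recipe.backbone == "ideal_helix":
        directions = np.column_stack([alphas[:, 0], alphas[:, 1], np.zeros(n)])
        directions /= np.linalg.norm(directions, axis=1, keepdims=True)
    else:
        directions = rng.normal(size=(n, 3))
        directions /= np.linalg.norm(directions, axis=1, keepdims=True)
    rhos = alphas + lengths[:, None] * directions

    n_gly = int(round(recipe.gly_fraction * n))
    gly_idx = set(rng.choice(n, size=n_gly, replace=False).tolist())

    sites = []
    for i in range(n):
        is_gly = i in gly_idx
        sites.append(SiteGeometry(
            residue_id=("A", i + 1, " "),
            amino_acid="GLY" if is_gly else "ALA",
            alpha_pos=alphas[i],
            rho_pos=alphas[i].copy() if is_gly else rhos[i],
            has_distinct_rho=not is_gly,
        ))
    return ProteinSites(sites=sites, label=label)


# ---------------------------------------------------------------------------
# Rates
# ---------------------------------------------------------------------------

_PREDICTOR_FUNCS = {
    "WCN_rho_alpharho": packing.wcn_rho_alpharho,
    "WCN_alpha_alpharho": packing.wcn_alpha_alpharho,
    "WCN_alpha_alpha": packing.wcn_alpha_alpha,
    "WCN_rho_rho": packing.wcn_rho_rho,
}


def _predictor_values(sites: ProteinSites, name: str) -> np.ndarray:
    if name in _PREDICTOR_FUNCS:
        return _PREDICTOR_FUNCS[name](sites).values
    if name == "RSA":
        return packing.rsa(write_fixture_pdb(sites)).values
    raise ValueError(f"unknown generating predictor {name!r}")


def make_rates(sites: ProteinSites, recipe: RateRecipe) -> RateProfile:
    """Generate rates as a noisy decreasing linear function of a predictor.

    raw_i = a - b * x_i + eps_i with eps_i iid Gaussian(0, sigma_eps^2),
    floored at a small positive value; relative rates renormalized to mean 1
    after flooring. Deterministic given the seed.
    """
    rng = np.random.default_rng(recipe.seed)
    x = _predictor_values(sites, recipe.predictor)
    b = recipe.slope
    if recipe.target_r2 is not None:
        sd_x = float(x.std())
        noise_sd = b * sd_x * np.sqrt((1.0 - recipe.target_r2) / recipe.target_r2)
    else:
        noise_sd = float(recipe.noise_sd or 0.0)
    total_sd = float(np.hypot(b * x.std(), noise_sd))
    a = recipe.intercept
    if a is None:
        # keep raw rates positive with a ~6 sigma margin so the floor is inert
        a = b * float(x.mean()) + max(1.0, 6.0 * total_sd)
    eps = rng.normal(0.0, noise_sd, size=x.size) if noise_sd > 0 else np.zeros(x.size)
    raw = np.maximum(a - b * x + eps, recipe.floor)
    positions = [rid[1] for rid in sites.residue_ids]
    return RateProfile.from_raw(positions, raw)


def make_dataset(
    n_proteins: int,
    geometry: GeometryRecipe | Sequence[GeometryRecipe] = GeometryRecipe(),
    rates: RateRecipe = RateRecipe(),
    seed: int = 0,
) -> list[tuple[ProteinSites, RateProfile]]:
    """Independent synthetic proteins with per-protein derived seeds."""
    if n_proteins < 1:
        raise ValueError("n_proteins must be >= 1")
    geometries = list(geometry) if isinstance(geometry, Sequence) else [geometry]
    children = np.random.SeedSequence(seed).spawn(n_proteins)
    out = []
    for k, child in enumerate(children):
        g_seed, r_seed = (int(s) % 2**31 for s in child.generate_state(2))
        g = dataclasses.replace(geometries[k % len(geometries)], seed=g_seed)
        r = dataclasses.replace(rates, seed=r_seed)
        sites = make_sites(g, label=f"synth_{k:03d}")
        out.append((sites, make_rates(sites, r)))
    return out


# ---------------------------------------------------------------------------
# Fixture files
# ---------------------------------------------------------------------------

# fixed local backbone offsets (A) relative to C-alpha; only CA and CB carry
# information, the rest make the record a structurally plausible residue
_BACKBONE_OFFSETS = {
    "N": np.array([-0.930, -1.010, 0.0]),
    "C": np.array([1.200, -0.770, 0.0]),
    "O": np.array([1.950, -1.680, 0.0]),
}


def _pdb_atom(serial: int, name: str, resname: str, chain: str, resseq: int,
              xyz: np.ndarray, element: str) -> str:
    # single-letter-element atom names start in column 14 of the 13-16 field
    name_field = f" {name:<3s}" if len(name) < 4 else name
    return (
        f"ATOM  {serial:5d} {name_field:<4s} {resname:>3s} {chain}{resseq:4d}    "
        f"{xyz[0]:8.3f}{xyz[1]:8.3f}{xyz[2]:8.3f}{1.0:6.2f}{0.0:6.2f}"
        f"          {element:>2s}"
    )


def write_fixture_pdb(sites: ProteinSites) -> str:
    """Emit a poly-Ala/Gly PDB whose parse recovers alpha and rho exactly.

    Each site becomes one residue with N, C, O at fixed offsets from the
    C-alpha, CA at alpha_pos and — for sites with a distinct side-chain
    node — CB at rho_pos, so CB is the sole side-chain heavy atom and the
    parsed geometric center equals rho_pos to PDB coordinate precision.
    """
    lines = []
    serial = 1
    chain = sites.residue_ids[0][0]
    for site in sites:
        resseq = site.residue_id[1]
        resname = "GLY" if not site.has_distinct_rho else "ALA"
        for name in ("N", "CA", "C", "O"):
            xyz = site.alpha_pos if name == "CA" else site.alpha_pos + _BACKBONE_OFFSETS[name]
            lines.append(_pdb_atom(serial, name, resname, chain, resseq, xyz,
                                   name[0]))
            serial += 1
        if site.has_distinct_rho:
            lines.append(_pdb_atom(serial, "CB", resname, chain, resseq,
                                   site.rho_pos, "C"))
            serial += 1
    lines.append(f"TER   {serial:5d}      {resname:>3s} {chain}{resseq:4d}")
    lines.append("END")
    return "\n".join(lines) + "\n"


def write_fixture_rates_tsv(rates: RateProfile) -> str:
    """Two-column TSV (position, raw rate) for the rate-file reader."""
    return "".join(f"{pos}\t{raw!r}\n" for pos, raw, _ in rates.entries)


def write_dataset(
    out_dir: str | os.PathLike,
    dataset: Sequence[tuple[ProteinSites, RateProfile]],
    geometry: GeometryRecipe | None = None,
    rates: RateRecipe | None = None,
    seed: int | None = None,
) -> dict:
    """Write fixture PDBs, rate TSVs, and a manifest JSON; returns the manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    entries = []
    for sites, profile in dataset:
        pdb_path = out / f"{sites.label}.pdb"
        tsv_path = out / f"{sites.label}.rates.tsv"
        pdb_path.write_text(write_fixture_pdb(sites))
        tsv_path.write_text(write_fixture_rates_tsv(profile))
        entries.append({
            "label": sites.label,
            "structure": pdb_path.name,
            "chain": sites.residue_ids[0][0],
            "rates": tsv_path.name,
            "rates_dialect": "two_column_tsv",
        })
    manifest = {
        "proteins": entries,
        "geometry_recipe": dataclasses.asdict(geometry) if geometry else None,
        "rate_recipe": dataclasses.asdict(rates) if rates else None,
        "seed": seed,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
    return manifest
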