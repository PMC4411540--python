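"""Two-node-per-residue elastic-network stress model of mutation.

The protein is modelled as a parameter-free anisotropic network (pfANM) over
the alpha and rho nodes of every site: each pair of nodes belonging to
distinct sites is joined by a spring whose equilibrium length is the observed
distance d and whose force constant is k = 1/d^2. Sites without a distinct
side-chain node (glycine, unresolved side chains) contribute a single node
that plays both roles.

A mutation at site i replaces its side chain, which is modelled as adding
independent zero-mean random increments delta to the equilibrium lengths of
the springs incident to the side-chain node rho_i. Because the native (active)
conformation is held fixed, the energy penalty of the mutation at that
conformation is simply

    dV* = 1/2 * sum_{j != i} (k_{rho_i alpha_j} delta^2 + k_{rho_i rho_j} delta^2),

and averaging over mutations with perturbation variance sigma^2 gives

    <dV*>_i = (sigma^2 / 2) * sum_{j != i} (k_{rho_i alpha_j} + k_{rho_i rho_j})
            = (sigma^2 / 2) * WCN_rho_alpharho(i).

This closed form — the expected destabilization is proportional to the
side-chain weighted contact number, whatever the perturbation distribution —
is the model's central prediction: under weak selection the substitution rate
of a site decreases linearly with its side-chain contact density. No normal
modes, minimization or Hessian eigen-decomposition is involved.

When a neighbor j carries a single merged node, the rho_i–(node j) spring is
one physical spring but receives two independent perturbation slots (one per
interaction class), consistent with the duplicate-counting convention of
:func:`packrate.packing.wcn_rho_alpharho`.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import cached_property
from typing import Literal, Mapping

import numpy as np
from scipy.spatial.distance import cdist

from .errors import (
    DegenerateGeometryError,
    InvalidDistributionError,
    InvalidPerturbationError,
    NoVariationError,
)
from .structures import ProteinSites

NodeKind = Literal["alpha", "rho"]
#: A perturbation key: (neighbor site index, interaction class of the spring).
SpringKey = tuple[int, NodeKind]


@dataclass(frozen=True)
class Spring:
    node_a: tuple[int, NodeKind]
    node_b: tuple[int, NodeKind]
    force_constant: float
    equilibrium_length: float


@dataclass
class ElasticNetwork:
    """pfANM over the alpha/rho nodes of a ProteinSites (k = 1/d^2)."""

    sites: ProteinSites

    def __post_init__(self) -> None:
        a, r = self.sites.alpha, self.sites.rho
        self._d_ra = cdist(r, a)
        self._d_rr = cdist(r, r)
        self._d_aa = cdist(a, a)
        for d in (self._d_ra, self._d_rr, self._d_aa):
            np.fill_diagonal(d, np.inf)
        dmin = min(float(self._d_ra.min()), float(self._d_rr.min()),
                   float(self._d_aa.min()))
        if dmin == 0.0:
            d = self._d_ra if self._d_ra.min() == 0 else (
                self._d_rr if self._d_rr.min() == 0 else self._d_aa)
            i, j = map(int, np.unravel_index(int(np.argmin(d)), d.shape))
            ids = self.sites.residue_ids
            raise DegenerateGeometryError(
                f"degenerate geometry: coincident nodes between sites {ids[i]} and {ids[j]}"
            )

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    @cached_property
    def nodes(self) -> list[tuple[int, NodeKind, np.ndarray]]:
        """One alpha node per site plus a rho node where it is distinct."""
        out: list[tuple[int, NodeKind, np.ndarray]] = []
        for i, site in enumerate(self.sites):
            out.append((i, "alpha", site.alpha_pos))
            if site.has_distinct_rho:
                out.append((i, "rho", site.rho_pos))
        return out

    @cached_property
    def springs(self) -> list[Spring]:
        """Every unordered node pair between distinct sites, k = 1/d^2."""
        nodes = self.nodes
        out = []
        for a in range(len(nodes)):
            ia, ka, pa = nodes[a]
            for b in range(a + 1, len(nodes)):
                ib, kb, pb = nodes[b]
                if ia == ib:
                    continue  # no intra-site springs
                d = float(np.linalg.norm(pa - pb))
                out.append(Spring((ia, ka), (ib, kb), 1.0 / d**2, d))
        return out

    def incident_rho_constants(self, site: int) -> tuple[np.ndarray, np.ndarray]:
        """Force constants of the rho_i–alpha_j and rho_i–rho_j interactions.

        Returns (k_rho_alpha, k_rho_rho), each of length n_sites with the
        focal entry set to 0. For a merged-node neighbor the two entries refer
        to the same physical spring (and are equal).
        """
        if not 0 <= site < self.n_sites:
            raise IndexError(f"site index {site} out of range")
        k_ra = np.where(np.isinf(self._d_ra[site]), 0.0, 1.0 / self._d_ra[site] ** 2)
        k_rr = np.where(np.isinf(self._d_rr[site]), 0.0, 1.0 / self._d_rr[site] ** 2)
        return k_ra, k_rr


def build_network(sites: ProteinSites) -> ElasticNetwork:
    """Assemble the pfANM spring network for a parsed structure."""
    return ElasticNetwork(sites=sites)


@dataclass
class MutationModel:
    """Distribution of spring-length increments plus selection pressure.

    sigma is the standard deviation of the zero-mean increment distribution
    (Angstrom). Only sigma^2 enters any expected quantity; the family matters
    solely for Monte-Carlo sampling. beta is the selection pressure of the
    fixation weight exp(-beta * dV*).
    """

    sigma: float = 0.3
    distribution: Literal["gaussian", "uniform"] = "gaussian"
    beta: float = 0.0

    def __post_init__(self) -> None:
        if not self.sigma > 0:
            raise InvalidDistributionError("invalid distribution: sigma must be > 0")
        if self.distribution not in ("gaussian", "uniform"):
            raise InvalidDistributionError(
                f"invalid distribution: {self.distribution!r}"
            )
        if self.beta < 0:
            raise ValueError("beta must be >= 0")

    def sample(self, rng: np.random.Generator, size) -> np.ndarray:
        if self.distribution == "gaussian":
            return rng.normal(0.0, self.sigma, size=size)
        half = self.sigma * np.sqrt(3.0)  # uniform on [-h, h] has variance h^2/3
        return rng.uniform(-half, half, size=size)


@dataclass
class StressProfile:
    """Per-site expected destabilization of the active conformation."""

    dvstar: np.ndarray
    mc_mean: np.ndarray | None = None
    mc_stderr: np.ndarray | None = None
    label: str = ""

    def __post_init__(self) -> None:
        self.dvstar = np.asarray(self.dvstar, dtype=float)


def delta_v_star(
    network: ElasticNetwork,
    mutated_site: int,
    perturbations: Mapping[SpringKey, float],
) -> float:
    """Energy penalty of one mutation, evaluated at the active conformation.

    ``perturbations`` maps (neighbor site j, interaction class) to the
    length increment delta of the corresponding spring; springs incident to
    rho of the mutated site are the only valid keys. Omitted springs are
    unperturbed (delta = 0).
    """
    k_ra, k_rr = network.incident_rho_constants(mutated_site)
    total = 0.0
    for (j, kind), delta in perturbations.items():
        if (
            not isinstance(j, (int, np.integer))
            or not 0 <= j < network.n_sites
            or j == mutated_site
            or kind not in ("alpha", "rho")
        ):
            raise InvalidPerturbationError(
                f"invalid perturbation set: spring ({j}, {kind!r}) is not incident "
                f"to the side-chain node of site {mutated_site}"
            )
        k = k_ra[j] if kind == "alpha" else k_rr[j]
        total += k * float(delta) ** 2
    return 0.5 * total


def expected_stress_closed_form(
    network: ElasticNetwork, model: MutationModel
) -> StressProfile:
    """<dV*> per site: (sigma^2/2) * sum_j (k_rho_alpha + k_rho_rho).

    Exactly proportional to the side-chain weighted contact number
    WCN_rho_alpharho; holds for any zero-mean increment distribution with
    variance sigma^2.
    """
    n = network.n_sites
    dv = np.empty(n)
    for i in range(n):
        k_ra, k_rr = network.incident_rho_constants(i)
        dv[i] = 0.5 * model.sigma**2 * (k_ra.sum() + k_rr.sum())
    return StressProfile(dvstar=dv, label=network.sites.label)


def expected_stress_monte_carlo(
    network: ElasticNetwork,
    model: MutationModel,
    n_mutations: int,
    seed: int,
) -> StressProfile:
    """Estimate <dV*> by averaging dV* over sampled mutations at each site.

    Per site, ``n_mutations`` independent perturbation sets are drawn (one
    increment per incident interaction class) and the mean and standard error
    of dV* are returned alongside the closed form. Deterministic given seed.
    """
    if n_mutations < 2:
        raise ValueError("n_mutations must be >= 2")
    rng = np.random.default_rng(seed)
    n = network.n_sites
    mean = np.empty(n)
    stderr = np.empty(n)
    for i in range(n):
        k_ra, k_rr = network.incident_rho_constants(i)
        ks = np.concatenate([k_ra, k_rr])  # focal entries are 0, harmless
        deltas = model.sample(rng, (n_mutations, ks.size))
        dv = 0.5 * (deltas**2) @ ks
        mean[i] = dv.mean()
        stderr[i] = dv.std(ddof=1) / np.sqrt(n_mutations)
    closed = expected_stress_closed_form(network, model)
    return StressProfile(dvstar=closed.dvstar, mc_mean=mean, mc_stderr=stderr,
                         label=network.sites.label)


def predicted_rates(
    stress: StressProfile | np.ndarray,
    empirical_rates: np.ndarray | None = None,
) -> np.ndarray:
    """Per-site predicted relative rates from the stress profile.

    With empirical rates supplied, returns the least-squares affine map of
    -<dV*> onto them (the construction behind predicted-rate profiles and
    observed-vs-predicted scatter comparisons). Without, returns the
    sign-flipped stress vector shifted to mean 1: 1 + (mean(<dV*>) - <dV*>),
    a mean-1 decreasing profile with unit slope in energy units. The overall
    proportionality constant of the rate law is never estimated — only
    relative rates are meaningful.
    """
    dv = stress.dvstar if isinstance(stress, StressProfile) else np.asarray(stress, float)
    if dv.size < 2 or np.ptp(dv) == 0.0:
        raise NoVariationError("no variation: stress vector is constant")
    x = -dv
    if empirical_rates is None:
        return 1.0 + (dv.mean() - dv)
    y = np.asarray(empirical_rates, dtype=float)
    if y.shape != dv.shape:
        raise ValueError("empirical rates must align with the stress profile")
    slope, intercept = np.polyfit(x, y, 1)
    return intercept + slope * x


def fixation_probability(delta_v: float | np.ndarray, beta: float):
    """Unnormalized fixation weight exp(-beta * dV*) of a mutation."""
    if beta < 0:
        raise ValueError("beta must be >= 0")
    return np.exp(-beta * np.asarray(delta_v, dtype=float))


def stress_to_frame(sites: ProteinSites, profile: StressProfile,
                    predicted: np.ndarray | None = None):
    """Per-site stress table (residue id, <dV*>, MC columns, predicted rate)."""
    import pandas as pd

    data = {
        "chain": [r[0] for r in sites.residue_ids],
        "resseq": [r[1] for r in sites.residue_ids],
        "icode": [r[2] for r in sites.residue_ids],
        "amino_acid": sites.amino_acids,
        "expected_dVstar": profile.dvstar,
    }
    if profile.mc_mean is not None:
        data["mc_mean"] = profile.mc_mean
        data["mc_stderr"] = profile.mc_stderr
    if predicted is not None:
        data["predicted_rate"] = predicted
    return pd.DataFrame(data)
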