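"""Elementary metabolite unit (EMU) decomposition and MID simulation.

An EMU is a specific subset of a metabolite's carbon atoms.  The key
property of the EMU framework is that the mass isotopomer distribution
(MID) of any EMU at isotopic steady state satisfies a *linear* balance once
EMUs are processed in order of increasing size: cleavage reactions map an
EMU to a same-size EMU of a substrate, and condensation reactions build its
MID as the convolution of strictly smaller source EMUs.  Decomposing the
atom-mapped network backwards from the measured fragments therefore reduces
isotopomer simulation to a cascade of small linear systems — orders of
magnitude smaller than the full 2^n positional-isotopomer state space.

:func:`enumerate_isotopomers` solves that full 2^n state space directly and
serves as the exhaustive oracle against which the EMU path is verified on
small networks.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from functools import reduce

import numpy as np

from .atom_network import FluxVector, MetabolicNetwork

__all__ = [
    "EMU",
    "EMUReaction",
    "EMUNetwork",
    "InputLabeling",
    "MIDVector",
    "ConnectivityError",
    "DegenerateFluxError",
    "IsotopomerSizeError",
    "decompose",
    "simulate_mids",
    "convolve",
    "enumerate_isotopomers",
]


class ConnectivityError(ValueError):
    """A target EMU cannot be produced from any substrate."""


class DegenerateFluxError(ValueError):
    """The EMU balance system is singular at the given fluxes."""


class IsotopomerSizeError(ValueError):
    """Network exceeds the exhaustive-enumeration carbon cap."""


@dataclass(frozen=True, order=True)
class EMU:
    """A metabolite id together with a set of 1-based carbon positions."""

    metabolite: str
    indices: tuple[int, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "indices", tuple(sorted(self.indices)))
        if len(self.indices) == 0:
            raise ValueError("EMU must contain at least one carbon")
        if len(set(self.indices)) != len(self.indices) or min(self.indices) < 1:
            raise ValueError(f"invalid carbon index set {self.indices}")

    @property
    def size(self) -> int:
        return len(self.indices)

    def __str__(self) -> str:
        return f"{self.metabolite}[{','.join(map(str, self.indices))}]"


@dataclass(frozen=True)
class EMUReaction:
    """Production of ``target`` from ``sources`` carried by one reaction flux.

    ``flux_key`` is ``(reaction_id, direction)`` with direction ``'f'`` or
    ``'b'``; more than one source EMU marks a condensation (convolution).
    """

    target: EMU
    sources: tuple[EMU, ...]
    flux_key: tuple[str, str]


@dataclass
class EMUNetwork:
    """Minimal EMU reaction network sufficient to simulate the targets."""

    network: MetabolicNetwork
    targets: tuple[EMU, ...]
    producers: dict[EMU, list[EMUReaction]]

    @property
    def balanced_emus(self) -> list[EMU]:
        return sorted(e for e in self.producers
                      if self.network.metabolite(e.metabolite).role == "balanced")

    def layers(self) -> list[list[EMU]]:
        """Balanced EMUs grouped by size, ascending (the solve order)."""
        by_size: dict[int, list[EMU]] = {}
        for e in self.balanced_emus:
            by_size.setdefault(e.size, []).append(e)
        return [sorted(by_size[s]) for s in sorted(by_size)]


@dataclass
class InputLabeling:
    """Isotopic composition of the substrate (carbon-source) metabolites.

    ``mixtures`` maps substrate metabolite id to a list of
    ``(pattern, fraction)`` components.  A pattern is either a 0/1 string
    over the metabolite's carbons (``"100"`` = [1-13C]) or the word
    ``"natural"``, meaning every position is 13C independently with
    probability ``natural_p``.  Fractions must be nonnegative and sum to 1.
    """

    mixtures: dict[str, list[tuple[str, float]]]
    natural_p: float = 0.0107

    def __post_init__(self) -> None:
        for mid, comps in self.mixtures.items():
            total = sum(f for _, f in comps)
            if any(f < 0 for _, f in comps) or abs(total - 1.0) > 1e-9:
                raise ValueError(f"{mid}: mixture fractions must be >= 0 and sum to 1")

    def emu_mid(self, emu: EMU, n_carbons: int) -> np.ndarray:
        """MID of a substrate EMU (length ``size + 1``)."""
        if emu.metabolite not in self.mixtures:
            raise KeyError(f"no labeling specified for substrate {emu.metabolite}")
        mid = np.zeros(emu.size + 1)
        for pattern, frac in self.mixtures[emu.metabolite]:
            if pattern == "natural":
                k = np.arange(emu.size + 1)
                from scipy.stats import binom

                mid += frac * binom.pmf(k, emu.size, self.natural_p)
            else:
                if len(pattern) != n_carbons or set(pattern) - {"0", "1"}:
                    raise ValueError(
                        f"{emu.metabolite}: bad pattern {pattern!r} for "
                        f"{n_carbons} carbons")
                weight = sum(pattern[i - 1] == "1" for i in emu.indices)
                mid[weight] += frac
        return mid

    def isotopomer_distribution(self, mid_id: str, n_carbons: int) -> np.ndarray:
        """Full 2^n positional-isotopomer distribution of a substrate."""
        dist = np.zeros(2 ** n_carbons)
        for pattern, frac in self.mixtures[mid_id]:
            if pattern == "natural":
                p = self.natural_p
                for state in range(2 ** n_carbons):
                    k = bin(state).count("1")
                    dist[state] += frac * p ** k * (1 - p) ** (n_carbons - k)
            else:
                state = sum(1 << (i) for i, ch in enumerate(pattern) if ch == "1")
                dist[state] += frac
        return dist


@dataclass
class MIDVector:
    """Mass fractions M+0 … M+n of one fragment or EMU."""

    id: str
    fractions: np.ndarray

    def __post_init__(self) -> None:
        self.fractions = np.asarray(self.fractions, dtype=float)
        if np.any(self.fractions < -1e-12):
            raise ValueError(f"{self.id}: negative mass fraction")

    @property
    def size(self) -> int:
        return len(self.fractions) - 1


def _directed_reactions(net: MetabolicNetwork):
    """Yield (substrates, products, flux_key) for each flux direction."""
    for r in net.reactions:
        yield r.substrates, r.products, (r.id, "f")
        if r.reversible:
            yield r.products, r.substrates, (r.id, "b")


def _trace_sources(substrates, product_map: str, indices: tuple[int, ...]):
    """Source EMUs (grouped per substrate *occurrence*) feeding the given
    carbon positions of one product occurrence."""
    letter_origin: dict[str, tuple[int, str, int]] = {}
    for occ, (mid, amap) in enumerate(substrates):
        for pos, letter in enumerate(amap, start=1):
            letter_origin[letter] = (occ, mid, pos)
    groups: dict[int, tuple[str, list[int]]] = {}
    for i in indices:
        occ, mid, pos = letter_origin[product_map[i - 1]]
        groups.setdefault(occ, (mid, []))[1].append(pos)
    return tuple(EMU(mid, tuple(pos)) for occ, (mid, pos) in sorted(groups.items()))


def decompose(net: MetabolicNetwork, targets: list[EMU]) -> EMUNetwork:
    """Trace target EMUs back to the substrate inputs (Antoniewicz-style).

    Returns the minimal EMU network whose balance systems, solved by
    increasing size, yield the MIDs of all targets.  Raises
    :class:`ConnectivityError` if a balanced EMU has no producing reaction.
    """
    for t in targets:
        m = net.metabolite(t.metabolite)
        if max(t.indices) > m.n_carbons:
            raise ValueError(f"{t}: carbon index out of range for {m.id}")
    producers: dict[EMU, list[EMUReaction]] = {}
    stack = list(targets)
    seen: set[EMU] = set()
    while stack:
        emu = stack.pop()
        if emu in seen:
            continue
        seen.add(emu)
        role = net.metabolite(emu.metabolite).role
        if role == "substrate":
            continue
        if role == "sink":
            raise ConnectivityError(f"sink metabolite {emu.metabolite} is consumed")
        rxns: list[EMUReaction] = []
        for substrates, products, flux_key in _directed_reactions(net):
            for mid, amap in products:
                if mid != emu.metabolite:
                    continue
                sources = _trace_sources(substrates, amap, emu.indices)
                rxns.append(EMUReaction(emu, sources, flux_key))
                stack.extend(sources)
        if not rxns:
            raise ConnectivityError(f"balanced EMU {emu} has no producing reaction")
        producers[emu] = rxns
    return EMUNetwork(net, tuple(targets), producers)


def convolve(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Discrete convolution of two MIDs (the MID of a condensation)."""
    return np.convolve(np.asarray(a, float), np.asarray(b, float))


def _flux_value(fluxes: FluxVector, key: tuple[str, str]) -> float:
    rid, direction = key
    return fluxes.forward(rid) if direction == "f" else fluxes.backward(rid)


def simulate_mids(
    emunet: EMUNetwork,
    fluxes: FluxVector,
    labeling: InputLabeling,
) -> dict[EMU, np.ndarray]:
    """Steady-state MIDs of every EMU in the network.

    Solves, for each size layer in increasing order, the linear balance
    ``(sum of production fluxes) * X_i = sum_r f_r * (source MID)_r`` over the
    balanced EMUs of that size; condensation sources are convolutions of
    already-solved smaller EMUs.  Same-size cycles (e.g. from reversible
    reactions) are handled exactly because each layer is one linear solve.
    """
    net = emunet.network
    known: dict[EMU, np.ndarray] = {}

    def source_mid(e: EMU) -> np.ndarray:
        if e in known:
            return known[e]
        if net.metabolite(e.metabolite).role == "substrate":
            mid = labeling.emu_mid(e, net.metabolite(e.metabolite).n_carbons)
            known[e] = mid
            return mid
        raise KeyError(e)

    for layer in emunet.layers():
        size = layer[0].size
        n = len(layer)
        idx = {e: i for i, e in enumerate(layer)}
        A = np.zeros((n, n))
        rhs = np.zeros((n, size + 1))
        for e in layer:
            i = idx[e]
            for rxn in emunet.producers[e]:
                f = _flux_value(fluxes, rxn.flux_key)
                if f == 0.0:
                    continue
                A[i, i] -= f
                if len(rxn.sources) == 1 and rxn.sources[0] in idx:
                    A[i, idx[rxn.sources[0]]] += f
                else:
                    mid = reduce(convolve, (source_mid(s) for s in rxn.sources))
                    rhs[i] -= f * mid
        try:
            X = np.linalg.solve(A, rhs)
        except np.linalg.LinAlgError:
            dead = layer[int(np.argmin(np.abs(np.diag(A))))]
            raise DegenerateFluxError(
                f"singular EMU balance in size-{size} layer (near {dead}); "
                "a branch may carry zero flux") from None
        for e in layer:
            known[e] = X[idx[e]]
    # include substrate EMUs referenced only as targets
    for t in emunet.targets:
        if t not in known:
            source_mid(t)
    return known


# ---------------------------------------------------------------------------
# Exhaustive positional-isotopomer oracle
# ---------------------------------------------------------------------------


def _transition_matrix(substrates, product_map: str, n_prod_carbons: int,
                       carbon_counts: dict[str, int]) -> np.ndarray:
    """T mapping the joint substrate isotopomer distribution (Kronecker
    product, first substrate varying slowest) to the product occurrence's
    isotopomer distribution."""
    sub_sizes = [carbon_counts[mid] for mid, _ in substrates]
    letter_origin: dict[str, tuple[int, int]] = {}
    for occ, (mid, amap) in enumerate(substrates):
        for pos, letter in enumerate(amap):
            letter_origin[letter] = (occ, pos)
    T = np.zeros((2 ** n_prod_carbons, int(np.prod([2 ** s for s in sub_sizes]))))
    for col, states in enumerate(itertools.product(
            *[range(2 ** s) for s in sub_sizes])):
        out_state = 0
        for p_pos, letter in enumerate(product_map):
            occ, s_pos = letter_origin[letter]
            if states[occ] >> s_pos & 1:
                out_state |= 1 << p_pos
        T[out_state, col] += 1.0
    return T


def enumerate_isotopomers(
    net: MetabolicNetwork,
    fluxes: FluxVector,
    labeling: InputLabeling,
    targets: list[EMU],
    *,
    cap: int = 12,
    tol: float = 1e-14,
    max_iter: int = 200_000,
) -> dict[EMU, np.ndarray]:
    """Exact MIDs by balancing all 2^n positional isotopomers.

    Independent of the EMU machinery: the full (bilinear, because of
    condensations) isotopomer balance is solved by fixed-point iteration of
    the normalized production map, then marginalized to the requested EMUs'
    MIDs.  Intended as a verification oracle for small networks; refuses
    networks whose balanced metabolites carry more than ``cap`` carbons in
    total.
    """
    balanced = net.balanced_metabolites
    total_carbons = sum(m.n_carbons for m in balanced)
    if total_carbons > cap:
        raise IsotopomerSizeError(
            f"{total_carbons} balanced carbons exceeds the cap of {cap}")
    counts = {m.id: m.n_carbons for m in net.metabolites}

    # precompute, per balanced metabolite: producing terms and total production
    terms: dict[str, list[tuple[float, list[str], np.ndarray]]] = {
        m.id: [] for m in balanced}
    total_prod = {m.id: 0.0 for m in balanced}
    for substrates, products, flux_key in _directed_reactions(net):
        f = _flux_value(fluxes, flux_key)
        if f == 0.0:
            continue
        for mid, amap in products:
            if mid in terms:
                T = _transition_matrix(substrates, amap, counts[mid], counts)
                terms[mid].append((f, [s for s, _ in substrates], T))
                total_prod[mid] += f

    dists: dict[str, np.ndarray] = {}
    for m in net.metabolites:
        if m.role == "substrate":
            dists[m.id] = labeling.isotopomer_distribution(m.id, m.n_carbons)
    current = {m.id: np.full(2 ** m.n_carbons, 1.0 / 2 ** m.n_carbons)
               for m in balanced}
    current[""] = np.ones(1)  # never referenced; keeps dicts homogeneous

    def lookup(mid: str, state: dict[str, np.ndarray]) -> np.ndarray:
        return state[mid] if mid in state else dists[mid]

    for _ in range(max_iter):
        new = {}
        delta = 0.0
        for m in balanced:
            if total_prod[m.id] == 0.0:
                raise DegenerateFluxError(f"metabolite {m.id} has zero production")
            acc = np.zeros(2 ** m.n_carbons)
            for f, sub_ids, T in terms[m.id]:
                joint = reduce(np.kron, (lookup(s, current) for s in sub_ids))
                acc += f * (T @ joint)
            acc /= total_prod[m.id]
            delta = max(delta, float(np.max(np.abs(acc - current[m.id]))))
            new[m.id] = acc
        current.update(new)
        if delta < tol:
            break
    else:
        raise RuntimeError("isotopomer fixed point did not converge")

    out: dict[EMU, np.ndarray] = {}
    for t in targets:
        dist = lookup(t.metabolite, current)
        mid = np.zeros(t.size + 1)
        for state, p in enumerate(dist):
            weight = sum(state >> (i - 1) & 1 for i in t.indices)
            mid[weight] += p
        out[t] = mid
    return out
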