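"""Carbon-atom-mapped metabolic networks.

A network is a set of metabolites (each with a carbon count and a balancing
role) and reactions whose substrates and products carry atom-map strings:
one lowercase letter per carbon, with every letter appearing exactly once on
each side of the reaction.  This is the representation used by
isotope-tracing flux analysis, where the fate of individual carbon positions
— not just stoichiometry — determines the labeling patterns a flux
distribution produces.

The plain-text dialect::

    # comment
    met GLC 6 substrate
    met PYR 3 balanced
    met CO2 1 sink
    v1: GLC (abcdef) -> F6P (abcdef)
    v2: PYR (abc) <-> PEP (abc)        # '<->' marks a reversible reaction

Metabolite roles: ``balanced`` species obey the steady-state balance
S·v = 0; ``substrate`` species are external carbon sources (their labeling
is an input); ``sink`` species absorb effluxes and are exempt from
balancing.  Cofactors without carbon maps may be declared with 0 carbons and
role ``sink``.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import null_space

__all__ = [
    "Metabolite",
    "Reaction",
    "MetabolicNetwork",
    "FluxVector",
    "NetworkParseError",
    "InfeasibleConstraintsError",
    "parse_network",
    "serialize_network",
    "validate_atom_balance",
    "stoichiometric_matrix",
    "free_flux_dimension",
]

ROLES = ("balanced", "substrate", "sink")

DEFAULT_FLUX_BOUND = 1000.0  # mmol g-DCW^-1 h^-1


class NetworkParseError(ValueError):
    """Malformed network text (carries the offending line number)."""


class InfeasibleConstraintsError(ValueError):
    """Equality constraints inconsistent with the steady-state balance."""


@dataclass(frozen=True)
class Metabolite:
    id: str
    n_carbons: int
    role: str = "balanced"

    def __post_init__(self) -> None:
        if self.n_carbons < 0:
            raise ValueError(f"{self.id}: n_carbons must be >= 0")
        if self.role not in ROLES:
            raise ValueError(f"{self.id}: unknown role {self.role!r}")


@dataclass(frozen=True)
class Reaction:
    """One atom-mapped reaction.

    ``substrates`` and ``products`` are lists of ``(metabolite_id, atom_map)``
    pairs; the atom map is a string of lowercase letters, one per carbon, and
    may be empty for carbon-free species.
    """

    id: str
    substrates: tuple[tuple[str, str], ...]
    products: tuple[tuple[str, str], ...]
    reversible: bool = False
    lower: float = 0.0
    upper: float = DEFAULT_FLUX_BOUND

    def __post_init__(self) -> None:
        if self.lower > self.upper:
            raise ValueError(f"{self.id}: lower bound exceeds upper bound")

    def atom_balance_violations(self) -> list[str]:
        """Check that each atom letter occurs exactly once per side."""
        violations: list[str] = []
        for side_name, side in (("substrate", self.substrates),
                                ("product", self.products)):
            letters = "".join(m for _, m in side)
            for ch in set(letters):
                if letters.count(ch) > 1:
                    violations.append(
                        f"{self.id}: letter {ch!r} duplicated on {side_name} side")
        sub_letters = set("".join(m for _, m in self.substrates))
        prod_letters = set("".join(m for _, m in self.products))
        for ch in sorted(sub_letters - prod_letters):
            violations.append(f"{self.id}: substrate letter {ch!r} not placed in products")
        for ch in sorted(prod_letters - sub_letters):
            violations.append(f"{self.id}: product letter {ch!r} has no substrate origin")
        return violations


@dataclass
class MetabolicNetwork:
    metabolites: list[Metabolite] = field(default_factory=list)
    reactions: list[Reaction] = field(default_factory=list)

    def __post_init__(self) -> None:
        ids = [m.id for m in self.metabolites]
        if len(ids) != len(set(ids)):
            raise ValueError("duplicate metabolite ids")
        rids = [r.id for r in self.reactions]
        if len(rids) != len(set(rids)):
            raise ValueError("duplicate reaction ids")
        self._met = {m.id: m for m in self.metabolites}
        for r in self.reactions:
            for mid, amap in list(r.substrates) + list(r.products):
                if mid not in self._met:
                    raise NetworkParseError(
                        f"reaction {r.id}: undeclared metabolite {mid!r}")
                if len(amap) != self._met[mid].n_carbons:
                    raise NetworkParseError(
                        f"reaction {r.id}: atom map {amap!r} does not match "
                        f"{mid} ({self._met[mid].n_carbons} carbons)")

    def metabolite(self, mid: str) -> Metabolite:
        return self._met[mid]

    def reaction(self, rid: str) -> Reaction:
        for r in self.reactions:
            if r.id == rid:
                return r
        raise KeyError(rid)

    @property
    def balanced_metabolites(self) -> list[Metabolite]:
        return [m for m in self.metabolites if m.role == "balanced"]

    @property
    def reaction_ids(self) -> list[str]:
        return [r.id for r in self.reactions]

    @property
    def reversible_ids(self) -> list[str]:
        return [r.id for r in self.reactions if r.reversible]


@dataclass
class FluxVector:
    """Net fluxes per reaction and exchange fluxes per reversible reaction.

    Exchange fluxes quantify bidirectional shuttling: the forward/backward
    rates of a reversible reaction are ``max(net, 0) + exch`` and
    ``max(-net, 0) + exch``.
    """

    net: dict[str, float]
    exchange: dict[str, float] = field(default_factory=dict)

    def forward(self, rid: str) -> float:
        v = self.net[rid]
        return max(v, 0.0) + self.exchange.get(rid, 0.0)

    def backward(self, rid: str) -> float:
        v = self.net[rid]
        return max(-v, 0.0) + self.exchange.get(rid, 0.0)

    def validate(self, net: MetabolicNetwork, atol: float = 1e-6) -> None:
        """Raise if irreversibility, sign, or steady state is violated."""
        for r in net.reactions:
            v = self.net[r.id]
            if not r.reversible and v < -atol:
                raise ValueError(f"irreversible reaction {r.id} has net flux {v}")
        for rid, e in self.exchange.items():
            if e < -atol:
                raise ValueError(f"exchange flux of {rid} is negative")
        S, mets, rids = stoichiometric_matrix(net)
        if len(mets) == 0:
            return
        resid = S @ np.array([self.net[r] for r in rids])
        if np.max(np.abs(resid)) > atol:
            worst = mets[int(np.argmax(np.abs(resid)))]
            raise ValueError(f"steady-state violated at {worst} by {np.max(np.abs(resid)):.3g}")


_MET_RE = re.compile(r"^met\s+(\S+)\s+(\d+)\s+(\S+)\s*$")
_RXN_RE = re.compile(r"^(\S+)\s*:\s*(.+?)\s*(<->|->)\s*(.*)$")
_TERM_RE = re.compile(r"^(\S+)\s*(?:\(([a-z]*)\))?$")


def _parse_side(text: str, rid: str, lineno: int) -> tuple[tuple[str, str], ...]:
    terms = []
    text = text.strip()
    if not text:
        return ()
    for term in text.split("+"):
        m = _TERM_RE.match(term.strip())
        if not m:
            raise NetworkParseError(
                f"line {lineno}: cannot parse term {term.strip()!r} in reaction {rid}")
        terms.append((m.group(1), m.group(2) or ""))
    return tuple(terms)


def parse_network(text: str) -> MetabolicNetwork:
    """Parse the plain-text atom-map dialect into a validated network."""
    metabolites: list[Metabolite] = []
    reactions: list[Reaction] = []
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        m = _MET_RE.match(line)
        if m:
            metabolites.append(Metabolite(m.group(1), int(m.group(2)), m.group(3)))
            continue
        m = _RXN_RE.match(line)
        if m:
            rid, lhs, arrow, rhs = m.groups()
            reactions.append(Reaction(
                id=rid,
                substrates=_parse_side(lhs, rid, lineno),
                products=_parse_side(rhs, rid, lineno),
                reversible=(arrow == "<->"),
                lower=-DEFAULT_FLUX_BOUND if arrow == "<->" else 0.0,
            ))
            continue
        raise NetworkParseError(f"line {lineno}: malformed line {line!r}")
    return MetabolicNetwork(metabolites, reactions)


def serialize_network(net: MetabolicNetwork) -> str:
    """Inverse of :func:`parse_network` (round-trips to an equal network)."""
    lines = [f"met {m.id} {m.n_carbons} {m.role}" for m in net.metabolites]
    for r in net.reactions:
        arrow = "<->" if r.reversible else "->"

        def side(terms):
            return " + ".join(f"{mid} ({amap})" if amap else mid for mid, amap in terms)

        lines.append(f"{r.id}: {side(r.substrates)} {arrow} {side(r.products)}")
    return "\n".join(lines) + "\n"


def validate_atom_balance(net: MetabolicNetwork) -> list[str]:
    """Return all carbon-conservation violations (empty list means valid)."""
    out: list[str] = []
    for r in net.reactions:
        out.extend(r.atom_balance_violations())
    return out


def stoichiometric_matrix(
    net: MetabolicNetwork,
) -> tuple[np.ndarray, list[str], list[str]]:
    """Stoichiometric matrix over balanced metabolites.

    Returns ``(S, metabolite_ids, reaction_ids)`` with ``S[i, j]`` the net
    coefficient of balanced metabolite i in reaction j.  Substrate and sink
    species are excluded: they are not balanced at steady state.
    """
    mets = [m.id for m in net.balanced_metabolites]
    idx = {mid: i for i, mid in enumerate(mets)}
    rids = net.reaction_ids
    S = np.zeros((len(mets), len(rids)))
    for j, r in enumerate(net.reactions):
        for mid, _ in r.substrates:
            if mid in idx:
                S[idx[mid], j] -= 1.0
        for mid, _ in r.products:
            if mid in idx:
                S[idx[mid], j] += 1.0
    return S, mets, rids


def _constraint_system(
    net: MetabolicNetwork,
    equality_constraints: dict[str, float] | list[tuple[str, float]] | None,
) -> tuple[np.ndarray, np.ndarray, list[str]]:
    """Stack S·v = 0 with fixed-flux rows; returns (A, b, reaction_ids)."""
    S, _, rids = stoichiometric_matrix(net)
    rows = [S] if S.size else [np.zeros((0, len(rids)))]
    b = [np.zeros(S.shape[0])]
    if equality_constraints:
        items = (equality_constraints.items()
                 if isinstance(equality_constraints, dict) else equality_constraints)
        pos = {rid: j for j, rid in enumerate(rids)}
        for rid, value in items:
            if rid not in pos:
                raise KeyError(f"unknown reaction {rid!r} in constraint")
            row = np.zeros(len(rids))
            row[pos[rid]] = 1.0
            rows.append(row[None, :])
            b.append(np.array([float(value)]))
    A = np.vstack(rows)
    return A, np.concatenate(b), rids


def free_flux_dimension(
    net: MetabolicNetwork,
    equality_constraints: dict[str, float] | list[tuple[str, float]] | None = None,
    *,
    include_exchange: bool = True,
    rtol: float = 1e-9,
) -> int:
    """Degrees of freedom of the flux model under equality constraints.

    Dimension of the affine solution space of {S·v = 0} ∪ {v_i = c_i}; each
    reversible reaction contributes one additional exchange-flux parameter
    when ``include_exchange`` is true.
    """
    A, b, rids = _constraint_system(net, equality_constraints)
    rank = np.linalg.matrix_rank(A, tol=None)
    # consistency: b must lie in the column space of A
    if np.any(b):
        aug_rank = np.linalg.matrix_rank(np.hstack([A, b[:, None]]))
        if aug_rank > rank:
            raise InfeasibleConstraintsError("equality constraints are inconsistent")
    dim = len(rids) - rank
    if include_exchange:
        dim += len(net.reversible_ids)
    return dim


def null_space_parameterization(
    net: MetabolicNetwork,
    equality_constraints: dict[str, float] | list[tuple[str, float]] | None = None,
) -> tuple[np.ndarray, np.ndarray, list[str]]:
    """Affine parameterization v = v0 + N·theta of the constrained flux space.

    Returns ``(v0, N, reaction_ids)`` where N's columns span the null space of
    the stacked equality system and v0 is a minimum-norm particular solution.
    """
    A, b, rids = _constraint_system(net, equality_constraints)
    v0, residuals, rank, _ = np.linalg.lstsq(A, b, rcond=None)
    if np.linalg.norm(A @ v0 - b) > 1e-6 * max(1.0, np.linalg.norm(b)):
        raise InfeasibleConstraintsError("equality constraints are inconsistent")
    N = null_space(A)
    return v0, N, rids
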