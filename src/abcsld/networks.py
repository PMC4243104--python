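"""Discrete-state mass-action reaction networks.

A :class:`ReactionNetwork` is a list of species, a list of mass-action
reactions with stochastic rate constants, and an integer initial copy-number
state.  Propensities follow the classical combinatorial convention of the
stochastic simulation algorithm: for a reaction with rate constant ``c``,

* zeroth order              ``a = c``
* first order   ``A -> ...``        ``a = c * #A``
* second order  ``A + B -> ...``    ``a = c * #A * #B``
* homodimerization ``2A -> ...``    ``a = c * #A * (#A - 1) / 2``

The factor 1/2 in the homodimerization case counts unordered reactant pairs;
``dimer_convention="full"`` switches to ``c * #A * (#A - 1)`` for
cross-checking against conventions that fold the 1/2 into ``c``.

Two benchmark systems ship as built-ins: a reversible dimerization model
with decay (:func:`build_system1`) and a prokaryotic auto-regulatory gene
network (:func:`build_system2`).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np
import yaml

__all__ = [
    "Species",
    "Reaction",
    "ReactionNetwork",
    "propensity",
    "build_system1",
    "build_system2",
    "load_network",
    "save_network",
]

_MAX_MOLECULARITY = 2


@dataclass(frozen=True)
class Species:
    """A chemical species: a unique name and its position in the state vector."""

    name: str
    index: int


@dataclass(frozen=True)
class Reaction:
    """One mass-action reaction channel.

    Parameters
    ----------
    reactants, products
        Maps species name -> stoichiometric coefficient (non-negative int).
        Missing species have coefficient 0.
    rate_constant
        Stochastic rate constant ``c`` (per-time units appropriate to the
        reaction order).
    """

    reactants: dict[str, int]
    products: dict[str, int]
    rate_constant: float

    def __post_init__(self) -> None:
        if not self.reactants and not self.products:
            raise ValueError("reaction must have at least one reactant or product")
        if self.rate_constant < 0:
            raise ValueError(f"rate constant must be >= 0, got {self.rate_constant}")
        for side in (self.reactants, self.products):
            for name, coef in side.items():
                if coef < 0 or coef != int(coef):
                    raise ValueError(f"stoichiometry of {name!r} must be a non-negative integer")
        if sum(self.reactants.values()) > _MAX_MOLECULARITY:
            raise ValueError("total reactant molecularity must be <= 2")

    def __str__(self) -> str:
        def side(s: dict[str, int]) -> str:
            if not s:
                return "0"
            return " + ".join(f"{c} {n}" if c != 1 else n for n, c in s.items())

        return f"{side(self.reactants)} -> {side(self.products)} @ {self.rate_constant:g}"


@dataclass
class ReactionNetwork:
    """Species, reactions and initial state of a mass-action jump process."""

    species: list[Species]
    reactions: list[Reaction]
    initial_state: np.ndarray
    dimer_convention: str = "half"

    # dense stoichiometry matrices, built in __post_init__
    reactant_matrix: np.ndarray = field(init=False, repr=False)
    change_matrix: np.ndarray = field(init=False, repr=False)
    # compact per-reaction reactant lists for the simulation kernels:
    # (species index, stoichiometric order), -1-padded, species in index order
    reactant_idx: np.ndarray = field(init=False, repr=False)
    reactant_ord: np.ndarray = field(init=False, repr=False)

    def __post_init__(self) -> None:
        names = [s.name for s in self.species]
        if len(set(names)) != len(names):
            raise ValueError("species names must be unique")
        if [s.index for s in self.species] != list(range(len(names))):
            raise ValueError("species indices must be contiguous from 0")
        if self.dimer_convention not in ("half", "full"):
            raise ValueError("dimer_convention must be 'half' or 'full'")
        self.initial_state = np.asarray(self.initial_state, dtype=np.int64)
        if self.initial_state.shape != (len(names),):
            raise ValueError("initial_state length must equal species count")
        if (self.initial_state < 0).any():
            raise ValueError("initial_state must be non-negative")
        index = {n: i for i, n in enumerate(names)}
        n_r, n_s = len(self.reactions), len(names)
        self.reactant_matrix = np.zeros((n_r, n_s), dtype=np.int64)
        self.change_matrix = np.zeros((n_r, n_s), dtype=np.int64)
        for j, rxn in enumerate(self.reactions):
            for side, sign in ((rxn.reactants, -1), (rxn.products, +1)):
                for name, coef in side.items():
                    if name not in index:
                        raise ValueError(f"reaction {j} references unknown species {name!r}")
                    if sign < 0:
                        self.reactant_matrix[j, index[name]] = coef
                    self.change_matrix[j, index[name]] += sign * coef
        self.reactant_idx = np.full((n_r, 2), -1, dtype=np.int64)
        self.reactant_ord = np.zeros((n_r, 2), dtype=np.int64)
        for j in range(n_r):
            slot = 0
            for s in range(n_s):
                coef = self.reactant_matrix[j, s]
                if coef > 0:
                    self.reactant_idx[j, slot] = s
                    self.reactant_ord[j, slot] = coef
                    slot += 1

    @property
    def species_names(self) -> list[str]:
        return [s.name for s in self.species]

    @property
    def rate_constants(self) -> np.ndarray:
        return np.array([r.rate_constant for r in self.reactions], dtype=float)

    @property
    def n_species(self) -> int:
        return len(self.species)

    @property
    def n_reactions(self) -> int:
        return len(self.reactions)

    def with_rates(self, rates: np.ndarray) -> "ReactionNetwork":
        """Return a copy of the network with the rate constants replaced.

        The inference drivers use this to evaluate a parameter proposal on a
        network whose structure is known but whose rates are not.
        """
        rates = np.asarray(rates, dtype=float)
        if rates.shape != (self.n_reactions,):
            raise ValueError(f"expected {self.n_reactions} rates, got {rates.shape}")
        reactions = [
            Reaction(r.reactants, r.products, c) for r, c in zip(self.reactions, rates)
        ]
        return ReactionNetwork(
            self.species, reactions, self.initial_state.copy(), self.dimer_convention
        )


def propensity(network: ReactionNetwork, state: np.ndarray, reaction_index: int) -> float:
    """Mass-action propensity of one reaction channel in the given state."""
    state = np.asarray(state)
    if (state < 0).any():
        raise ValueError("state must be non-negative")
    rxn = network.reactions[reaction_index]
    dimer_factor = 0.5 if network.dimer_convention == "half" else 1.0
    a = rxn.rate_constant
    row = network.reactant_matrix[reaction_index]
    for i, coef in enumerate(row):
        n = state[i]
        if coef == 1:
            a *= n
        elif coef == 2:
            a *= n * (n - 1) * dimer_factor
    return float(a)


def build_system1(dimer_convention: str = "half") -> ReactionNetwork:
    """Reversible-dimerization benchmark: 3 species, 4 reactions.

    S1 decays, two S1 form a dimer S2 (reversibly), and S2 converts to S3.
    Initial state (10000, 0, 0), rate constants (0.1, 0.002, 0.5, 0.04).
    """
    species = [Species("S1", 0), Species("S2", 1), Species("S3", 2)]
    reactions = [
        Reaction({"S1": 1}, {}, 0.1),
        Reaction({"S1": 2}, {"S2": 1}, 0.002),
        Reaction({"S2": 1}, {"S1": 2}, 0.5),
        Reaction({"S2": 1}, {"S3": 1}, 0.04),
    ]
    return ReactionNetwork(species, reactions, np.array([10000, 0, 0]), dimer_convention)


def build_system2(r7_product: str = "P2", dimer_convention: str = "half") -> ReactionNetwork:
    """Prokaryotic auto-regulatory gene network: 5 species, 8 reactions.

    Protein dimers repress transcription of their own gene by binding the
    promoter (R1/R2); R3 is transcription, R4 mRNA decay, R5/R6 the
    protein/dimer interchange, R7 translation, R8 protein decay.

    The printed source reaction list has R7 producing the dimer P2 directly
    (``mRNA -> mRNA + P2``) while the surrounding narrative describes R7 as
    translation producing protein P.  The default follows the printed list;
    pass ``r7_product="P"`` for the narrative reading.  Initial state
    (DNA, mRNA, P, P2, DNA.P2) = (10, 100, 100, 800, 100), rate constants
    (0.1, 0.7, 0.35, 0.01, 0.1, 0.9, 0.2, 0.01).
    """
    if r7_product not in ("P", "P2"):
        raise ValueError("r7_product must be 'P' or 'P2'")
    names = ["DNA", "mRNA", "P", "P2", "DNA.P2"]
    species = [Species(n, i) for i, n in enumerate(names)]
    reactions = [
        Reaction({"DNA": 1, "P2": 1}, {"DNA.P2": 1}, 0.1),
        Reaction({"DNA.P2": 1}, {"DNA": 1, "P2": 1}, 0.7),
        Reaction({"DNA": 1}, {"DNA": 1, "mRNA": 1}, 0.35),
        Reaction({"mRNA": 1}, {}, 0.01),
        Reaction({"P": 2}, {"P2": 1}, 0.1),
        Reaction({"P2": 1}, {"P": 2}, 0.9),
        Reaction({"mRNA": 1}, {"mRNA": 1, r7_product: 1}, 0.2),
        Reaction({"P": 1}, {}, 0.01),
    ]
    return ReactionNetwork(species, reactions, np.array([10, 100, 100, 800, 100]), dimer_convention)


# ---------------------------------------------------------------------------
# serialization: a small YAML/JSON-compatible schema
#
#   species: [S1, S2, S3]
#   initial_state: [10000, 0, 0]
#   reactions:
#     - "S1 -> 0 @ 0.1"                      # string form, or
#     - {reactants: {S1: 2}, products: {S2: 1}, rate: 0.002}
# ---------------------------------------------------------------------------

_ARROW = re.compile(r"^(?P<lhs>.*?)->(?P<rhs>.*?)@(?P<rate>.*)$")


def _parse_side(text: str) -> dict[str, int]:
    text = text.strip()
    if text in ("", "0", "()"):
        return {}
    out: dict[str, int] = {}
    for term in text.split("+"):
        term = term.strip()
        m = re.match(r"^(\d+)\s*(\S+)$", term)
        if m:
            coef, name = int(m.group(1)), m.group(2)
        else:
            coef, name = 1, term
        out[name] = out.get(name, 0) + coef
    return out


def _parse_reaction(spec) -> Reaction:
    if isinstance(spec, str):
        m = _ARROW.match(spec)
        if not m:
            raise ValueError(f"cannot parse reaction {spec!r}; expected 'reactants -> products @ rate'")
        return Reaction(_parse_side(m.group("lhs")), _parse_side(m.group("rhs")), float(m.group("rate")))
    return Reaction(dict(spec.get("reactants", {})), dict(spec.get("products", {})), float(spec["rate"]))


def network_from_dict(data: dict) -> ReactionNetwork:
    species = [Species(str(n), i) for i, n in enumerate(data["species"])]
    reactions = [_parse_reaction(r) for r in data["reactions"]]
    return ReactionNetwork(
        species,
        reactions,
        np.asarray(data["initial_state"], dtype=np.int64),
        data.get("dimer_convention", "half"),
    )


def network_to_dict(network: ReactionNetwork) -> dict:
    return {
        "species": network.species_names,
        "initial_state": [int(x) for x in network.initial_state],
        "reactions": [
            {"reactants": dict(r.reactants), "products": dict(r.products), "rate": float(r.rate_constant)}
            for r in network.reactions
        ],
        "dimer_convention": network.dimer_convention,
    }


def load_network(path) -> ReactionNetwork:
    """Read a network from a YAML (or JSON, a YAML subset) file."""
    with open(path) as fh:
        return network_from_dict(yaml.safe_load(fh))


def save_network(network: ReactionNetwork, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(network_to_dict(network), fh, sort_keys=False)
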