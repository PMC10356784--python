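import numpy as np
import pytest

from covrecon.model_io import MetabolicModel, Metabolite, Reaction
from covrecon.synthetic import KineticModel, KineticReaction


def random_stable_jacobian(n: int, rng: np.random.Generator, density: float = 0.4) -> np.ndarray:
    """Sparse random J made Hurwitz by diagonal dominance."""
    J = rng.normal(size=(n, n)) * (rng.uniform(size=(n, n)) < density)
    np.fill_diagonal(J, 0.0)
    np.fill_diagonal(J, -(np.abs(J).sum(axis=1) + rng.uniform(0.5, 1.5, n)))
    return J


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def chain2_model() -> KineticModel:
    """inflow -> A -> B -> outflow, all rate constants 1 (steady state A=B=1)."""
    return KineticModel(
        species=["A", "B"],
        reactions=[
            KineticReaction("in", {}, {"A": 1.0}, "k_in"),
            KineticReaction("ab", {"A": 1.0}, {"B": 1.0}, "k_ab"),
            KineticReaction("out", {"B": 1.0}, {}, "k_out"),
        ],
        parameters={"k_in": 1.0, "k_ab": 1.0, "k_out": 1.0},
    )


@pytest.fixture
def toy_metabolic_model() -> MetabolicModel:
    """Five metabolites, four reactions, mixed reversibility and genes."""
    mets = [Metabolite(id=f"{x}_c", name=x.upper(), compartment="c")
            for x in ("glc", "g6p", "f6p", "pyr", "atp")]
    rxns = [
        Reaction("HEX1", {"glc_c": -1, "atp_c": -1, "g6p_c": 1}, reversible=False,
                 gene_association=["g_hex"], name="hexokinase"),
        Reaction("PGI", {"g6p_c": -1, "f6p_c": 1}, reversible=True,
                 gene_association=["g_pgi"], name="isomerase"),
        Reaction("LOWER", {"f6p_c": -1, "pyr_c": 2}, reversible=False,
                 gene_association=["g_low1", "g_low2"], name="lower glycolysis"),
        Reaction("PYRSINK", {"pyr_c": -1, "atp_c": 1}, reversible=False,
                 gene_association=[], name="sink"),
    ]
    return MetabolicModel(metabolites=mets, reactions=rxns, id="toy")
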