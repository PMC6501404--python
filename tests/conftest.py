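import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))

from seraflux import synthetic
from seraflux.model import Gpr, MetabolicModel, Reaction


@pytest.fixture(scope="session")
def toy_core():
    return synthetic.make_toy_core_model()


@pytest.fixture(scope="session")
def core_rpkm():
    return synthetic.make_core_expression_profiles(seed=0)


def build_chain(length: int = 3, uptake: float = 10.0, with_genes: bool = True) -> MetabolicModel:
    """Linear pathway EX -> T -> R1..R(length) -> biomass; analytic Z = uptake."""
    m = MetabolicModel(id="chain")
    m.add_reaction(Reaction("EX_s", {"s_e": -1, "s_b": 1}, -uptake, 1000, subsystem="Exchange"))
    m.add_reaction(
        Reaction("T_s", {"s_e": -1, "c1_c": 1}, 0, 1000, subsystem="Transportation",
                 gpr=Gpr.gene_("gT") if with_genes else None)
    )
    for i in range(1, length + 1):
        m.add_reaction(
            Reaction(f"R{i}", {f"c{i}_c": -1, f"c{i+1}_c": 1}, 0, 1000, subsystem="Chain",
                     gpr=Gpr.gene_(f"g{i}") if with_genes else None)
        )
    m.add_reaction(Reaction("BIOMASS", {f"c{length+1}_c": -1}, 0, 1000, subsystem="Biomass"))
    m.objective_reaction_id = "BIOMASS"
    m.validate()
    return m


def build_diamond(uptake: float = 10.0) -> MetabolicModel:
    """Two equivalent parallel branches between source and sink."""
    m = MetabolicModel(id="diamond")
    m.add_reaction(Reaction("EX_s", {"s_e": -1, "s_b": 1}, -uptake, 1000, subsystem="Exchange"))
    m.add_reaction(Reaction("T_s", {"s_e": -1, "u_c": 1}, 0, 1000, gpr=Gpr.gene_("gT")))
    m.add_reaction(Reaction("RA", {"u_c": -1, "w_c": 1}, 0, 1000, gpr=Gpr.gene_("gA")))
    m.add_reaction(Reaction("RB", {"u_c": -1, "w_c": 1}, 0, 1000, gpr=Gpr.gene_("gB")))
    m.add_reaction(Reaction("BIOMASS", {"w_c": -1}, 0, 1000))
    m.objective_reaction_id = "BIOMASS"
    m.validate()
    return m


@pytest.fixture
def chain3():
    return build_chain(3)


@pytest.fixture
def diamond():
    return build_diamond()
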