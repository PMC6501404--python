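"""In-text fixtures: the iSR929 biomass composition and minimal medium.

These are the worked inputs printed in the model's description: the full
biomass equation (modified from the *E. coli* composition for *Serratia*
growth, with growth-associated ATP hydrolysis of 45.7318 mmol/gDW) and the
defined minimal-medium component list used for all simulations.
"""

from __future__ import annotations

from .model import MediumSpec

__all__ = [
    "ISR929_BIOMASS_EQUATION",
    "MINIMAL_MEDIUM_COMPONENTS",
    "GLUCOSE_UPTAKE_BATCH",
    "minimal_medium",
]

#: Experimentally observed glucose uptake rate for batch growth (mmol/gDW/h).
GLUCOSE_UPTAKE_BATCH = 10.53

#: Minimal-medium components beside the carbon source: water, ammonia,
#: sulfate, phosphate, calcium, iron (the printed token is "fe3"),
#: hydrogen sulfide, potassium, magnesium, pantothenate, and nicotinate
#: D-ribonucleotide.
MINIMAL_MEDIUM_COMPONENTS = (
    "h2o",
    "nh4",
    "so4",
    "pi",
    "ca2",
    "fe3",
    "h2s",
    "k",
    "mg2",
    "pnto-r",
    "nmn",
)

ISR929_BIOMASS_EQUATION = (
    "0.05 5mthf + 5.0E-5 accoa + 0.488 ala_L + 0.0010 amp + 0.281 arg_L + "
    "0.229 asn_L + 0.229 asp_L + 45.7318 atp + 1.29E-4 clpn_SM + 6.0E-6 coa + "
    "0.126 ctp + 0.087 cys_L + 0.0247 datp + 0.0254 dctp + 0.0254 dgtp + "
    "0.0247 dttp + 1.0E-5 fad + 0.25 gln_L + 0.25 glu_L + 0.582 gly + "
    "0.154 glycogen + 0.203 gtp + 45.5608 h2o + 0.09 his_L + 0.276 ile_L + "
    "0.428 leu_L + 0.0084 lps_SM + 0.326 lys_L + 0.146 met_L + 0.00215 nad + "
    "5.0E-5 nadh + 1.3E-4 nadp + 4.0E-4 nadph + 0.001935 pe_SM + "
    "0.0276 peptido_SM + 4.64E-4 pg_SM + 0.176 phe_L + 0.21 pro_L + "
    "5.2E-5 ps_SM + 0.035 ptrc + 0.205 ser_L + 0.0070 spmd + 3.0E-6 succoa + "
    "0.241 thr_L + 0.054 trp_L + 0.131 tyr_L + 0.0030 udpg + 0.136 utp + "
    "0.402 val_L --> 45.5608 adp + 45.56035 h + 45.5628 pi + 0.7302 ppi + Biomass"
)


def minimal_medium(
    carbon_source: str = "glc",
    uptake: float = GLUCOSE_UPTAKE_BATCH,
    component_rate: float = 1000.0,
) -> MediumSpec:
    """The defined minimal medium with a chosen carbon source and uptake.

    Non-carbon components are left effectively unconstrained (rate 1000);
    only the carbon source uptake is pinned to its measured value.
    """
    components = {mid: component_rate for mid in MINIMAL_MEDIUM_COMPONENTS}
    components[carbon_source] = uptake
    return MediumSpec(components=components, carbon_source=carbon_source)
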